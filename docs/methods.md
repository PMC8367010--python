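# Methods

## Model and estimation

An ordinal series `y_1..y_n` with categories `1..m` is represented by the
indicator vector `Y_t = (Y_t1, .., Y_tq)`, `q = m − 1`, dropping category
`m` as reference. Conditional on the history, the cumulative-logit
(proportional-odds) model sets

    logit P(Y_t ≤ j | F_{t−1}) = η_tj = α_j + β′ z_{t−1},  j = 1..q,

with strictly ordered thresholds `α_1 < … < α_q` and a shared slope `β`
on covariates known before `Y_t` (external series and/or lagged category
indicators). The predictor is always `α_j + β′z`; generators or users who
want minus signs on the slopes (as in a latent-variable formulation
`X_t = −β′z + e`) pass negated covariate columns instead. This keeps one
canonical form throughout the engine.

Inference uses the partial likelihood — the product of one-step
conditional category probabilities — so lagged responses are handled
exactly like any other covariate. The score of an observation is

    s_t(θ) = Z_{t−1} D_t′ Σ_t^{−1} (Y_t − π_t),

where `Z_{t−1}` is the p×q block stacking the q×q identity over repeated
covariate rows, `D_t` is the Jacobian of the response function
h(η) = (F(η_1), F(η_2) − F(η_1), …) (lower bidiagonal in the orientation
`D[i,j] = ∂h_i/∂η_j`, which is why the transpose appears in the product),
and `Σ_t` is the conditional covariance of the indicator vector. The sum
of the `s_t` is exactly the gradient of the log partial likelihood; the
test suite verifies this identity by central finite differences on
randomized instances, which pins down the orientation unambiguously.

Fitting is Fisher scoring with the conditional information
`G_n = Σ_t Z D′Σ^{−1}D Z′`, step-halving (max 20 halvings) on steps that
decrease the likelihood, violate the threshold order, or produce
non-finite values, and convergence declared at `‖S_n(θ̂)‖_∞ < 1e−8`
(max 100 iterations). Initial values are the logits of the empirical
cumulative frequencies with zero slopes; every category must occur at
least once or the thresholds are unidentified and fitting refuses to
start. Iterates whose norm exceeds 1e4 raise a separation error.
Threshold ordering is enforced by step rejection rather than
reparameterization so the estimate stays in the coordinates the score
process is built in.

Numerical choices: `Σ_t` is never inverted explicitly — each q×q system
is solved per observation (batched); probabilities are clipped at 1e−12
inside log evaluations only, so an extreme fit yields a very negative but
finite likelihood while the same degeneracy inside a covariance
computation raises an error naming the offending time point; the inverse
square root of the score-variance estimate uses a symmetric
eigendecomposition with an eigenvalue floor of 1e−10, below which a
rank-deficiency error names the null-space components.

## Score-variance normalizer

The limiting variance of `n^{−1/2}S_k` is estimated by

* `outer` (default): `(1/n) Σ_t s_t(θ̂) s_t(θ̂)′`, the per-observation
  outer-product estimator a score test constructs directly, or
* `model`: `G_n(θ̂)/n`.

The literal expression `(1/n)S_n(θ̂)S_n(θ̂)′` is identically zero at the
MPLE, so it cannot be the intended normalizer; the outer-product reading
is the one consistent with the score-test construction, and both variants
estimate the same limit under correct specification (the tests check they
agree within 15% in spectral norm at n = 2000). The choice is exposed
because published simulation results of this kind rarely state which
variant was computed; all rates reported here use `outer`.

## Test statistics and critical values

Under parameter stability the standardized path
`k ↦ n^{−1/2} T̂^{−1/2} S_k(θ̂)` converges to a vector of independent
Brownian bridges; it is pinned to zero at `k = n` by construction because
the full-sample score vanishes at the estimate.

**W1** takes, per tested component `i`, `max_k |path_k,i|`, and rejects
when any tested component reaches `C(α*)`,
`α* = 1 − (1−α)^{1/j}` for `j` tested components. This component-wise
reading (rather than a max over the Euclidean norm) is what makes the
joint rejection rate factorize as
`1 − W1 = (1 − W1^{(1)})(1 − W1^{(2)})`, a relation the simulation study
reproduces. `C` solves `P(sup|B(u)| ≥ x) = α*` using the alternating
series `2 Σ_{k≥1} (−1)^{k+1} e^{−2k²x²}` (terms summed until < 1e−14)
inverted by Brent's method on (1e−6, 10).

**W2** takes `max_{l<k/n<u} ‖ξ_k‖²/((k/n)(1−k/n))` over the tested
sub-vector. The path rows already carry `n^{−1/2}`, so squaring supplies
the `n^{−1}` scaling. Its critical value inverts the classical large-x
tail approximation for `sup_{l<t<u} Σ_i B_i²(t)/(t(1−t))`,

    x^{j/2} e^{−x/2} / (2^{j/2}Γ(j/2)) · {(1 − j/x)·log((1−l)u/(l(1−u))) + 4/x},

by bisection on (j+1, 200). The approximation is asymptotic in `x` and
only used for `x > j`; at level 0.05 with j = 2 and window (0.05, 0.95)
it gives 13.08 (≈ 13.1). A Monte-Carlo cross-check against discretized
bridge paths in the test suite confirms both tail formulas. Critical
values are always computed at call time; nothing is tabulated. Window
default (l, u) = (0.05, 0.95).

## Localization and segmentation

After a rejection, `k̂*` is the smallest index attaining the maximum
absolute standardized score of the flagged component (first-max
tie-break); with several tested components, the component with the
largest maximum drives localization — the same one a per-component
diagnosis would name. `k̂*` is reported 1-based as the last index of the
pre-change segment. Binary segmentation retests each side of a split
recursively, refitting the model (and its normalizer) per segment,
stopping when a segment accepts, falls below `2·min_seg` observations
(default `min_seg = 30`), or fails to refit; no level correction is
applied across recursion depth. Split points are clipped so that no
unfittable fragment shorter than `min_seg` is created.

## Synthetic data generator

The stock generator draws a 3-category series from

    logit P(Y_t ≤ j) = α_j − β₁ cos(2πt/12) − β₂ Y_{(t−1)1} − β₃ Y_{(t−1)2}

with baseline θ₀ = (−0.5, 0.2, 2, 0.5, 1), i.e. a seasonal cycle of
period 12 plus first-order category feedback, the regime switching to
θ* after a chosen k*. Stock alternatives shift α₁ → −1 and/or β₁ → 3.
The pre-sample state `Y_0` is the reference category (both lag indicators
zero) and sampling starts at t = 1 so the cosine phase is anchored to the
calendar index; an optional burn-in prepends discarded transitions at
t ≤ 0 without moving that phase. Because the covariate vector takes only
12 cosine phases × 3 lag states per regime, the sequential draw runs off
a precomputed cumulative-probability table built through the same
`category_probs` code the estimator uses. A piecewise variant chains any
number of regimes for multi-change experiments.

What the generator does not emulate: covariate misspecification, ordinal
scales with m ≠ 3, gradual (non-abrupt) drifts, missing observations, or
overdispersion beyond the model. Passing Monte-Carlo checks therefore
demonstrates correctness of the method under its own model, not
robustness to violations of it.

## Monte-Carlo experiments

Size and power experiments run 1000 replicates of length-1000 series
(defaults; both configurable), fit each replicate, and reject per the
rules above with components (α₁, β₁): the component-wise rates use
`C(α*)` with `α* = 1 − 0.95^{1/2}`, the joint W1 rejects if either
component does, and W2 uses its asymptotic critical value on the same two
components. Power experiments reuse the null (asymptotic) critical
values. Per-replicate RNG streams are spawned from one master seed, so
tables are bit-for-bit reproducible; replicates whose fit fails are
dropped and counted (a warning fires above 5% failures — in practice none
fail at these settings). With the vectorized fitter one experiment takes
roughly ten seconds on one CPU, which is why the full 1000-replicate
studies are run directly in the acceptance suite rather than scaled-down
surrogates.

## Worked-application pipeline

`run_analysis` mirrors the workflow used for ordinal clinical series such
as newborn sleep-state recordings: fit the full model (optionally after
recoding raw labels onto an explicit ordinal scale, e.g. awake < quiet <
indeterminate < active, via `category_order`, with lagged indicators as
covariates via `lag_design`), run the joint stability test over all p
parameters, diagnose per component with the j = 1 critical value, locate
the change through the dominant component, and compare the split model
(both sides refitted; AIC counts both segments' parameters, 2p, against
the summed segment log-likelihoods) with the single-regime fit. The AIC
parameter-counting convention is stated here explicitly because reported
analyses often leave it implicit.

## Known limitations

* Logit link only; no category-specific slopes (non-proportional odds),
  no missing data, no regularized or sandwich-robust variants beyond the
  two normalizer choices.
* The W2 critical value relies on an asymptotic tail expansion; at small
  `x` (light trimming, few components, large α) the approximation
  degrades, and the implementation refuses `x ≤ j` rather than
  extrapolate.
* Binary segmentation inherits the level of each single test; with many
  recursive tests the family-wise error is not controlled.
* Localization of a change in a component with a weak shift is noisy
  (median error on the order of tens of observations at n = 1000 for
  moderate shifts); the consistency of `k̂*` is asymptotic in both n and
  the shift size.
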