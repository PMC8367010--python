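"""Exception hierarchy for ordcpt.

All errors raised by the library derive from :class:`OrdcptError` so callers
can catch everything with a single except clause; numerical failures are kept
distinct from usage errors for exit-code mapping in the CLI.
"""


class OrdcptError(Exception):
    """Base class for all ordcpt errors."""


class InvalidInputError(OrdcptError, ValueError):
    """Malformed data, indices or options supplied by the caller."""


class InvalidParameterError(OrdcptError, ValueError):
    """Parameter vector violates its constraints (e.g. unordered thresholds)."""


class DegenerateProbabilityError(OrdcptError, FloatingPointError):
    """A fitted category probability underflowed, making the conditional
    covariance numerically singular."""

    def __init__(self, t: int, msg: str | None = None):
        self.t = t
        super().__init__(msg or f"degenerate category probability at t={t}")


class SingularNormalizerError(OrdcptError, FloatingPointError):
    """The score-variance estimate is rank deficient on the tested components."""


class ConvergenceError(OrdcptError, RuntimeError):
    """Optimizer failed to converge; carries the last iterate."""

    def __init__(self, msg: str, last_params=None, n_iter: int | None = None):
        self.last_params = last_params
        self.n_iter = n_iter
        super().__init__(msg)


class SeparationError(ConvergenceError):
    """Parameter estimates diverged (quasi-complete separation)."""
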