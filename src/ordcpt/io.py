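"""Reading ordinal series, analysis configuration, and the end-to-end
fit -> test -> locate -> refit pipeline.

The file format is delimited text with a header: an optional ``t`` column
(1-based, consecutive), an integer ``y`` column, then any covariate
columns.  For autoregressive designs the reader can build the lagged
category indicators ``Y_{(t-1)1} .. Y_{(t-1)q}`` from the response itself;
the first usable observation is then t = 2.  An explicit category order
(e.g. awake < quiet < indeterminate < active for newborn sleep states)
recodes raw labels onto ranks 1..m before fitting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .changepoint import locate_changepoint
from .estimation import fit_mple
from .exceptions import InvalidInputError
from .model import CovariateSeries, OrdinalSeries
from .score_tests import score_process, w1_statistic, w2_statistic


def read_series(
    path,
    m: int,
    covariate_cols: list[str] | None = None,
    lag_design: bool = False,
    category_order: list[int] | None = None,
    sep: str | None = None,
) -> tuple[OrdinalSeries, CovariateSeries]:
    """Load a series (and covariates) from CSV/TSV.

    ``category_order`` lists the raw codes from lowest to highest ordinal
    rank; raw code ``category_order[j-1]`` becomes category j.  With
    ``lag_design`` the q = m - 1 indicator columns of the previous
    response are appended as covariates and the first row is dropped.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if "y" not in df.columns:
        raise InvalidInputError(f"{path}: no 'y' column in header {list(df.columns)}")
    if df.isna().any().any():
        raise InvalidInputError(f"{path}: missing values are not supported")
    if "t" in df.columns:
        t = df["t"].to_numpy()
        if not np.array_equal(t, np.arange(t[0], t[0] + len(t))):
            raise InvalidInputError(f"{path}: 't' column must be consecutive")
    y_raw = df["y"].to_numpy()
    if not np.issubdtype(y_raw.dtype, np.integer):
        if not np.allclose(y_raw, np.round(y_raw)):
            raise InvalidInputError(f"{path}: 'y' must be integer categories")
        y_raw = np.round(y_raw).astype(np.int64)
    if category_order is not None:
        if sorted(category_order) != sorted(set(int(v) for v in y_raw)) or len(category_order) != m:
            raise InvalidInputError(
                f"category_order {category_order} does not match observed codes"
            )
        rank = {code: j + 1 for j, code in enumerate(category_order)}
        y = np.array([rank[v] for v in y_raw], dtype=np.int64)
    else:
        y = y_raw.astype(np.int64)
    bad = np.where((y < 1) | (y > m))[0]
    if bad.size:
        raise InvalidInputError(
            f"{path}: category codes outside 1..{m} at rows {(bad + 2).tolist()[:10]} "
            "(1-based, counting the header)"
        )
    cols = []
    if covariate_cols:
        missing = [c for c in covariate_cols if c not in df.columns]
        if missing:
            raise InvalidInputError(f"{path}: covariate columns {missing} not found")
        cols.append(df[covariate_cols].to_numpy(dtype=float))
    if lag_design:
        q = m - 1
        ind = np.zeros((len(y), q))
        j = y - 1
        keep = j < q
        ind[np.nonzero(keep)[0], j[keep]] = 1.0
        lag = ind[:-1]  # indicator of y_{t-1}, aligned with y_t for t >= 2
        y = y[1:]
        cols = [c[1:] for c in cols]
        cols.append(lag)
    z = np.hstack(cols) if cols else np.zeros((len(y), 0))
    return OrdinalSeries(y, m), CovariateSeries(z)


def write_series(path, series: OrdinalSeries, cov: CovariateSeries | None = None,
                 covariate_names: list[str] | None = None) -> None:
    """Round-trippable CSV/TSV writer (counterpart of read_series)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    data = {"t": np.arange(1, series.n + 1), "y": series.y}
    if cov is not None and cov.d:
        names = covariate_names or [f"z{i + 1}" for i in range(cov.d)]
        for i, name in enumerate(names):
            data[name] = cov.z[:, i]
    pd.DataFrame(data).to_csv(path, sep=sep, index=False)


@dataclass
class AnalysisConfig:
    """Configuration for the end-to-end change-point analysis."""

    m: int
    covariate_cols: list[str] = field(default_factory=list)
    lag_design: bool = False
    category_order: list[int] | None = None
    alpha: float = 0.05
    stat: str = "w1"
    components: list[str] | None = None  # None = all parameters
    window: tuple[float, float] = (0.05, 0.95)
    tau_method: str = "outer"
    min_seg: int = 30
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        path = Path(path)
        with open(path) as fh:
            raw = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
        cfg = cls(**raw)
        if cfg.stat not in ("w1", "w2"):
            raise InvalidInputError(f"stat must be 'w1' or 'w2', got {cfg.stat!r}")
        return cfg


def run_analysis(
    series: OrdinalSeries,
    cov: CovariateSeries,
    config: AnalysisConfig,
) -> dict:
    """Full pipeline on one series: joint stability test over all
    parameters, per-component diagnosis, localization, and a split
    vs. no-split model comparison by AIC.

    The split model refits each side of the located change; its AIC counts
    both segments' parameters (2p) against the summed segment
    log-likelihoods.
    """
    fitted = fit_mple(series, cov, tau_method=config.tau_method)
    proc = score_process(fitted, series, cov)
    joint_w1 = w1_statistic(proc, config.components, alpha=config.alpha)
    joint_w2 = w2_statistic(
        proc, config.components, l=config.window[0], u=config.window[1],
        alpha=config.alpha,
    )
    # per-component diagnosis at the plain level (j = 1 critical value)
    diagnosis = [
        w1_statistic(proc, [name], alpha=config.alpha).to_dict()
        for name in proc.param_names
    ]
    report = {
        "fit": fitted.summary_dict(),
        "joint_tests": {"w1": joint_w1.to_dict(), "w2": joint_w2.to_dict()},
        "component_tests": diagnosis,
        "changepoint": None,
        "split_comparison": None,
    }
    primary = joint_w1 if config.stat == "w1" else joint_w2
    if not primary.rejected:
        return report

    flagged = [d for d in diagnosis if d["rejected"]]
    if flagged:
        top = max(flagged, key=lambda d: d["value"])
    else:  # joint rejection without a single dominant component
        top = max(diagnosis, key=lambda d: d["value"])
    comp_name = top["components"][0]
    k_hat = locate_changepoint(proc, comp_name)
    report["changepoint"] = {"k_hat": k_hat, "component": comp_name}

    p = fitted.theta_hat.p
    if min(k_hat, series.n - k_hat) > p + 5:
        left = fit_mple(
            OrdinalSeries(series.y[:k_hat], series.m),
            CovariateSeries(cov.z[:k_hat]),
            tau_method=config.tau_method,
        )
        right = fit_mple(
            OrdinalSeries(series.y[k_hat:], series.m),
            CovariateSeries(cov.z[k_hat:]),
            tau_method=config.tau_method,
        )
        aic_split = -2.0 * (left.loglik + right.loglik) + 2.0 * (2 * p)
        report["split_comparison"] = {
            "aic_no_split": fitted.aic,
            "aic_split": aic_split,
            "left": left.summary_dict(),
            "right": right.summary_dict(),
            "split_preferred": bool(aic_split < fitted.aic),
        }
    return report
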