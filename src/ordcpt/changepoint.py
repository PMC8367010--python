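"""Change-point localization and binary segmentation.

A rejected stability test is followed by localization: the change-point
estimate is the (smallest, on ties) index k at which the standardized
score component attains its maximum magnitude.  The estimator is
consistent for the true change location as n grows.  Multiple changes are
found by binary segmentation — test, split at the located point, recurse
on both halves until no segment rejects or segments become too short to
refit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidInputError, OrdcptError
from .estimation import FittedModel, fit_mple
from .model import CovariateSeries, OrdinalSeries
from .score_tests import ScoreProcess, TestResult, score_process, w1_statistic, w2_statistic


def locate_changepoint(proc: ScoreProcess, component: int | str) -> int:
    """Smallest 1-based index k maximizing |standardized score component|.

    Interprets the located index as the last observation of the pre-change
    segment.
    """
    idx = proc.resolve_components([component])[0]
    mag = np.abs(proc.path[:, idx])
    return int(np.argmax(mag)) + 1  # argmax returns first maximum


def _locate_from_result(proc: ScoreProcess, result: TestResult) -> int:
    """Localization after a (possibly joint) rejection.

    With several tested components, the component with the largest maximum
    drives the localization — the same component a per-component diagnosis
    would flag.
    """
    if result.per_component is not None:
        comp = result.components[int(np.argmax(result.per_component))]
        return locate_changepoint(proc, comp)
    # quadratic-form statistic: argmax of the weighted form itself
    return result.argmax_k


@dataclass(frozen=True)
class Segment:
    """A fitted homogeneous stretch [start, end] (1-based, inclusive)."""

    start: int
    end: int
    fitted: FittedModel | None
    note: str = ""

    @property
    def aic(self) -> float | None:
        return None if self.fitted is None else self.fitted.aic


@dataclass
class SegmentationResult:
    """Binary-segmentation output: located changes and per-segment refits."""

    changepoints: list[int] = field(default_factory=list)
    segments: list[Segment] = field(default_factory=list)
    trace: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "changepoints": self.changepoints,
            "segments": [
                {
                    "start": s.start,
                    "end": s.end,
                    "aic": s.aic,
                    "note": s.note,
                    "fit": None if s.fitted is None else s.fitted.summary_dict(),
                }
                for s in self.segments
            ],
            "trace": self.trace,
        }


def binary_segmentation(
    series: OrdinalSeries,
    cov: CovariateSeries | None = None,
    alpha: float = 0.05,
    stat: str = "w1",
    components=None,
    min_seg: int = 30,
    window: tuple[float, float] = (0.05, 0.95),
    tau_method: str = "outer",
) -> SegmentationResult:
    """Recursive test-and-split detection of multiple change-points.

    Each segment of length >= 2*min_seg is refitted and tested at level
    ``alpha`` (no correction across recursion depth); a rejection splits
    the segment at the located change-point.  Segments whose refit fails
    are flagged and not recursed into.
    """
    if cov is None:
        cov = CovariateSeries.empty(series.n)
    if stat not in ("w1", "w2"):
        raise InvalidInputError(f"stat must be 'w1' or 'w2', got {stat!r}")
    if min_seg < series.q + cov.d + 5:
        raise InvalidInputError(
            f"min_seg={min_seg} too small to refit p={series.q + cov.d} parameters"
        )
    result = SegmentationResult()
    _segment(series, cov, 1, series.n, alpha, stat, components, min_seg, window,
             tau_method, result)
    result.changepoints.sort()
    result.segments.sort(key=lambda s: s.start)
    return result


def _segment(series, cov, start, end, alpha, stat, components, min_seg, window,
             tau_method, result: SegmentationResult) -> None:
    length = end - start + 1
    sub_y = OrdinalSeries(series.y[start - 1 : end], series.m)
    sub_z = CovariateSeries(cov.z[start - 1 : end])
    if length < 2 * min_seg:
        result.segments.append(_refit(sub_y, sub_z, start, end, tau_method,
                                      note="too short to test"))
        return
    try:
        fitted = fit_mple(sub_y, sub_z, tau_method=tau_method)
        proc = score_process(fitted, sub_y, sub_z)
        if stat == "w1":
            test = w1_statistic(proc, components, alpha=alpha)
        else:
            test = w2_statistic(proc, components, l=window[0], u=window[1], alpha=alpha)
    except OrdcptError as exc:
        result.segments.append(Segment(start, end, None, note=f"fit failed: {exc}"))
        return
    entry = {"start": start, "end": end, **test.to_dict()}
    if not test.rejected:
        result.trace.append(entry)
        result.segments.append(Segment(start, end, fitted))
        return
    k_local = _locate_from_result(proc, test)
    k_abs = start - 1 + k_local
    # refuse degenerate splits that would leave an unfittable piece
    if k_abs - start + 1 < min_seg or end - k_abs < min_seg:
        k_abs = int(np.clip(k_abs, start - 1 + min_seg, end - min_seg))
    entry["changepoint"] = k_abs
    result.trace.append(entry)
    result.changepoints.append(k_abs)
    _segment(series, cov, start, k_abs, alpha, stat, components, min_seg, window,
             tau_method, result)
    _segment(series, cov, k_abs + 1, end, alpha, stat, components, min_seg, window,
             tau_method, result)


def _refit(sub_y, sub_z, start, end, tau_method, note="") -> Segment:
    try:
        fitted = fit_mple(sub_y, sub_z, tau_method=tau_method)
    except OrdcptError as exc:
        return Segment(start, end, None, note=f"refit failed: {exc}")
    return Segment(start, end, fitted, note=note)
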