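"""Aggregation-kinetics parameters: area-2h, AUC, end-point circularity.

Per-well curves of normalized projected area are reduced to three
parameters; replicate wells are summarized per condition and conditions
are compared with a two-sided Mann-Whitney U test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .imaging.types import FrameMeasurement

__all__ = [
    "AggregationCurve",
    "WellParameters",
    "ConditionSummary",
    "MannWhitneyResult",
    "build_curve",
    "curve_from_areas",
    "area_at",
    "compute_auc",
    "end_circularity",
    "extract_parameters",
    "summarize_condition",
    "compare_conditions",
]

PARAMETER_NAMES = ("area_2h", "auc", "circularity_end")


@dataclass
class AggregationCurve:
    """Per-well time series of total aggregate area normalized to frame 0."""

    times: np.ndarray  # hours, strictly increasing, uniform spacing
    normalized_area: np.ndarray
    well_id: str = "well"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.normalized_area = np.asarray(self.normalized_area, dtype=float)
        if self.times.shape != self.normalized_area.shape or self.times.ndim != 1:
            raise ValueError("times and normalized_area must be matching 1-D arrays")
        if len(self.times) < 1:
            raise ValueError("curve must have at least one sample")
        dt = np.diff(self.times)
        if len(dt) and (dt <= 0).any():
            raise ValueError("times must be strictly increasing")
        if len(dt) and not np.allclose(dt, dt[0]):
            raise ValueError("times must be uniformly spaced")
        if not math.isclose(self.normalized_area[0], 1.0, rel_tol=1e-9):
            raise ValueError("normalized_area[0] must be 1 (normalization convention)")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def frame_interval(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else float("nan")


def build_curve(
    measurements: "list[FrameMeasurement]",
    frame_interval_h: float,
    well_id: str = "well",
) -> AggregationCurve:
    """Normalize per-frame total areas to the first frame.

    Raises if the first frame has zero area (nothing to normalize to).
    """
    if not measurements:
        raise ValueError("no measurements")
    areas = np.array([m.total_area_px for m in measurements], dtype=float)
    return curve_from_areas(areas, frame_interval_h, well_id=well_id)


def curve_from_areas(
    areas: np.ndarray, frame_interval_h: float, well_id: str = "well"
) -> AggregationCurve:
    areas = np.asarray(areas, dtype=float)
    if areas[0] <= 0:
        raise ValueError("total area at t=0 is zero; cannot normalize")
    times = np.arange(len(areas)) * frame_interval_h
    return AggregationCurve(times=times, normalized_area=areas / areas[0],
                            well_id=well_id)


def area_at(curve: AggregationCurve, t_h: float) -> float:
    """Normalized area at the sample nearest ``t_h`` (exact on-grid).

    The 2-h parameter falls exactly on the 15-min grid; off-grid queries
    warn and return the nearest sample.
    """
    if t_h < curve.times[0] or t_h > curve.times[-1]:
        raise ValueError(
            f"t_h={t_h} outside curve range [{curve.times[0]}, {curve.times[-1]}]"
        )
    idx = int(np.argmin(np.abs(curve.times - t_h)))
    if not math.isclose(curve.times[idx], t_h, abs_tol=1e-9):
        warnings.warn(
            f"t_h={t_h} is off the sampling grid; using nearest sample "
            f"t={curve.times[idx]}",
            stacklevel=2,
        )
    return float(curve.normalized_area[idx])


def compute_auc(curve: AggregationCurve, window_h: float) -> float:
    """Trapezoidal integral of the curve over [0, window_h] hours.

    ``window_h`` may fall between samples; the final partial trapezoid is
    cut by linear interpolation. Exceeding the curve raises.
    """
    if window_h <= 0:
        raise ValueError("window_h must be > 0")
    if window_h > curve.times[-1] + 1e-9:
        raise ValueError(
            f"window_h={window_h} exceeds curve duration {curve.times[-1]}"
        )
    t, y = curve.times, curve.normalized_area
    inside = t <= window_h + 1e-12
    t_in, y_in = t[inside], y[inside]
    if t_in[-1] < window_h - 1e-12:
        y_end = float(np.interp(window_h, t, y))
        t_in = np.append(t_in, window_h)
        y_in = np.append(y_in, y_end)
    return float(np.trapezoid(y_in, t_in))


def end_circularity(final_measurement: FrameMeasurement) -> float:
    """Unweighted mean circularity of retained aggregates at the final frame.

    Returns NaN (with a warning) when no aggregates are retained.
    """
    circs = [o.circularity for o in final_measurement.objects
             if not math.isnan(o.circularity)]
    if not circs:
        warnings.warn("no retained aggregates at final frame; circularity is NaN",
                      stacklevel=2)
        return float("nan")
    return float(np.mean(circs))


@dataclass
class WellParameters:
    """The three per-well aggregation parameters."""

    area_2h: float
    auc: float
    circularity_end: float
    window_h: float
    well_id: str = "well"

    def as_dict(self) -> dict:
        return {"area_2h": self.area_2h, "auc": self.auc,
                "circularity_end": self.circularity_end}


def extract_parameters(
    curve: AggregationCurve,
    final_measurement: "FrameMeasurement | None",
    window_h: float,
) -> WellParameters:
    """Full per-well reduction. ``window_h`` is always explicit.

    Curves shorter than 2 h cannot provide area-2h; it is reported as NaN
    with a warning (the assay itself always runs 6-24 h).
    """
    circ = end_circularity(final_measurement) if final_measurement is not None \
        else float("nan")
    if curve.times[-1] >= 2.0:
        a2h = area_at(curve, 2.0)
    else:
        warnings.warn("curve shorter than 2 h; area_2h is NaN", stacklevel=2)
        a2h = float("nan")
    return WellParameters(
        area_2h=a2h,
        auc=compute_auc(curve, window_h),
        circularity_end=circ,
        window_h=window_h,
        well_id=curve.well_id,
    )


@dataclass
class ConditionSummary:
    """Replicate-level parameters plus mean and sample SD per parameter."""

    label: str
    replicates: list  # list[WellParameters]
    means: dict = field(init=False)
    sds: dict = field(init=False)

    def __post_init__(self) -> None:
        if not self.replicates:
            raise ValueError("need >= 1 replicate")
        self.means, self.sds = {}, {}
        for name in PARAMETER_NAMES:
            vals = np.array([getattr(r, name) for r in self.replicates], dtype=float)
            finite = vals[np.isfinite(vals)]
            if len(finite) == 0:
                self.means[name] = float("nan")
                self.sds[name] = float("nan")
                continue
            self.means[name] = float(finite.mean())
            # sample SD (ddof=1); single replicate reported as SD = 0
            self.sds[name] = float(finite.std(ddof=1)) if len(finite) > 1 else 0.0

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)

    def values(self, parameter: str) -> np.ndarray:
        if parameter not in PARAMETER_NAMES:
            raise KeyError(f"unknown parameter {parameter!r}; "
                           f"expected one of {PARAMETER_NAMES}")
        return np.array([getattr(r, parameter) for r in self.replicates], dtype=float)


def summarize_condition(
    label: str,
    curves: "list[AggregationCurve]",
    final_measurements: "list[FrameMeasurement] | None",
    window_h: float,
) -> ConditionSummary:
    """Reduce replicate curves of one condition to a summary.

    Mixed frame intervals across replicates are rejected.
    """
    if not curves:
        raise ValueError("need >= 1 curve")
    intervals = {round(c.frame_interval, 9) for c in curves if c.n_frames > 1}
    if len(intervals) > 1:
        raise ValueError(f"mixed frame intervals across replicates: {sorted(intervals)}")
    if final_measurements is None:
        final_measurements = [None] * len(curves)
    if len(final_measurements) != len(curves):
        raise ValueError("final_measurements must align with curves")
    reps = [extract_parameters(c, fm, window_h)
            for c, fm in zip(curves, final_measurements)]
    return ConditionSummary(label=label, replicates=reps)


@dataclass
class MannWhitneyResult:
    u_statistic: float
    p_value: float
    method: str
    parameter: str
    n_a: int
    n_b: int


def compare_conditions(
    a: ConditionSummary, b: ConditionSummary, parameter: str
) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test on one parameter.

    Policy: the exact null distribution is used for small tie-free
    samples and the tie-corrected normal approximation otherwise
    (scipy's ``method="auto"`` implements exactly this switch).
    """
    x, y = a.values(parameter), b.values(parameter)
    if len(x) < 3 or len(y) < 3:
        warnings.warn("fewer than 3 replicates per group; test is weak",
                      stacklevel=2)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    tie_free = len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
    method = "exact" if (len(x) <= 8 and len(y) <= 8 and tie_free) else "asymptotic"
    return MannWhitneyResult(
        u_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method=method,
        parameter=parameter,
        n_a=len(x),
        n_b=len(y),
    )
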