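"""Quantitative analysis of single-cell biosensor traces.

Because the degron reporter is constitutively expressed, the slope of its
fluorescence accumulation reports on how strongly the APC/C is degrading
it: full APC/C activity keeps the level near steady state (slope ~ 0),
while a proteasome block (MG132) removes all degradation so the slope
equals the synthesis rate.  Percent APC/C inactivation is therefore the
accumulation slope in a pre-MG132 window expressed against the post-MG132
slope:  100 * (1 - slope_pre / slope_post).

The module also classifies traces as transient (pulse that decays back
towards baseline — the APC/C reactivated) versus sustained (monotone
accumulation — it did not), estimates when two median traces diverge
(used to time the onset of phosphatase action), and classifies CDK2
activity traces into cycling versus quiescent cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SlopeFit",
    "InactivationEstimate",
    "TraceClass",
    "DivergenceResult",
    "fit_slope",
    "percent_inactivation",
    "classify_trace",
    "fraction_transient",
    "normalize_to_control",
    "median_trace",
    "divergence_time",
    "classify_cdk2",
    "fraction_cycling",
]


# pre-MG132 accumulation window: 1-5 h after mitogen stimulation
DEFAULT_PRE_WINDOW = (1.0, 5.0)
# post-MG132 window: opens after an equilibration gap, spans 2 h
POST_MG132_GAP = 0.5
POST_MG132_SPAN = 2.0


@dataclass(frozen=True)
class SlopeFit:
    """Ordinary least-squares line over one time window of a trace."""

    window: tuple[float, float]
    slope: float
    intercept: float
    residual_sd: float
    n_points: int


@dataclass(frozen=True)
class InactivationEstimate:
    """Slope-ratio estimate of percent APC/C inactivation.

    ``percent_inactivation = 100 * (1 - slope_pre / slope_post)`` — the
    shortfall of the pre-MG132 accumulation slope relative to the MG132
    full-synthesis reference slope.  Defined only for slope_post > 0; the
    value is at most 100 (slope_pre >= 0) and can be negative if the trace
    accumulated faster before MG132 than after.
    """

    slope_pre: float
    slope_post: float
    percent_inactivation: float


@dataclass(frozen=True)
class TraceClass:
    """Transient/sustained/none call for one reporter trace."""

    label: str  # "transient" | "sustained" | "none"
    peak_value: float
    baseline: float
    terminal_value: float
    peak_time: float
    prominence: float


@dataclass(frozen=True)
class DivergenceResult:
    """Earliest sustained separation between two aligned median traces."""

    divergence_time: float | None
    epsilon: float
    sustain_points: int


def _as_series(trace) -> tuple[np.ndarray, np.ndarray]:
    """Accept a (times, values) pair or a tidy DataFrame slice."""
    if isinstance(trace, pd.DataFrame):
        return trace["time_h"].to_numpy(float), trace["value"].to_numpy(float)
    times, values = trace
    return np.asarray(times, dtype=float), np.asarray(values, dtype=float)


def fit_slope(trace, window: tuple[float, float]) -> SlopeFit:
    """OLS line over samples with start <= t < end (half-open window)."""
    times, values = _as_series(trace)
    start, end = window
    mask = (times >= start) & (times < end)
    n = int(mask.sum())
    if n < 2:
        raise ValueError(
            f"window [{start}, {end}) contains {n} samples; need >= 2"
        )
    t, v = times[mask], values[mask]
    slope, intercept = np.polyfit(t, v, 1)
    resid = v - (slope * t + intercept)
    residual_sd = float(np.sqrt(np.sum(resid**2) / (n - 2))) if n > 2 else 0.0
    return SlopeFit(
        window=(float(start), float(end)),
        slope=float(slope),
        intercept=float(intercept),
        residual_sd=residual_sd,
        n_points=n,
    )


def percent_inactivation(
    trace,
    mg132_time: float,
    pre_window: tuple[float, float] = DEFAULT_PRE_WINDOW,
    post_window: tuple[float, float] | None = None,
) -> InactivationEstimate:
    """Percent APC/C inactivation from pre- vs post-MG132 slopes.

    The default pre window is 1–5 h after mitogen stimulation (accumulation
    above background but before the G1/S switch).  The default post window
    opens 0.5 h after MG132 addition (equilibration gap) and spans 2 h.
    Raises ``ValueError`` when the windows straddle ``mg132_time`` or the
    post-MG132 slope is not positive (the full-inhibition reference
    failed).
    """
    if post_window is None:
        post_window = (
            mg132_time + POST_MG132_GAP,
            mg132_time + POST_MG132_GAP + POST_MG132_SPAN,
        )
    if pre_window[1] > mg132_time:
        raise ValueError("pre_window must end at or before mg132_time")
    if post_window[0] < mg132_time:
        raise ValueError("post_window must start at or after mg132_time")
    pre = fit_slope(trace, pre_window)
    post = fit_slope(trace, post_window)
    if post.slope <= 0:
        raise ValueError(
            f"post-MG132 slope is {post.slope:.4g} <= 0; "
            "percent inactivation undefined"
        )
    pct = 100.0 * (1.0 - pre.slope / post.slope)
    return InactivationEstimate(
        slope_pre=pre.slope, slope_post=post.slope, percent_inactivation=pct
    )


def _moving_median(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return values.copy()
    half = window // 2
    padded = np.pad(values, half, mode="edge")
    return np.array(
        [np.median(padded[i : i + window]) for i in range(len(values))]
    )


def _mad_noise_scale(values: np.ndarray) -> float:
    """Robust noise sigma from first differences (MAD / sqrt(2), scaled)."""
    d = np.diff(values)
    mad = np.median(np.abs(d - np.median(d)))
    return 1.4826 * mad / math.sqrt(2.0)


def classify_trace(
    trace,
    min_prominence: float | None = None,
    terminal_fraction: float = 0.5,
    smooth_window: int = 5,
) -> TraceClass:
    """Classify a reporter trace as transient, sustained, or none.

    After moving-median smoothing, the trace is ``none`` when its peak
    rises less than ``min_prominence`` above baseline (default: 3x a
    robust noise scale estimated from first differences); ``transient``
    when the peak is interior and the terminal level has fallen back to
    within ``terminal_fraction`` of the rise; ``sustained`` otherwise.
    """
    times, values = _as_series(trace)
    if len(values) < 5:
        raise ValueError("need >= 5 samples to classify a trace")
    if smooth_window >= len(values):
        raise ValueError("smoothing window must be shorter than the trace")
    smooth = _moving_median(values, smooth_window)
    if min_prominence is None:
        min_prominence = 3.0 * _mad_noise_scale(values)

    baseline = float(smooth[0])
    peak_idx = int(np.argmax(smooth))
    peak = float(smooth[peak_idx])
    terminal = float(smooth[-1])
    prominence = peak - baseline

    if prominence < min_prominence:
        label = "none"
    elif (
        peak_idx < len(smooth) - 1
        and terminal <= baseline + terminal_fraction * prominence
    ):
        label = "transient"
    else:
        label = "sustained"
    return TraceClass(
        label=label,
        peak_value=peak,
        baseline=baseline,
        terminal_value=terminal,
        peak_time=float(times[peak_idx]),
        prominence=float(prominence),
    )


def fraction_transient(classes) -> float:
    """Fraction of traces labelled transient among all classified traces."""
    labels = [c.label if isinstance(c, TraceClass) else c for c in classes]
    if not labels:
        raise ValueError("cannot take a fraction of zero traces")
    return sum(1 for l in labels if l == "transient") / len(labels)


def normalize_to_control(f_condition: float, f_control: float) -> float:
    """Condition fraction expressed relative to the control fraction."""
    if f_control <= 0:
        raise ValueError("control fraction must be > 0 to normalize")
    return f_condition / f_control


def median_trace(table, channel: str = "apc_reporter", scenario: str | None = None):
    """Pointwise median across cells on the shared sampling grid.

    For an even number of cells the lower of the two middle values is
    taken, so every reported value is an actually observed one and the
    result is bit-reproducible.  All cells must share the grid exactly; no
    interpolation is attempted.

    Returns ``(times, median_values)``.
    """
    from .synth import TraceTable

    if isinstance(table, TraceTable):
        df = table.data
    else:
        df = table
    sel = df[df["channel"] == channel]
    if scenario is not None:
        sel = sel[sel["scenario"] == scenario]
    if sel.empty:
        raise ValueError(f"no traces for channel {channel!r} scenario {scenario!r}")
    wide = sel.pivot(index="time_h", columns="cell_id", values="value")
    if wide.isna().any().any():
        raise ValueError("traces are not aligned on a common grid")
    arr = np.sort(wide.to_numpy(float), axis=1)
    lower_mid = (arr.shape[1] - 1) // 2  # lower middle value for even counts
    return wide.index.to_numpy(float), arr[:, lower_mid]


def divergence_time(
    median_a,
    median_b,
    epsilon: float,
    sustain_points: int = 3,
) -> DivergenceResult:
    """Earliest sustained separation |a - b| >= epsilon of two median traces.

    Returns the first grid time at which the separation holds for
    ``sustain_points`` consecutive samples; ``divergence_time`` is None if
    that never happens.
    """
    ta, va = _as_series(median_a)
    tb, vb = _as_series(median_b)
    if ta.shape != tb.shape or not np.allclose(ta, tb):
        raise ValueError("median traces are not on the same grid")
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    if sustain_points < 1:
        raise ValueError("sustain_points must be >= 1")

    apart = np.abs(va - vb) >= epsilon
    run = 0
    for i, flag in enumerate(apart):
        run = run + 1 if flag else 0
        if run >= sustain_points:
            start = i - sustain_points + 1
            return DivergenceResult(
                divergence_time=float(ta[start]),
                epsilon=float(epsilon),
                sustain_points=sustain_points,
            )
    return DivergenceResult(
        divergence_time=None, epsilon=float(epsilon), sustain_points=sustain_points
    )


def classify_cdk2(
    trace,
    threshold: float = 1.0,
    sustain_points: int = 3,
) -> str:
    """Call a CDK2 trace cycling iff activity stays >= threshold for
    ``sustain_points`` consecutive samples; quiescent otherwise."""
    _, values = _as_series(trace)
    if len(values) < sustain_points:
        raise ValueError("trace shorter than sustain_points")
    run = 0
    for v in values:
        run = run + 1 if v >= threshold else 0
        if run >= sustain_points:
            return "cycling"
    return "quiescent"


def fraction_cycling(labels) -> float:
    """Fraction of cells labelled cycling."""
    labels = list(labels)
    if not labels:
        raise ValueError("cannot take a fraction of zero labels")
    return sum(1 for l in labels if l == "cycling") / len(labels)
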