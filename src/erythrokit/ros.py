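"""Amperometric ROS trace analysis.

The intracellular ROS level is estimated from the maximum oxidation
current of a single-cell amperometric recording, baseline-subtracted and
normalized to a ferrocene reference current.  Baseline subtraction makes
the normalized value invariant to a constant offset on the whole trace.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.ndimage import median_filter

from .io import XYSeries

MIN_TRACE_POINTS = 20


@dataclasses.dataclass(frozen=True)
class RosRecord:
    baseline_pA: float
    max_current_pA: float
    reference_pA: float
    normalized: float


def baseline_current(trace: XYSeries, baseline_fraction: float = 0.2) -> float:
    """Median current over the initial ``baseline_fraction`` of samples, pA."""
    if len(trace) < MIN_TRACE_POINTS:
        raise ValueError(f"trace too short (< {MIN_TRACE_POINTS} points)")
    n = max(int(baseline_fraction * len(trace)), 1)
    return float(np.median(trace.y[:n]))


def max_current(trace: XYSeries, smooth_window: int = 5) -> float:
    """Maximum of the moving-median-smoothed trace, pA (spike robust)."""
    if len(trace) < MIN_TRACE_POINTS:
        raise ValueError(f"trace too short (< {MIN_TRACE_POINTS} points)")
    return float(median_filter(trace.y, size=smooth_window, mode="nearest").max())


def normalize_ros(max_pA: float, baseline_pA: float, reference_pA: float) -> float:
    """(max - baseline) / reference; reference must be positive."""
    if reference_pA <= 0:
        raise ValueError("reference current must be positive")
    return (max_pA - baseline_pA) / reference_pA


def analyze_trace(trace: XYSeries, reference_pA: float,
                  baseline_fraction: float = 0.2, smooth_window: int = 5) -> RosRecord:
    """Full single-trace pipeline: baseline, smoothed maximum, normalization."""
    base = baseline_current(trace, baseline_fraction)
    peak = max_current(trace, smooth_window)
    return RosRecord(base, peak, reference_pA,
                     normalize_ros(peak, base, reference_pA))
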