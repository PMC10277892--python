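"""Peak detection and repeat binning.

Replaces the interactive peak-picking step of fragment-analysis viewers:
traces are smoothed (moving average), baseline-corrected (rolling minimum),
and local maxima passing height and prominence filters are kept. Apex sizes
are refined by 3-point parabolic interpolation for sub-grid accuracy.

Called peaks are then binned to integer repeat numbers on the locus lattice
``size = flank_bp + unit_len * repeat``; peaks falling outside the analysis
window or too far from the lattice are dropped. The result, a
:class:`RepeatPeakSet` (repeat -> RFU), is the input of the instability
index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict

import numpy as np
from scipy.ndimage import minimum_filter1d, uniform_filter1d
from scipy.signal import find_peaks

from .errors import InvalidParameterError, ValidationError
from .traceio import Peak, PeakTable, RepeatLocus, Trace

__all__ = ["RepeatPeakSet", "call_peaks", "bin_to_repeats", "estimate_flank"]

log = logging.getLogger(__name__)


@dataclass
class RepeatPeakSet:
    """Per-sample mapping repeat count -> peak height within the locus window."""

    sample_id: str
    heights: Dict[int, float]
    locus: RepeatLocus = field(repr=False)

    def __post_init__(self) -> None:
        for r, h in self.heights.items():
            if not (self.locus.window_min_repeat <= r <= self.locus.window_max_repeat):
                raise ValidationError(
                    f"repeat {r} outside analysis window "
                    f"[{self.locus.window_min_repeat}, {self.locus.window_max_repeat}]"
                )
            if h <= 0:
                raise ValidationError(f"height for repeat {r} must be > 0 (got {h})")
        self.heights = dict(sorted(self.heights.items()))

    @property
    def is_empty(self) -> bool:
        return not self.heights

    def __len__(self) -> int:
        return len(self.heights)


def _odd_window(width_bp: float, dx: float) -> int:
    n = max(1, int(round(width_bp / dx)))
    return n if n % 2 == 1 else n + 1


def call_peaks(
    trace: Trace,
    smooth_window_bp: float = 0.5,
    min_height: float = 50.0,
    min_prominence: float = 25.0,
    baseline_window_bp: float = 20.0,
) -> PeakTable:
    """Detect peaks in a calibrated trace.

    Parameters
    ----------
    trace
        Calibrated trace (bp grid).
    smooth_window_bp
        Moving-average window; must be narrower than the trace span.
    min_height, min_prominence
        Absolute RFU filters applied to the smoothed, baseline-subtracted
        signal.
    baseline_window_bp
        Width of the rolling-minimum baseline estimator; should be much
        wider than one peak.

    Returns
    -------
    PeakTable
        Peaks sorted by size, apex positions refined by parabolic
        interpolation of the three samples around each local maximum.
    """
    if not trace.calibrated:
        raise ValidationError("call_peaks requires a calibrated (bp) trace")
    if len(trace) < 3:
        return PeakTable(sample_id=trace.sample_id, peaks=[])
    dx = float(np.median(np.diff(trace.x)))
    span = trace.x[-1] - trace.x[0]
    if smooth_window_bp >= span:
        raise InvalidParameterError(
            f"smooth_window_bp ({smooth_window_bp}) must be narrower than the trace span ({span:.3g})"
        )

    y = trace.y.astype(float)
    baseline = minimum_filter1d(y, _odd_window(baseline_window_bp, dx), mode="nearest")
    baseline = uniform_filter1d(baseline, _odd_window(baseline_window_bp, dx), mode="nearest")
    y = y - baseline
    y = uniform_filter1d(y, _odd_window(smooth_window_bp, dx), mode="nearest")

    idx, _props = find_peaks(y, height=min_height, prominence=min_prominence)

    peaks = []
    for i in idx:
        size = float(trace.x[i])
        height = float(y[i])
        if 0 < i < len(y) - 1:
            denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
            if denom < 0:
                delta = 0.5 * (y[i - 1] - y[i + 1]) / denom
                delta = float(np.clip(delta, -0.5, 0.5))
                size = float(trace.x[i] + delta * dx)
                height = float(y[i] - 0.25 * (y[i - 1] - y[i + 1]) * delta)
        peaks.append(Peak(size_bp=size, height=height))
    peaks.sort(key=lambda p: p.size_bp)
    return PeakTable(sample_id=trace.sample_id, peaks=peaks)


def bin_to_repeats(
    peaks: PeakTable,
    locus: RepeatLocus,
    residual_tol_bp: float = 1.0,
) -> RepeatPeakSet:
    """Bin peak sizes to integer repeat counts on the locus lattice.

    ``repeat = round((size_bp - flank_bp) / unit_len)``. Peaks with lattice
    residual above ``residual_tol_bp`` or outside the analysis window are
    dropped. When two peaks bin to one repeat the taller wins (logged).

    An empty result is a valid outcome (``RepeatPeakSet.is_empty``), distinct
    from an error.
    """
    if not 0 < residual_tol_bp < locus.unit_len / 2:
        raise InvalidParameterError(
            f"residual_tol_bp must lie in (0, unit_len/2) = (0, {locus.unit_len / 2}); "
            f"got {residual_tol_bp}"
        )
    heights: Dict[int, float] = {}
    for p in peaks:
        repeat = int(round((p.size_bp - locus.flank_bp) / locus.unit_len))
        residual = abs(p.size_bp - locus.size_of(repeat))
        if residual > residual_tol_bp:
            continue
        if not (locus.window_min_repeat <= repeat <= locus.window_max_repeat):
            continue
        if p.height <= 0:
            continue
        if repeat in heights:
            log.warning(
                "%s: two peaks bin to repeat %d; keeping the taller (%.1f vs %.1f RFU)",
                peaks.sample_id, repeat, max(heights[repeat], p.height),
                min(heights[repeat], p.height),
            )
            heights[repeat] = max(heights[repeat], p.height)
        else:
            heights[repeat] = p.height
    return RepeatPeakSet(sample_id=peaks.sample_id, heights=heights, locus=locus)


def estimate_flank(peaks: PeakTable, known_repeat: int, locus: RepeatLocus) -> float:
    """Estimate the non-repeat flank length from a sample of known genotype.

    ``flank = tallest-peak size - unit_len * known_repeat``; by construction
    the tallest peak then bins exactly to ``known_repeat``.
    """
    if len(peaks) == 0:
        raise ValidationError("cannot estimate flank from an empty peak table")
    tallest = peaks.tallest()
    return float(tallest.size_bp - locus.unit_len * known_repeat)
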