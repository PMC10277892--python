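"""Electropherogram and peak-table I/O.

Fragment analysis of a fluorescently labelled repeat amplicon yields a trace
(fragment size in bp vs. fluorescence in RFU) and, after peak detection, a
peak table. This module defines the domain containers — :class:`RepeatLocus`,
:class:`Trace`, :class:`Peak`/:class:`PeakTable` — and readers/writers for
two plain-text dialects:

* ``generic`` — comma-delimited with header ``size_bp,height[,area]``.
* ``peakscanner`` — tolerant mapping of common fragment-analysis export
  headers (``Size``, ``Height``, ``Area under peak``/``Area``); extra columns
  (dye, sample peak number, ...) are ignored.

Traces are stored as two-column CSV (``size_bp,intensity`` when calibrated,
``scan,intensity`` when raw). Raw scan-unit traces are converted to base
pairs with :func:`calibrate_sizes` against an internal size standard.

Readers reject malformed rows with row-numbered messages rather than
silently coercing them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import CalibrationError, FormatError, ValidationError

__all__ = [
    "RepeatLocus",
    "Trace",
    "Peak",
    "PeakTable",
    "read_peak_table",
    "write_peak_table",
    "read_trace",
    "write_trace",
    "calibrate_sizes",
]


@dataclass(frozen=True)
class RepeatLocus:
    """An amplified short-tandem-repeat locus.

    Parameters
    ----------
    name
        Locus label (e.g. ``"Htt_CAG"`` or ``"mBAT24"``).
    repeat_unit
        Repeat unit sequence; its length in bp is ``unit_len``.
    flank_bp
        Total non-repeat amplicon length (both primer-to-repeat flanks).
        A fragment carrying ``n`` repeat units sizes at
        ``flank_bp + unit_len * n``.
    window_min_repeat, window_max_repeat
        Integer analysis window. Peaks binning outside the window are
        excluded; in heterozygous animals this is what gates out the
        unexpanded wild-type allele.
    """

    name: str
    repeat_unit: str
    flank_bp: float
    window_min_repeat: int
    window_max_repeat: int

    def __post_init__(self) -> None:
        if len(self.repeat_unit) < 1:
            raise ValidationError("repeat_unit must be at least 1 bp")
        if self.flank_bp < 0:
            raise ValidationError("flank_bp must be >= 0")
        if not self.window_min_repeat < self.window_max_repeat:
            raise ValidationError(
                "window_min_repeat must be < window_max_repeat "
                f"(got {self.window_min_repeat} >= {self.window_max_repeat})"
            )

    @property
    def unit_len(self) -> int:
        return len(self.repeat_unit)

    def size_of(self, repeat: int) -> float:
        """Expected fragment size (bp) of an allele with ``repeat`` units."""
        return self.flank_bp + self.unit_len * repeat


@dataclass
class Trace:
    """One electropherogram: a strictly increasing size grid and intensities."""

    sample_id: str
    x: np.ndarray
    y: np.ndarray
    calibrated: bool = True

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.ndim != 1 or self.y.ndim != 1:
            raise ValidationError("trace x and y must be 1-D")
        if len(self.x) != len(self.y):
            raise ValidationError(
                f"trace x and y lengths differ ({len(self.x)} vs {len(self.y)})"
            )
        if len(self.x) and np.any(np.diff(self.x) <= 0):
            raise ValidationError("trace x must be strictly increasing")
        if np.any(self.y < 0):
            raise ValidationError("trace intensities must be >= 0")

    def __len__(self) -> int:
        return len(self.x)


@dataclass(frozen=True)
class Peak:
    size_bp: float
    height: float
    area: Optional[float] = None

    def __post_init__(self) -> None:
        if self.height < 0:
            raise ValidationError("peak height must be >= 0")


@dataclass
class PeakTable:
    """Ordered peak list for one sample, sizes strictly increasing."""

    sample_id: str
    peaks: list = field(default_factory=list)

    def __post_init__(self) -> None:
        sizes = [p.size_bp for p in self.peaks]
        if any(b <= a for a, b in zip(sizes, sizes[1:])):
            raise ValidationError("peak sizes must be strictly increasing")

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def tallest(self) -> Peak:
        if not self.peaks:
            raise ValidationError("peak table is empty")
        return max(self.peaks, key=lambda p: p.height)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "size_bp": [p.size_bp for p in self.peaks],
                "height": [p.height for p in self.peaks],
                "area": [p.area for p in self.peaks],
            }
        )


_DIALECTS = ("generic", "peakscanner")

# header synonyms accepted in the peakscanner dialect (lower-cased, stripped)
_PS_SIZE = {"size", "size (bp)", "size_bp"}
_PS_HEIGHT = {"height", "height (rfu)", "peak height"}
_PS_AREA = {"area", "area under peak", "area in point"}


def _check_dialect(dialect: str) -> None:
    if dialect not in _DIALECTS:
        raise FormatError(f"unknown peak-table dialect {dialect!r}; expected one of {_DIALECTS}")


def _numeric_column(df: pd.DataFrame, col: str, path: Path) -> np.ndarray:
    # exact (correctly rounded) parsing via Python floats; pandas' fast
    # parser can be one ulp off, which breaks round-trip value identity
    out = np.empty(len(df), dtype=float)
    bad = []
    for i, v in enumerate(df[col].tolist()):
        try:
            out[i] = float(v)
        except (TypeError, ValueError):
            bad.append(i)
    if bad:
        rows = ", ".join(str(i + 2) for i in bad[:10])  # 1-based incl. header row
        raise FormatError(f"{path}: non-numeric or missing {col!r} in row(s) {rows}")
    return out


def read_peak_table(path, dialect: str = "generic", sample_id: Optional[str] = None) -> PeakTable:
    """Read a peak table exported from fragment-analysis software.

    Raises :class:`FormatError` for missing columns or non-numeric rows and
    :class:`ValidationError` for non-monotone sizes.
    """
    _check_dialect(dialect)
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, skip_blank_lines=True)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise FormatError(f"{path}: not a readable delimited peak table ({exc})") from exc

    cols = {c.strip().lower(): c for c in df.columns}
    if dialect == "generic":
        size_col, height_col = cols.get("size_bp"), cols.get("height")
        area_col = cols.get("area")
    else:
        size_col = next((cols[c] for c in cols if c in _PS_SIZE), None)
        height_col = next((cols[c] for c in cols if c in _PS_HEIGHT), None)
        area_col = next((cols[c] for c in cols if c in _PS_AREA), None)
    if size_col is None or height_col is None:
        raise FormatError(
            f"{path}: missing size/height columns for dialect {dialect!r} "
            f"(found {list(df.columns)})"
        )

    sizes = _numeric_column(df, size_col, path)
    heights = _numeric_column(df, height_col, path)
    areas = _numeric_column(df, area_col, path) if area_col is not None else None

    if np.any(np.diff(sizes) <= 0):
        raise ValidationError(f"{path}: peak sizes are not strictly increasing")

    peaks = [
        Peak(float(s), float(h), float(areas[i]) if areas is not None else None)
        for i, (s, h) in enumerate(zip(sizes, heights))
    ]
    return PeakTable(sample_id=sample_id or path.stem, peaks=peaks)


def write_peak_table(table: PeakTable, path, dialect: str = "generic") -> None:
    """Write ``table`` so that :func:`read_peak_table` round-trips it."""
    _check_dialect(dialect)
    path = Path(path)
    has_area = any(p.area is not None for p in table.peaks)
    if dialect == "generic":
        header = ["size_bp", "height"] + (["area"] if has_area else [])
    else:
        header = ["Size", "Height"] + (["Area under peak"] if has_area else [])
    lines = [",".join(header)]
    for p in table.peaks:
        row = [repr(float(p.size_bp)), repr(float(p.height))]
        if has_area:
            row.append("" if p.area is None else repr(float(p.area)))
        lines.append(",".join(row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_trace(path, sample_id: Optional[str] = None) -> Trace:
    """Read a two-column delimited trace (``size_bp,intensity`` or ``scan,intensity``)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, skip_blank_lines=True)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise FormatError(f"{path}: not a readable delimited trace ({exc})") from exc
    cols = {c.strip().lower(): c for c in df.columns}
    if "size_bp" in cols:
        xcol, calibrated = cols["size_bp"], True
    elif "scan" in cols:
        xcol, calibrated = cols["scan"], False
    else:
        raise FormatError(f"{path}: expected a 'size_bp' or 'scan' column (found {list(df.columns)})")
    ycol = cols.get("intensity") or cols.get("rfu")
    if ycol is None:
        raise FormatError(f"{path}: expected an 'intensity' column (found {list(df.columns)})")
    x = _numeric_column(df, xcol, path)
    y = _numeric_column(df, ycol, path)
    return Trace(sample_id=sample_id or path.stem, x=x, y=y, calibrated=calibrated)


def write_trace(trace: Trace, path) -> None:
    path = Path(path)
    xname = "size_bp" if trace.calibrated else "scan"
    lines = [f"{xname},intensity"]
    lines += [f"{repr(float(a))},{repr(float(b))}" for a, b in zip(trace.x, trace.y)]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def calibrate_sizes(trace_raw: Trace, ladder: Sequence[Tuple[float, float]]) -> Trace:
    """Map raw scan units to base pairs against a size standard.

    Piecewise-linear interpolation between ladder points ``(scan_unit,
    known_bp)``; linear extrapolation beyond the first/last rung using the
    terminal segment slopes.
    """
    if len(ladder) < 2:
        raise CalibrationError("size calibration needs at least 2 ladder points")
    scans = np.asarray([p[0] for p in ladder], dtype=float)
    bps = np.asarray([p[1] for p in ladder], dtype=float)
    if np.any(np.diff(scans) <= 0) or np.any(np.diff(bps) <= 0):
        raise ValidationError("ladder must be strictly increasing in both coordinates")

    x = np.asarray(trace_raw.x, dtype=float)
    mapped = np.interp(x, scans, bps)
    lo_slope = (bps[1] - bps[0]) / (scans[1] - scans[0])
    hi_slope = (bps[-1] - bps[-2]) / (scans[-1] - scans[-2])
    below = x < scans[0]
    above = x > scans[-1]
    mapped[below] = bps[0] + (x[below] - scans[0]) * lo_slope
    mapped[above] = bps[-1] + (x[above] - scans[-1]) * hi_slope
    return Trace(sample_id=trace_raw.sample_id, x=mapped, y=trace_raw.y.copy(), calibrated=True)
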