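"""Somatic instability indices and microsatellite-instability comparison.

The somatic instability index of a sample summarizes its above-threshold
electropherogram peaks in one signed number of repeat units:

1. the **main allele** ``m`` is the tallest peak (ties break to the smaller
   repeat);
2. peaks with height below ``threshold_frac`` of the main peak are dropped
   (the "signal-to-noise threshold", 5% by convention);
3. retained heights are normalized to sum to one;
4. the index is the normalized-height-weighted sum of ``repeat - m``.

Expansion (``repeat > m``) and contraction (``repeat < m``) contributions
are reported separately but computed over the *jointly* normalized retained
set, so ``expansion_index + contraction_index == instability_index``
exactly. A single retained peak gives zero for all three. Negative values
occur when contraction products dominate — the signed convention this
module follows.

Microsatellite instability (MSI) at mononucleotide loci is assessed as the
main-allele shift of a sample versus a reference plus the difference of
their instability indices; a sample is flagged unstable when the absolute
shift reaches ``min_shift`` repeat units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence

import pandas as pd

from .errors import InvalidParameterError, ValidationError
from .peakcall import RepeatPeakSet

__all__ = [
    "InstabilityResult",
    "MSIResult",
    "main_allele",
    "instability_index",
    "index_cohort",
    "msi_compare",
]

log = logging.getLogger(__name__)

_MODES = ("all", "expansion", "contraction")


@dataclass(frozen=True)
class InstabilityResult:
    sample_id: str
    main_allele: int
    threshold_frac: float
    n_peaks_retained: int
    instability_index: float
    expansion_index: float
    contraction_index: float

    def value(self, mode: str = "all") -> float:
        """Index value for a mode: ``all`` (signed), ``expansion`` (>= 0) or
        ``contraction`` (<= 0)."""
        if mode not in _MODES:
            raise InvalidParameterError(f"mode must be one of {_MODES}")
        return {
            "all": self.instability_index,
            "expansion": self.expansion_index,
            "contraction": self.contraction_index,
        }[mode]


@dataclass(frozen=True)
class MSIResult:
    locus_name: str
    sample_id: str
    reference_id: str
    main_allele_shift: int
    index_difference: float
    unstable: bool


def main_allele(rps: RepeatPeakSet) -> int:
    """Tallest peak's repeat count; ties break to the smaller repeat."""
    if rps.is_empty:
        raise ValidationError(f"{rps.sample_id}: empty peak set has no main allele")
    hmax = max(rps.heights.values())
    return min(r for r, h in rps.heights.items() if h == hmax)


def instability_index(
    rps: RepeatPeakSet,
    threshold_frac: float = 0.05,
    mode: str = "all",
) -> InstabilityResult:
    """Compute the somatic instability index of one sample.

    Parameters
    ----------
    rps
        Non-empty peak set (repeat -> RFU) within the locus window.
    threshold_frac
        Signal-to-noise threshold as a fraction of the main-peak height,
        in [0, 1). The main peak always survives the cutoff.
    mode
        Validated convenience selector for :meth:`InstabilityResult.value`;
        the result always carries all three indices.
    """
    if not 0.0 <= threshold_frac < 1.0:
        raise InvalidParameterError("threshold_frac must be in [0, 1)")
    if mode not in _MODES:
        raise InvalidParameterError(f"mode must be one of {_MODES}")
    m = main_allele(rps)
    cutoff = threshold_frac * rps.heights[m]
    retained = {r: h for r, h in rps.heights.items() if h >= cutoff}
    total = sum(retained.values())
    expansion = sum(h * (r - m) for r, h in retained.items() if r > m) / total
    contraction = sum(h * (r - m) for r, h in retained.items() if r < m) / total
    return InstabilityResult(
        sample_id=rps.sample_id,
        main_allele=m,
        threshold_frac=threshold_frac,
        n_peaks_retained=len(retained),
        instability_index=expansion + contraction,
        expansion_index=expansion,
        contraction_index=contraction,
    )


def index_cohort(
    peak_sets: Sequence[RepeatPeakSet],
    groups: Optional[Mapping[str, str]] = None,
    threshold_frac: float = 0.05,
) -> pd.DataFrame:
    """Index a batch of samples; one row per sample.

    ``groups`` maps sample_id to group label; when omitted the label is the
    sample_id up to its last underscore (the cohort simulator's and CLI's
    naming convention). Per-sample failures are logged and skipped, the
    batch continues.
    """
    if len(peak_sets) == 0:
        raise ValidationError("index_cohort needs at least one sample")
    rows = []
    for rps in peak_sets:
        try:
            res = instability_index(rps, threshold_frac=threshold_frac)
        except (ValidationError, InvalidParameterError) as exc:
            log.warning("skipping sample %s: %s", rps.sample_id, exc)
            continue
        if groups is not None:
            group = groups.get(rps.sample_id, "")
        else:
            group = rps.sample_id.rsplit("_", 1)[0]
        rows.append(
            {
                "sample_id": res.sample_id,
                "group": group,
                "main_allele": res.main_allele,
                "threshold": res.threshold_frac,
                "n_peaks": res.n_peaks_retained,
                "instability_index": res.instability_index,
                "expansion_index": res.expansion_index,
                "contraction_index": res.contraction_index,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id", "group", "main_allele", "threshold", "n_peaks",
            "instability_index", "expansion_index", "contraction_index",
        ],
    )


def msi_compare(
    sample: RepeatPeakSet,
    reference: RepeatPeakSet,
    threshold_frac: float = 0.05,
    min_shift: int = 1,
) -> MSIResult:
    """Compare a sample to a reference at one microsatellite locus.

    Symmetric under swapping sample and reference up to the sign of the
    shift and index difference.
    """
    if sample.locus != reference.locus:
        raise ValidationError(
            f"locus mismatch: {sample.locus.name} vs {reference.locus.name}"
        )
    if min_shift < 1:
        raise InvalidParameterError("min_shift must be >= 1")
    shift = main_allele(sample) - main_allele(reference)
    diff = (
        instability_index(sample, threshold_frac).instability_index
        - instability_index(reference, threshold_frac).instability_index
    )
    return MSIResult(
        locus_name=sample.locus.name,
        sample_id=sample.sample_id,
        reference_id=reference.sample_id,
        main_allele_shift=int(shift),
        index_difference=float(diff),
        unstable=abs(shift) >= min_shift,
    )
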