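"""Synthetic fragment-analysis data with known ground truth.

Every downstream stage (peak calling, binning, instability indexing, group
statistics) can be exercised without animal data by simulating:

1. **Somatic expansion** — a mosaic compound-Poisson model. A fraction
   ``expanding_fraction`` of cells in the tissue is expansion-competent
   (striatal neurons in a bulk punch; glia and other cells keep the
   inherited tract). Each competent cell accrues ``Poisson(expansion_rate *
   months)`` unit gains and ``Poisson(contraction_rate * months)`` unit
   losses, floored at one repeat. The mosaic structure is what keeps the
   modal (main) allele at the inherited length while producing the expanded
   tail seen in real striatal traces; the tissue-level true mean gain is
   ``expanding_fraction * (expansion_rate - contraction_rate) * months``.

2. **PCR stutter** — geometric slippage: a template with ``n`` repeats
   contributes relative weight ``minus_ratio**k`` at ``n - k`` and
   ``plus_ratio**k`` at ``n + k`` (k = 1..max_steps), then the distribution
   is renormalized. Minus stutter dominates for trinucleotide repeats.

3. **Capillary electrophoresis** — Gaussian peak shapes on the bp axis,
   per-peak sizing jitter, amplitude attenuation per repeat above the main
   allele (PCR efficiency decay), and additive baseline noise.

Cohorts mirror the blocked-expansion study design (baseline / vehicle /
non-targeting control / treated groups, 5-6 animals each); per-animal seeds
are derived deterministically from the design seed so a cohort is
bit-reproducible.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, ValidationError
from .peakcall import RepeatPeakSet
from .traceio import RepeatLocus, Trace

__all__ = [
    "RepeatDistribution",
    "ExpansionModelParams",
    "StutterParams",
    "TraceRenderParams",
    "GroupSpec",
    "CohortDesign",
    "CohortTruth",
    "simulate_cell_population",
    "apply_stutter",
    "render_trace",
    "peak_set_from_distribution",
    "simulate_cohort",
    "blocked_expansion_design",
    "derive_seed",
    "HTT_CAG_LOCUS",
    "mbat_locus",
]

#: Normalized abundance over integer repeat counts.
RepeatDistribution = Dict[int, float]

#: Synthetic stand-in for the human HTT exon-1 CAG amplicon. The true flank
#: length of the assay is instrument/primer specific and user-supplied in
#: real analyses (see ``peakcall.estimate_flank``); 100 bp is this package's
#: synthetic default. Window spans the knock-in (~110) and humanized
#: (~120-130) inherited alleles plus expansion room.
HTT_CAG_LOCUS = RepeatLocus(
    name="Htt_CAG", repeat_unit="CAG", flank_bp=100.0,
    window_min_repeat=70, window_max_repeat=170,
)


def mbat_locus(name: str = "mBAT24", main_repeat: int = 24, flank_bp: float = 60.0) -> RepeatLocus:
    """A mononucleotide (poly-A) microsatellite locus, Bethesda-panel style."""
    return RepeatLocus(
        name=name, repeat_unit="A", flank_bp=flank_bp,
        window_min_repeat=max(1, main_repeat - 15), window_max_repeat=main_repeat + 15,
    )


@dataclass(frozen=True)
class ExpansionModelParams:
    """Parameters of the mosaic somatic-expansion model for one tissue sample.

    ``expansion_rate``/``contraction_rate`` are expected +1/-1 repeat events
    per expansion-competent cell per month. ``expanding_fraction`` is the
    fraction of cells in the sample that are expansion-competent; with
    ``expanding_fraction=1`` the model reduces to a plain compound-Poisson
    process over all cells.
    """

    inherited_repeat: int
    expansion_rate: float = 0.0
    contraction_rate: float = 0.0
    months: float = 0.0
    n_cells: int = 100_000
    expanding_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.inherited_repeat < 1:
            raise InvalidParameterError("inherited_repeat must be >= 1")
        if self.expansion_rate < 0 or self.contraction_rate < 0:
            raise InvalidParameterError("expansion/contraction rates must be >= 0")
        if self.months < 0:
            raise InvalidParameterError("months must be >= 0")
        if self.n_cells < 1:
            raise InvalidParameterError("n_cells must be >= 1")
        if not 0.0 <= self.expanding_fraction <= 1.0:
            raise InvalidParameterError("expanding_fraction must be in [0, 1]")

    @property
    def true_mean_gain(self) -> float:
        """Expected tissue-level mean repeat gain."""
        return self.expanding_fraction * (self.expansion_rate - self.contraction_rate) * self.months


@dataclass(frozen=True)
class StutterParams:
    """Geometric PCR stutter. Defaults match typical trinucleotide stutter
    (dominant one-step minus products, weak plus stutter)."""

    minus_ratio: float = 0.15
    plus_ratio: float = 0.01
    max_steps: int = 4

    def __post_init__(self) -> None:
        if not 0.0 <= self.minus_ratio < 1.0 or not 0.0 <= self.plus_ratio < 1.0:
            raise InvalidParameterError("stutter ratios must be in [0, 1)")
        if self.max_steps < 0:
            raise InvalidParameterError("max_steps must be >= 0")


@dataclass(frozen=True)
class TraceRenderParams:
    """Capillary-electrophoresis rendering parameters.

    ``amplitude`` is the apex RFU of the tallest peak before noise;
    ``decay_per_repeat`` multiplies peak amplitude per repeat above the main
    allele (1.0 = no length bias).
    """

    amplitude: float = 10_000.0
    peak_sigma_bp: float = 0.6
    size_jitter_sd_bp: float = 0.05
    baseline_sd: float = 20.0
    decay_per_repeat: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise InvalidParameterError("amplitude must be > 0")
        if self.peak_sigma_bp <= 0:
            raise InvalidParameterError("peak_sigma_bp must be > 0")
        if self.size_jitter_sd_bp < 0 or self.baseline_sd < 0:
            raise InvalidParameterError("noise SDs must be >= 0")
        if not 0.0 < self.decay_per_repeat <= 1.0:
            raise InvalidParameterError("decay_per_repeat must be in (0, 1]")


@dataclass(frozen=True)
class GroupSpec:
    """One cohort group: label, size, and per-animal generative parameters.

    ``rate_cv`` is the coefficient of variation of a per-animal gamma
    multiplier (mean 1) applied to both event rates, modelling inter-animal
    heterogeneity in expansion propensity.
    """

    label: str
    n_animals: int
    expansion: ExpansionModelParams
    stutter: StutterParams = StutterParams()
    render: TraceRenderParams = TraceRenderParams()
    rate_cv: float = 0.0

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise InvalidParameterError("n_animals must be >= 1")
        if self.rate_cv < 0:
            raise InvalidParameterError("rate_cv must be >= 0")


@dataclass(frozen=True)
class CohortDesign:
    groups: Tuple[GroupSpec, ...]
    locus: RepeatLocus = HTT_CAG_LOCUS
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups", tuple(self.groups))
        labels = [g.label for g in self.groups]
        if len(set(labels)) != len(labels):
            raise InvalidParameterError(f"duplicate group labels: {labels}")
        if not self.groups:
            raise InvalidParameterError("design needs at least one group")


@dataclass
class CohortTruth:
    """Ground truth emitted alongside a simulated cohort."""

    per_animal: pd.DataFrame  # columns: group, animal, true_gain
    per_group: Dict[str, float]  # design-level true mean gain

    def write(self, path) -> None:
        self.per_animal.to_csv(path, index=False)


def derive_seed(seed: int, *parts) -> int:
    """Deterministic child seed from a parent seed and a label path."""
    key = "|".join([str(seed), *map(str, parts)]).encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "little") % (2**31)


def simulate_cell_population(params: ExpansionModelParams) -> RepeatDistribution:
    """Simulate one tissue sample's repeat-length distribution.

    Returns a normalized abundance over integer repeat counts (>= 1),
    reproducible for a fixed ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_cells
    repeats = np.full(n, params.inherited_repeat, dtype=np.int64)
    lam_up = params.expansion_rate * params.months
    lam_dn = params.contraction_rate * params.months
    if (lam_up > 0 or lam_dn > 0) and params.expanding_fraction > 0:
        competent = rng.random(n) < params.expanding_fraction
        k = int(competent.sum())
        if k:
            gains = rng.poisson(lam_up, k) if lam_up > 0 else 0
            losses = rng.poisson(lam_dn, k) if lam_dn > 0 else 0
            repeats[competent] = repeats[competent] + gains - losses
    np.maximum(repeats, 1, out=repeats)  # no zero/negative tracts
    values, counts = np.unique(repeats, return_counts=True)
    return {int(v): float(c) / n for v, c in zip(values, counts)}


def _validated_dist(dist: RepeatDistribution) -> RepeatDistribution:
    if not dist:
        raise ValidationError("repeat distribution is empty")
    if any(w < 0 for w in dist.values()):
        raise ValidationError("repeat distribution has negative weights")
    total = float(sum(dist.values()))
    if total <= 0:
        raise ValidationError("repeat distribution has zero total weight")
    return {int(r): w / total for r, w in sorted(dist.items())}


def apply_stutter(dist: RepeatDistribution, sp: StutterParams) -> RepeatDistribution:
    """Convolve a repeat distribution with the geometric stutter kernel.

    Identity when both ratios are zero; output is renormalized and its
    support widens by at most ``max_steps`` on each side.
    """
    dist = _validated_dist(dist)
    if (sp.minus_ratio == 0.0 and sp.plus_ratio == 0.0) or sp.max_steps == 0:
        return dict(dist)
    out: RepeatDistribution = {}
    for r, w in dist.items():
        out[r] = out.get(r, 0.0) + w
        for k in range(1, sp.max_steps + 1):
            if sp.minus_ratio > 0 and r - k >= 1:
                out[r - k] = out.get(r - k, 0.0) + w * sp.minus_ratio**k
            if sp.plus_ratio > 0:
                out[r + k] = out.get(r + k, 0.0) + w * sp.plus_ratio**k
    total = sum(out.values())
    return {r: w / total for r, w in sorted(out.items())}


def _main_repeat(dist: RepeatDistribution) -> int:
    wmax = max(dist.values())
    return min(r for r, w in dist.items() if w == wmax)


def render_trace(
    dist: RepeatDistribution,
    locus: RepeatLocus,
    rp: TraceRenderParams = TraceRenderParams(),
    sample_id: str = "synthetic",
    grid_step_bp: float = 0.05,
) -> Trace:
    """Render a repeat distribution to a calibrated electropherogram.

    Peak centers sit on the locus lattice (plus sizing jitter), shapes are
    Gaussian with ``peak_sigma_bp``, amplitudes follow abundance times the
    length-decay factor, and the tallest peak apex equals ``amplitude``
    before noise. The grid covers the locus analysis window.
    """
    dist = _validated_dist(dist)
    rng = np.random.default_rng(rp.seed)
    main = _main_repeat(dist)

    pad = max(4.0 * rp.peak_sigma_bp, 2.0)
    lo = locus.size_of(locus.window_min_repeat) - pad
    hi = locus.size_of(locus.window_max_repeat) + pad
    x = np.arange(lo, hi + grid_step_bp, grid_step_bp)
    y = np.zeros_like(x)

    weights = {
        r: w * rp.decay_per_repeat ** (r - main)
        for r, w in dist.items()
        if locus.window_min_repeat <= r <= locus.window_max_repeat
    }
    if not weights:
        raise ValidationError("no repeats of the distribution fall inside the locus window")
    scale = rp.amplitude / max(weights.values())
    two_sigma_sq = 2.0 * rp.peak_sigma_bp**2
    for r, w in weights.items():
        mu = locus.size_of(r)
        if rp.size_jitter_sd_bp > 0:
            mu += rng.normal(0.0, rp.size_jitter_sd_bp)
        y += scale * w * np.exp(-((x - mu) ** 2) / two_sigma_sq)
    if rp.baseline_sd > 0:
        y += rng.normal(0.0, rp.baseline_sd, size=y.shape)
    np.clip(y, 0.0, None, out=y)
    return Trace(sample_id=sample_id, x=x, y=y, calibrated=True)


def peak_set_from_distribution(
    dist: RepeatDistribution,
    locus: RepeatLocus,
    rp: TraceRenderParams = TraceRenderParams(),
    sample_id: str = "synthetic",
) -> RepeatPeakSet:
    """Idealized peak table of a distribution (no CE noise): abundance times
    length decay, scaled so the tallest peak equals ``amplitude``."""
    dist = _validated_dist(dist)
    main = _main_repeat(dist)
    weights = {
        r: w * rp.decay_per_repeat ** (r - main)
        for r, w in dist.items()
        if locus.window_min_repeat <= r <= locus.window_max_repeat and w > 0
    }
    if not weights:
        return RepeatPeakSet(sample_id=sample_id, heights={}, locus=locus)
    scale = rp.amplitude / max(weights.values())
    return RepeatPeakSet(
        sample_id=sample_id,
        heights={r: scale * w for r, w in weights.items()},
        locus=locus,
    )


def simulate_cohort(
    design: CohortDesign,
    output: str = "peaks",
) -> Tuple[Union[List[RepeatPeakSet], List[Trace]], CohortTruth]:
    """Simulate every animal of a cohort design.

    ``output="peaks"`` yields idealized :class:`RepeatPeakSet` per animal
    (amplicon distribution after stutter, no CE noise); ``output="traces"``
    yields rendered electropherograms. Per-animal seeds are derived from the
    design seed, the group label and the animal index, so the whole cohort
    is reproducible and no seed is reused across groups.
    """
    if output not in ("peaks", "traces"):
        raise InvalidParameterError("output must be 'peaks' or 'traces'")
    samples: list = []
    rows = []
    for g in design.groups:
        for i in range(g.n_animals):
            aseed = derive_seed(design.seed, g.label, i)
            factor = 1.0
            if g.rate_cv > 0:
                shape = 1.0 / g.rate_cv**2
                factor = float(np.random.default_rng(derive_seed(aseed, "animal")).gamma(shape, 1.0 / shape))
            p = replace(
                g.expansion,
                expansion_rate=g.expansion.expansion_rate * factor,
                contraction_rate=g.expansion.contraction_rate * factor,
                seed=derive_seed(aseed, "cells"),
            )
            sample_id = f"{g.label}_{i + 1:02d}"
            dist = apply_stutter(simulate_cell_population(p), g.stutter)
            if output == "peaks":
                samples.append(
                    peak_set_from_distribution(dist, design.locus, g.render, sample_id=sample_id)
                )
            else:
                rp = replace(g.render, seed=derive_seed(aseed, "render"))
                samples.append(render_trace(dist, design.locus, rp, sample_id=sample_id))
            rows.append({"group": g.label, "animal": sample_id, "true_gain": p.true_mean_gain})
    truth = CohortTruth(
        per_animal=pd.DataFrame(rows),
        per_group={g.label: g.expansion.true_mean_gain for g in design.groups},
    )
    return samples, truth


def blocked_expansion_design(
    gains: Optional[Dict[str, float]] = None,
    n_animals: int = 6,
    inherited_repeat: int = 110,
    months: float = 2.0,
    expanding_fraction: float = 0.5,
    n_cells: int = 100_000,
    rate_cv: float = 0.3,
    stutter: StutterParams = StutterParams(),
    render: TraceRenderParams = TraceRenderParams(),
    locus: RepeatLocus = HTT_CAG_LOCUS,
    seed: int = 0,
) -> CohortDesign:
    """Study-shaped cohort: baseline / vehicle / non-targeting control /
    treated groups with specified true mean repeat gains.

    ``gains`` maps group label to tissue-level true mean gain; the
    expansion rate solves ``gain = expanding_fraction * rate * months``.
    Defaults mirror a blocked-expansion experiment: untreated baseline at
    injection age (gain 0), PBS and NTC controls expanding freely, and a
    treated group with strongly suppressed expansion.
    """
    if gains is None:
        gains = {"baseline": 0.0, "PBS": 4.0, "NTC": 4.0, "siMSH3": 0.5}
    denom = expanding_fraction * months
    groups = []
    for label, gain in gains.items():
        if gain < 0:
            raise InvalidParameterError("group gains must be >= 0")
        rate = gain / denom if denom > 0 else 0.0
        groups.append(
            GroupSpec(
                label=label,
                n_animals=n_animals,
                expansion=ExpansionModelParams(
                    inherited_repeat=inherited_repeat,
                    expansion_rate=rate,
                    months=months,
                    n_cells=n_cells,
                    expanding_fraction=expanding_fraction,
                ),
                stutter=stutter,
                render=render,
                rate_cv=rate_cv,
            )
        )
    return CohortDesign(groups=tuple(groups), locus=locus, seed=seed)
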