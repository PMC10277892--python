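"""Run configuration: a single YAML file with CLI overrides.

Precedence is CLI > config file > package defaults. Only the keys a command
needs have to be present; ``simulate`` additionally requires a
``simulation`` section describing the cohort design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, Optional

import yaml

from .errors import ConfigError, InvalidParameterError
from .synthetic import (
    CohortDesign,
    ExpansionModelParams,
    GroupSpec,
    StutterParams,
    TraceRenderParams,
)
from .traceio import RepeatLocus

__all__ = ["RunConfig", "load_config", "design_from_config"]

DEFAULT_LOCUS = RepeatLocus(
    name="Htt_CAG", repeat_unit="CAG", flank_bp=100.0,
    window_min_repeat=70, window_max_repeat=170,
)


@dataclass
class RunConfig:
    locus: RepeatLocus = DEFAULT_LOCUS
    threshold_frac: float = 0.05
    smooth_window_bp: float = 0.5
    min_height: float = 50.0
    min_prominence: float = 25.0
    residual_tol_bp: float = 1.0
    control: Optional[str] = None
    alpha: float = 0.05
    seed: int = 0
    n_mc: int = 200_000
    simulation: Optional[Dict[str, Any]] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold_frac < 1.0:
            raise ConfigError("threshold_frac must be in [0, 1)")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError("alpha must be in (0, 1)")


def load_config(path: Optional[str]) -> RunConfig:
    """Load a YAML config; ``None`` returns package defaults."""
    if path is None:
        return RunConfig()
    p = Path(path)
    if not p.exists():
        raise ConfigError(f"config file not found: {p}")
    try:
        raw = yaml.safe_load(p.read_text(encoding="utf-8")) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"{p}: invalid YAML ({exc})") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{p}: top level must be a mapping")

    kwargs: Dict[str, Any] = {}
    if "locus" in raw:
        try:
            kwargs["locus"] = RepeatLocus(**raw["locus"])
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"{p}: bad locus section ({exc})") from exc
    if "threshold_frac" in raw:
        kwargs["threshold_frac"] = float(raw["threshold_frac"])
    for key in ("smooth_window_bp", "min_height", "min_prominence", "residual_tol_bp"):
        if key in raw.get("peakcall", {}):
            kwargs[key] = float(raw["peakcall"][key])
    stats = raw.get("stats", {})
    if "control" in stats:
        kwargs["control"] = str(stats["control"])
    if "alpha" in stats:
        kwargs["alpha"] = float(stats["alpha"])
    if "seed" in stats:
        kwargs["seed"] = int(stats["seed"])
    if "n_mc" in stats:
        kwargs["n_mc"] = int(stats["n_mc"])
    if "simulation" in raw:
        kwargs["simulation"] = raw["simulation"]
    try:
        return RunConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{p}: {exc}") from exc


def design_from_config(cfg: RunConfig, seed: Optional[int] = None) -> CohortDesign:
    """Build a :class:`CohortDesign` from the config's ``simulation`` section.

    Each group entry gives either ``gain`` (tissue-level true mean repeat
    gain; the expansion rate is solved from it) or an explicit
    ``expansion_rate``.
    """
    sim = cfg.simulation
    if not sim:
        raise ConfigError("config has no 'simulation' section")
    try:
        months = float(sim.get("months", 2.0))
        fraction = float(sim.get("expanding_fraction", 0.5))
        n_cells = int(sim.get("n_cells", 100_000))
        inherited = int(sim.get("inherited_repeat", 110))
        rate_cv = float(sim.get("rate_cv", 0.3))
        stutter = StutterParams(**sim.get("stutter", {}))
        render = TraceRenderParams(**sim.get("render", {}))
        design_seed = int(seed if seed is not None else sim.get("seed", cfg.seed))
        groups = []
        for spec in sim["groups"]:
            label = str(spec["label"])
            n_animals = int(spec.get("n_animals", 6))
            if "expansion_rate" in spec:
                rate = float(spec["expansion_rate"])
            else:
                gain = float(spec.get("gain", 0.0))
                denom = fraction * months
                rate = gain / denom if denom > 0 else 0.0
            groups.append(
                GroupSpec(
                    label=label,
                    n_animals=n_animals,
                    expansion=ExpansionModelParams(
                        inherited_repeat=int(spec.get("inherited_repeat", inherited)),
                        expansion_rate=rate,
                        contraction_rate=float(spec.get("contraction_rate", 0.0)),
                        months=months,
                        n_cells=n_cells,
                        expanding_fraction=fraction,
                    ),
                    stutter=stutter,
                    render=render,
                    rate_cv=float(spec.get("rate_cv", rate_cv)),
                )
            )
        return CohortDesign(groups=tuple(groups), locus=cfg.locus, seed=design_seed)
    except (KeyError, TypeError, ValueError, InvalidParameterError) as exc:
        raise ConfigError(f"bad simulation section: {exc}") from exc
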