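"""Run configuration: YAML/JSON parsing, validation, protocol defaults.

Omitted keys fall back to the protocol's constants (lead 6, truncation at
150 matched sets, interim totals 500/1000/1500 with terminal 1908,
two-tailed alphas 0.001 interim / 0.025 terminal / 0.05 overall Holm,
8-percentage-point poor-outcome margin).  Unknown keys are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Optional, Tuple, Union

import yaml

from .engine import GSConfig
from .outcomes import RapidResponse
from .phase2 import Phase2Config
from .schemes import XRegionSpec, YRegionSpec
from .selection import SelectionConfig

__all__ = ["RunConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Configuration file violates the schema."""


@dataclass(frozen=True)
class EnsembleConfig:
    """Nested factorial sizes of the null ensemble.

    Defaults give the 200-scheme desk scale (10 X-cells x 5 Y-marginals
    x 4 conditional sets); the full-scale study uses 10 x 10 x 10.
    """

    n_x: int = 10
    n_y: int = 5
    n_cond: int = 4

    def __post_init__(self) -> None:
        if min(self.n_x, self.n_y, self.n_cond) < 1:
            raise ConfigError("ensemble sizes must be positive integers")


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration for a full run."""

    selection: SelectionConfig = field(default_factory=SelectionConfig)
    phase2: Phase2Config = field(default_factory=Phase2Config)
    gs: GSConfig = field(default_factory=GSConfig)
    x_region: XRegionSpec = field(default_factory=XRegionSpec)
    y_region: YRegionSpec = field(default_factory=YRegionSpec)
    ensemble: EnsembleConfig = field(default_factory=EnsembleConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        """Full normalized key tree (round-trip stable)."""
        s = self.selection
        return {
            "selection": {
                "lead": s.lead,
                "truncation_m": s.truncation_m,
                "scores": {
                    "ICH": s.scores[RapidResponse.ICH],
                    "NEI": s.scores[RapidResponse.NEI],
                    "MNI": s.scores[RapidResponse.MNI],
                },
                "cascade": s.cascade,
            },
            "phase2": {
                "poor_margin": self.phase2.poor_margin,
                "ich_scenario_threshold": self.phase2.ich_scenario_threshold,
            },
            "alpha": {
                "interim": self.gs.alpha_interim,
                "terminal": self.gs.alpha_terminal,
                "holm_overall": self.gs.holm_overall,
            },
            "gs": {
                "assessment_min_per_arm": self.gs.assessment_min_per_arm,
                "assessment_max_sets": self.gs.assessment_max_sets,
                "interim_totals": list(self.gs.interim_totals),
                "terminal_total": self.gs.terminal_total,
                "stop_on_interim_rejection": self.gs.stop_on_interim_rejection,
            },
            "regions": {
                "x": {"ich": list(self.x_region.ich), "mni": list(self.x_region.mni)},
                "y": {"poor": list(self.y_region.poor), "good": list(self.y_region.good)},
            },
            "ensemble": {
                "n_x": self.ensemble.n_x,
                "n_y": self.ensemble.n_y,
                "n_cond": self.ensemble.n_cond,
            },
            "seed": self.seed,
        }


def _take(section: dict, key: str, default: Any) -> Any:
    return section.pop(key) if key in section else default


def _no_leftovers(section: Mapping, where: str) -> None:
    if section:
        raise ConfigError(f"unknown key(s) {sorted(section)} in section {where!r}")


def _pair(v: Any, where: str) -> Tuple[float, float]:
    try:
        lo, hi = float(v[0]), float(v[1])
    except (TypeError, ValueError, IndexError) as exc:
        raise ConfigError(f"{where} must be a [lo, hi] pair") from exc
    return lo, hi


def from_dict(doc: Optional[Mapping[str, Any]]) -> RunConfig:
    """Build a validated RunConfig from a nested mapping."""
    doc = dict(doc or {})
    defaults = RunConfig()

    sel = dict(doc.pop("selection", {}) or {})
    scores_doc = dict(_take(sel, "scores", None) or {})
    if scores_doc:
        try:
            scores = {RapidResponse[k]: int(v) for k, v in scores_doc.items()}
        except KeyError as exc:
            raise ConfigError(f"unknown rapid-response category {exc} in selection.scores")
    else:
        scores = dict(defaults.selection.scores)
    try:
        selection = SelectionConfig(
            lead=int(_take(sel, "lead", defaults.selection.lead)),
            truncation_m=int(_take(sel, "truncation_m", defaults.selection.truncation_m)),
            scores=scores,
            cascade=bool(_take(sel, "cascade", defaults.selection.cascade)),
        )
    except ValueError as exc:
        raise ConfigError(f"selection: {exc}") from exc
    _no_leftovers(sel, "selection")

    p2 = dict(doc.pop("phase2", {}) or {})
    try:
        phase2 = Phase2Config(
            poor_margin=float(_take(p2, "poor_margin", defaults.phase2.poor_margin)),
            ich_scenario_threshold=int(
                _take(p2, "ich_scenario_threshold", defaults.phase2.ich_scenario_threshold)
            ),
        )
    except ValueError as exc:
        raise ConfigError(f"phase2: {exc}") from exc
    _no_leftovers(p2, "phase2")

    alpha = dict(doc.pop("alpha", {}) or {})
    gs_doc = dict(doc.pop("gs", {}) or {})
    try:
        gs = GSConfig(
            assessment_min_per_arm=int(
                _take(gs_doc, "assessment_min_per_arm", defaults.gs.assessment_min_per_arm)
            ),
            assessment_max_sets=int(
                _take(gs_doc, "assessment_max_sets", defaults.gs.assessment_max_sets)
            ),
            interim_totals=tuple(
                int(t) for t in _take(gs_doc, "interim_totals", defaults.gs.interim_totals)
            ),
            terminal_total=int(_take(gs_doc, "terminal_total", defaults.gs.terminal_total)),
            alpha_interim=float(_take(alpha, "interim", defaults.gs.alpha_interim)),
            alpha_terminal=float(_take(alpha, "terminal", defaults.gs.alpha_terminal)),
            holm_overall=float(_take(alpha, "holm_overall", defaults.gs.holm_overall)),
            stop_on_interim_rejection=bool(
                _take(
                    gs_doc,
                    "stop_on_interim_rejection",
                    defaults.gs.stop_on_interim_rejection,
                )
            ),
        )
    except ValueError as exc:
        raise ConfigError(f"gs/alpha: {exc}") from exc
    _no_leftovers(alpha, "alpha")
    _no_leftovers(gs_doc, "gs")

    regions = dict(doc.pop("regions", {}) or {})
    xr = dict(regions.pop("x", {}) or {})
    yr = dict(regions.pop("y", {}) or {})
    try:
        x_region = XRegionSpec(
            ich=_pair(_take(xr, "ich", defaults.x_region.ich), "regions.x.ich"),
            mni=_pair(_take(xr, "mni", defaults.x_region.mni), "regions.x.mni"),
        )
        y_region = YRegionSpec(
            poor=_pair(_take(yr, "poor", defaults.y_region.poor), "regions.y.poor"),
            good=_pair(_take(yr, "good", defaults.y_region.good), "regions.y.good"),
        )
    except ValueError as exc:
        raise ConfigError(f"regions: {exc}") from exc
    _no_leftovers(xr, "regions.x")
    _no_leftovers(yr, "regions.y")
    _no_leftovers(regions, "regions")

    ens = dict(doc.pop("ensemble", {}) or {})
    ensemble = EnsembleConfig(
        n_x=int(_take(ens, "n_x", defaults.ensemble.n_x)),
        n_y=int(_take(ens, "n_y", defaults.ensemble.n_y)),
        n_cond=int(_take(ens, "n_cond", defaults.ensemble.n_cond)),
    )
    _no_leftovers(ens, "ensemble")

    seed = doc.pop("seed", 0)
    if not isinstance(seed, int) or seed < 0:
        raise ConfigError("seed must be a non-negative integer")
    _no_leftovers(doc, "<top level>")

    return RunConfig(
        selection=selection,
        phase2=phase2,
        gs=gs,
        x_region=x_region,
        y_region=y_region,
        ensemble=ensemble,
        seed=seed,
    )


def load_config(path: Union[str, Path, None]) -> RunConfig:
    """Load and validate a YAML or JSON config file (None -> all defaults)."""
    if path is None:
        return RunConfig()
    text = Path(path).read_text()
    doc = yaml.safe_load(text)
    if doc is None:
        doc = {}
    if not isinstance(doc, Mapping):
        raise ConfigError("config file must contain a mapping at the top level")
    return from_dict(doc)
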