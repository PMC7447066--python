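"""Key-value analysis configuration (YAML), mirroring the CLI flags."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["AnalysisConfig", "load_config", "save_config"]


@dataclass
class AnalysisConfig:
    """Tunable spans and cutoffs for the whole pipeline (nm / deg / fractions)."""

    loop_span: tuple[int, int] = (40, 63)
    helix_spans: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {"h1": (3, 19), "h2": (23, 39), "h3": (64, 78), "h4": (82, 98)}
    )
    hydrophobic_set: tuple[str, ...] = ("ALA", "VAL", "LEU", "ILE", "PRO", "PHE", "MET", "TRP")
    window_fraction: float = 0.10
    bin_width: float = 0.01
    reform_cutoff: float = 0.40
    reform_verdict_threshold: float = 0.5
    hb_distance: float = 0.35
    hb_angle: float = 30.0
    contact_cutoff: float = 0.45
    cation_pi_cutoff: float = 0.6
    protonation_overrides: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.window_fraction <= 1.0):
            raise ValueError("window_fraction must be in (0, 1]")
        for name in ("bin_width", "reform_cutoff", "hb_distance", "hb_angle",
                     "contact_cutoff", "cation_pi_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def load_config(path: str | Path) -> AnalysisConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "loop_span" in raw:
        raw["loop_span"] = tuple(raw["loop_span"])
    if "helix_spans" in raw:
        raw["helix_spans"] = {k: tuple(v) for k, v in raw["helix_spans"].items()}
    if "hydrophobic_set" in raw:
        raw["hydrophobic_set"] = tuple(raw["hydrophobic_set"])
    return AnalysisConfig(**raw)


def save_config(cfg: AnalysisConfig, path: str | Path) -> None:
    data = asdict(cfg)
    data["loop_span"] = list(cfg.loop_span)
    data["helix_spans"] = {k: list(v) for k, v in cfg.helix_spans.items()}
    data["hydrophobic_set"] = list(cfg.hydrophobic_set)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
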