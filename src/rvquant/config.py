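"""Run configuration: geometric conventions and output options.

Several geometric choices of the parcellation (layer height fractions,
angular conventions, chirality) and of the statistics (consensus vs
per-expert averaging) are conventions rather than facts, so every run
records them in a validated config that the provenance record preserves.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["RunConfig", "ConfigError"]


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass
class RunConfig:
    #: normalized-height boundaries apical|medial, medial|basal, basal|valvular
    layer_bounds: tuple = (0.25, 0.50, 0.75)
    #: flip the left/right handedness for mirrored anatomies
    flip_chirality: bool = False
    #: 'consensus' combines experts by the >0.5 vote before the regional
    #: statistics; 'per_expert' computes per-expert deltas and averages them
    consensus_mode: str = "consensus"
    #: in-plane rasterization spacing for contour stacks, mm
    raster_spacing: float = 1.0
    #: number of short-axis overlay planes
    n_overlay_planes: int = 4
    seed: int = 0
    figure_dpi: int = 150
    colormap: str = "RdBu_r"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        b = tuple(float(x) for x in self.layer_bounds)
        if len(b) != 3 or not (0.0 < b[0] < b[1] < b[2] < 1.0):
            raise ConfigError(
                f"layer_bounds must be strictly increasing in (0, 1), got {b}")
        self.layer_bounds = b
        if self.consensus_mode not in ("consensus", "per_expert"):
            raise ConfigError(
                f"consensus_mode must be 'consensus' or 'per_expert', got {self.consensus_mode!r}")
        if self.raster_spacing <= 0:
            raise ConfigError("raster_spacing must be positive")
        if self.n_overlay_planes < 1:
            raise ConfigError("n_overlay_planes must be >= 1")
        if self.figure_dpi < 1:
            raise ConfigError("figure_dpi must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "layer_bounds" in raw:
            raw["layer_bounds"] = tuple(raw["layer_bounds"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["layer_bounds"] = list(d["layer_bounds"])
        return d

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
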