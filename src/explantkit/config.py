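"""Run configuration: a flat key-value (TOML) file per analysis run."""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass
from pathlib import Path

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    """Parameters shared across the analysis stages.

    ``bin_width`` is the normalized-distance bin for gradient profiles
    (0.04 for explants, 0.02 for embryos — about two cell diameters);
    ``depth_limits`` gates nuclei by imaging depth (µm);
    ``background_spot_count`` is the number of cytoplasmic background
    spots per channel side; circle diameters are in pixels, as the
    measurement protocols specify them.
    """

    analysis_mode: str = "explant"
    bin_width: float = 0.04
    depth_limits: tuple[float, float] = (0.0, 180.0)
    background_spot_count: int = 12
    nuclear_circle_diameter_px: int = 6
    cytoplasm_circle_diameter_px: int = 4
    edge_fraction: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        if self.analysis_mode not in ("explant", "embryo"):
            raise ValueError("analysis_mode must be 'explant' or 'embryo'")
        if not 0 < self.bin_width <= 0.5:
            raise ValueError("bin_width must be in (0, 0.5]")
        for name in ("background_spot_count", "nuclear_circle_diameter_px",
                     "cytoplasm_circle_diameter_px"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        lo, hi = self.depth_limits
        if not lo <= hi:
            raise ValueError("depth_limits must be an increasing range")

    @classmethod
    def for_mode(cls, mode: str, **overrides) -> "RunConfig":
        """Mode presets: explant (bin 0.04, depth <= 180 µm) or embryo
        (bin 0.02, depth 60-120 µm from the animal pole)."""
        defaults = {
            "explant": dict(analysis_mode="explant", bin_width=0.04,
                            depth_limits=(0.0, 180.0)),
            "embryo": dict(analysis_mode="embryo", bin_width=0.02,
                           depth_limits=(60.0, 120.0)),
        }[mode]
        defaults.update(overrides)
        return cls(**defaults)


def load_config(path: str | Path) -> RunConfig:
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    if "depth_limits" in raw:
        raw["depth_limits"] = tuple(raw["depth_limits"])
    return RunConfig(**raw)


def save_config(config: RunConfig, path: str | Path) -> None:
    lines = []
    for f in dataclasses.fields(config):
        v = getattr(config, f.name)
        if isinstance(v, str):
            lines.append(f'{f.name} = "{v}"')
        elif isinstance(v, tuple):
            lines.append(f"{f.name} = [{', '.join(str(x) for x in v)}]")
        elif isinstance(v, bool):
            lines.append(f"{f.name} = {str(v).lower()}")
        else:
            lines.append(f"{f.name} = {v}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
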