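"""Run configuration: defaults mirror the measurement conventions used
throughout (19.9-um arc step, principal-curve df 10 / inset df 60, smoothing
df = n/2, 1/8-diameter insets, 5-degree alignment resolution, 0.76-mm /
R^2 > 0.95 sine-law segment rule)."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    # input / simulation
    input_dir: str | None = None        # fixture dir with TIFFs + manifest
    simulate: bool = True               # generate a synthetic recording first
    pixel_scale: float | None = 16.0    # um/pixel; required for external TIFFs
    frame_interval: float = 0.170       # h
    t_end: float = 6.10                 # h
    raster: tuple[int, int] = (512, 512)

    # GP simulation parameters
    beta: float = 0.4                   # mm^-1 h^-1
    gamma: float = 1.5                  # h^-1
    base_angle: float = 90.0            # deg
    length: float = 4.0                 # mm
    rod_diameter: float = 0.25          # mm
    noise: bool = True

    # analysis parameters
    step_um: float = 19.9
    df_median: float = 10.0
    df_inset: float = 60.0
    df_frac: float = 0.5                # smoothing df as a fraction of n
    inset_fraction: float = 0.125
    align_resolution: float = 5.0       # deg
    trough_min_extent: float = 0.5      # mm
    trough_depth_frac: float = 0.3
    tip_margin: float = 0.3             # mm masked at the free tip end
    s_min: float = 0.0                  # mm, apical restriction for fits
    min_segment_mm: float = 0.76
    r2_min: float = 0.95
    threshold_method: str = "otsu"
    anchor_edge: str = "nearest"        # base pick for the first frame
    include_intercept: bool = False

    seed: int = 0
    out_dir: str = "run"

    @property
    def step_mm(self) -> float:
        return self.step_um / 1000.0

    def validate(self) -> None:
        if not self.simulate and self.input_dir is None:
            raise ConfigError("config: either 'simulate' or 'input_dir' is required")
        if not self.simulate and self.pixel_scale is None:
            raise ConfigError("config key 'pixel_scale' is required for external TIFFs")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["raster"] = list(self.raster)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "raster" in data:
            data["raster"] = tuple(data["raster"])
        return cls(**data)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
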