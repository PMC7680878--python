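"""Run configuration shared by the CLI and the batch pipeline."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

from .colorspace import HUE_MIN_DEG, HUE_MAX_DEG, SAT_MIN_FRAC

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All tunable pipeline parameters with their defaults.

    Every report written by the pipeline embeds the effective config so
    a run can be reproduced exactly.
    """

    # foreground / background separation
    white_thresh: float = 0.85
    sat_thresh: float = 0.15
    # texture segmentation
    window: int = 5
    texture_thresh: float | None = None   # None -> Otsu; else quantile in [0,1]
    morph_radius: int = 2
    # yellow-red gamut filter (off by default: purple/brown petals are valid)
    apply_gamut: bool = False
    hue_min: float = HUE_MIN_DEG
    hue_max: float = HUE_MAX_DEG
    sat_min_frac: float = SAT_MIN_FRAC
    # clustering / classification
    k: int = 3
    seed: int = 0
    use_L: bool = False
    multicolor_thresh: float = 20.0
    # reporting
    palette_path: str | None = None
    plot_subsample: int = 5000

    def segmentation_kwargs(self) -> dict:
        return {
            "white_thresh": self.white_thresh,
            "sat_thresh": self.sat_thresh,
            "window": self.window,
            "texture_thresh": self.texture_thresh,
            "morph_radius": self.morph_radius,
            "apply_gamut": self.apply_gamut,
        }

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        doc = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)
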