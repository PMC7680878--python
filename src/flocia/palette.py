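"""Reference palette of UPOV ray-floret color categories.

The seven categories of the UPOV sunflower descriptor — *yellowish white*
through *reddish brown* — are each represented by a mean color vector
``mu_c`` in Lab8 space, computed from exemplar images.  "Multicolored" is
not a palette entry: it is a judgment derived from the per-category
percentages (see :mod:`flocia.classification`).

Because the descriptor's own exemplar scans are not redistributable, the
package ships a default palette built from synthetic flat-color swatches,
one plausible sRGB color per category name.  Rebuild from real descriptor
scans with :func:`build_palette` to match an actual calibration set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .colorspace import rgb_to_lab8

__all__ = [
    "CATEGORY_NAMES",
    "ReferencePalette",
    "build_palette",
    "default_palette",
    "save_palette",
    "load_palette",
    "DEFAULT_SWATCH_RGB",
]

#: The seven UPOV ray-floret color categories, in descriptor order (1..7).
CATEGORY_NAMES: tuple[str, ...] = (
    "yellowish white",
    "light yellow",
    "medium yellow",
    "orange yellow",
    "orange",
    "purple",
    "reddish brown",
)

#: Synthetic sRGB swatch per category used to build the default palette.
#: Colors are plausible for the category names; they are NOT calibrated
#: against any official descriptor scan.
DEFAULT_SWATCH_RGB: dict[str, tuple[int, int, int]] = {
    "yellowish white": (252, 244, 200),
    "light yellow": (255, 236, 140),
    "medium yellow": (255, 214, 64),
    "orange yellow": (255, 178, 32),
    "orange": (244, 124, 24),
    "purple": (122, 38, 92),
    "reddish brown": (128, 52, 32),
}


class PaletteError(ValueError):
    """Raised for incomplete or inconsistent palettes."""


@dataclass(frozen=True)
class ReferencePalette:
    """Ordered mapping of the 7 categories to Lab8 mean vectors.

    Attributes
    ----------
    entries : dict
        ``{category name: (L8, a8, b8) ndarray}`` in descriptor order.
    provenance : dict
        ``{category name: list of source identifiers}``.
    """

    entries: dict[str, np.ndarray]
    provenance: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if tuple(self.entries) != CATEGORY_NAMES:
            raise PaletteError(
                f"palette must contain exactly the 7 categories in order; "
                f"got {tuple(self.entries)!r}"
            )
        vecs = self.vectors()
        if vecs.shape != (7, 3):
            raise PaletteError("each palette entry must be a 3-vector")
        if np.any(vecs < 0) or np.any(vecs > 255):
            raise PaletteError("palette vectors must lie in [0, 255]")
        # distinctness: no two categories may collapse onto one vector
        for i in range(7):
            for j in range(i + 1, 7):
                if np.allclose(vecs[i], vecs[j]):
                    raise PaletteError(
                        f"categories {CATEGORY_NAMES[i]!r} and "
                        f"{CATEGORY_NAMES[j]!r} have identical mean vectors"
                    )

    def vectors(self) -> np.ndarray:
        """(7, 3) array of Lab8 mean vectors in category order."""
        return np.array([self.entries[n] for n in CATEGORY_NAMES], dtype=np.float64)

    def ab_vectors(self) -> np.ndarray:
        """(7, 2) array of the chroma (a8, b8) components."""
        return self.vectors()[:, 1:]

    def __getitem__(self, name: str) -> np.ndarray:
        return self.entries[name]


def build_palette(
    exemplars: Iterable[tuple[str, np.ndarray, np.ndarray]],
) -> ReferencePalette:
    """Build a palette from masked exemplar images.

    Parameters
    ----------
    exemplars : iterable of (category name, RGB image, boolean mask)
        At least one exemplar per category; a category's mean vector is
        the arithmetic mean of Lab8 pixels pooled over all of its
        exemplars' masks.  The result is invariant to exemplar order.
    """
    sums: dict[str, np.ndarray] = {n: np.zeros(3) for n in CATEGORY_NAMES}
    counts: dict[str, int] = {n: 0 for n in CATEGORY_NAMES}
    sources: dict[str, list[str]] = {n: [] for n in CATEGORY_NAMES}
    for idx, (name, img, mask) in enumerate(exemplars):
        if name not in sums:
            raise PaletteError(f"unknown category {name!r}")
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise PaletteError(f"empty mask for exemplar {idx} ({name!r})")
        lab8 = rgb_to_lab8(img)
        sums[name] += lab8[mask].sum(axis=0)
        counts[name] += int(mask.sum())
        sources[name].append(f"exemplar-{idx}")
    missing = [n for n in CATEGORY_NAMES if counts[n] == 0]
    if missing:
        raise PaletteError(f"no exemplars for categories: {missing}")
    entries = {n: sums[n] / counts[n] for n in CATEGORY_NAMES}
    return ReferencePalette(entries=entries, provenance=sources)


def default_palette() -> ReferencePalette:
    """Palette built from the package's synthetic flat-color swatches."""
    exemplars = []
    for name, rgb in DEFAULT_SWATCH_RGB.items():
        swatch = np.full((8, 8, 3), rgb, dtype=np.uint8)
        exemplars.append((name, swatch, np.ones((8, 8), dtype=bool)))
    pal = build_palette(exemplars)
    prov = {n: ["builtin-synthetic-swatch"] for n in CATEGORY_NAMES}
    return ReferencePalette(entries=pal.entries, provenance=prov)


def save_palette(palette: ReferencePalette, path: str | Path) -> None:
    """Write a palette to JSON (vectors serialized as decimal text)."""
    cats = []
    for i, name in enumerate(CATEGORY_NAMES, start=1):
        v = palette.entries[name]
        cats.append(
            {
                "index": i,
                "name": name,
                "L": repr(float(v[0])),
                "a": repr(float(v[1])),
                "b": repr(float(v[2])),
                "sources": palette.provenance.get(name, []),
            }
        )
    Path(path).write_text(json.dumps({"categories": cats}, indent=2))


def load_palette(path: str | Path) -> ReferencePalette:
    """Load a palette saved by :func:`save_palette`.

    The save/load round trip preserves vector values exactly.
    """
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise PaletteError(f"malformed palette JSON: {exc}") from exc
    cats = doc.get("categories")
    if not isinstance(cats, list) or len(cats) != 7:
        n = len(cats) if isinstance(cats, list) else "no"
        raise PaletteError(f"palette must list exactly 7 categories, found {n}")
    entries: dict[str, np.ndarray] = {}
    provenance: dict[str, list[str]] = {}
    for c in sorted(cats, key=lambda c: c.get("index", 0)):
        try:
            name = c["name"]
            vec = np.array([float(c["L"]), float(c["a"]), float(c["b"])])
        except (KeyError, TypeError, ValueError) as exc:
            raise PaletteError(f"malformed palette entry: {c!r}") from exc
        entries[name] = vec
        provenance[name] = list(c.get("sources", []))
    return ReferencePalette(entries=entries, provenance=provenance)
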