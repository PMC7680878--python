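"""Deterministic synthetic flowers and rating tables for testing.

:func:`generate_flower` renders a single composite flower head the way
the acquisition protocol expects to see one: smooth radial petals of
known palette colors around a high-frequency speckled disk, on a
near-white background.  The renderer returns the exact ground-truth
masks and per-category pixel fractions, so segmentation and
classification can be scored against a known answer.  The emulation is
statistical, not photorealistic: petals are rounded wedges, chroma noise
is isotropic Gaussian on (a8, b8), and lightness carries a mild radial
shading gradient to exercise the illumination-invariant (ab-plane)
design of the classifier.

:func:`generate_ratings` simulates many raters assigning subjects to
categories at a controllable agreement level, as a test harness for
Fleiss kappa.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .colorspace import lab8_to_rgb, rgb_to_lab8
from .evaluation import RatingTable
from .palette import CATEGORY_NAMES, DEFAULT_SWATCH_RGB

__all__ = [
    "SyntheticFlowerSpec",
    "GroundTruth",
    "generate_flower",
    "generate_ratings",
]


@dataclass(frozen=True)
class SyntheticFlowerSpec:
    """Parameters of one synthetic flower rendering.

    Attributes
    ----------
    size : int
        Side length of the square output image in pixels.
    disk_radius_frac : float
        Disk radius as a fraction of the flower radius; 0 renders a
        disk-free flower.
    petal_count : int
        Number of petal lobes around the head.
    composition : dict
        ``{category name: target fraction}`` of petal area; fractions
        must sum to 1.  Colors are the palette swatch colors.
    chroma_sigma : float
        Std dev of Gaussian noise added to petal (a8, b8), in Lab8 units.
    noise_correlation_px : float
        Spatial correlation length of the petal chroma noise, in pixels.
        Petal color varies smoothly (correlated field); set to 0 for
        white noise.
    speckle_amplitude : float
        Half-range of the uniform per-pixel speckle on the disk (8-bit
        RGB units); drives the texture contrast of disk florets.
    background_rgb : tuple
        Near-white backdrop color.
    seed : int
        Renders are byte-identical for a fixed spec and seed.
    """

    size: int = 256
    disk_radius_frac: float = 0.45
    petal_count: int = 16
    composition: dict[str, float] = field(
        default_factory=lambda: {"medium yellow": 1.0}
    )
    chroma_sigma: float = 3.0
    noise_correlation_px: float = 3.0
    speckle_amplitude: float = 60.0
    background_rgb: tuple[int, int, int] = (248, 248, 246)
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.composition.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"composition fractions sum to {total}, expected 1")
        unknown = set(self.composition) - set(CATEGORY_NAMES)
        if unknown:
            raise ValueError(f"unknown categories in composition: {sorted(unknown)}")
        if not 0.0 <= self.disk_radius_frac < 1.0:
            raise ValueError("disk_radius_frac must be in [0, 1)")


@dataclass(frozen=True)
class GroundTruth:
    """Exact masks and composition of a rendered flower."""

    flower: np.ndarray   # petals + disk
    disk: np.ndarray
    petals: np.ndarray
    composition: dict[str, float]   # measured fractions of petal pixels

    def __post_init__(self) -> None:
        if np.any(self.disk & ~self.flower) or np.any(self.petals != (self.flower & ~self.disk)):
            raise ValueError("ground-truth mask algebra violated")


def _chroma_noise_field(
    rng: np.random.Generator, n: int, sigma: float, correlation_px: float
) -> np.ndarray:
    """Gaussian chroma-noise field with the requested marginal std."""
    field = rng.normal(0.0, 1.0, (n, n))
    if correlation_px > 0:
        from scipy import ndimage as ndi

        field = ndi.gaussian_filter(field, correlation_px, mode="reflect")
        sd = field.std()
        if sd > 0:
            field /= sd
    return sigma * field


def generate_flower(spec: SyntheticFlowerSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render a flower image and its ground truth.

    Petal colors are assigned by angular position so that the measured
    per-category fractions track the requested composition to within
    pixel quantization (about a percentage point).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.size
    yy, xx = np.mgrid[0:n, 0:n].astype(np.float64)
    cx = cy = (n - 1) / 2.0
    r = np.hypot(xx - cx, yy - cy)
    theta = np.arctan2(yy - cy, xx - cx) % (2 * np.pi)

    flower_radius = 0.42 * n
    # scalloped petal outline: lobes of depth 12% around the mean radius
    outline = flower_radius * (0.88 + 0.12 * np.abs(np.cos(spec.petal_count * theta / 2.0)))
    disk_radius = spec.disk_radius_frac * flower_radius

    flower = r <= np.maximum(outline, disk_radius)
    disk = r <= disk_radius
    petals = flower & ~disk

    # angular color sectors in requested proportion
    cats = [c for c in CATEGORY_NAMES if c in spec.composition]
    fracs = np.array([spec.composition[c] for c in cats])
    bounds = 2 * np.pi * np.concatenate([[0.0], np.cumsum(fracs)])
    bounds[-1] = 2 * np.pi + 1e-9
    sector = np.digitize(theta, bounds[1:-1])

    # paint petals in Lab8: swatch color + chroma noise + radial shading on L
    swatch_lab8 = {
        c: rgb_to_lab8(np.full((1, 1, 3), DEFAULT_SWATCH_RGB[c], dtype=np.uint8))[0, 0]
        for c in cats
    }
    lab8 = np.zeros((n, n, 3), dtype=np.float64)
    for i, c in enumerate(cats):
        m = petals & (sector == i)
        lab8[m] = swatch_lab8[c]
    shade = 1.0 - 0.08 * (r / flower_radius)
    lab8[petals, 0] *= shade[petals]
    for ch in (1, 2):
        lab8[petals, ch] += _chroma_noise_field(
            rng, n, spec.chroma_sigma, spec.noise_correlation_px
        )[petals]
    lab8 = np.clip(lab8, 0.0, 255.0)

    img = np.zeros((n, n, 3), dtype=np.uint8)
    img[...] = spec.background_rgb
    img[petals] = lab8_to_rgb(lab8[petals][None, :, :])[0]

    # speckled disk: dark base + uniform per-pixel texture noise
    base = np.array([95.0, 62.0, 30.0])
    n_disk = int(disk.sum())
    if n_disk:
        speckle = rng.uniform(-spec.speckle_amplitude, spec.speckle_amplitude, (n_disk, 1))
        img[disk] = np.clip(base + speckle, 0, 255).astype(np.uint8)

    # measured composition from the rendered petal mask
    counts = {c: int((petals & (sector == i)).sum()) for i, c in enumerate(cats)}
    total = max(sum(counts.values()), 1)
    composition = {c: counts[c] / total for c in cats}

    truth = GroundTruth(flower=flower, disk=disk, petals=petals, composition=composition)
    return img, truth


def generate_ratings(
    n_subjects: int,
    n_raters: int,
    agreement: float,
    n_categories: int,
    seed: int = 0,
) -> RatingTable:
    """Simulate a rating table with a controllable agreement level.

    Each subject has a true category drawn uniformly; each rater reports
    it with probability ``agreement`` and otherwise picks uniformly
    among the other categories.  ``agreement=1`` yields unanimity
    (kappa = 1); ``agreement = 1/n_categories`` makes ratings uniform
    and independent, so kappa concentrates near 0 for large N.
    """
    if not 0.0 <= agreement <= 1.0:
        raise ValueError("agreement must be a fraction in [0, 1]")
    if n_subjects < 1 or n_raters < 2 or n_categories < 2:
        raise ValueError("need >=1 subject, >=2 raters and >=2 categories")
    rng = np.random.default_rng(seed)
    truth = rng.integers(0, n_categories, size=n_subjects)
    counts = np.zeros((n_subjects, n_categories), dtype=np.int64)
    for i, t in enumerate(truth):
        correct = rng.random(n_raters) < agreement
        ratings = np.where(
            correct,
            t,
            (t + 1 + rng.integers(0, n_categories - 1, size=n_raters)) % n_categories,
        )
        counts[i] = np.bincount(ratings, minlength=n_categories)
    return RatingTable(counts=counts)
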