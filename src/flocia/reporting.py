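"""Machine-readable reports and color-space plots.

Reports are JSON documents embedding the effective run configuration
and package version; batch runs additionally produce a combined CSV of
per-image category percentages and mean vectors.  Plots show the
(a8, b8) chroma plane (optionally with the L8 axis in 3-D): the pixel
cloud of one image, the seven palette category dots, and the image's
mean-vector dot.
"""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import __version__
from .classification import ClusterResult, CompositionReport, is_multicolored
from .config import RunConfig
from .palette import CATEGORY_NAMES, ReferencePalette
from .segmentation import SegmentationResult

__all__ = ["report_to_dict", "write_report", "combined_table", "plot_color_space"]

# display colors for the seven category dots (sRGB fractions)
_CATEGORY_PLOT_COLORS = {
    "yellowish white": "#fcf4c8",
    "light yellow": "#ffec8c",
    "medium yellow": "#ffd640",
    "orange yellow": "#ffb220",
    "orange": "#f47c18",
    "purple": "#7a265c",
    "reddish brown": "#803420",
}


def report_to_dict(
    report: CompositionReport,
    clusters: ClusterResult | None,
    seg: SegmentationResult,
    config: RunConfig,
    image_id: str = "",
) -> dict:
    """Assemble one image's results into a JSON-serializable record."""
    doc: dict = {
        "image": image_id,
        "software_version": __version__,
        "config": config.to_dict(),
        "n_pixels": report.n_pixels,
        "percentages": report.percentages,
        "dominant_category": report.dominant_category,
        "multicolored": (
            is_multicolored(report, config.multicolor_thresh)
            if report.n_pixels
            else None
        ),
        "mean_vector": (
            None if report.mean_vector is None else [float(v) for v in report.mean_vector]
        ),
        "segmentation_params": seg.params_used,
    }
    if clusters is not None:
        doc["clusters"] = {
            "k_used": clusters.k_used,
            "seed": clusters.seed,
            "sizes": clusters.sizes.tolist(),
            "centers_ab": clusters.centers.tolist(),
            "dominant": list(clusters.dominant),
        }
    return doc


def write_report(doc: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(doc, indent=2))


def combined_table(docs: list[dict]) -> pd.DataFrame:
    """Batch summary: one row per image, category percentages + mean vector."""
    rows = []
    for d in docs:
        row: dict = {"image": d["image"], "n_pixels": d["n_pixels"]}
        for name in CATEGORY_NAMES:
            row[name] = d["percentages"][name]
        row["dominant_category"] = d["dominant_category"]
        mv = d["mean_vector"]
        row["L8"], row["a8"], row["b8"] = (mv if mv else (np.nan,) * 3)
        rows.append(row)
    return pd.DataFrame(rows)


def plot_color_space(
    path: str | Path,
    palette: ReferencePalette,
    pixels: np.ndarray | None = None,
    mean_vector: np.ndarray | None = None,
    mode: str = "2d",
    subsample: int = 5000,
    seed: int = 0,
) -> None:
    """Scatter the palette dots, a pixel cloud and the mean-vector dot.

    Parameters
    ----------
    pixels : (N, 3) Lab8 array, optional
        Ray-floret pixel cloud; subsampled (seeded) for legibility.
    mean_vector : (3,) Lab8 vector, optional
        The image's dominant-color dot.
    mode : "2d" or "3d"
        Chroma plane only, or with the L8 axis added.
    """
    if mode not in ("2d", "3d"):
        raise ValueError("mode must be '2d' or '3d'")
    fig = plt.figure(figsize=(6, 6))
    ax = fig.add_subplot(111, projection="3d" if mode == "3d" else None)

    if pixels is not None and len(pixels):
        pixels = np.asarray(pixels, dtype=np.float64)
        if len(pixels) > subsample:
            idx = np.random.default_rng(seed).choice(len(pixels), subsample, replace=False)
            pixels = pixels[idx]
        coords = (pixels[:, 1], pixels[:, 2]) if mode == "2d" else (
            pixels[:, 1], pixels[:, 2], pixels[:, 0])
        ax.scatter(*coords, s=2, c="0.6", alpha=0.3, label="ray pixels")

    vecs = palette.vectors()
    for name, v in zip(CATEGORY_NAMES, vecs):
        coords = (v[1], v[2]) if mode == "2d" else (v[1], v[2], v[0])
        ax.scatter(*coords, s=90, c=_CATEGORY_PLOT_COLORS[name],
                   edgecolors="k", zorder=3, label=name)

    if mean_vector is not None:
        v = np.asarray(mean_vector, dtype=np.float64)
        coords = (v[1], v[2]) if mode == "2d" else (v[1], v[2], v[0])
        ax.scatter(*coords, s=120, c="tab:blue", marker="o",
                   edgecolors="k", zorder=4, label="image mean")

    ax.set_xlabel("a8")
    ax.set_ylabel("b8")
    if mode == "3d":
        ax.set_zlabel("L8")
    ax.legend(loc="best", fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
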