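"""Slide tiling, tissue filtering and patch resizing.

Slides are cut into a non-overlapping grid of fixed physical size
(0.27 x 0.27 mm: 1024 px at 40x, 512 px at 20x), background tiles are
dropped by a grayscale tissue fraction threshold, and retained tiles are
area-average downsampled to the network input size.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

log = logging.getLogger(__name__)

_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class GridConfig:
    patch_px_40x: int = 1024
    patch_px_20x: int = 512
    target_px: int = 256
    min_tissue_fraction: float = 0.75
    #: tissue = grayscale strictly below this fraction of full brightness
    gray_tissue_threshold: float = 0.88

    def __post_init__(self) -> None:
        if self.patch_px_40x != 2 * self.patch_px_20x:
            raise ValueError(
                "patch_px_40x must equal 2*patch_px_20x (constant physical size)"
            )
        if not (0.0 <= self.min_tissue_fraction <= 1.0):
            raise ValueError("min_tissue_fraction must lie in [0, 1]")
        if self.target_px > self.patch_px_20x:
            raise ValueError("target_px must not exceed the smaller patch side")

    def side_for(self, magnification: str) -> int:
        if magnification == "40x":
            return self.patch_px_40x
        if magnification == "20x":
            return self.patch_px_20x
        raise ValueError(f"unknown magnification {magnification!r}")


@dataclass
class Patch:
    """One retained grid tile, resized to the network input size."""

    wsi_id: str
    grid_row: int
    grid_col: int
    origin_x_px: int
    origin_y_px: int
    tissue_fraction: float
    image: np.ndarray = field(repr=False)


def read_slide(path: str | Path) -> np.ndarray:
    """Read a TIFF or PNG slide as an (H, W, 3) uint8 RGB array (level 0)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff", ".svs"):
        img = tifffile.imread(path)
    else:
        img = np.asarray(Image.open(path).convert("RGB"))
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    if img.shape[2] == 4:
        img = img[:, :, :3]
    return np.ascontiguousarray(img, dtype=np.uint8)


def extract_grid(
    width: int, height: int, magnification: str, config: GridConfig
) -> list[tuple[int, int, int, int]]:
    """Non-overlapping tile coordinates ``(row, col, origin_x, origin_y)``.

    The grid is anchored at (0, 0); partial edge tiles are dropped, so a
    W x H slide yields exactly floor(W/side)*floor(H/side) tiles.
    """
    side = config.side_for(magnification)
    n_cols, n_rows = width // side, height // side
    if n_cols == 0 or n_rows == 0:
        warnings.warn(
            f"slide {width}x{height} smaller than one {side}px tile; empty grid",
            stacklevel=2,
        )
        return []
    return [
        (r, c, c * side, r * side) for r in range(n_rows) for c in range(n_cols)
    ]


def tissue_fraction(patch_rgb: np.ndarray, gray_tissue_threshold: float) -> float:
    """Fraction of pixels whose luma falls strictly below the threshold.

    Luma is the standard 0.299R + 0.587G + 0.114B grayscale; the threshold
    is a fraction of full brightness (255).
    """
    gray = patch_rgb.astype(np.float64) @ _LUMA
    return float(np.mean(gray < gray_tissue_threshold * 255.0))


def filter_patches(patches: list[Patch], config: GridConfig) -> list[Patch]:
    """Keep patches with at least ``min_tissue_fraction`` tissue (inclusive)."""
    return [p for p in patches if p.tissue_fraction >= config.min_tissue_fraction]


def resize_patch(patch_rgb: np.ndarray, target_px: int) -> np.ndarray:
    """Area-average (anti-aliased) downsample to a target_px square."""
    h, w = patch_rgb.shape[:2]
    if h < target_px or w < target_px:
        raise ValueError(f"refusing to upscale {w}x{h} patch to {target_px}")
    if h == target_px and w == target_px:
        return patch_rgb
    out = Image.fromarray(patch_rgb).resize(
        (target_px, target_px), Image.Resampling.BOX
    )
    return np.asarray(out)


def patchify_slide(
    slide: np.ndarray,
    wsi_id: str,
    magnification: str,
    config: GridConfig | None = None,
) -> tuple[list[Patch], pd.DataFrame]:
    """Tile, filter and resize one slide.

    Returns the retained patches and the full patch manifest (one row per
    grid tile, ``kept`` flagging those that passed the tissue filter).
    """
    config = config or GridConfig()
    side = config.side_for(magnification)
    h, w = slide.shape[:2]
    rows = []
    retained: list[Patch] = []
    for r, c, x, y in extract_grid(w, h, magnification, config):
        tile = slide[y : y + side, x : x + side]
        tf = tissue_fraction(tile, config.gray_tissue_threshold)
        kept = tf >= config.min_tissue_fraction
        if kept:
            retained.append(
                Patch(
                    wsi_id=wsi_id,
                    grid_row=r,
                    grid_col=c,
                    origin_x_px=x,
                    origin_y_px=y,
                    tissue_fraction=tf,
                    image=resize_patch(tile, config.target_px),
                )
            )
        rows.append(
            {
                "wsi_id": wsi_id, "row": r, "col": c,
                "origin_x": x, "origin_y": y,
                "tissue_fraction": tf, "kept": kept,
            }
        )
    manifest = pd.DataFrame(
        rows,
        columns=["wsi_id", "row", "col", "origin_x", "origin_y",
                 "tissue_fraction", "kept"],
    )
    return retained, manifest


def patchify_manifest(
    slide_manifest: pd.DataFrame, config: GridConfig | None = None
) -> tuple[dict[str, list[Patch]], pd.DataFrame]:
    """Patchify every slide listed in a ``wsi_id,path,magnification,score``
    manifest.  Returns per-slide retained patches and the combined patch
    manifest."""
    config = config or GridConfig()
    per_slide: dict[str, list[Patch]] = {}
    frames = []
    for rec in slide_manifest.itertuples(index=False):
        slide = read_slide(rec.path)
        patches, pm = patchify_slide(slide, rec.wsi_id, rec.magnification, config)
        per_slide[rec.wsi_id] = patches
        frames.append(pm)
        log.debug("patchified %s: %d/%d tiles kept", rec.wsi_id, len(patches), len(pm))
    combined = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    return per_slide, combined
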