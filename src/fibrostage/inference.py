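"""Whole-slide inference: patch prediction, majority vote, heatmaps.

A slide's fibrosis stage is the modal class among its retained patches;
the per-class patch-prediction ratio vector doubles as the slide's score
vector for one-vs-rest curve analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image

from .nn import TinyCNN
from .patching import Patch
from .preprocess import HsvThresholds, preprocess_for_model

#: qualitative palette, one color per 7-class stage (0,1A,1B,1C,2,3,4);
#: the 5-class mode reuses the subset at stages 0,1,2,3,4
DEFAULT_PALETTE = (
    (64, 64, 64),      # 0 - gray
    (255, 221, 113),   # 1A - light yellow
    (255, 158, 74),    # 1B - orange
    (237, 102, 93),    # 1C - salmon
    (173, 139, 201),   # 2 - purple
    (237, 151, 202),   # 3 - pink
    (162, 0, 37),      # 4 - dark red
)


@dataclass
class PatchPredictionSet:
    """Per-patch class predictions and probabilities for one slide."""

    wsi_id: str
    pred_class: np.ndarray      # (n,) int
    probabilities: np.ndarray   # (n, C), rows sum to 1
    grid_coords: np.ndarray     # (n, 2) = (row, col)

    def __post_init__(self) -> None:
        if not np.allclose(self.probabilities.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("patch probabilities must sum to 1")
        if not np.array_equal(self.pred_class,
                              self.probabilities.argmax(axis=1)):
            raise ValueError("predicted class must be the argmax probability")


@dataclass
class WsiPrediction:
    """Majority-vote stage and patch-ratio vector for one slide."""

    wsi_id: str
    pred_index: int
    ratio_vector: np.ndarray  # (C,), sums to 1


def predict_patches(
    model: TinyCNN,
    patches: list[Patch],
    thresholds: HsvThresholds | None = None,
) -> PatchPredictionSet:
    """Classify every retained patch of one slide.

    Patches are run through the identical preprocessing used at training
    time minus augmentation; background patches must already have been
    filtered out.
    """
    if not patches:
        raise ValueError("no retained patches: slide has no tissue to score")
    x = np.stack([preprocess_for_model(p.image, thresholds) for p in patches])
    probs = model.predict_proba(x)
    return PatchPredictionSet(
        wsi_id=patches[0].wsi_id,
        pred_class=probs.argmax(axis=1),
        probabilities=probs,
        grid_coords=np.array([(p.grid_row, p.grid_col) for p in patches]),
    )


def aggregate_majority(
    preds: PatchPredictionSet, num_classes: int, tie_break: str = "higher"
) -> WsiPrediction:
    """Slide stage = most frequent patch class.

    Ties are broken toward the more severe (``"higher"``) or milder
    (``"lower"``) ordinal stage.
    """
    if tie_break not in ("higher", "lower"):
        raise ValueError("tie_break must be 'higher' or 'lower'")
    counts = np.bincount(preds.pred_class, minlength=num_classes)
    ratios = counts / counts.sum()
    best = np.flatnonzero(counts == counts.max())
    winner = int(best.max() if tie_break == "higher" else best.min())
    return WsiPrediction(
        wsi_id=preds.wsi_id, pred_index=winner, ratio_vector=ratios
    )


def render_heatmap(
    preds: PatchPredictionSet,
    slide: np.ndarray,
    side: int,
    palette: tuple = DEFAULT_PALETTE,
    num_classes: int | None = None,
    tile_px: int = 16,
    alpha: float = 0.45,
) -> np.ndarray:
    """Class-colored tile overlay on a slide thumbnail (RGBA uint8).

    One tile per retained patch at its grid position; filtered background
    tiles stay untinted.  Output dimensions equal the thumbnail's.
    """
    num_classes = num_classes or int(preds.probabilities.shape[1])
    if len(palette) < num_classes:
        raise ValueError(
            f"palette has {len(palette)} colors, need {num_classes}"
        )
    h, w = slide.shape[:2]
    n_rows, n_cols = h // side, w // side
    th, tw = n_rows * tile_px, n_cols * tile_px
    thumb = np.asarray(
        Image.fromarray(slide[: n_rows * side, : n_cols * side]).resize(
            (tw, th), Image.Resampling.BILINEAR
        ),
        dtype=np.float64,
    )
    out = thumb.copy()
    for (r, c), cls in zip(preds.grid_coords, preds.pred_class):
        color = np.asarray(palette[int(cls)], dtype=np.float64)
        ys, xs = r * tile_px, c * tile_px
        tile = out[ys : ys + tile_px, xs : xs + tile_px]
        out[ys : ys + tile_px, xs : xs + tile_px] = (
            (1 - alpha) * tile + alpha * color
        )
    rgba = np.dstack([out, np.full((th, tw), 255.0)])
    return (rgba + 0.5).astype(np.uint8)


def save_heatmap_png(
    path,
    preds: PatchPredictionSet,
    slide: np.ndarray,
    side: int,
    class_names: tuple[str, ...],
    palette: tuple = DEFAULT_PALETTE,
) -> None:
    """Write the heatmap with a stage legend (matplotlib figure)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Patch as LegendPatch

    rgba = render_heatmap(
        preds, slide, side, palette, num_classes=len(class_names)
    )
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(rgba)
    ax.set_axis_off()
    handles = [
        LegendPatch(color=np.asarray(palette[i]) / 255.0, label=name)
        for i, name in enumerate(class_names)
    ]
    ax.legend(handles=handles, loc="upper right", fontsize=7, title="stage")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
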