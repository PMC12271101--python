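"""Label schemes, stratified folds, class weights and patch training.

Labels follow the Kleiner CRN fibrosis stages.  The 7-class scheme keeps
the score-1 subclasses (0, 1A, 1B, 1C, 2, 3, 4, ordinal ranks 0..6); the
5-class scheme merges {1A, 1B, 1C} into stage 1.  Every patch inherits
the expert score of its parent slide, cross-validation folds split by
slide (never by patch), and the class-imbalance weights

    w_i = sum_j N_j / (2 N_i)

are computed from the patch counts of the training split.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .evaluation import cohen_kappa, confusion_matrix, mcc_multiclass
from .nn import RAdam, TinyCNN, weighted_cross_entropy
from .patching import Patch
from .preprocess import AugmentConfig, HsvThresholds, augment, collagen_highlight, normalize

log = logging.getLogger(__name__)

SCORES_7 = ("0", "1A", "1B", "1C", "2", "3", "4")
SCORES_5 = ("0", "1", "2", "3", "4")
_TO_FIVE = {"0": "0", "1A": "1", "1B": "1", "1C": "1", "2": "2", "3": "3", "4": "4"}


def ordinal_rank(score: str) -> int:
    """Position of a 7-class score in the Kleiner stage order."""
    return SCORES_7.index(score)


def to_five_class(score: str) -> str:
    """Project a 7-class score onto the 5-class scheme ({1A,1B,1C} -> 1)."""
    return _TO_FIVE[score]


@dataclass(frozen=True)
class LabelScheme:
    """Five- or seven-class labeling of the Kleiner stages."""

    mode: str = "seven_class"

    def __post_init__(self) -> None:
        if self.mode not in ("five_class", "seven_class"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def class_names(self) -> tuple[str, ...]:
        return SCORES_7 if self.mode == "seven_class" else SCORES_5

    @property
    def num_classes(self) -> int:
        return len(self.class_names)

    def index_of(self, score: str) -> int:
        """Class index of a 7-class fibrosis score under this scheme."""
        if self.mode == "seven_class":
            return SCORES_7.index(score)
        return SCORES_5.index(to_five_class(score))


def map_labels(score: str, scheme: LabelScheme) -> int:
    return scheme.index_of(score)


# ---------------------------------------------------------------------------
# folds

@dataclass
class FoldSplit:
    """Slide-level k-fold assignment, stratified by fibrosis score."""

    assignment: pd.Series  # index = wsi_id, value = fold in 0..k-1
    k: int
    seed: int

    def val_ids(self, fold: int) -> list[str]:
        return list(self.assignment.index[self.assignment == fold])

    def train_ids(self, fold: int) -> list[str]:
        return list(self.assignment.index[self.assignment != fold])

    def to_json_dict(self) -> dict:
        return {
            "k": self.k, "seed": self.seed,
            "assignment": {w: int(f) for w, f in self.assignment.items()},
        }


def stratified_folds(manifest: pd.DataFrame, k: int = 5, seed: int = 0) -> FoldSplit:
    """Partition slides into k folds preserving the score distribution.

    Within each class the slides are shuffled (seeded) and dealt into k
    near-equal parts; the fold receiving each class's remainder rotates
    with the class index, so per-class fold sizes differ by at most one
    and no single fold accumulates every remainder.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    rng = np.random.default_rng(np.random.SeedSequence([211, seed & 0x7FFFFFFF]))
    assignment: dict[str, int] = {}
    classes = sorted(manifest["score"].unique(), key=ordinal_rank)
    for ci, score in enumerate(classes):
        ids = sorted(manifest.loc[manifest["score"] == score, "wsi_id"])
        if len(ids) < k:
            warnings.warn(
                f"class {score!r} has only {len(ids)} slides for {k} folds; "
                "some folds will lack this class",
                stacklevel=2,
            )
        order = rng.permutation(len(ids))
        base, rem = divmod(len(ids), k)
        sizes = np.full(k, base, dtype=int)
        for i in range(rem):
            sizes[(ci + i) % k] += 1
        bounds = np.concatenate([[0], np.cumsum(sizes)])
        for fold in range(k):
            for pos in order[bounds[fold] : bounds[fold + 1]]:
                assignment[ids[pos]] = fold
    series = pd.Series(assignment, name="fold").loc[manifest["wsi_id"]]
    return FoldSplit(assignment=series, k=k, seed=seed)


# ---------------------------------------------------------------------------
# class weights

def compute_class_weights(counts: Mapping[str, int] | Sequence[int] | np.ndarray):
    """Inverse-frequency class weights w_i = (sum_j N_j) / (2 N_i).

    Accepts a mapping class-name -> patch count (returns a mapping) or a
    count vector (returns an array).  No renormalization is applied; with
    equal counts every weight is exactly 1.
    """
    if isinstance(counts, Mapping):
        names = list(counts)
        vec = np.array([counts[n] for n in names], dtype=float)
    else:
        names = None
        vec = np.asarray(counts, dtype=float)
    if (vec <= 0).any():
        empty = (
            [names[i] for i in np.flatnonzero(vec <= 0)]
            if names is not None
            else list(np.flatnonzero(vec <= 0))
        )
        raise ValueError(f"class weight undefined for empty class(es): {empty}")
    w = vec.sum() / (2.0 * vec)
    if names is not None:
        return dict(zip(names, w))
    return w


# ---------------------------------------------------------------------------
# training

@dataclass(frozen=True)
class TrainConfig:
    """Patch-classifier optimization settings.

    Defaults follow the reference protocol: RAdam (lr 1e-3, betas
    0.9/0.999, eps 1e-8), minibatches of 128 patches, at most 50 epochs,
    early stop once slide-level validation MCC *and* unweighted kappa
    exceed 0.8.
    """

    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8
    batch_size: int = 128
    max_epochs: int = 50
    stop_threshold: float = 0.8
    architecture: str = "tiny_cnn"
    augment: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if not (0 < self.beta1 < 1 and 0 < self.beta2 < 1):
            raise ValueError("betas must lie in (0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.architecture not in ("tiny_cnn", "resnet34"):
            raise ValueError(f"unknown architecture {self.architecture!r}")


def build_model(num_classes: int, config: TrainConfig) -> TinyCNN:
    if config.architecture == "resnet34":
        raise NotImplementedError(
            "the resnet34 option requires a GPU-scale deep-learning backend; "
            "use architecture='tiny_cnn'"
        )
    return TinyCNN(num_classes=num_classes, seed=config.seed)


def train_model(
    train_patches: Mapping[str, list[Patch]],
    train_scores: Mapping[str, str],
    val_patches: Mapping[str, list[Patch]],
    val_scores: Mapping[str, str],
    scheme: LabelScheme,
    config: TrainConfig | None = None,
    thresholds: HsvThresholds | None = None,
    augment_config: AugmentConfig | None = None,
) -> tuple[TinyCNN, pd.DataFrame]:
    """Train the patch classifier with per-epoch slide-level validation.

    Each epoch is one shuffled pass over all retained training patches.
    After every epoch the validation slides are scored end to end (patch
    prediction -> majority vote) and training stops at the first epoch
    where both the unweighted kappa and the MCC of the slide-level
    predictions exceed ``stop_threshold``, or at ``max_epochs``.  The
    checkpoint returned is the stopping-epoch model; the history records
    ``epoch, loss, val_kappa, val_mcc``.
    """
    from .inference import aggregate_majority, predict_patches

    config = config or TrainConfig()
    if not train_patches or not val_patches:
        raise ValueError("training and validation sets must be nonempty")

    # assemble training tensors; labels inherited from the parent slide
    x_raw, y = [], []
    for wsi_id, patches in train_patches.items():
        label = scheme.index_of(train_scores[wsi_id])
        for p in patches:
            x_raw.append(collagen_highlight(p.image, thresholds))
            y.append(label)
    y = np.asarray(y, dtype=int)
    counts = np.bincount(y, minlength=scheme.num_classes)
    if (counts == 0).any():
        missing = [scheme.class_names[i] for i in np.flatnonzero(counts == 0)]
        raise ValueError(
            f"class(es) {missing} absent from the training split; "
            "class weights undefined"
        )
    weights = compute_class_weights(counts)

    model = build_model(scheme.num_classes, config)
    opt = RAdam(
        model.params, lr=config.learning_rate, beta1=config.beta1,
        beta2=config.beta2, epsilon=config.epsilon,
    )
    rng = np.random.default_rng(np.random.SeedSequence([73, config.seed & 0x7FFFFFFF]))
    aug = augment_config if config.augment else None
    if config.augment and aug is None:
        aug = AugmentConfig()

    val_ids = list(val_patches)
    val_x = {
        w: np.stack(
            [normalize(collagen_highlight(p.image, thresholds))
             for p in val_patches[w]]
        )
        for w in val_ids
    }
    val_true = np.array([scheme.index_of(val_scores[w]) for w in val_ids])

    history = []
    n = len(x_raw)
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            if aug is not None:
                xb = np.stack([normalize(augment(x_raw[i], aug, rng)) for i in idx])
            else:
                xb = np.stack([normalize(x_raw[i]) for i in idx])
            logits, cache = model.forward(xb, train=True)
            loss, dlogits = weighted_cross_entropy(
                logits, y[idx], weights, return_grad=True
            )
            opt.step(model.backward(dlogits, cache))
            losses.append(loss)

        # slide-level validation: majority vote over patch predictions
        val_pred = []
        for w in val_ids:
            probs = model.predict_proba(val_x[w])
            preds = _prediction_set(w, probs, val_patches[w])
            val_pred.append(
                aggregate_majority(preds, scheme.num_classes).pred_index
            )
        cm = confusion_matrix(val_true, np.asarray(val_pred), scheme.num_classes)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            kappa = cohen_kappa(cm, "none")
            mcc = mcc_multiclass(cm)
        history.append(
            {"epoch": epoch, "loss": float(np.mean(losses)),
             "val_kappa": kappa, "val_mcc": mcc}
        )
        log.info(
            "epoch %d: loss %.4f val_kappa %.3f val_mcc %.3f",
            epoch, history[-1]["loss"], kappa, mcc,
        )
        if kappa > config.stop_threshold and mcc > config.stop_threshold:
            break
    return model, pd.DataFrame(history)


def _prediction_set(wsi_id: str, probs: np.ndarray, patches: list[Patch]):
    from .inference import PatchPredictionSet

    return PatchPredictionSet(
        wsi_id=wsi_id,
        pred_class=probs.argmax(axis=1),
        probabilities=probs,
        grid_coords=np.array([(p.grid_row, p.grid_col) for p in patches]),
    )
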