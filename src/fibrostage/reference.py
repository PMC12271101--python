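"""Published reference numbers from the rodent Sirius-Red fibrosis study.

The staging pipeline was originally developed on a proprietary dataset of
914 Sirius-Red-stained rodent liver whole-slide images (999,711 retained
patches).  The per-class composition of that dataset and the published
5-fold cross-validation result tables are kept here as plain data: the
composition drives the class mix of scaled-down synthetic experiments, and
the result tables exercise the report-averaging arithmetic.
"""

from __future__ import annotations

SCORES_7: tuple[str, ...] = ("0", "1A", "1B", "1C", "2", "3", "4")
SCORES_5: tuple[str, ...] = ("0", "1", "2", "3", "4")

# Per-class whole-slide-image counts of the reference dataset.
WSI_COUNTS: dict[str, int] = {
    "0": 187, "1A": 146, "1B": 121, "1C": 113, "2": 133, "3": 108, "4": 106,
}

# Per-class retained-patch counts of the reference dataset.
PATCH_COUNTS: dict[str, int] = {
    "0": 173_598, "1A": 116_566, "1B": 171_051, "1C": 74_433,
    "2": 166_974, "3": 148_739, "4": 148_350,
}

WSI_TOTAL = 914
PATCH_TOTAL = 999_711

# Published 5-fold cross-validation results, one row per fold, columns
# (kappa, linear kappa, quadratic kappa, MCC, AUROC, AUPRC).
FIVE_CLASS_FOLD_METRICS: list[dict[str, float]] = [
    {"kappa": 0.815, "linear_kappa": 0.873, "quadratic_kappa": 0.912,
     "mcc": 0.815, "auroc": 0.982, "auprc": 0.949},
    {"kappa": 0.869, "linear_kappa": 0.909, "quadratic_kappa": 0.937,
     "mcc": 0.871, "auroc": 0.979, "auprc": 0.927},
    {"kappa": 0.793, "linear_kappa": 0.785, "quadratic_kappa": 0.770,
     "mcc": 0.794, "auroc": 0.968, "auprc": 0.914},
    {"kappa": 0.732, "linear_kappa": 0.784, "quadratic_kappa": 0.812,
     "mcc": 0.735, "auroc": 0.941, "auprc": 0.826},
    {"kappa": 0.808, "linear_kappa": 0.851, "quadratic_kappa": 0.880,
     "mcc": 0.810, "auroc": 0.959, "auprc": 0.913},
]

SEVEN_CLASS_FOLD_METRICS: list[dict[str, float]] = [
    {"kappa": 0.801, "linear_kappa": 0.814, "quadratic_kappa": 0.820,
     "mcc": 0.803, "auroc": 0.981, "auprc": 0.916},
    {"kappa": 0.814, "linear_kappa": 0.850, "quadratic_kappa": 0.877,
     "mcc": 0.817, "auroc": 0.985, "auprc": 0.929},
    {"kappa": 0.808, "linear_kappa": 0.822, "quadratic_kappa": 0.819,
     "mcc": 0.811, "auroc": 0.973, "auprc": 0.904},
    {"kappa": 0.807, "linear_kappa": 0.861, "quadratic_kappa": 0.895,
     "mcc": 0.809, "auroc": 0.984, "auprc": 0.930},
    {"kappa": 0.806, "linear_kappa": 0.869, "quadratic_kappa": 0.908,
     "mcc": 0.807, "auroc": 0.967, "auprc": 0.887},
]


def scaled_wsi_counts(factor: float = 0.1) -> dict[str, int]:
    """Reference per-class WSI counts scaled by ``factor`` (round-half-even).

    Used to build synthetic datasets whose class imbalance mirrors the
    reference dataset at desk scale.
    """
    return {s: round(n * factor) for s, n in WSI_COUNTS.items()}
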