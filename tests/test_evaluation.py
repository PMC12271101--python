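"""Metric implementations vs independent brute-force oracles."""

import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score, matthews_corrcoef

from fibrostage.evaluation import (
    METRIC_COLUMNS,
    average_metrics,
    cohen_kappa,
    confusion_matrix,
    macro_ovr,
    mcc_multiclass,
    ovr_curves,
)
from fibrostage.reference import (
    FIVE_CLASS_FOLD_METRICS,
    SEVEN_CLASS_FOLD_METRICS,
)


def pairwise_auroc(pos_scores, neg_scores):
    """Brute-force AUROC: enumerate every positive-negative pair, counting
    ties as one half."""
    wins = ties = 0
    for p in pos_scores:
        for n in neg_scores:
            if p > n:
                wins += 1
            elif p == n:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos_scores) * len(neg_scores))


def _cm_to_labels(cm):
    true, pred = [], []
    for i in range(cm.shape[0]):
        for j in range(cm.shape[1]):
            true += [i] * cm[i, j]
            pred += [j] * cm[i, j]
    return np.array(true), np.array(pred)


class TestKappa:
    def test_perfect_agreement_is_one(self):
        cm = np.diag([5, 7, 3])
        for w in ("none", "linear", "quadratic"):
            assert cohen_kappa(cm, w) == pytest.approx(1.0)

    def test_chance_level_agreement_is_zero(self):
        assert cohen_kappa(np.array([[25, 25], [25, 25]])) == pytest.approx(0.0)

    def test_hand_worked_binary_example(self):
        # po = 0.85, pe = 0.53 -> kappa = 0.32/0.47
        cm = np.array([[6, 2], [1, 11]])
        assert cohen_kappa(cm, "none") == pytest.approx(0.6809, abs=5e-5)

    def test_unweighted_equals_zero_one_weighted(self, rng):
        for _ in range(20):
            cm = rng.integers(0, 30, (4, 4))
            cm[0, 0] += 1
            assert cohen_kappa(cm, "none") == pytest.approx(
                1 - (cm * (1 - np.eye(4))).sum()
                / ((np.outer(cm.sum(1), cm.sum(0)) / cm.sum())
                   * (1 - np.eye(4))).sum()
            )

    def test_quadratic_invariant_to_class_reversal(self, rng):
        cm = rng.integers(0, 20, (5, 5))
        assert cohen_kappa(cm[::-1, ::-1], "quadratic") == pytest.approx(
            cohen_kappa(cm, "quadratic")
        )

    @pytest.mark.parametrize("weighting", ["none", "linear", "quadratic"])
    def test_matches_sklearn_on_random_matrices(self, weighting, rng):
        sk_w = {"none": None, "linear": "linear", "quadratic": "quadratic"}
        for _ in range(40):
            c = int(rng.integers(2, 7))
            cm = rng.integers(0, 12, (c, c))
            cm += np.eye(c, dtype=int)  # keep marginals non-degenerate
            true, pred = _cm_to_labels(cm)
            assert cohen_kappa(cm, weighting) == pytest.approx(
                cohen_kappa_score(true, pred, labels=list(range(c)),
                                  weights=sk_w[weighting]),
                abs=1e-10,
            )

    def test_degenerate_marginals_return_zero_with_warning(self):
        cm = np.zeros((3, 3), dtype=int)
        cm[1, 1] = 10
        with pytest.warns(UserWarning, match="degenerate"):
            assert cohen_kappa(cm) == 0.0


class TestMcc:
    def test_perfect_prediction_is_one(self):
        assert mcc_multiclass(np.diag([4, 9, 2])) == pytest.approx(1.0)

    def test_binary_anticorrelation_is_minus_one(self):
        assert mcc_multiclass(np.array([[0, 10], [10, 0]])) == pytest.approx(-1.0)

    def test_matches_sklearn_on_random_matrices(self, rng):
        for _ in range(40):
            c = int(rng.integers(2, 7))
            cm = rng.integers(0, 12, (c, c))
            cm += np.eye(c, dtype=int)
            true, pred = _cm_to_labels(cm)
            assert mcc_multiclass(cm) == pytest.approx(
                matthews_corrcoef(true, pred), abs=1e-10
            )

    def test_independent_marginals_give_near_zero(self, rng):
        true = rng.integers(0, 4, 10_000)
        pred = rng.integers(0, 4, 10_000)
        cm = confusion_matrix(true, pred, 4)
        assert abs(mcc_multiclass(cm)) < 0.05

    def test_zero_variance_marginal_warns(self):
        cm = np.array([[5, 0], [5, 0]])
        with pytest.warns(UserWarning, match="zero-variance"):
            assert mcc_multiclass(cm) == 0.0


class TestOvrCurves:
    @staticmethod
    def _ratios(scores):
        r = np.zeros((len(scores), 2))
        r[:, 1] = scores
        r[:, 0] = 1 - r[:, 1]
        return r

    def test_perfect_separation(self):
        truth = np.array([1, 1, 0, 0])
        auroc, auprc = ovr_curves(self._ratios([1, 1, 0, 0]), truth, 1)
        assert auroc == 1.0 and auprc == 1.0

    def test_constant_scores_give_half_auroc(self):
        truth = np.array([1, 1, 0, 0])
        auroc, _ = ovr_curves(self._ratios([0.4] * 4), truth, 1)
        assert auroc == pytest.approx(0.5)

    def test_worked_example_matches_pairwise_enumeration(self):
        scores = [0.9, 0.8, 0.4, 0.7, 0.3, 0.1]
        truth = np.array([1, 1, 1, 0, 0, 0])
        auroc, _ = ovr_curves(self._ratios(scores), truth, 1)
        oracle = pairwise_auroc(scores[:3], scores[3:])
        assert oracle == pytest.approx(8 / 9)
        assert auroc == pytest.approx(oracle)

    def test_rank_formula_equals_pairwise_oracle_on_random_sets(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 200))
            scores = rng.choice(np.linspace(0, 1, 17), size=n)
            truth = rng.integers(0, 2, n)
            if truth.min() == truth.max():
                continue
            auroc, _ = ovr_curves(self._ratios(scores), truth, 1)
            assert auroc == pytest.approx(
                pairwise_auroc(scores[truth == 1], scores[truth == 0]),
                abs=1e-12,
            )

    def test_random_scorer_auprc_near_prevalence(self, rng):
        n, prev = 4000, 0.25
        truth = (rng.random(n) < prev).astype(int)
        scores = rng.random(n)
        _, auprc = ovr_curves(self._ratios(scores), truth, 1)
        assert auprc == pytest.approx(prev, abs=0.05)

    def test_single_class_ground_truth_rejected(self):
        with pytest.raises(ValueError, match="positive and one negative"):
            ovr_curves(self._ratios([0.5, 0.6]), np.array([1, 1]), 1)

    def test_macro_skips_absent_classes_with_warning(self, rng):
        ratios = rng.dirichlet(np.ones(4), size=12)
        truth = rng.integers(0, 3, 12)  # class 3 never occurs
        with pytest.warns(UserWarning, match="class 3"):
            auroc, auprc = macro_ovr(ratios, truth, 4)
        assert 0.0 <= auroc <= 1.0 and 0.0 <= auprc <= 1.0


class TestAveraging:
    def test_five_class_reference_fold_rows(self):
        report = average_metrics(FIVE_CLASS_FOLD_METRICS)
        table = report.to_frame()
        avg = table[table["fold"] == "Average"].iloc[0]
        assert avg["kappa"] == 0.803
        assert avg["auroc"] == 0.966

    def test_seven_class_reference_fold_rows(self):
        report = average_metrics(SEVEN_CLASS_FOLD_METRICS)
        avg = report.to_frame().iloc[-1]
        assert avg["kappa"] == 0.807
        assert avg["auroc"] == 0.978

    def test_identical_folds_average_to_themselves(self):
        row = dict(zip(METRIC_COLUMNS, [0.5, 0.6, 0.7, 0.5, 0.9, 0.8]))
        report = average_metrics([row] * 5)
        for k, v in row.items():
            assert report.average[k] == pytest.approx(v)

    def test_metrics_invariant_to_slide_order(self, rng):
        from fibrostage.evaluation import evaluate_fold

        n = 40
        truth = rng.integers(0, 4, n)
        pred = rng.integers(0, 4, n)
        ratios = rng.dirichlet(np.ones(4), size=n)
        perm = rng.permutation(n)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = evaluate_fold(truth, pred, ratios, 4)
            b = evaluate_fold(truth[perm], pred[perm], ratios[perm], 4)
        for k in a:
            assert a[k] == pytest.approx(b[k], abs=1e-12)

    def test_empty_fold_list_rejected(self):
        with pytest.raises(ValueError):
            average_metrics([])
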