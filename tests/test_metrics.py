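"""Tolerance-margin accuracy metrics, Fleiss' kappa, Mann-Whitney U."""

import itertools

import numpy as np
import pandas as pd
import pytest

from skintone import (
    EvalConfig,
    balanced_accuracy,
    evaluate,
    fleiss_kappa,
    mann_whitney,
    subgroup_compare,
    tolerance_accuracy,
)
from skintone.metrics import class_tolerance, confusion_matrix, pair_correct, per_class_recall

# Fixed 20-subject, 3-rater, 5-category table; the kappa value was frozen
# before the build from an independent reference implementation
# (statsmodels.stats.inter_rater.fleiss_kappa).
KAPPA_TABLE = np.array(
    [
        [2, 0, 0, 0, 1], [1, 0, 1, 0, 1], [1, 0, 0, 2, 0], [0, 0, 1, 2, 0],
        [2, 0, 1, 0, 0], [1, 1, 1, 0, 0], [1, 0, 0, 1, 1], [0, 2, 1, 0, 0],
        [0, 1, 0, 1, 1], [1, 0, 0, 2, 0], [1, 0, 0, 0, 2], [1, 0, 0, 0, 2],
        [0, 1, 1, 0, 1], [1, 1, 0, 1, 0], [1, 0, 2, 0, 0], [0, 0, 0, 2, 1],
        [1, 1, 0, 1, 0], [1, 0, 1, 0, 1], [1, 0, 1, 1, 0], [0, 2, 1, 0, 0],
    ]
)
KAPPA_REFERENCE = -0.030855539971949536


def brute_force_accuracy(gold, pred, margin, k):
    tol = int(np.floor(margin * k))
    return sum(1 for g, p in zip(gold, pred) if abs(p - g) <= tol) / len(gold)


class TestToleranceAccuracy:
    def test_margin_to_class_tolerance(self):
        # 10% = one Monk class; 20% = two Monk classes = one Fitzpatrick class
        assert class_tolerance(0.10, 10) == 1
        assert class_tolerance(0.20, 10) == 2
        assert class_tolerance(0.10, 6) == 0
        assert class_tolerance(0.20, 6) == 1

    def test_perfect_classifier(self):
        gold = [1, 5, 10, 3]
        for margin in (0.0, 0.1, 0.2, 0.5):
            assert tolerance_accuracy(gold, gold, margin, 10) == 1.0

    def test_hand_counted_monk_pairs(self):
        gold, pred = [5, 5], [6, 8]
        assert tolerance_accuracy(gold, pred, 0.10, 10) == 0.5
        assert tolerance_accuracy(gold, pred, 0.20, 10) == 0.5  # |8-5| = 3 > 2

    @pytest.mark.parametrize("k", [6, 10])
    @pytest.mark.parametrize("margin", [0.0, 0.1, 0.2])
    def test_matches_brute_force_oracle(self, k, margin, rng):
        gold = rng.integers(1, k + 1, 1000)
        pred = rng.integers(1, k + 1, 1000)
        assert tolerance_accuracy(gold, pred, margin, k) == brute_force_accuracy(gold, pred, margin, k)

    def test_non_decreasing_in_margin(self, rng):
        gold = rng.integers(1, 11, 300)
        pred = rng.integers(1, 11, 300)
        accs = [tolerance_accuracy(gold, pred, m, 10) for m in (0.0, 0.1, 0.2, 0.5)]
        assert all(a <= b for a, b in zip(accs, accs[1:]))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            tolerance_accuracy([], [], 0.1, 10)

    def test_ita_axis_margin_semantics(self):
        gold, pred = [5, 5], [6, 9]
        gold_ita = np.array([40.0, 40.0])
        pred_ita = np.array([25.0, -60.0])  # deviations 15° and 100°
        ok = pair_correct(gold, pred, 0.10, 10, semantics="ita_fraction",
                          gold_ita=gold_ita, pred_ita=pred_ita)
        assert list(ok) == [True, False]  # 10% of the 200° table span = 20°


class TestBalancedAccuracy:
    def test_single_class_all_correct(self):
        assert balanced_accuracy([3] * 8, [3] * 8, 0.1, 10) == 1.0

    def test_mean_of_recalls_ignores_class_sizes(self):
        gold = [1] * 9 + [6]
        pred = [1] * 9 + [1]  # class 1 recall 1.0, class 6 recall 0.0
        assert balanced_accuracy(gold, pred, 0.1, 10) == 0.5

    def test_unsupported_classes_excluded(self):
        rec = per_class_recall([2, 2, 4], [2, 2, 4], 0.0, 10)
        assert np.isnan(rec[0]) and rec[1] == 1.0 and rec[3] == 1.0

    def test_imbalance_pulls_balanced_below_plain(self):
        # dominant class classified well, rare class always missed by 2+
        gold = [5] * 90 + [10] * 10
        pred = [5] * 90 + [7] * 10
        acc = tolerance_accuracy(gold, pred, 0.1, 10)
        bal = balanced_accuracy(gold, pred, 0.1, 10)
        assert bal < acc

    def test_equals_plain_accuracy_when_recalls_equal(self):
        gold = [1, 1, 2, 2]
        pred = [1, 3, 2, 4]  # both classes have recall 0.5 at margin 0
        assert balanced_accuracy(gold, pred, 0.0, 10) == tolerance_accuracy(gold, pred, 0.0, 10)


class TestEvaluate:
    def test_report_invariants(self, rng):
        gold = rng.integers(1, 11, 400)
        pred = np.clip(gold + rng.integers(-2, 3, 400), 1, 10)
        rep = evaluate(gold, pred, 10, scale_name="monk")
        assert rep.accuracy <= rep.sufficient_accuracy
        cm = np.array(rep.confusion_matrix)
        assert cm.sum() == 400
        assert np.array_equal(cm.sum(axis=1), np.bincount(gold, minlength=11)[1:])
        recs = [r for r in rep.per_class_recall if r is not None]
        assert rep.balanced_accuracy == pytest.approx(np.mean(recs))

    def test_confusion_matrix_counts(self):
        cm = confusion_matrix([1, 1, 2], [1, 2, 2], 3)
        assert cm.tolist() == [[1, 1, 0], [0, 1, 0], [0, 0, 0]]

    def test_invalid_margin_config(self):
        with pytest.raises(ValueError):
            EvalConfig(accuracy_margin=1.5)


class TestFleissKappa:
    def test_unanimous_agreement_is_one(self):
        tab = np.zeros((12, 4), dtype=int)
        tab[np.arange(12), np.arange(12) % 4] = 3
        assert fleiss_kappa(tab) == pytest.approx(1.0)

    def test_frozen_reference_table(self):
        assert fleiss_kappa(KAPPA_TABLE) == pytest.approx(KAPPA_REFERENCE, abs=1e-6)

    def test_matches_independent_implementation(self, rng):
        from statsmodels.stats.inter_rater import fleiss_kappa as sm_kappa

        for _ in range(5):
            tab = np.zeros((15, 4), dtype=int)
            for i in range(15):
                for c in rng.integers(0, 4, 4):
                    tab[i, c] += 1
            assert fleiss_kappa(tab) == pytest.approx(float(sm_kappa(tab)), abs=1e-12)

    def test_invariant_to_category_relabeling(self, rng):
        tab = rng.multinomial(5, [0.3, 0.3, 0.2, 0.2], size=25)
        perm = rng.permutation(4)
        assert fleiss_kappa(tab) == pytest.approx(fleiss_kappa(tab[:, perm]), abs=1e-12)

    def test_ragged_rater_counts_rejected(self):
        with pytest.raises(ValueError, match="same number"):
            fleiss_kappa(np.array([[2, 1], [1, 1]]))


class TestMannWhitney:
    def test_extreme_separation_exact(self):
        U, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert U == 0.0
        assert p == pytest.approx(0.1, abs=1e-12)  # 2 x 1/C(6,3)

    def test_exhaustive_enumeration_oracle(self):
        """The exact p equals direct enumeration of all rank assignments."""
        a, b = [1.3, 2.1, 4.8], [0.2, 3.3, 5.1, 6.0]
        U_obs, p = mann_whitney(a, b)
        pooled = sorted(a + b)
        n_a = len(a)
        count = total = 0
        for combo in itertools.combinations(range(len(pooled)), n_a):
            ranks_a = [r + 1 for r in combo]
            u_a = sum(ranks_a) - n_a * (n_a + 1) / 2
            u = min(u_a, n_a * (len(b)) - u_a)
            if u <= min(U_obs, n_a * len(b) - U_obs):
                count += 1
            total += 1
        assert p == pytest.approx(count / total, abs=1e-12)

    def test_identical_groups(self):
        _, p = mann_whitney([1.0, 2.0, 3.0, 4.0] * 5, [1.0, 2.0, 3.0, 4.0] * 5)
        assert p > 0.99

    def test_symmetry_identity(self, rng):
        a = rng.normal(0, 1, 12)
        b = rng.normal(0.5, 1, 15)
        U_a, p_ab = mann_whitney(a, b)
        U_b, p_ba = mann_whitney(b, a)
        assert p_ab == pytest.approx(p_ba, abs=1e-12)
        assert U_a + U_b == pytest.approx(len(a) * len(b))

    def test_approximation_close_to_exact_at_n8(self, rng):
        from scipy.stats import mannwhitneyu

        a = rng.normal(0, 1, 8)
        b = rng.normal(0.8, 1, 8)
        _, p = mann_whitney(a, b)  # exact branch (n <= 8, no ties)
        p_approx = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
        assert abs(p - p_approx) < 0.02

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            mann_whitney([], [1.0])


class TestSubgroupCompare:
    @staticmethod
    def _tables(deviations_by_region):
        rows_r, rows_g = [], []
        i = 0
        for region, devs in deviations_by_region.items():
            for d in devs:
                rows_g.append({"image_id": f"im{i}", "region": region, "scale": "monk",
                               "class": 5, "image_type": "clinical"})
                rows_r.append({"image_id": f"im{i}", "region": region, "monk": 5 + d})
                i += 1
        return pd.DataFrame(rows_r), pd.DataFrame(rows_g)

    def test_identical_distributions_large_p(self):
        res, gold = self._tables({"arm": [0, 1, 0, 1] * 8, "face": [0, 1, 0, 1] * 8})
        rep = subgroup_compare(res, gold, "body_site")
        assert rep["p"] > 0.9
        assert rep["n"] == [32, 32]

    def test_extreme_separation_significant(self):
        res, gold = self._tables({"arm": [0] * 30, "face": [3] * 30})
        rep = subgroup_compare(res, gold, "body_site")
        assert rep["p"] < 0.001
        assert rep["accuracy"] == [1.0, 0.0]

    def test_light_dark_partition_covers_everything(self, rng):
        rows_r, rows_g = [], []
        for i in range(60):
            cls = int(rng.integers(1, 11))
            rows_g.append({"image_id": f"im{i}", "region": "arm", "scale": "monk",
                           "class": cls, "image_type": "clinical"})
            rows_r.append({"image_id": f"im{i}", "region": "arm",
                           "monk": int(np.clip(cls + rng.integers(-1, 2), 1, 10))})
        rep = subgroup_compare(pd.DataFrame(rows_r), pd.DataFrame(rows_g), "light_vs_dark")
        assert sum(rep["n"]) == 60
        assert rep["groups"] == ["classes 1-5", "classes 6-10"]

    def test_empty_group_reported_not_raised(self):
        res, gold = self._tables({"arm": [0, 1, 0]})
        rep = subgroup_compare(res, gold, "body_site")
        assert rep["p"] is None and "not computable" in rep["note"]
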