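"""ROC/AUC, per-study means, Wilcoxon-Pratt and threshold calibration."""

import itertools

import numpy as np
import pytest
from scipy import stats

from cd4imm.evaluation import (
    ConfusionCounts,
    StudySet,
    auc,
    confusion_at_threshold,
    fraction_synthesized,
    per_study_auc,
    roc_points,
    sensitivity,
    specificity,
    threshold_table,
    wilcoxon_pratt,
)


def pair_auc(scores, labels):
    """Brute-force Mann-Whitney probability with ties counted half."""
    s = np.asarray(scores, float)
    y = np.asarray(labels)
    pos, neg = s[y == 1], s[y == 0]
    comp = (pos[:, None] > neg[None, :]) + 0.5 * (pos[:, None] == neg[None, :])
    return comp.mean()


class TestRocPoints:
    def test_perfect_separation_passes_through_0_1(self):
        pts = roc_points([3, 4, 1, 2], [1, 1, 0, 0])
        assert [0.0, 1.0] in pts.tolist()
        assert pts[0].tolist() == [0.0, 0.0] and pts[-1].tolist() == [1.0, 1.0]

    def test_constant_scores_two_points(self):
        pts = roc_points([5, 5, 5, 5], [1, 0, 1, 0])
        assert pts.tolist() == [[0.0, 0.0], [1.0, 1.0]]

    def test_hand_enumerated_staircase(self):
        # scores (higher=positive): pos {9, 7, 4}, neg {8, 5, 2}
        pts = roc_points([9, 7, 4, 8, 5, 2], [1, 1, 1, 0, 0, 0])
        expected = [
            [0, 0],
            [0, 1 / 3],        # cut at 9: 1 TP
            [1 / 3, 1 / 3],    # 8: 1 FP
            [1 / 3, 2 / 3],    # 7
            [2 / 3, 2 / 3],    # 5
            [2 / 3, 1.0],      # 4
            [1.0, 1.0],        # 2
        ]
        assert np.allclose(pts, expected)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_points([1, 2], [1, 1])


class TestAuc:
    def test_perfect_and_random_endpoints(self):
        assert auc([4, 3, 2, 1], [1, 1, 0, 0]) == 1.0
        assert auc([1, 1, 1, 1], [1, 0, 1, 0]) == 0.5

    def test_orientation_flip(self):
        s, y = [10.0, 20.0, 30.0, 40.0], [1, 1, 0, 0]
        assert auc(s, y, orientation="lower") == 1.0
        assert auc(s, y, orientation="higher") == 0.0

    def test_matches_pair_oracle_random_instances(self, rng):
        for _ in range(300):
            n = int(rng.integers(4, 200))
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            # integer scores force ties
            s = rng.integers(0, 12, n).astype(float)
            assert auc(s, y) == pytest.approx(pair_auc(s, y), abs=1e-12)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        for _ in range(50):
            n = int(rng.integers(10, 100))
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            s = rng.normal(size=n)
            assert auc(s, y) == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_label_inversion_complement_for_tie_free_scores(self, rng):
        s = rng.permutation(50).astype(float)
        y = rng.integers(0, 2, 50)
        y[:2] = [0, 1]
        assert auc(s, y) + auc(s, 1 - y) == pytest.approx(1.0, abs=1e-12)


class TestPerStudyAuc:
    def _studies(self):
        return [
            StudySet("s1", ["AAA", "CCC"], ["DDD", "EEE"]),
            StudySet("s2", ["FFF"], ["GGG", "HHH"]),
        ]

    def test_unweighted_mean(self):
        scores = {"AAA": 1, "CCC": 2, "DDD": 9, "EEE": 8, "FFF": 5, "GGG": 1, "HHH": 9}
        tab, mean = per_study_auc(self._studies(), scores, orientation="lower")
        assert tab.loc[tab.study_id == "s1", "auc"].item() == 1.0
        assert tab.loc[tab.study_id == "s2", "auc"].item() == 0.5
        assert mean == 0.75

    def test_degenerate_study_skipped_with_warning(self):
        studies = self._studies() + [StudySet("empty_neg", ["III"], [])]
        scores = dict.fromkeys("AAA CCC DDD EEE FFF GGG HHH III".split(), 1.0)
        with pytest.warns(UserWarning, match="empty_neg"):
            tab, mean = per_study_auc(studies, scores)
        assert np.isnan(tab.loc[tab.study_id == "empty_neg", "auc"].item())

    def test_overlapping_pos_neg_rejected(self):
        with pytest.raises(ValueError):
            StudySet("bad", ["AAA"], ["AAA"])


def enumeration_oracle(d):
    """Independent two-sided Pratt p: enumerate sign assignments of nonzero ranks."""
    d = np.asarray(d, float)
    ranks = stats.rankdata(np.abs(d))
    r = ranks[d != 0]
    signs_obs = d[d != 0] > 0
    if r.size == 0:
        return 1.0
    center = r.sum() / 2
    w_obs = r[signs_obs].sum()
    count = 0
    for signs in itertools.product([False, True], repeat=r.size):
        w = r[list(signs)].sum()
        if abs(w - center) >= abs(w_obs - center) - 1e-12:
            count += 1
    return count / 2 ** r.size


class TestWilcoxonPratt:
    def test_identical_vectors_give_one(self):
        assert wilcoxon_pratt([0.1, 0.2, 0.3, 0.4, 0.5], [0.1, 0.2, 0.3, 0.4, 0.5]) == 1.0

    def test_exact_matches_enumeration_with_zeros(self, rng):
        for _ in range(40):
            n = int(rng.integers(3, 11))
            d = np.round(rng.normal(size=n), 1)
            d[rng.random(n) < 0.25] = 0.0
            p = wilcoxon_pratt(d, np.zeros(n))
            assert p == pytest.approx(enumeration_oracle(d), abs=1e-12)

    def test_swap_symmetry(self, rng):
        a, b = rng.normal(size=8), rng.normal(size=8)
        assert wilcoxon_pratt(a, b) == pytest.approx(wilcoxon_pratt(b, a), abs=1e-12)

    def test_approx_branch_matches_scipy(self, rng):
        # no zeros, n > 12 -> normal approximation; scipy is the oracle
        for _ in range(20):
            a = rng.normal(size=30)
            b = a + rng.normal(0.2, 1.0, size=30)
            expected = stats.wilcoxon(
                a, b, zero_method="pratt", correction=False, method="approx"
            ).pvalue
            assert wilcoxon_pratt(a, b) == pytest.approx(expected, rel=1e-10)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_pratt([1, 2], [1, 2, 3])


class TestConfusion:
    def test_formulas_match_quoted_definitions(self):
        c = ConfusionCounts(tp=3, fp=10, tn=77, fn=10)
        assert sensitivity(c) == pytest.approx(100 * 3 / 13)
        assert specificity(c) == pytest.approx(100 * 77 / 87)
        assert fraction_synthesized(c) == pytest.approx(13.0)

    def test_examples(self):
        assert sensitivity(ConfusionCounts(20, 0, 0, 80)) == 20.0
        assert specificity(ConfusionCounts(0, 9, 91, 0)) == 91.0

    def test_threshold_rule_is_score_at_most_t(self):
        c = confusion_at_threshold([10, 50, 90], [1, 0, 0], 50)
        assert (c.tp, c.fp, c.tn, c.fn) == (1, 1, 1, 0)

    def test_empty_class_errors(self):
        with pytest.raises(ValueError):
            sensitivity(ConfusionCounts(0, 1, 1, 0))


class TestThresholdTable:
    def _fixture(self, rng):
        studies, scores = [], {}
        for i in range(6):
            pos = [f"P{i}{j}" for j in range(5)]
            neg = [f"N{i}{j}" for j in range(8)]
            studies.append(StudySet(f"s{i}", pos, neg))
            for p in pos:
                scores[p] = float(rng.uniform(0, 60))
            for p in neg:
                scores[p] = float(rng.uniform(30, 100))
        return studies, scores

    def test_extreme_cutoffs(self, rng):
        studies, scores = self._fixture(rng)
        tab = threshold_table(studies, scores, cutoffs=[-1, 101])
        assert tab.iloc[0]["avg_sensitivity"] == 0.0
        assert tab.iloc[0]["avg_specificity"] == 100.0
        assert tab.iloc[1]["avg_sensitivity"] == 100.0
        assert tab.iloc[1]["avg_specificity"] == 0.0

    def test_monotone_in_cutoff(self, rng):
        studies, scores = self._fixture(rng)
        tab = threshold_table(studies, scores, cutoffs=np.linspace(0, 100, 21))
        sens = tab["avg_sensitivity"].to_numpy()
        spec = tab["avg_specificity"].to_numpy()
        assert (np.diff(sens) >= -1e-12).all()
        assert (np.diff(spec) <= 1e-12).all()

    def test_matches_hand_computed_confusion(self):
        st = StudySet("s", ["A", "B"], ["C", "D"])
        scores = {"A": 10.0, "B": 50.0, "C": 30.0, "D": 90.0}
        tab = threshold_table([st], scores, cutoffs=[40])
        # at t=40: predicted positive {A, C} -> TP=1 FN=1 FP=1 TN=1
        assert tab.iloc[0]["avg_sensitivity"] == 50.0
        assert tab.iloc[0]["avg_specificity"] == 50.0
        assert tab.iloc[0]["avg_fraction_synthesized"] == 50.0
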