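"""Feature-ranking oracles: closed-form ANOVA, brute-force MI and ENTR."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from confsel.feature_selection import (
    FeatureScoreTable,
    anova_f_scores,
    binned_mutual_information,
    common_features,
    feature_score_table,
    mutual_information,
    rqa_entropy,
    rqa_scores,
    select_features,
)

from conftest import make_table


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def mi_bruteforce_bits(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in MI by an explicit double loop over the joint histogram."""
    n = len(y)
    mi = 0.0
    for xv in np.unique(x):
        for yv in np.unique(y):
            pxy = np.sum((x == xv) & (y == yv)) / n
            if pxy == 0:
                continue
            px = np.sum(x == xv) / n
            py = np.sum(y == yv) / n
            mi += pxy * np.log2(pxy / (px * py))
    return mi


def entr_bruteforce(series: np.ndarray, epsilon: float, l_min: int) -> float:
    """O(N^2) recurrence-matrix enumeration of diagonal-line entropy."""
    n = len(series)
    recur = np.abs(series[:, None] - series[None, :]) <= epsilon
    lengths = []
    for offset in range(1, n):  # strict upper triangle diagonals
        diag = [recur[i, i + offset] for i in range(n - offset)]
        run = 0
        for val in diag + [False]:
            if val:
                run += 1
            else:
                if run >= l_min:
                    lengths.append(run)
                run = 0
    if not lengths:
        return 0.0
    _, counts = np.unique(lengths, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


# ---------------------------------------------------------------------------
# ANOVA F
# ---------------------------------------------------------------------------

class TestAnova:
    def test_closed_form_f_equals_8(self):
        """class0={1,2}, class1={3,4}: SSB=4, SSW=1, df_w=2 -> F=8."""
        table = make_table([[1.0], [2.0], [3.0], [4.0]], [0, 0, 1, 1])
        ranking = anova_f_scores(table, k=1)
        assert ranking.scores[0] == pytest.approx(8.0)

    def test_constant_feature_f_zero(self):
        table = make_table([[5.0, 1.0], [5.0, 2.0], [5.0, 3.0], [5.0, 4.0]],
                           [0, 0, 1, 1])
        assert anova_f_scores(table, k=1).scores[0] == 0.0

    def test_perfect_separator_ranks_first(self):
        # zero within-class variance, distinct means: largest finite + 1
        table = make_table(
            [[0.0, 1.0], [0.0, 2.0], [1.0, 3.0], [1.0, 4.0]], [0, 0, 1, 1]
        )
        ranking = anova_f_scores(table, k=1)
        assert ranking.ranks[0] == 1
        assert np.isfinite(ranking.scores).all()

    def test_matches_sklearn(self, rng):
        from sklearn.feature_selection import f_classif

        table = make_table(
            rng.standard_normal((60, 5)), (rng.uniform(size=60) < 0.4).astype(int)
        )
        f_ref, _ = f_classif(table.values, table.labels)
        np.testing.assert_allclose(anova_f_scores(table, k=2).scores, f_ref, rtol=1e-9)

    def test_null_f_distribution_calibrated(self, rng):
        """Label permutation makes F follow F(1, n-2)."""
        from scipy.stats import f as f_dist

        n = 60
        x = rng.standard_normal((n, 1))
        labels = np.array([0] * 30 + [1] * 30)
        fs = []
        for _ in range(500):
            perm = rng.permutation(labels)
            fs.append(anova_f_scores(make_table(x, perm), k=1).scores[0])
        fs = np.sort(fs)
        theo = f_dist(1, n - 2)
        for q in (0.25, 0.5, 0.75, 0.9):
            emp = np.quantile(fs, q)
            lo, hi = theo.ppf(q - 0.06), theo.ppf(q + 0.06)
            assert lo < emp < hi

    def test_affine_invariance(self, rng):
        table = make_table(rng.standard_normal((40, 3)),
                           (rng.uniform(size=40) < 0.5).astype(int))
        scaled = make_table(table.values * [3.0, -0.5, 100.0] + [1, 2, 3],
                            table.labels)
        np.testing.assert_allclose(
            anova_f_scores(table, k=1).scores, anova_f_scores(scaled, k=1).scores,
            rtol=1e-9,
        )


# ---------------------------------------------------------------------------
# Mutual information
# ---------------------------------------------------------------------------

class TestMutualInformation:
    def test_label_copy_gives_one_bit(self):
        labels = np.array([0, 1] * 20)
        table = make_table(labels[:, None].astype(float), labels)
        mi = mutual_information(table, n_bins=10, k=1)
        assert mi.scores[0] == pytest.approx(1.0)

    def test_derived_joint_table(self):
        """counts {(0,0):2,(0,1):1,(1,0):1,(1,1):2} -> 0.0817 bits."""
        x = np.array([0, 0, 0, 1, 1, 1])
        y = np.array([0, 0, 1, 0, 1, 1])
        assert binned_mutual_information(x, y) == pytest.approx(0.08170, abs=1e-4)

    def test_oracle_equivalence_small_tables(self, rng):
        for _ in range(30):
            n_bins = rng.integers(2, 7)
            x = rng.integers(0, n_bins, size=40)
            y = rng.integers(0, 2, size=40)
            assert binned_mutual_information(x, y) == pytest.approx(
                mi_bruteforce_bits(x, y), abs=1e-12
            )

    def test_independent_feature_mi_vanishes(self, rng):
        """MI of an independent feature shrinks as n grows (plug-in bias)."""
        mis = []
        for n in (100, 3000):
            labels = (rng.uniform(size=n) < 0.5).astype(int)
            table = make_table(rng.standard_normal((n, 1)), labels)
            mis.append(mutual_information(table, n_bins=10, k=1).scores[0])
        assert mis[1] < mis[0]
        assert mis[1] < 0.01

    def test_constant_feature_zero(self):
        table = make_table(np.ones((20, 1)), [0, 1] * 10)
        assert mutual_information(table, n_bins=10, k=1).scores[0] == 0.0

    def test_equal_frequency_binning_is_monotone_invariant(self, rng):
        x = rng.standard_normal(200)
        labels = (rng.uniform(size=200) < 0.3).astype(int)
        t1 = make_table(x[:, None], labels)
        t2 = make_table(np.exp(x)[:, None], labels)  # monotone transform
        assert mutual_information(t1, 8, 1).scores[0] == pytest.approx(
            mutual_information(t2, 8, 1).scores[0], abs=1e-12
        )


# ---------------------------------------------------------------------------
# Recurrence entropy
# ---------------------------------------------------------------------------

class TestRqaEntropy:
    def test_uniform_two_lengths_gives_ln2(self):
        """A line-length histogram {2:1, 3:1} has entropy ln 2.

        The series repeats a 2-point motif (1,2) once and a 3-point motif
        (4,5,6) once, with all other values far apart, so the recurrence
        plot contains exactly one diagonal line of length 2 and one of
        length 3.
        """
        series = np.array(
            [1.0, 2.0, 100.0, 4.0, 5.0, 6.0, 200.0,
             1.0, 2.0, 300.0, 4.0, 5.0, 6.0, 400.0]
        )
        eps = 0.1
        assert entr_bruteforce(series, eps, 2) == pytest.approx(np.log(2), abs=1e-12)
        assert rqa_entropy(series, eps, 2) == pytest.approx(np.log(2), abs=1e-12)

    def test_all_lines_equal_length_entropy_zero(self):
        # period-2 alternation: every diagonal line has the same length
        series = np.array([0.0, 5.0] * 6)
        assert rqa_entropy(series, epsilon=0.1, l_min=2) >= 0.0
        assert rqa_entropy(series, epsilon=0.1, l_min=12) == 0.0

    def test_constant_series_matches_oracle(self):
        series = np.zeros(12)
        assert rqa_entropy(series, 0.5, 2) == pytest.approx(
            entr_bruteforce(series, 0.5, 2), abs=1e-12
        )

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        n=st.integers(5, 50),
        l_min=st.integers(2, 4),
    )
    def test_oracle_equivalence_random_series(self, seed, n, l_min):
        rng = np.random.default_rng(seed)
        series = np.round(rng.standard_normal(n), 1)  # rounding makes ties common
        eps = float(rng.uniform(0.05, 1.0))
        assert rqa_entropy(series, eps, l_min) == pytest.approx(
            entr_bruteforce(series, eps, l_min), abs=1e-12
        )

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            rqa_entropy(np.array([1.0, np.nan, 2.0]), 0.5, 2)
        with pytest.raises(ValueError):
            rqa_entropy(np.arange(5.0), -1.0, 2)


class TestRqaScores:
    def test_duplicate_columns_identical_scores(self, rng):
        x = rng.standard_normal(80)
        table = make_table(np.column_stack([x, x]), (rng.uniform(size=80) < 0.5).astype(int))
        scores = rqa_scores(table, 0.10, 2, k=1).scores
        assert scores[0] == scores[1]

    def test_saturated_threshold_ties_broken_by_column_order(self, rng):
        table = make_table(rng.standard_normal((30, 3)),
                           (rng.uniform(size=30) < 0.5).astype(int))
        ranking = rqa_scores(table, epsilon_quantile=1.0, l_min=2, k=2)
        # all pairs recurrent for every feature -> identical scores
        assert len(set(np.round(ranking.scores, 12))) == 1
        assert ranking.top_k_set == {"f000", "f001"}

    def test_matches_single_series_entropy(self, rng):
        x = rng.standard_normal(60)
        table = make_table(x[:, None], (rng.uniform(size=60) < 0.5).astype(int))
        dist = np.abs(x[:, None] - x[None, :])
        eps = np.quantile(dist[np.triu_indices(60, k=1)], 0.10)
        expected = rqa_entropy(x, float(eps), 2)
        assert rqa_scores(table, 0.10, 2, k=1).scores[0] == pytest.approx(expected)


# ---------------------------------------------------------------------------
# Score table and selection
# ---------------------------------------------------------------------------

def _ranking_from_order(method, names, order, k):
    from confsel.feature_selection import FeatureRanking

    scores = np.zeros(len(names))
    for r, name in enumerate(order):
        scores[names.index(name)] = len(order) - r
    return FeatureRanking(method, tuple(names), scores, k)


class TestFeatureScoreTable:
    def test_score_counts_methods(self):
        names = [f"f{i}" for i in range(6)]
        r1 = _ranking_from_order("anova", names, ["f0", "f1"], 2)
        r2 = _ranking_from_order("mi", names, ["f0", "f2"], 2)
        r3 = _ranking_from_order("rqa", names, ["f0", "f3"], 2)
        scores = feature_score_table((r1, r2, r3))
        assert scores.scores["f0"] == 3
        assert scores.scores["f1"] == scores.scores["f2"] == scores.scores["f3"] == 1
        assert scores.scores["f4"] == 0

    def test_score_sum_is_3k(self, rng):
        names = [f"f{i}" for i in range(12)]
        rankings = tuple(
            _ranking_from_order(m, names, list(rng.permutation(names)[:4]), 4)
            for m in ("anova", "mi", "rqa")
        )
        scores = feature_score_table(rankings)
        assert sum(scores.scores.values()) == 12

    def test_disjoint_top10_over_40_features(self, rng):
        names = [f"f{i:02d}" for i in range(40)]
        blocks = [names[:10], names[10:20], names[20:30]]
        rankings = tuple(
            _ranking_from_order(m, names, blk, 10)
            for m, blk in zip(("anova", "mi", "rqa"), blocks)
        )
        scores = feature_score_table(rankings)
        counts = np.bincount(list(scores.scores.values()), minlength=4)
        assert counts.tolist() == [10, 30, 0, 0]


class TestSelection:
    def _tables(self, rng):
        table = make_table(rng.standard_normal((20, 5)),
                           (rng.uniform(size=20) < 0.5).astype(int))
        scores = FeatureScoreTable(
            table.feature_names,
            {"f000": 3, "f001": 2, "f002": 1, "f003": 0, "f004": 3},
        )
        return table, scores

    def test_min_score_3_intersection(self, rng):
        table, scores = self._tables(rng)
        selected = select_features(table, scores, 3)
        assert selected.feature_names == ("f000", "f004")

    def test_min_score_1_union(self, rng):
        table, scores = self._tables(rng)
        assert select_features(table, scores, 1).feature_names == (
            "f000", "f001", "f002", "f004",
        )

    def test_empty_selection_raises(self, rng):
        table, _ = self._tables(rng)
        empty = FeatureScoreTable(table.feature_names,
                                  {f: 0 for f in table.feature_names})
        with pytest.raises(ValueError, match="min_score"):
            select_features(table, empty, 1)

    def test_common_features(self):
        a = FeatureScoreTable(("x", "y", "z"), {"x": 3, "y": 3, "z": 0})
        b = FeatureScoreTable(("x", "y", "z"), {"x": 3, "y": 1, "z": 3})
        assert common_features(a, b, 3) == {"x"}
        assert common_features(a, a, 3) == {"x", "y"}
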