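import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial.distance import jensenshannon
from sklearn.metrics import adjusted_rand_score
from statsmodels.stats.inter_rater import fleiss_kappa as sm_fleiss_kappa

from cm1subtype.agreement import (
    adjusted_rand_index,
    average_sensitivity,
    contingency,
    cramers_v,
    fleiss_kappa,
    js_distance,
    landis_koch_band,
    agreement_report,
    ratings_from_contingency,
    ratings_from_labels,
)
from cm1subtype.published_tables import get_table
from cm1subtype.types import DomainError


def random_contingency(rng, max_n=40):
    """Random small two-labelling cross-classification."""
    n = rng.integers(5, max_n + 1)
    r, c = rng.integers(2, 5), rng.integers(2, 5)
    a = rng.integers(0, r, size=n)
    b = rng.integers(0, c, size=n)
    return pd.crosstab(pd.Series(a), pd.Series(b)), a, b


def pair_counting_ari(a, b) -> float:
    """Brute-force ARI over all unordered sample pairs."""
    n00 = n01 = n10 = n11 = 0
    for i, j in itertools.combinations(range(len(a)), 2):
        same_a, same_b = a[i] == a[j], b[i] == b[j]
        if same_a and same_b:
            n11 += 1
        elif same_a:
            n10 += 1
        elif same_b:
            n01 += 1
        else:
            n00 += 1
    denom = (n11 + n10) * (n10 + n00) + (n11 + n01) * (n01 + n00)
    if denom == 0:
        return 1.0
    return 2 * (n11 * n00 - n10 * n01) / denom


class TestContingency:
    def test_identical_labellings_are_diagonal(self):
        idx = pd.Index([f"s{i}" for i in range(10)])
        a = pd.Series(["LA"] * 6 + ["B"] * 4, index=idx)
        t = contingency(a, a)
        assert t.loc["LA", "LA"] == 6 and t.loc["B", "B"] == 4
        assert t.to_numpy().sum() == 10
        assert t.loc["LA", "B"] == 0

    def test_canonical_category_order(self):
        idx = pd.Index(range(6))
        a = pd.Series(["B", "LA", "H", "N", "LB", "INC"], index=idx)
        t = contingency(a, a)
        assert list(t.index) == ["LA", "LB", "H", "N", "B", "INC"]

    def test_exclude_inc_drops_samples(self):
        idx = pd.Index(range(6))
        a = pd.Series(["LA", "LA", "LB", "LB", "LB", "LA"], index=idx)
        b = pd.Series(["LA", "INC", "LB", "LB", "INC", "LA"], index=idx)
        t = contingency(a, b, include_inc=False)
        assert t.to_numpy().sum() == 4
        assert "INC" not in t.columns

    def test_mismatched_samples_listed(self):
        a = pd.Series(["LA"], index=["s1"])
        b = pd.Series(["LA"], index=["s2"])
        with pytest.raises(DomainError, match="s1"):
            contingency(a, b)

    def test_reconstructed_labels_reproduce_published_block(self):
        """Rebuilding per-sample label files from the published discovery
        table and cross-tabulating them returns the printed counts."""
        ref = get_table("cm1_vs_original", "discovery")
        rows_a, rows_b = [], []
        for i in ref.index:
            for j in ref.columns:
                n = int(ref.loc[i, j])
                rows_a.extend([i] * n)
                rows_b.extend([j] * n)
        idx = pd.Index([f"s{i}" for i in range(len(rows_a))])
        t = contingency(pd.Series(rows_a, index=idx), pd.Series(rows_b, index=idx))
        pd.testing.assert_frame_equal(
            t.astype(int), ref.astype(int), check_names=False
        )


class TestCramersV:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ([[10, 0], [0, 10]], 1.0),   # perfect association
            ([[6, 2], [2, 6]], 0.5),     # chi2 = 4, N = 16
            ([[5, 5], [5, 5]], 0.0),     # independence
        ],
    )
    def test_reference_tables(self, table, expected):
        assert cramers_v(pd.DataFrame(table)) == pytest.approx(expected, abs=1e-12)

    def test_transpose_invariance_and_count_scaling(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            t, _, _ = random_contingency(rng)
            v = cramers_v(t)
            assert cramers_v(t.T) == pytest.approx(v, abs=1e-12)
            assert cramers_v(t * 7) == pytest.approx(v, abs=1e-12)

    def test_zero_marginal_category_dropped_with_warning(self):
        t = pd.DataFrame([[10, 0, 5], [2, 0, 9]], columns=["x", "dead", "y"])
        with pytest.warns(UserWarning, match="dead"):
            v = cramers_v(t)
        assert 0 <= v <= 1


class TestAverageSensitivity:
    def test_published_discovery_diagonal(self):
        # diagonal 435,234,67,31,103 over row sums 466,268,87,58,118
        t = get_table("cm1_vs_original", "discovery")
        expected = (435 / 466 + 234 / 268 + 67 / 87 + 31 / 58 + 103 / 118) / 5
        assert average_sensitivity(t) == pytest.approx(expected, abs=1e-12)
        assert average_sensitivity(t) == pytest.approx(0.7968, abs=5e-4)

    def test_identity_table_is_one(self):
        t = pd.DataFrame(np.diag([5, 3, 2]), index=list("abc"), columns=list("abc"))
        assert average_sensitivity(t) == 1.0

    def test_one_empty_diagonal_cell_costs_exactly_one_rth(self):
        t = pd.DataFrame(
            [[4, 0, 0], [0, 4, 0], [4, 0, 0]], index=list("abc"), columns=list("abc")
        )
        assert average_sensitivity(t) == pytest.approx(1 - 1 / 3)

    def test_empty_row_rejected(self):
        t = pd.DataFrame([[2, 0], [0, 0]], index=list("ab"), columns=list("ab"))
        with pytest.raises(DomainError):
            average_sensitivity(t)


def brute_force_fleiss(n: np.ndarray) -> float:
    """Direct agreement-proportion evaluation: kappa = (Pbar - Pe)/(1 - Pe)."""
    s, _ = n.shape
    k = n[0].sum()
    p = n.sum(axis=0) / (s * k)
    p_i = [(row @ row - k) / (k * (k - 1)) for row in n]
    pbar = float(np.mean(p_i))
    pe = float(p @ p)
    return (pbar - pe) / (1 - pe)


class TestFleissKappa:
    def test_published_discovery_value(self):
        t = get_table("cm1_vs_original", "discovery")
        ratings = ratings_from_contingency(t)
        assert len(ratings) == 997
        assert fleiss_kappa(ratings) == pytest.approx(0.814, abs=1e-3)

    def test_unanimous_raters_give_one(self):
        ratings = pd.DataFrame([[3, 0], [0, 3], [3, 0]], columns=["LA", "B"])
        assert fleiss_kappa(ratings) == pytest.approx(1.0)

    def test_small_table_matches_brute_force(self):
        ratings = np.array([[2, 0], [0, 2], [1, 1], [1, 1]])
        assert fleiss_kappa(pd.DataFrame(ratings)) == pytest.approx(
            brute_force_fleiss(ratings), abs=1e-12
        )

    def test_random_matrices_match_brute_force_and_statsmodels(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            s, c, k = rng.integers(3, 12), rng.integers(2, 5), rng.integers(2, 6)
            n = np.zeros((s, c), dtype=int)
            for i in range(s):
                votes = rng.integers(0, c, size=k)
                for v in votes:
                    n[i, v] += 1
            if (n.sum(axis=0) ** 2).sum() == (s * k) ** 2:
                continue  # degenerate single-category case
            ours = fleiss_kappa(pd.DataFrame(n))
            assert ours == pytest.approx(brute_force_fleiss(n), abs=1e-10)
            assert ours == pytest.approx(sm_fleiss_kappa(n), abs=1e-10)

    def test_lower_bound_from_category_prevalences(self):
        rng = np.random.default_rng(21)
        for _ in range(25):
            s, c, k = rng.integers(2, 10), rng.integers(2, 5), rng.integers(2, 5)
            n = np.zeros((s, c), dtype=int)
            for i in range(s):
                for v in rng.integers(0, c, size=k):
                    n[i, v] += 1
            p_sq = float(((n.sum(axis=0) / (s * k)) ** 2).sum())
            if p_sq == 1.0:
                continue
            assert fleiss_kappa(pd.DataFrame(n)) >= -p_sq / (1 - p_sq) - 1e-12

    def test_single_category_undefined(self):
        ratings = pd.DataFrame([[2], [2], [2]], columns=["LA"])
        with pytest.raises(DomainError, match="undefined"):
            fleiss_kappa(ratings)

    def test_ratings_from_labels_agrees_with_contingency_route(self):
        idx = pd.Index([f"s{i}" for i in range(12)])
        a = pd.Series(["LA"] * 5 + ["LB"] * 4 + ["B"] * 3, index=idx)
        b = pd.Series(["LA"] * 4 + ["INC"] * 2 + ["LB"] * 3 + ["B"] * 3, index=idx)
        k1 = fleiss_kappa(ratings_from_labels(a, b))
        k2 = fleiss_kappa(ratings_from_contingency(contingency(a, b)))
        assert k1 == pytest.approx(k2, abs=1e-12)


class TestAdjustedRandIndex:
    def test_identical_partitions_give_one(self):
        t = pd.DataFrame(np.diag([4, 3, 3]))
        assert adjusted_rand_index(t) == pytest.approx(1.0)

    def test_random_tables_match_pair_counting_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            t, a, b = random_contingency(rng, max_n=40)
            ours = adjusted_rand_index(t)
            assert ours == pytest.approx(pair_counting_ari(a, b), abs=1e-12)
            assert ours == pytest.approx(adjusted_rand_score(a, b), abs=1e-12)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(23)
        t, _, _ = random_contingency(rng)
        base = adjusted_rand_index(t)
        perm_rows = t.sample(frac=1, random_state=1)
        perm_cols = t[t.columns.to_series().sample(frac=1, random_state=2)]
        assert adjusted_rand_index(perm_rows) == pytest.approx(base, abs=1e-12)
        assert adjusted_rand_index(perm_cols) == pytest.approx(base, abs=1e-12)

    def test_tiny_n_rejected(self):
        with pytest.raises(DomainError):
            adjusted_rand_index(pd.DataFrame([[1]]))


class TestJSDistance:
    def test_identical_distributions_are_zero(self):
        assert js_distance([0.3, 0.7], [0.3, 0.7]) == 0.0

    def test_disjoint_supports_are_one(self):
        assert js_distance([1, 0], [0, 1]) == pytest.approx(1.0)

    def test_hand_evaluated_mixture(self):
        # M = [0.75, 0.25]; JSD = 0.31128...; sqrt = 0.5579
        assert js_distance([1, 0], [0.5, 0.5]) == pytest.approx(0.5579, abs=1e-4)

    def test_matches_scipy_and_symmetry(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            p = rng.dirichlet(np.ones(6))
            q = rng.dirichlet(np.ones(6))
            assert js_distance(p, q) == pytest.approx(
                float(jensenshannon(p, q, base=2)), abs=1e-12
            )
            assert js_distance(p, q) == pytest.approx(js_distance(q, p), abs=1e-15)

    def test_triangle_inequality(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            p, q, r = (rng.dirichlet(np.ones(5)) for _ in range(3))
            assert js_distance(p, r) <= js_distance(p, q) + js_distance(q, r) + 1e-12

    def test_unnormalised_rejected(self):
        with pytest.raises(DomainError):
            js_distance([0.5, 0.4], [0.5, 0.5])


class TestLandisKoch:
    @pytest.mark.parametrize(
        "kappa,band",
        [
            (-0.1, "poor"),
            (0.1, "slight"),
            (0.2, "slight"),
            (0.3, "fair"),
            (0.60, "moderate"),
            (0.75, "substantial"),
            (0.814, "almost perfect"),
            (1.0, "almost perfect"),
        ],
    )
    def test_band_cutpoints(self, kappa, band):
        assert landis_koch_band(kappa) == band


def test_agreement_report_consistent_with_components(toy_labels):
    a, b = toy_labels
    report = agreement_report(a, b)
    table = contingency(a, b)
    assert report.adjusted_rand_index == pytest.approx(adjusted_rand_index(table))
    assert report.fleiss_kappa == pytest.approx(
        fleiss_kappa(ratings_from_contingency(table))
    )
    assert report.cramers_v == pytest.approx(cramers_v(table))
    assert report.kappa_band == landis_koch_band(report.fleiss_kappa)
    assert report.n_samples == 10
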