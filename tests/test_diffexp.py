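"""Kolmogorov-Smirnov testing, Bonferroni control, Gaussian summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from scqpcr import CtTable, normalize
from scqpcr.diffexp import (
    bonferroni,
    cluster_vs_rest,
    compare_groups,
    gaussian_fit,
    ks_permutation_pvalue,
    ks_two_sample,
)
from scqpcr.subpop import ClusterResult, kmeans_partition
from scqpcr.synthetic import generate, null_spec


def _matrix(values, groups):
    values = np.asarray(values, dtype=float)
    # build through a CtTable so the matrix is a genuine pipeline object
    ct = 24.0 - values
    table = CtTable(
        cell_ids=[f"c{i}" for i in range(values.shape[0])],
        gene_ids=[f"g{j}" for j in range(values.shape[1])],
        ct=ct,
        group=np.array(groups, dtype=object),
        chip=np.array(["chip1"] * values.shape[0], dtype=object),
    )
    return normalize(table, bound=50)  # wide bound: no clipping


class TestKsTwoSample:
    def test_identical_samples(self):
        d, p = ks_two_sample([0.0, 1.0, 2.0, 3.0, 4.0], [0.0, 1.0, 2.0, 3.0, 4.0])
        assert d == 0.0 and p == 1.0

    def test_disjoint_supports(self):
        with pytest.warns(UserWarning, match="low power"):
            d, _ = ks_two_sample([0.0, 0.0], [1.0, 1.0])
        assert d == 1.0

    def test_pooled_point_evaluation(self):
        with pytest.warns(UserWarning):
            d, _ = ks_two_sample([0.0, 1.0, 2.0], [0.5, 1.5])
        assert d == pytest.approx(1.0 / 3.0)

    def test_statistic_matches_scipy(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.normal(size=rng.integers(5, 40))
            b = rng.normal(0.5, 1.2, size=rng.integers(5, 40))
            d, _ = ks_two_sample(a, b)
            assert d == pytest.approx(stats.ks_2samp(a, b).statistic)

    def test_ties_at_floor_handled_exactly(self):
        # heavy point mass at the floor on both sides
        a = [-5.0] * 4 + [0.0, 1.0]
        b = [-5.0] * 2 + [0.0, 1.0, 2.0, 3.0]
        d, _ = ks_two_sample(a, b)
        assert d == pytest.approx(stats.ks_2samp(a, b).statistic)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])

    # 3-decimal grid keeps value differences far above float ulp, so the
    # shift cannot merge distinct observations
    _grid = st.floats(-10, 10, allow_nan=False).map(lambda x: round(x, 3))

    @settings(max_examples=40, deadline=None)
    @given(
        st.lists(_grid, min_size=5, max_size=15),
        st.lists(_grid, min_size=5, max_size=15),
        st.floats(-3, 3, allow_nan=False).map(lambda x: round(x, 3)),
    )
    def test_symmetry_and_location_invariance(self, a, b, shift):
        d1, p1 = ks_two_sample(a, b)
        d2, p2 = ks_two_sample(b, a)
        assert d1 == pytest.approx(d2) and p1 == pytest.approx(p2)
        d3, p3 = ks_two_sample([x + shift for x in a], [x + shift for x in b])
        assert d3 == pytest.approx(d1) and p3 == pytest.approx(p1)


class TestPermutationOracle:
    def test_identity_case(self):
        assert ks_permutation_pvalue([1.0, 2.0], [1.0, 2.0]) == 1.0

    def test_extreme_separation_is_minimal_p(self):
        a, b = [0.0, 0.0, 0.0], [9.0, 9.0, 9.0]
        from math import comb

        # only the 2 fully-separated assignments reach D = 1
        assert ks_permutation_pvalue(a, b) == pytest.approx(2 / comb(6, 3))

    def test_refuses_large_enumerations(self):
        with pytest.raises(ValueError, match="max_enumeration"):
            ks_permutation_pvalue(np.zeros(15), np.ones(15))


class TestBonferroni:
    def test_arithmetic_cap_and_identity(self):
        p_adj, sig, m = bonferroni([0.0004] + [0.5] * 95, alpha=0.05)
        assert m == 96
        assert p_adj[0] == pytest.approx(0.0384) and sig[0]
        assert p_adj[1] == 1.0 and not sig[1]
        p_adj1, _, m1 = bonferroni([0.123])
        assert m1 == 1 and p_adj1[0] == pytest.approx(0.123)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([0.5, 1.2])


class TestCompareGroups:
    def test_identical_single_gene_not_significant(self):
        values = np.array([[0.0], [1.0], [2.0], [0.0], [1.0], [2.0]])
        m = _matrix(values, ["A"] * 3 + ["B"] * 3)
        dx = compare_groups(m, alpha=0.05)
        assert dx.m == 1
        assert dx.significant_genes == []

    def test_medians_and_failed_fractions_attached(self, study_matrix):
        dx = compare_groups(study_matrix, alpha=0.05)
        cols = set(dx.table.columns)
        assert {"median_WT", "median_KO", "failed_frac_WT", "failed_frac_KO"} <= cols
        assert dx.table["ks_D"].between(0, 1).all()
        assert (dx.table["p_adj"] >= dx.table["p_raw"] - 1e-15).all()

    def test_group_count_errors(self, study_matrix):
        with pytest.raises(ValueError, match="two groups"):
            compare_groups(study_matrix, groups=np.array(["X"] * study_matrix.n_cells))

    def test_planted_shift_detected(self):
        spec = null_spec(seed=42, n_genes=12, n_per_group=50, shifted_genes={"g01": 4.0})
        table, _ = generate(spec)
        dx = compare_groups(normalize(table), alpha=0.05)
        assert dx.significant_genes == ["g01"]
        row = dx.table.set_index("gene").loc["g01"]
        assert row["direction"] in ("up", "down")


class TestClusterVsRest:
    def test_k1_refused(self, study_matrix):
        res = ClusterResult(
            labels=np.ones(study_matrix.n_cells, dtype=int),
            k=1,
            centroids=np.zeros((1, study_matrix.n_genes)),
            seed=0,
            n_restarts=1,
            wcss=0.0,
        )
        with pytest.raises(ValueError, match="at least two"):
            cluster_vs_rest(study_matrix, res)

    def test_planted_cluster_flags_marker_genes_up(self):
        rng = np.random.default_rng(6)
        n, g = 90, 10
        values = rng.normal(0.0, 0.5, size=(n, g))
        values[60:, :5] += 4.0  # planted cluster overexpresses 5 genes
        m = _matrix(values, ["A"] * 45 + ["B"] * 45)
        clusters = kmeans_partition(m, k=2, seed=0, n_restarts=10)
        per = cluster_vs_rest(m, clusters, alpha=0.05)
        minority = 2  # 30 planted cells: the smaller, higher-numbered cluster
        tab = per[minority].table.set_index("gene")
        flagged_up = set(tab.index[(tab["significant"]) & (tab["direction"] == "up")])
        assert flagged_up == {"g0", "g1", "g2", "g3", "g4"}


class TestGaussianFit:
    @pytest.mark.parametrize(
        "values, mu, sigma, degenerate",
        [
            ([0.0, 0.0, 0.0, 0.0], 0.0, 0.0, True),
            ([-1.0, 1.0], 0.0, np.sqrt(2), False),
            ([5.0], 5.0, 0.0, True),
        ],
    )
    def test_formulas(self, values, mu, sigma, degenerate):
        fit = gaussian_fit(values)
        assert fit.mu == pytest.approx(mu)
        assert fit.sigma == pytest.approx(sigma)
        assert fit.degenerate is degenerate
        assert fit.n == len(values)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gaussian_fit([])
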