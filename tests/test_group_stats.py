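import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from oxtmap.atlas_io import ExpressionMatrix
from oxtmap.errors import AnalysisError
from oxtmap.group_stats import (
    bonferroni,
    coexpression_contrast,
    differential_expression,
    fisher_z_compare,
    pearson_matrix,
    rank_sum_test,
    steiger_matrix_test,
)
from oxtmap.spatial_map import SampleClassification


def exact_ranksum_p(a, b):
    """Enumeration oracle: two-sided p = proportion of group-a subsets whose
    rank sum is at least as extreme as observed (no ties assumed)."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    obs = ranks[: len(a)].sum()
    n = len(pooled)
    mean = len(a) * (n + 1) / 2
    count = 0
    total = 0
    for combo in itertools.combinations(range(n), len(a)):
        s = ranks[list(combo)].sum()
        total += 1
        if abs(s - mean) >= abs(obs - mean) - 1e-9:
            count += 1
    return count / total


def _z(values, cols=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    cols = cols or [f"s{i}" for i in range(values.shape[1])]
    rows = [f"g{i}" for i in range(values.shape[0])]
    return ExpressionMatrix(rows, cols, values, "z_scored")


class TestRankSum:
    def test_identical_groups_p_one(self):
        U, p = rank_sum_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_maximal_separation_exact(self):
        U, p = rank_sum_test([4.0, 5.0, 6.0], [1.0, 2.0, 3.0])
        assert U == 9.0  # maximal U for 3 vs 3
        assert p == pytest.approx(2 / 20)  # 2 of C(6,3)=20 assignments as extreme

    def test_empty_group_rejected(self):
        with pytest.raises(AnalysisError):
            rank_sum_test([], [1.0])

    @given(
        st.integers(1, 5),
        st.integers(1, 5),
        st.integers(0, 2**32 - 1),
    )
    def test_exact_branch_matches_enumeration(self, n1, n2, seed):
        rng = np.random.default_rng(seed)
        # distinct values -> no ties, total n <= 10 -> exact branch
        pooled = rng.choice(np.arange(100), size=n1 + n2, replace=False).astype(float)
        a, b = pooled[:n1], pooled[n1:]
        _, p = rank_sum_test(a, b)
        assert p == pytest.approx(exact_ranksum_p(a, b), abs=1e-12)


class TestBonferroni:
    def test_simple_scaling(self):
        np.testing.assert_allclose(bonferroni([0.01], 6), [0.06])

    def test_capped_at_one(self):
        np.testing.assert_allclose(bonferroni([0.5], 6), [1.0])

    def test_matches_scan_oracle(self, rng):
        p = rng.uniform(1e-6, 1, size=40)
        expected = np.array([min(1.0, 50 * x) for x in p])
        np.testing.assert_allclose(bonferroni(p, 50), expected)

    def test_family_smaller_than_tests_rejected(self):
        with pytest.raises(AnalysisError):
            bonferroni([0.1, 0.2, 0.3], 2)


class TestFisherZ:
    def test_equal_correlations_give_zero(self):
        z, p = fisher_z_compare(0.3, 100, 0.3, 57)
        assert z == 0.0
        assert p == pytest.approx(1.0)

    def test_known_example_against_formula_oracle(self):
        z, p = fisher_z_compare(0.5, 103, 0.2, 103)
        expected_z = (math.atanh(0.5) - math.atanh(0.2)) / math.sqrt(2 / 100)
        assert z == pytest.approx(expected_z, abs=1e-12)
        assert z == pytest.approx(2.451, abs=5e-4)
        assert p == pytest.approx(2 * stats.norm.sf(expected_z), abs=1e-12)
        assert p == pytest.approx(0.0143, abs=5e-4)

    def test_antisymmetry(self):
        z1, p1 = fisher_z_compare(0.6, 40, -0.1, 80)
        z2, p2 = fisher_z_compare(-0.1, 80, 0.6, 40)
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)

    def test_one_sample_limit(self):
        """As n2 -> infinity the test reduces to the one-sample comparison of
        r1 against a fixed rho: z -> (atanh(r1) - atanh(rho)) * sqrt(n1 - 3)."""
        r1, n1, rho = 0.42, 120, 0.25
        z, _ = fisher_z_compare(r1, n1, rho, 10**9)
        closed = (math.atanh(r1) - math.atanh(rho)) * math.sqrt(n1 - 3)
        assert z == pytest.approx(closed, abs=1e-6)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(AnalysisError):
            fisher_z_compare(0.5, 3, 0.2, 50)
        with pytest.raises(AnalysisError):
            fisher_z_compare(1.0, 50, 0.2, 50)


class TestSteiger:
    def _random_corr(self, rng, k=4):
        x = rng.normal(size=(200, k))
        return np.corrcoef(x.T)

    def test_identical_matrices(self, rng):
        R = self._random_corr(rng)
        chi2, df, p = steiger_matrix_test(R, 50, R, 80)
        assert chi2 == 0.0
        assert p == pytest.approx(1.0)

    def test_two_gene_example_against_step_oracle(self):
        R1 = np.array([[1.0, 0.5], [0.5, 1.0]])
        R2 = np.eye(2)
        chi2, df, p = steiger_matrix_test(R1, 53, R2, 53)
        expected = math.atanh(0.5) ** 2 / (2 / 50)
        assert df == 1
        assert chi2 == pytest.approx(expected, abs=1e-12)
        assert chi2 == pytest.approx(7.54, abs=5e-3)
        assert p == pytest.approx(stats.chi2.sf(expected, 1), abs=1e-12)

    def test_df_for_six_genes(self, rng):
        R = self._random_corr(rng, k=6)
        _, df, _ = steiger_matrix_test(R, 20, np.eye(6), 20)
        assert df == 15

    def test_symmetric_in_arguments(self, rng):
        R1, R2 = self._random_corr(rng), self._random_corr(rng)
        a = steiger_matrix_test(R1, 40, R2, 90)
        b = steiger_matrix_test(R2, 90, R1, 40)
        assert a == b

    def test_sample_size_scaling_closed_form(self, rng):
        R1, R2 = self._random_corr(rng), self._random_corr(rng)
        n1, n2 = 40, 90
        chi2_a, _, _ = steiger_matrix_test(R1, n1, R2, n2)
        chi2_b, _, _ = steiger_matrix_test(R1, 2 * n1, R2, 2 * n2)
        factor = (1 / (n1 - 3) + 1 / (n2 - 3)) / (1 / (2 * n1 - 3) + 1 / (2 * n2 - 3))
        assert chi2_b == pytest.approx(chi2_a * factor, rel=1e-12)

    def test_perfect_correlation_rejected(self):
        R = np.array([[1.0, 1.0], [1.0, 1.0]])
        with pytest.raises(AnalysisError):
            steiger_matrix_test(R, 50, np.eye(2), 50)


class TestPearsonMatrix:
    def test_duplicated_gene_rows_fully_correlated(self, rng):
        x = rng.normal(size=20)
        expr = _z(np.vstack([x, x, rng.normal(size=20)]))
        R, _ = pearson_matrix(expr, expr.col_ids, expr.row_ids)
        assert R[0, 1] == pytest.approx(1.0)

    def test_matches_covariance_oracle(self, rng):
        data = rng.normal(size=(6, 200))
        expr = _z(data)
        R, pair_p = pearson_matrix(expr, expr.col_ids, expr.row_ids)
        for i in range(6):
            for j in range(6):
                xi = data[i] - data[i].mean()
                xj = data[j] - data[j].mean()
                expected = (xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj))
                assert R[i, j] == pytest.approx(expected, abs=1e-10)
        # spot-check the t-transform p-value
        r = R[0, 1]
        t = r * math.sqrt(198 / (1 - r**2))
        assert pair_p[0, 1] == pytest.approx(2 * stats.t.sf(abs(t), 198), abs=1e-12)

    def test_independent_genes_have_small_correlations(self, rng):
        data = rng.normal(size=(6, 1000))
        R, _ = pearson_matrix(_z(data), [f"s{i}" for i in range(1000)],
                              [f"g{i}" for i in range(6)])
        off = R[np.triu_indices(6, 1)]
        assert np.all(np.abs(off) < 0.11)

    def test_zero_variance_gene_rejected(self):
        expr = _z(np.vstack([np.zeros(10), np.arange(10.0)]))
        with pytest.raises(AnalysisError, match="zero-variance"):
            pearson_matrix(expr, expr.col_ids, expr.row_ids)

    def test_too_few_samples_rejected(self):
        expr = _z(np.random.default_rng(0).normal(size=(2, 3)))
        with pytest.raises(AnalysisError):
            pearson_matrix(expr, expr.col_ids, expr.row_ids)


def _classifications(n_aff, n_unaff, compartment="subcortex"):
    cls = [
        SampleClassification(f"a{i}", compartment, "affected", 0.01, False)
        for i in range(n_aff)
    ]
    cls += [
        SampleClassification(f"u{i}", compartment, "unaffected", 1.0, False)
        for i in range(n_unaff)
    ]
    return cls


class TestDifferentialExpression:
    def test_duplicated_samples_in_both_groups_give_p_one(self, rng):
        data = rng.normal(size=(2, 10))
        doubled = np.hstack([data, data])
        cols = [f"a{i}" for i in range(10)] + [f"u{i}" for i in range(10)]
        expr = _z(doubled, cols=cols)
        res = differential_expression(
            expr, _classifications(10, 10), ["g0", "g1"], "m",
            compartments=("subcortex",),
        )
        for r in res:
            assert r.p_raw == pytest.approx(1.0)
            assert r.mean_diff_z == pytest.approx(0.0, abs=1e-12)

    def test_empty_group_flagged_untestable(self, rng):
        expr = _z(rng.normal(size=(1, 5)), cols=[f"u{i}" for i in range(5)])
        res = differential_expression(
            expr, _classifications(0, 5), ["g0"], "m", compartments=("subcortex",)
        )
        assert len(res) == 1
        assert not res[0].testable
        assert math.isnan(res[0].p_raw)
        assert not res[0].significant

    def test_family_size_recorded_and_applied(self, rng):
        cols = [f"a{i}" for i in range(8)] + [f"u{i}" for i in range(8)]
        data = rng.normal(size=(3, 16))
        res = differential_expression(
            _z(data, cols=cols), _classifications(8, 8), ["g0", "g1", "g2"], "m",
            compartments=("subcortex",),
        )
        for r in res:
            assert r.m_tests == 3
            assert r.p_bonf == pytest.approx(min(1.0, 3 * r.p_raw))

    def test_shift_detected_with_correct_sign(self, rng):
        cols = [f"a{i}" for i in range(60)] + [f"u{i}" for i in range(300)]
        data = rng.normal(size=(1, 360))
        data[0, :60] += 1.0
        res = differential_expression(
            _z(data, cols=cols), _classifications(60, 300), ["g0"], "m",
            compartments=("subcortex",),
        )
        assert res[0].significant
        assert res[0].mean_diff_z > 0.5


class TestCoexpressionContrast:
    def _build(self, rng, r_aff, r_unaff, n1=200, n2=800):
        genes = ["OXTR", "AVPR1A", "OXT"]
        cov_a = np.eye(3)
        cov_a[0, 1] = cov_a[1, 0] = r_aff
        cov_u = np.eye(3)
        cov_u[0, 1] = cov_u[1, 0] = r_unaff
        xa = rng.multivariate_normal(np.zeros(3), cov_a, size=n1).T
        xu = rng.multivariate_normal(np.zeros(3), cov_u, size=n2).T
        cols = [f"a{i}" for i in range(n1)] + [f"u{i}" for i in range(n2)]
        expr = ExpressionMatrix(genes, cols, np.hstack([xa, xu]), "z_scored")
        return expr, _classifications(n1, n2), genes

    def test_identical_groups_no_differences(self, rng):
        data = rng.multivariate_normal(
            np.zeros(3), [[1, 0.5, 0], [0.5, 1, 0], [0, 0, 1]], size=100
        ).T
        cols = [f"a{i}" for i in range(100)] + [f"u{i}" for i in range(100)]
        expr = ExpressionMatrix(
            ["OXTR", "AVPR1A", "OXT"], cols, np.hstack([data, data]), "z_scored"
        )
        comp = coexpression_contrast(
            expr, _classifications(100, 100), ["OXTR", "AVPR1A", "OXT"], "OXTR"
        )
        assert comp.steiger_chi2 == pytest.approx(0.0, abs=1e-20)
        assert comp.steiger_p == pytest.approx(1.0)
        assert all(not f.significant for f in comp.fisher_results)

    def test_planted_contrast_detected(self, rng):
        expr, cls, genes = self._build(rng, r_aff=0.4, r_unaff=0.0)
        comp = coexpression_contrast(expr, cls, genes, "OXTR")
        hit = [f for f in comp.fisher_results if f.gene_b == "AVPR1A"]
        assert len(hit) == 1 and hit[0].significant
        assert hit[0].z > 0

    def test_filter_rule_both_drops_one_sided_pairs(self, rng):
        expr, cls, genes = self._build(rng, r_aff=0.4, r_unaff=0.0)
        either = coexpression_contrast(expr, cls, genes, "OXTR", filter_rule="either")
        both = coexpression_contrast(expr, cls, genes, "OXTR", filter_rule="both")
        assert any(f.gene_b == "AVPR1A" for f in either.fisher_results)
        assert not any(f.gene_b == "AVPR1A" for f in both.fisher_results)

    def test_steiger_gate_suppresses_pairwise_stage(self, rng):
        expr, cls, genes = self._build(rng, r_aff=0.05, r_unaff=0.0)
        comp = coexpression_contrast(expr, cls, genes, "OXTR", gate_on_steiger=True)
        if comp.steiger_p >= 0.05:
            assert comp.gated_out
            assert comp.fisher_results == []

    def test_no_retained_pairs_is_valid_outcome(self, rng):
        expr, cls, genes = self._build(rng, r_aff=0.0, r_unaff=0.0, n1=30, n2=30)
        comp = coexpression_contrast(expr, cls, genes, "OXTR")
        assert comp.m_pairs == len(comp.fisher_results)

    def test_bonferroni_family_is_retained_pair_count(self, rng):
        expr, cls, genes = self._build(rng, r_aff=0.5, r_unaff=0.3)
        comp = coexpression_contrast(expr, cls, genes, "OXTR")
        for f in comp.fisher_results:
            assert f.p_bonf == pytest.approx(min(1.0, comp.m_pairs * f.p_raw))
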