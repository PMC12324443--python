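"""AP-MS enrichment: completeness filter, normalization, imputation, testing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from phixlink.datamodel import QuantMatrix
from phixlink.enrichment import (EnrichmentResult, bh_adjust, call_depleted,
                                 call_enriched, filter_by_completeness,
                                 impute_mixed, normalize, welch_test)
from phixlink.synthetic import simulate_quant_matrix


def _matrix(data, groups, scale="log2"):
    df = pd.DataFrame(data).T
    df.columns = list(groups)
    return QuantMatrix(df, dict(groups), scale)


class TestCompleteness:
    groups = {"a1": "A", "a2": "A", "a3": "A", "b1": "B", "b2": "B", "b3": "B"}

    def test_full_in_one_group_retained(self):
        m = _matrix({"p": [5, 6, 7, np.nan, np.nan, np.nan]}, self.groups)
        assert filter_by_completeness(m, 0.8).proteins == ["p"]

    def test_two_thirds_in_both_groups_removed(self):
        m = _matrix({"p": [5, 6, np.nan, 7, 8, np.nan]}, self.groups)
        assert filter_by_completeness(m, 0.8).proteins == []

    def test_zero_threshold_keeps_everything(self):
        m = _matrix({"p": [np.nan] * 5 + [5.0], "q": [1, 2, 3, 4, 5, 6]},
                    self.groups)
        assert filter_by_completeness(m, 0.0).proteins == ["p", "q"]

    def test_empty_matrix_warns(self):
        m = QuantMatrix(pd.DataFrame(columns=["a1"], dtype=float),
                        {"a1": "A"}, scale="log2")
        with pytest.warns(UserWarning):
            out = filter_by_completeness(m, 0.8)
        assert out.intensities.empty


class TestNormalize:
    def test_scaled_sample_collapses_after_log2_median(self):
        rng = np.random.default_rng(0)
        base = rng.lognormal(17, 1, size=50)
        df = pd.DataFrame({"s1": base, "s2": base * 4})
        qm = QuantMatrix(df, {"s1": "A", "s2": "A"}, scale="raw")
        out = normalize(qm, "log2_median")
        np.testing.assert_allclose(out.intensities["s1"],
                                   out.intensities["s2"], rtol=1e-12)

    def test_centered_log2_matrix_is_unchanged(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(0, 1, size=(51, 3))
        vals -= np.median(vals, axis=0)
        df = pd.DataFrame(vals, columns=["s1", "s2", "s3"])
        qm = QuantMatrix(df, {c: "A" for c in df.columns}, scale="log2")
        out = normalize(qm, "log2_median")
        np.testing.assert_allclose(out.intensities.to_numpy(), vals, atol=1e-12)

    def test_glog_reduces_variance_mean_slope(self):
        # additive + multiplicative noise: raw variance grows with the mean
        rng = np.random.default_rng(2)
        mu = rng.uniform(1e2, 1e6, size=300)
        raw = mu[:, None] * rng.lognormal(0, 0.3, (300, 6)) + \
            rng.normal(0, 50, (300, 6))
        raw = np.abs(raw)
        qm = QuantMatrix(pd.DataFrame(raw, columns=[f"s{i}" for i in range(6)]),
                         {f"s{i}": "A" for i in range(6)}, scale="raw")

        def slope(values):
            m, v = values.mean(axis=1), values.var(axis=1, ddof=1)
            return np.polyfit(np.log10(m - m.min() + 1), np.log10(v + 1e-12), 1)[0]

        out = normalize(qm, "glog")
        assert slope(out.intensities.to_numpy()) < slope(raw)


class TestImputeMixed:
    groups = {"a1": "A", "a2": "A", "a3": "A", "b1": "B", "b2": "B", "b3": "B"}

    def test_mar_cell_gets_group_mean(self):
        m = _matrix({"p": [5.0, 7.0, np.nan, 20, 21, 22],
                     "q": [1, 2, 3, 4, 5, 6],
                     "r": [2, 3, 4, 5, 6, 7]}, self.groups)
        out = impute_mixed(m, seed=0)
        assert out.intensities.loc["p", "a3"] == pytest.approx(6.0)

    def test_fully_observed_matrix_unchanged(self):
        m = _matrix({"p": [1, 2, 3, 4, 5, 6.0]}, self.groups)
        out = impute_mixed(m, seed=0)
        pd.testing.assert_frame_equal(out.intensities, m.intensities)

    def test_mnar_draws_from_downshifted_gaussian(self):
        # group B entirely missing for half the proteins -> MNAR
        rng = np.random.default_rng(3)
        n = 4000
        vals = rng.normal(25, 1.0, size=(n, 6))
        vals[: n // 2, 3:] = np.nan
        df = pd.DataFrame(vals, columns=list(self.groups))
        m = QuantMatrix(df, self.groups, scale="log2")
        out = impute_mixed(m, downshift=1.8, width=0.3, seed=7)
        col = "b1"
        j = list(self.groups).index(col)
        obs = vals[n // 2:, j]
        m_s, s_s = obs.mean(), obs.std(ddof=1)
        draws = out.intensities[col].to_numpy()[: n // 2]
        assert draws.mean() == pytest.approx(m_s - 1.8 * s_s, abs=0.05)
        assert draws.std(ddof=1) == pytest.approx(0.3 * s_s, rel=0.15)

    def test_sample_with_single_observation_errors(self):
        m = _matrix({"p": [5.0, 7.0, 1.0, 20, 21, 22],
                     "q": [np.nan, 2, 3, 4, 5, 6]}, self.groups)
        m.intensities.loc["p", "a1"] = np.nan
        with pytest.raises(ValueError, match="< 2 observed"):
            impute_mixed(m, seed=0)

    def test_reproducible_for_fixed_seed(self):
        m, _ = simulate_quant_matrix(n_proteins=100, n_enriched=5, seed=4,
                                     missing_mar_rate=0.1,
                                     missing_mnar_rate=0.1)
        a = impute_mixed(m, seed=9).intensities
        b = impute_mixed(m, seed=9).intensities
        pd.testing.assert_frame_equal(a, b)


class TestWelch:
    groups = {"a1": "A", "a2": "A", "a3": "A", "b1": "B", "b2": "B", "b3": "B"}

    def test_identical_groups_give_null_result(self):
        m = _matrix({"p": [3, 4, 5, 3, 4, 5.0]}, self.groups)
        r, = welch_test(m, "A", "B")
        assert (r.t_stat, r.p) == (0.0, 1.0) or r.p == pytest.approx(1.0)

    def test_swapping_groups_negates_t(self):
        m = _matrix({"p": [10, 11, 12, 1, 2, 3.0]}, self.groups)
        fwd, = welch_test(m, "A", "B")
        rev, = welch_test(m, "B", "A")
        assert fwd.t_stat == pytest.approx(-rev.t_stat)
        assert fwd.p == pytest.approx(rev.p)
        assert fwd.log2_fc == pytest.approx(-rev.log2_fc)

    def test_matches_textbook_welch_formula(self):
        x, y = np.array([10, 11, 12.0]), np.array([1, 2, 3.0])
        m = _matrix({"p": np.concatenate([x, y])}, self.groups)
        r, = welch_test(m, "A", "B")
        # Welch statistic and Welch-Satterthwaite df, written out explicitly
        se2 = x.var(ddof=1) / 3 + y.var(ddof=1) / 3
        t_expect = (x.mean() - y.mean()) / np.sqrt(se2)
        df = se2 ** 2 / ((x.var(ddof=1) / 3) ** 2 / 2 +
                         (y.var(ddof=1) / 3) ** 2 / 2)
        p_expect = 2 * stats.t.sf(abs(t_expect), df)
        assert r.t_stat == pytest.approx(t_expect, rel=1e-12)
        assert r.p == pytest.approx(p_expect, rel=1e-9)

    def test_degenerate_equal_constant_groups(self):
        m = _matrix({"p": [5, 5, 5, 5, 5, 5.0]}, self.groups)
        r, = welch_test(m, "A", "B")
        assert (r.t_stat, r.p) == (0.0, 1.0)

    def test_type_one_error_controlled_on_null_matrix(self):
        # Welch at n=3/group is conservative by construction (the
        # Satterthwaite df approximation under-rejects at tiny n), so the
        # control property is one-sided: no inflation above nominal.
        matrix, _ = simulate_quant_matrix(n_proteins=2000, n_enriched=0,
                                          missing_mar_rate=0.0,
                                          missing_mnar_rate=0.0, seed=5)
        results = welch_test(matrix, "test", "ctrl")
        frac = np.mean([r.p < 0.05 for r in results])
        half = 2.576 * np.sqrt(0.05 * 0.95 / 2000)
        assert frac <= 0.05 + half

    def test_type_one_rate_exact_at_moderate_replication(self):
        # with n = 10/group the Welch approximation is accurate and the
        # null rejection rate matches nominal within binomial 99% bounds
        matrix, _ = simulate_quant_matrix(n_proteins=2000, n_enriched=0,
                                          n_per_group=10,
                                          missing_mar_rate=0.0,
                                          missing_mnar_rate=0.0, seed=6)
        results = welch_test(matrix, "test", "ctrl")
        frac = np.mean([r.p < 0.05 for r in results])
        half = 2.576 * np.sqrt(0.05 * 0.95 / 2000)
        assert 0.05 - half <= frac <= 0.05 + half


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2] * 3)

    def test_step_up_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04] * 4)

    def test_empty_input(self):
        assert len(bh_adjust([])) == 0

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=40))
    @settings(max_examples=100, deadline=None)
    def test_adjusted_values_monotone_in_sorted_order(self, ps):
        adj = bh_adjust(ps)
        order = np.argsort(ps)
        assert np.all(np.diff(np.asarray(adj)[order]) >= -1e-12)
        assert np.all(np.asarray(adj) >= np.asarray(ps) - 1e-12)
        assert np.all(np.asarray(adj) <= 1.0)


class TestCalls:
    def _res(self, lfc, padj):
        return EnrichmentResult("p", lfc, 0.0, 0.0, p_adj=padj)

    @pytest.mark.parametrize("lfc,padj,expected", [
        (3.0, 0.01, True),
        (3.0, 0.05, False),      # strict p_adj < alpha
        (1.9, 0.001, False),     # below fold-change floor
        (2.0, 0.049, True),      # inclusive log2FC >= 2
    ])
    def test_enrichment_boundaries(self, lfc, padj, expected):
        assert (call_enriched([self._res(lfc, padj)]) == {"p"}) is expected

    def test_depleted_is_symmetric(self):
        assert call_depleted([self._res(-3.0, 0.01)]) == {"p"}
        assert call_depleted([self._res(3.0, 0.01)]) == set()
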