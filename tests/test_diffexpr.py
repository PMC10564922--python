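"""NB Wald differential expression: size factors, fits, status calls."""

import numpy as np
import pandas as pd
import pytest

from cernaforge.diffexpr import (
    DEConfig,
    call_status,
    nb_wald_test,
    prefilter,
    size_factors,
)
from cernaforge.quantify import ExpressionMatrix


def make_em(counts, n_case=None):
    df = pd.DataFrame(np.asarray(counts))
    df.columns = [f"s{i}" for i in range(df.shape[1])]
    df.index = [f"f{i}" for i in range(df.shape[0])]
    n = df.shape[1]
    n_case = n_case if n_case is not None else n // 2
    groups = pd.Series(["case"] * n_case + ["control"] * (n - n_case), index=df.columns)
    return ExpressionMatrix(df, groups, unit="raw_count")


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        counts = pd.DataFrame(np.tile([[10], [55], [3]], (1, 4)))
        assert np.allclose(size_factors(counts), 1.0)

    def test_doubled_column_gets_double_factor(self):
        base = np.array([[10, 10, 10], [40, 40, 40], [7, 7, 7]], dtype=float)
        counts = pd.DataFrame(np.column_stack([base[:, 0] * 2, base[:, 1], base[:, 2]]))
        sf = size_factors(counts)
        # closed form: raw factors (2c, c, c) renormalized to geometric mean 1
        expected = np.array([2.0, 1.0, 1.0]) / 2.0 ** (1 / 3)
        assert np.allclose(sf, expected)
        assert np.exp(np.log(sf).mean()) == pytest.approx(1.0)

    def test_fallback_when_no_all_nonzero_feature(self):
        counts = pd.DataFrame([[0, 10], [10, 0]])
        with pytest.warns(RuntimeWarning, match="library-size"):
            sf = size_factors(counts)
        assert np.allclose(sf, 1.0)  # equal library sizes

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            size_factors(pd.DataFrame(np.zeros((3, 3))))


class TestNbWaldTest:
    def test_constant_feature_has_no_effect(self):
        counts = np.full((3, 8), 30)
        de = nb_wald_test(make_em(counts), DEConfig(prefilter_min_count=1))
        assert np.allclose(de["log2fc"], 0.0)
        assert (de["p_value"] > 0.9).all()
        assert (de["status"] == "NS").all()

    def test_matches_statsmodels_glm_at_fixed_dispersion(self):
        """Independent route: statsmodels NB GLM with the fitted dispersion."""
        import statsmodels.api as sm
        from cernaforge.diffexpr import _fit_feature

        rng = np.random.default_rng(5)
        s = np.exp(rng.normal(0, 0.2, 18))
        s /= np.exp(np.log(s).mean())
        case = np.array([True] * 10 + [False] * 8)
        for mu_case, mu_ctrl in [(40, 40), (120, 30), (15, 60)]:
            mu = np.where(case, mu_case, mu_ctrl) * s
            y = rng.negative_binomial(5, 5 / (5 + mu)).astype(float)
            mine = _fit_feature(y, s, case)
            X = np.column_stack([np.ones(18), case.astype(float)])
            glm = sm.GLM(y, X, offset=np.log(s),
                         family=sm.families.NegativeBinomial(
                             alpha=mine["dispersion"])).fit()
            assert mine["log2fc"] * np.log(2) == pytest.approx(glm.params[1], abs=1e-5)
            assert mine["wald_statistic"] == pytest.approx(
                glm.params[1] / glm.bse[1], rel=1e-4)

    def test_agrees_with_normal_approximation_on_large_counts(self):
        """At high counts the NB Wald z tracks a log-scale t statistic."""
        from scipy import stats

        rng = np.random.default_rng(8)
        n_feat = 150
        mu = np.where(np.arange(20) < 10, 5000, 5000 * rng.choice([1, 2], n_feat)[:, None])
        r = 1 / 0.05
        counts = rng.negative_binomial(r, r / (r + mu), size=(n_feat, 20))
        de = nb_wald_test(make_em(counts), DEConfig(prefilter_min_count=1))
        t_stats = [
            stats.ttest_ind(np.log(row[:10]), np.log(row[10:]), equal_var=False)[0]
            for row in counts
        ]
        corr = np.corrcoef(de["wald_statistic"], t_stats)[0, 1]
        assert corr > 0.95

    def test_sample_order_invariance_of_status_calls(self):
        rng = np.random.default_rng(4)
        counts = rng.negative_binomial(4, 4 / (4 + 60), size=(30, 12))
        counts[:5, :6] *= 5
        em = make_em(counts)
        de1 = nb_wald_test(em, DEConfig(prefilter_min_count=1))
        perm = rng.permutation(12)
        em2 = ExpressionMatrix(em.values.iloc[:, perm], em.groups, unit="raw_count")
        de2 = nb_wald_test(em2, DEConfig(prefilter_min_count=1))
        assert (de1["status"] == de2["status"]).all()

    def test_bh_adjustment_is_monotone_in_raw_p(self, bundle):
        de = nb_wald_test(bundle.mirna_counts, DEConfig.for_class("mirna"))
        de = de.dropna(subset=["p_value"]).sort_values("p_value")
        assert (de["adjusted_p"].diff().dropna() >= -1e-12).all()
        assert (de["adjusted_p"] >= de["p_value"] - 1e-12).all()
        assert (de["adjusted_p"] <= 1.0).all()

    def test_prefilter_uses_mean_count(self):
        counts = pd.DataFrame([[0, 0, 10, 10], [1, 1, 1, 1]])
        kept = prefilter(counts, 2.0)
        assert list(kept.index) == [0]


class TestCallStatus:
    @pytest.mark.parametrize(
        "lfc,p,expected",
        [
            (1.0, 0.01, "Up"),       # FC 2 > 1.5, significant
            (-0.81, 0.02, "Down"),   # FC 0.57 < 1/1.5, significant
            (0.3, 0.001, "NS"),      # fold-change gate fails
            (1.0, 0.2, "NS"),        # p gate fails
            (-0.5, 0.01, "NS"),      # FC 0.71 > 1/1.5
        ],
    )
    def test_methods_rule(self, lfc, p, expected):
        rec = pd.DataFrame({"log2fc": [lfc], "p_value": [p]})
        out = call_status(rec, DEConfig())
        assert out["status"].iloc[0] == expected

    def test_status_sign_invariant(self, bundle):
        de = nb_wald_test(bundle.mirna_counts, DEConfig.for_class("mirna"))
        assert (de.loc[de["status"] == "Up", "log2fc"] > 0).all()
        assert (de.loc[de["status"] == "Down", "log2fc"] < 0).all()

    def test_log2_threshold_variant(self):
        rec = pd.DataFrame({"log2fc": [1.0], "p_value": [0.01]})
        out = call_status(rec, DEConfig(log2_fc_threshold=True))
        assert out["status"].iloc[0] == "NS"  # |log2FC| 1.0 < 1.5
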