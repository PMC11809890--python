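"""Marginal likelihood (Laplace / AGQ), the fitter, ICC, and the ladder."""

import numpy as np
import pandas as pd
import pytest

from bivmlogit.data_model import AnalysisTable, encode_design
from bivmlogit.estimation import (
    agq_marginal_loglik,
    fit,
    icc,
    information_criteria,
    laplace_marginal_loglik,
    model_ladder,
)
from bivmlogit.model import LOGISTIC_RESIDUAL_VARIANCE, ModelLevel, Parameters
from bivmlogit.synthetic import SyntheticConfig, simulate


def _one_cluster_table(n=3, seed=0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "y1": rng.integers(0, 2, n),
        "y2": rng.integers(0, 2, n),
        "cluster": ["c0"] * n,
        "weight": np.ones(n),
    })
    return AnalysisTable(df, ())


def _trapezoid_log_integral(params, design, table, lo=-8.0, hi=8.0, m=10001):
    """Brute-force oracle: dense trapezoid integration of the one-cluster
    conditional likelihood over the random effect."""
    from bivmlogit.model import cluster_conditional_loglik

    us = np.linspace(lo, hi, m)
    ll = np.array([cluster_conditional_loglik(params, design, table, "c0", u)
                   for u in us])
    mx = ll.max()
    integral = np.trapezoid(np.exp(ll - mx), us)
    return mx + np.log(integral)


class TestIcc:
    def test_half_at_logistic_variance(self):
        assert icc(LOGISTIC_RESIDUAL_VARIANCE) == 0.5

    def test_zero(self):
        assert icc(0.0) == 0.0

    def test_null_model_survey_value(self):
        # inverting the formula at ICC 0.42 gives sigma^2 = 2.3824...
        sigma2 = 0.42 / 0.58 * LOGISTIC_RESIDUAL_VARIANCE
        assert sigma2 == pytest.approx(2.3824, abs=5e-4)
        assert icc(sigma2) == pytest.approx(0.42, abs=1e-12)

    def test_monotone_in_sigma2(self):
        s = np.linspace(0, 10, 50)
        vals = [icc(v) for v in s]
        assert np.all(np.diff(vals) > 0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            icc(-0.1)


class TestInformationCriteria:
    def test_aic(self):
        aic, _ = information_criteria(-100.0, 5, 1000, 68)
        assert aic == 210.0

    def test_bic_uses_cluster_count(self):
        _, bic = information_criteria(-100.0, 5, 1000, 68)
        assert bic == pytest.approx(200.0 + 5 * np.log(68), rel=1e-12)

    def test_bic_unit_flag(self):
        _, bic_c = information_criteria(-50.0, 3, 500, 20)
        _, bic_u = information_criteria(-50.0, 3, 500, 20, bic_n="units")
        assert bic_u - bic_c == pytest.approx(3 * np.log(500 / 20))


class TestLaplace:
    def test_sigma_zero_equals_fixed_effect(self, sim_table_small):
        d = encode_design(sim_table_small, ("education",), ("education",))
        p = Parameters(np.array([0.1, 0.2, -0.1, 0.4]),
                       np.array([-0.2, 0.3, 0.1, 0.2]),
                       0.8, "shared", (0.0,))
        from bivmlogit.estimation import _arrays, _fixed_effect_loglik
        y1, y2, w = _arrays(sim_table_small, d, False)
        assert laplace_marginal_loglik(p, d, sim_table_small) == pytest.approx(
            _fixed_effect_loglik(p, d, y1, y2, w), abs=1e-12)

    def test_gaussian_integrand_is_exact(self):
        """A cluster contributing no data (all weights zero) reduces the
        integrand to the Gaussian prior, whose log-integral is exactly 0."""
        t = _one_cluster_table(4)
        zero_w = t.data.copy()
        zero_w["weight"] = 0.0
        t0 = AnalysisTable(zero_w, ())
        d = encode_design(t0, (), ())
        p = Parameters(np.array([0.3]), np.array([-0.2]), 0.7, "shared", (1.7,))
        val = laplace_marginal_loglik(p, d, t0, weighted=True)
        assert val == pytest.approx(0.0, abs=1e-10)

    def test_within_2pct_of_trapezoid_oracle(self):
        t = _one_cluster_table(3, seed=1)
        d = encode_design(t, (), ())
        p = Parameters(np.array([0.3]), np.array([-0.2]),
                       np.log(3.0), "shared", (1.0,))
        lap = laplace_marginal_loglik(p, d, t)
        ref = _trapezoid_log_integral(p, d, t)
        assert abs(lap - ref) / abs(ref) < 0.02

    def test_invariant_to_cluster_relabeling(self, sim_table_small):
        d = encode_design(sim_table_small, (), ())
        p = Parameters(np.array([-0.2]), np.array([0.1]), 1.0, "shared", (1.2,))
        base = laplace_marginal_loglik(p, d, sim_table_small)
        renamed = sim_table_small.data.copy()
        mapping = {c: f"renamed_{i}" for i, c in
                   enumerate(sorted(renamed["cluster"].unique())[::-1])}
        renamed["cluster"] = renamed["cluster"].map(mapping)
        t2 = AnalysisTable(renamed, sim_table_small.schema)
        d2 = encode_design(t2, (), ())
        assert laplace_marginal_loglik(p, d2, t2) == pytest.approx(base, abs=1e-8)

    def test_weights_of_one_match_unweighted(self, sim_table_small):
        d = encode_design(sim_table_small, (), ())
        p = Parameters(np.array([0.0]), np.array([0.0]), 0.5, "shared", (0.9,))
        a = laplace_marginal_loglik(p, d, sim_table_small, weighted=False)
        b = laplace_marginal_loglik(p, d, sim_table_small, weighted=True)
        assert a == pytest.approx(b, abs=1e-10)  # generator weights are 1.0


class TestAgq:
    def test_one_node_equals_laplace(self, sim_table_small):
        d = encode_design(sim_table_small, (), ())
        p = Parameters(np.array([0.2]), np.array([-0.4]), 1.2, "shared", (1.5,))
        lap = laplace_marginal_loglik(p, d, sim_table_small)
        assert agq_marginal_loglik(p, d, sim_table_small, 1) == pytest.approx(
            lap, abs=1e-10)

    def test_node_convergence_on_five_clusters(self):
        cfg = SyntheticConfig(n_clusters=5, cluster_size_mean=8.0)
        t = simulate(cfg, seed=9)
        d = encode_design(t, (), ())
        p = Parameters(np.array([0.1]), np.array([0.0]), 1.0, "shared", (1.4,))
        a15 = agq_marginal_loglik(p, d, t, 15)
        a25 = agq_marginal_loglik(p, d, t, 25)
        assert a15 == pytest.approx(a25, abs=1e-6)

    def test_agq25_matches_trapezoid_oracle(self):
        t = _one_cluster_table(3, seed=1)
        d = encode_design(t, (), ())
        p = Parameters(np.array([0.3]), np.array([-0.2]),
                       np.log(3.0), "shared", (1.0,))
        ref = _trapezoid_log_integral(p, d, t)
        assert agq_marginal_loglik(p, d, t, 25) == pytest.approx(ref, abs=1e-6)

    def test_bivariate_one_node_equals_laplace(self, sim_table_small):
        d = encode_design(sim_table_small, (), ())
        p = Parameters(np.array([0.2]), np.array([-0.4]), 1.2,
                       "independent", (1.1, 0.7))
        lap = laplace_marginal_loglik(p, d, sim_table_small)
        assert agq_marginal_loglik(p, d, sim_table_small, 1) == pytest.approx(
            lap, abs=1e-10)

    def test_rejects_zero_nodes(self, sim_table_small):
        d = encode_design(sim_table_small, (), ())
        p = Parameters(np.array([0.0]), np.array([0.0]), 0.0, "shared", (1.0,))
        with pytest.raises(ValueError):
            agq_marginal_loglik(p, d, sim_table_small, 0)


class TestFit:
    def test_reduction_to_separate_logistic(self):
        """With the association and the zonal effect switched off, the joint
        MLE must reproduce two independent logistic fits (IRLS oracle via
        statsmodels) on the same data."""
        import statsmodels.api as sm

        cfg = SyntheticConfig(n_clusters=5, cluster_size_mean=40.0,
                              true_log_psi=0.0, true_sigma2=0.0)
        t = simulate(cfg, seed=11)
        # education's rare "higher" level quasi-separates at n=200; use the
        # well-populated covariates so both MLEs are interior
        covs = ("wealth", "media", "residence")
        r = fit(ModelLevel("full", covs, covs), t,
                fix_alpha=0.0, fix_sigma=0.0, se=False)
        d = encode_design(t, covs, covs)
        y1 = t.data["y1"].to_numpy()[d.row_index]
        y2 = t.data["y2"].to_numpy()[d.row_index]
        ref1 = sm.Logit(y1, d.X1).fit(disp=0).params
        ref2 = sm.Logit(y2, d.X2).fit(disp=0).params
        np.testing.assert_allclose(r.params.beta1, ref1, atol=1e-4)
        np.testing.assert_allclose(r.params.beta2, ref2, atol=1e-4)

    def test_null_fit_smoke(self):
        """Null model on a 2-cluster, 40-unit fixture converges with a
        valid ICC."""
        cfg = SyntheticConfig(n_clusters=2, cluster_size_mean=20.0)
        t = simulate(cfg, seed=5)
        r = fit(ModelLevel("null"), t, se=False)
        assert r.converged
        assert 0.0 <= r.icc["y1"] < 1.0
        assert np.isfinite(r.loglik)

    def test_single_cluster_rejected(self):
        cfg = SyntheticConfig(n_clusters=1, cluster_size_mean=30.0)
        t = simulate(cfg, seed=5)
        with pytest.raises(ValueError, match="2 clusters"):
            fit(ModelLevel("null"), t)

    def test_aor_table_consistency(self, sim_table_small):
        """exp of the coefficient CI equals the CI of the AOR."""
        r = fit(ModelLevel("individual", ("education",), ("education",)),
                sim_table_small)
        z = 1.959963984540054
        for _, row in r.aor_table.iterrows():
            if np.isfinite(row["se"]):
                assert row["aor"] == pytest.approx(np.exp(row["beta"]), rel=1e-12)
                assert row["ci_low"] == pytest.approx(
                    np.exp(row["beta"] - z * row["se"]), rel=1e-9)
                assert row["ci_high"] == pytest.approx(
                    np.exp(row["beta"] + z * row["se"]), rel=1e-9)

    def test_association_or_is_exp_alpha(self, sim_table_small):
        r = fit(ModelLevel("null"), sim_table_small, se=False)
        assert r.association_or["estimate"] == pytest.approx(
            np.exp(r.params.alpha), rel=1e-12)

    def test_fit_result_json_round_trip(self, sim_table_small, tmp_path):
        r = fit(ModelLevel("null"), sim_table_small, se=False)
        path = tmp_path / "fit.json"
        r.to_json(path)
        import json
        back = json.loads(path.read_text())
        assert back["loglik"] == pytest.approx(r.loglik)
        assert back["icc"]["y1"] == pytest.approx(r.icc["y1"])

    def test_independent_structure_runs(self, sim_table_small):
        r = fit(ModelLevel("null"), sim_table_small,
                re_structure="independent", se=False)
        assert len(r.params.sigma) == 2
        assert r.converged


class TestModelLadder:
    def test_four_rows_finite(self, sim_table_small):
        res = model_ladder(sim_table_small, ("education", "wealth"),
                           ("residence",))
        assert list(res.table["model"]) == ["null", "individual",
                                            "community", "full"]
        assert res.table["aic"].notna().all()
        assert res.table["bic"].notna().all()
        assert res.table["icc"].between(0, 1).all()

    def test_best_flag_matches_min_aic(self, sim_table_small):
        res = model_ladder(sim_table_small, ("education",), ("residence",))
        flagged = res.table.loc[res.table["best_aic"], "model"].iloc[0]
        assert flagged == res.table.loc[res.table["aic"].idxmin(), "model"]
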