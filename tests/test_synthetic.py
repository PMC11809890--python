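"""The survey generator: determinism, stated-world defaults, recovery harness."""

import numpy as np
import pandas as pd
import pytest

from bivmlogit.data_model import validate
from bivmlogit.estimation import fit
from bivmlogit.model import ModelLevel
from bivmlogit.synthetic import (
    SyntheticConfig,
    default_emdhs_like_config,
    recovery_experiment,
    simulate,
)


class TestDefaults:
    def test_default_config_states_the_survey_world(self):
        cfg = default_emdhs_like_config()
        assert cfg.n_clusters == 68
        assert cfg.n_clusters * cfg.cluster_size_mean == pytest.approx(3926, abs=5)
        assert cfg.covariate_marginals["residence"]["rural"] == pytest.approx(
            0.74, abs=0.005)
        assert cfg.covariate_marginals["education"]["no_education"] == pytest.approx(
            0.51, abs=0.005)
        assert cfg.covariate_marginals["media"]["no"] == pytest.approx(
            0.64, abs=0.005)
        assert cfg.true_log_psi == pytest.approx(np.log(6.381))
        assert cfg.true_sigma2 == pytest.approx(2.38)

    def test_region_informative_world(self):
        from bivmlogit.model import LOGISTIC_RESIDUAL_VARIANCE
        from bivmlogit.synthetic import region_informative_config

        cfg = region_informative_config()
        assert sum(cfg.covariate_marginals["region"].values()) == pytest.approx(
            1.0, abs=1e-6)
        # residual zonal variance inverts the adjusted-model ICC of 0.29
        assert cfg.true_sigma2 / (cfg.true_sigma2 + LOGISTIC_RESIDUAL_VARIANCE) \
            == pytest.approx(0.29, abs=1e-12)
        t = simulate(cfg, seed=4)
        per_cluster = t.data.groupby("cluster")["region"].nunique()
        assert (per_cluster == 1).all()

    def test_default_total_units_near_survey(self):
        totals = [simulate(default_emdhs_like_config(), seed=s).n_units
                  for s in range(3)]
        assert np.mean(totals) == pytest.approx(3926, rel=0.05)


class TestSimulate:
    def test_deterministic_given_seed(self):
        cfg = SyntheticConfig(n_clusters=6, cluster_size_mean=12.0)
        a = simulate(cfg, seed=3)
        b = simulate(cfg, seed=3)
        pd.testing.assert_frame_equal(a.data, b.data)
        c = simulate(cfg, seed=4)
        assert not a.data.equals(c.data)

    def test_uniform_world_gives_quarter_cells(self):
        cfg = SyntheticConfig(
            n_clusters=40, cluster_size_mean=100.0,
            true_beta1={"intercept": 0.0}, true_beta2={"intercept": 0.0},
            true_log_psi=0.0, true_sigma2=0.0)
        t = simulate(cfg, seed=8)
        n = t.n_units
        se3 = 3 * np.sqrt(0.25 * 0.75 / n)
        for mask in [
            (t.data.y1 == 1) & (t.data.y2 == 1),
            (t.data.y1 == 1) & (t.data.y2 == 0),
            (t.data.y1 == 0) & (t.data.y2 == 1),
            (t.data.y1 == 0) & (t.data.y2 == 0),
        ]:
            assert mask.mean() == pytest.approx(0.25, abs=se3)

    def test_passes_validation(self):
        rep = validate(simulate(SyntheticConfig(n_clusters=10,
                                                cluster_size_mean=20.0), seed=2))
        assert rep.warnings == []
        assert rep.zero_weight_count == 0

    def test_community_covariate_constant_within_cluster(self):
        t = simulate(SyntheticConfig(n_clusters=15, cluster_size_mean=25.0),
                     seed=6)
        per_cluster = t.data.groupby("cluster")["residence"].nunique()
        assert (per_cluster == 1).all()

    def test_explicit_cluster_sizes(self):
        cfg = SyntheticConfig(n_clusters=3, cluster_sizes=(5, 7, 9))
        t = simulate(cfg, seed=1)
        assert sorted(t.data.groupby("cluster").size()) == [5, 7, 9]

    def test_invalid_marginals_rejected(self):
        cfg = SyntheticConfig(covariate_marginals={"g": {"a": 0.6, "b": 0.6}})
        with pytest.raises(ValueError, match="sum"):
            simulate(cfg, seed=0)

    def test_lognormal_weights(self):
        cfg = SyntheticConfig(n_clusters=10, cluster_size_mean=50.0,
                              weight_rule="lognormal")
        t = simulate(cfg, seed=3)
        w = t.data["weight"]
        assert w.min() > 0
        assert w.nunique() > 1
        assert w.mean() == pytest.approx(1.0, abs=0.1)

    def test_within_cluster_correlation_grows_with_sigma2(self):
        """The between-cluster variance of the cluster outcome mean rises
        with the configured zonal variance (sigma^2 in {0, 1, 4})."""
        def spread(s2):
            vals = []
            for seed in range(10):
                cfg = SyntheticConfig(n_clusters=25, cluster_size_mean=25.0,
                                      true_sigma2=s2)
                t = simulate(cfg, seed=seed)
                vals.append(t.data.groupby("cluster")["y1"].mean().var())
            return np.mean(vals)

        v0, v1, v4 = spread(0.0), spread(1.0), spread(4.0)
        assert v0 < v1 < v4

    def test_crude_or_matches_brute_force_oracle(self):
        """Mean crude OR over 20 generator seeds agrees with a reference
        value from an independent 1e6-unit direct simulation at the same
        parameters (the crude OR exceeds exp(alpha) because the shared
        zonal effect adds marginal association)."""
        cfg = default_emdhs_like_config()
        rng = np.random.default_rng(123)
        N = 1_000_000
        eta1 = np.full(N, cfg.true_beta1["intercept"])
        eta2 = np.full(N, cfg.true_beta2["intercept"])
        for name, probs in cfg.covariate_marginals.items():
            levels = list(probs)
            draw = rng.choice(len(levels), N, p=list(probs.values()))
            for i, lev in enumerate(levels):
                b1 = cfg.true_beta1.get((name, lev), 0.0)
                b2 = cfg.true_beta2.get((name, lev), 0.0)
                if b1:
                    eta1 += b1 * (draw == i)
                if b2:
                    eta2 += b2 * (draw == i)
        u = rng.normal(0, np.sqrt(cfg.true_sigma2), N)
        p1 = 1 / (1 + np.exp(-(eta1 + u)))
        p2 = 1 / (1 + np.exp(-(eta2 + u)))
        psi = np.exp(cfg.true_log_psi)
        # direct quadratic-formula inversion (independent of the package)
        a = 1 + (p1 + p2) * (psi - 1)
        p11 = (a - np.sqrt(a * a - 4 * psi * (psi - 1) * p1 * p2)) / (2 * (psi - 1))
        p10 = p1 - p11
        p01 = p2 - p11
        r = rng.random(N)
        y1 = np.where(r < p11, 1, np.where(r < p11 + p10, 1,
                      np.where(r < p11 + p10 + p01, 0, 0)))
        y2 = np.where(r < p11, 1, np.where(r < p11 + p10, 0,
                      np.where(r < p11 + p10 + p01, 1, 0)))
        n11 = ((y1 == 1) & (y2 == 1)).sum()
        n10 = ((y1 == 1) & (y2 == 0)).sum()
        n01 = ((y1 == 0) & (y2 == 1)).sum()
        n00 = ((y1 == 0) & (y2 == 0)).sum()
        ref_log_or = np.log(n11 * n00 / (n10 * n01))

        log_ors = []
        for seed in range(20):
            t = simulate(cfg, seed=100 + seed)
            d = t.data
            c11 = ((d.y1 == 1) & (d.y2 == 1)).sum()
            c10 = ((d.y1 == 1) & (d.y2 == 0)).sum()
            c01 = ((d.y1 == 0) & (d.y2 == 1)).sum()
            c00 = ((d.y1 == 0) & (d.y2 == 0)).sum()
            log_ors.append(np.log(c11 * c00 / (c10 * c01)))
        mc_se = np.std(log_ors, ddof=1) / np.sqrt(len(log_ors))
        assert np.mean(log_ors) == pytest.approx(ref_log_or, abs=3 * mc_se)


class TestRecoveryExperiment:
    def test_small_run_report_shape(self):
        cfg = SyntheticConfig(n_clusters=10, cluster_size_mean=15.0)
        rep = recovery_experiment(cfg, n_reps=3, base_seed=7)
        # one summary row per free parameter of the full model
        k = 8 + 8 + 2  # two 8-coefficient predictors + alpha + log sigma
        assert len(rep.summary) == k
        assert set(rep.summary.columns) >= {
            "param", "true", "bias", "empirical_se", "coverage"}
        assert rep.estimates["replicate"].nunique() == 3

    def test_rejects_single_rep(self):
        with pytest.raises(ValueError):
            recovery_experiment(default_emdhs_like_config(), n_reps=1)

    def test_sigma_zero_truth_recovered_near_boundary(self):
        """With no true zonal effect the fitted variance collapses:
        sigma^2 < 0.05 in at least 8 of 10 seeds.  The fit must condition
        on the community covariate (as the full model does) because its
        cluster-constant effect is real between-cluster variance that a
        null model would rightly absorb into sigma^2."""
        covs = ("education", "wealth", "media", "residence")
        hits = 0
        for seed in range(10):
            cfg = SyntheticConfig(n_clusters=20, cluster_size_mean=20.0,
                                  true_sigma2=0.0)
            t = simulate(cfg, seed=seed)
            r = fit(ModelLevel("full", covs, covs), t, se=False)
            hits += r.sigma2[0] < 0.05
        assert hits >= 8

    def test_independence_truth_alpha_ci_covers_zero(self):
        """psi = 1, sigma = 0 truth: the Wald CI for the log association
        covers 0 in a clear majority of replicates (binomial bounds on a
        nominal 95% interval at 10 reps)."""
        cfg = SyntheticConfig(n_clusters=15, cluster_size_mean=25.0,
                              true_log_psi=0.0, true_sigma2=0.0)
        rep = recovery_experiment(cfg, n_reps=10, base_seed=21)
        row = rep.summary.loc[rep.summary["param"] == "alpha"].iloc[0]
        assert 0.8 <= row["coverage"] <= 1.0
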