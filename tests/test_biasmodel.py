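"""Hierarchical bias model: diagnostics, recovery, predictive bands."""

import numpy as np
import pandas as pd
import pytest

from bodycomp import (
    AreaBiasModel,
    BiasSimSpec,
    fit_bias_model,
    fit_by_group,
    gelman_rubin,
    simulate_bias_observations,
)
from bodycomp.biasmodel import PosteriorSamples, posterior_predictive_band

FAST = dict(chains=3, draws=500, warmup=250)


class TestGelmanRubin:
    def test_stationary_chains_near_one(self):
        rng = np.random.default_rng(0)
        chains = rng.normal(size=(3, 10_000))
        r = gelman_rubin(chains)
        assert round(r, 2) == 1.0
        assert r < 1.01

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(1)
        chains = rng.normal(size=(2, 500))
        chains[1] += 10.0
        assert gelman_rubin(chains) > 1.1

    def test_hand_formula_on_fixed_values(self):
        # brute-force application of the split formula on printed values
        seg = np.array([0.9, 1.1, 1.0, 1.0, 1.2, 0.8, 1.0, 1.0])
        chains = np.stack([seg, seg])
        segments = np.stack([seg[:4], seg[4:], seg[:4], seg[4:]])
        w = segments.var(axis=1, ddof=1).mean()
        b_over_n = segments.mean(axis=1).var(ddof=1)
        expected = np.sqrt((3 / 4 * w + b_over_n) / w)
        assert gelman_rubin(chains) == pytest.approx(expected, abs=1e-12)

    def test_matches_arviz_reference(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(3)
        chains = rng.normal(size=(3, 400))
        chains[2] += 0.4
        theirs = float(az.rhat(az.convert_to_dataset(chains), method="split")["x"].values)
        assert gelman_rubin(chains) == pytest.approx(theirs, abs=1e-12)

    def test_zero_variance_undefined(self):
        assert np.isnan(gelman_rubin(np.ones((2, 16))))


class TestModelValidation:
    def test_degenerate_zero_variance_rejected(self):
        df = pd.DataFrame({"area_cm2": [1.0, 2.0] * 4, "diff_cm2": 0.0, "model": [1, 1, 2, 2] * 2})
        with pytest.raises(ValueError, match="zero variance"):
            AreaBiasModel.from_dataframe(df)

    def test_single_model_rejected(self):
        df = pd.DataFrame({"area_cm2": [1.0, 2.0], "diff_cm2": [0.1, 0.2], "model": [1, 1]})
        with pytest.raises(ValueError, match="2 models"):
            AreaBiasModel.from_dataframe(df)

    def test_gradient_matches_finite_differences(self):
        obs = simulate_bias_observations(BiasSimSpec(n_slices=8, n_models=4, seed=5))
        model = AreaBiasModel.from_dataframe(obs)
        rng = np.random.default_rng(0)
        theta = rng.normal(0, 0.5, size=model.n_models + 4)
        lp, grad = model.logp_grad(theta)
        eps = 1e-6
        for k in range(theta.size):
            tp, tm = theta.copy(), theta.copy()
            tp[k] += eps
            tm[k] -= eps
            num = (model.logp_grad(tp)[0] - model.logp_grad(tm)[0]) / (2 * eps)
            assert grad[k] == pytest.approx(num, rel=1e-4, abs=1e-5)


class TestFit:
    def test_near_noiseless_posterior_matches_ols(self):
        spec = BiasSimSpec(alpha=-5.0, beta=-0.05, sigma_inter=0.0, sigma_intra=1e-3, seed=2)
        obs = simulate_bias_observations(spec)
        res = fit_bias_model(obs, seed=2, **FAST)
        a = obs.area_cm2.to_numpy()
        X = np.column_stack([np.ones_like(a), a - a.mean()])
        coef, *_ = np.linalg.lstsq(X, obs.diff_cm2.to_numpy(), rcond=None)
        assert res.params["alpha"][0] == pytest.approx(coef[0], rel=0.01)
        assert res.params["beta"][0] == pytest.approx(coef[1], rel=0.01)

    def test_parameter_recovery_credible_intervals(self):
        spec = BiasSimSpec(seed=11)  # alpha=-5, beta=-0.05, s_inter=1.5, s_intra=4
        res = fit_bias_model(simulate_bias_observations(spec), seed=11, **FAST)
        for name, truth in [
            ("alpha", spec.alpha),
            ("beta", spec.beta),
            ("sigma_inter", spec.sigma_inter),
            ("sigma_intra", spec.sigma_intra),
        ]:
            _, lo, hi = res.params[name]
            assert lo <= truth <= hi, name

    def test_vanishing_inter_model_variance_gives_high_icc(self):
        spec = BiasSimSpec(sigma_inter=0.01, sigma_intra=4.0, seed=3)
        res = fit_bias_model(simulate_bias_observations(spec), seed=3, **FAST)
        assert np.median(res.icc_draws()) > 0.9

    def test_converges_on_well_specified_data(self):
        res = fit_bias_model(simulate_bias_observations(BiasSimSpec(seed=4)), seed=4, **FAST)
        assert res.converged
        assert res.max_rhat < 1.1

    def test_summary_contains_all_parameters(self):
        res = fit_bias_model(simulate_bias_observations(BiasSimSpec(seed=5)), seed=5, **FAST)
        names = set(res.summary()["parameter"])
        assert {"alpha", "beta", "sigma_inter", "sigma_intra", "bias_at_mean_area_pct", "icc"} <= names
        mean, lo, hi = res.percent_bias_at_mean_area
        assert lo <= mean <= hi


def constant_posterior(alpha=-5.0, beta=-0.05, s1=0.0, s2=0.0, a_mean=125.0, n=200):
    shape = (2, n)
    return PosteriorSamples(
        alpha=np.full(shape, alpha),
        beta=np.full(shape, beta),
        u=np.zeros(shape + (3,)),
        sigma_inter=np.full(shape, s1),
        sigma_intra=np.full(shape, s2),
        a_mean=a_mean,
        accept_rate=1.0,
        n_divergent=0,
    )


class TestPredictiveBand:
    def test_zero_variance_posterior_collapses_to_line(self):
        samples = constant_posterior()
        grid = np.linspace(50, 200, 7)
        band = posterior_predictive_band(samples, grid)
        line = -5.0 - 0.05 * (grid - 125.0)
        np.testing.assert_allclose(band["lower"], line, atol=1e-9)
        np.testing.assert_allclose(band["upper"], line, atol=1e-9)

    def test_band_width_monotone_in_intra_sd(self):
        grid = np.linspace(50, 200, 5)
        narrow = posterior_predictive_band(constant_posterior(s2=2.0), grid, seed=0)
        wide = posterior_predictive_band(constant_posterior(s2=4.0), grid, seed=0)
        assert ((wide["upper"] - wide["lower"]) >= (narrow["upper"] - narrow["lower"]) - 1e-9).all()

    def test_band_contains_fitted_line(self):
        res = fit_bias_model(simulate_bias_observations(BiasSimSpec(seed=6)), seed=6, **FAST)
        grid = np.linspace(50, 200, 9)
        band = res.predictive_band(grid)
        line = res.fitted_line(grid)
        assert (band["lower"].to_numpy() <= line).all()
        assert (band["upper"].to_numpy() >= line).all()


class TestGroupFits:
    def test_groups_with_distinct_bias_ordered(self):
        hits = 0
        n_seeds = 6
        for seed in range(n_seeds):
            cnn = simulate_bias_observations(
                BiasSimSpec(alpha=-4.4, n_models=15, sigma_intra=2.0, seed=seed)
            ).assign(arch="cnn")
            trf = simulate_bias_observations(
                BiasSimSpec(alpha=-5.3, n_models=15, sigma_intra=2.0, seed=seed + 100)
            ).assign(arch="transformer")
            fits = fit_by_group(
                pd.concat([cnn, trf]), "arch", seed=seed, chains=2, draws=300, warmup=200
            )
            hits += fits["cnn"].params["alpha"][0] > fits["transformer"].params["alpha"][0]
        assert hits >= n_seeds - 1

    def test_single_group_consistent_with_direct_fit(self):
        obs = simulate_bias_observations(BiasSimSpec(seed=7)).assign(arch="cnn")
        grouped = fit_by_group(obs, "arch", seed=7, **FAST)["cnn"]
        direct = fit_bias_model(obs, seed=7, **FAST)
        assert grouped.params["alpha"][0] == pytest.approx(direct.params["alpha"][0], abs=0.5)
        assert grouped.params["beta"][0] == pytest.approx(direct.params["beta"][0], abs=0.01)
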