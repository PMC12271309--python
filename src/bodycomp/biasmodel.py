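"""Hierarchical Bayesian model of segmentation-area bias across models.

For slice ``n`` with consensus (ground-truth) area ``a_n`` and segmentation
model ``m`` predicting area ``A_nm``, the observed difference
``delta_nm = A_nm - a_n`` is modelled as

    delta_nm = alpha + beta * (a_n - a_bar) + u_m + eps_nm
    u_m   ~ Normal(0, sigma_inter^2)     (between-model effect)
    eps_nm ~ Normal(0, sigma_intra^2)    (within-model, slice-level noise)

The covariate is centred at the mean area ``a_bar`` so that ``alpha`` is the
bias at the mean area (also reported as a percentage, ``100 * alpha /
a_bar``).  ``beta`` captures the tendency of larger regions to be more
biased.  The intraclass correlation ``ICC = sigma_intra^2 / (sigma_intra^2 +
sigma_inter^2)`` is near 1 when models behave like one another (inter-model
spread small relative to slice-level noise).

Inference is Hamiltonian Monte Carlo (:mod:`bodycomp.hmc`) on the
unconstrained parameter vector ``(alpha, beta, z_1..z_M, log sigma_inter,
log sigma_intra)`` with the non-centered parameterisation ``u_m =
sigma_inter * z_m``.  Priors are weakly informative and scale-adaptive:
``alpha, beta ~ Normal(0, 10 sd(delta))`` and half-Normal(5 sd(delta)) on
both SDs.  Convergence is judged by the split Gelman-Rubin statistic with
the conventional bar ``rhat < 1.1``.

The public surface follows the statsmodels idiom: build an
:class:`AreaBiasModel` from data, call :meth:`~AreaBiasModel.fit`, inspect
the returned :class:`AreaBiasResults` (``summary()``, credible intervals,
``predictive_band``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hmc import HMCTrace, sample_chain

DEFAULT_CHAINS = 3
DEFAULT_DRAWS = 1500
DEFAULT_WARMUP = 500
RHAT_BAR = 1.1


def gelman_rubin(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction factor (split-R-hat).

    *chains* has shape ``(n_chains, n_draws)`` for one scalar parameter.
    Each chain is split in half (requiring at least 2 chains, hence >= 4
    segments of >= 4 draws); with ``W`` the mean within-segment variance and
    ``B/n`` the variance of segment means,

        rhat = sqrt( ((n-1)/n * W + B/n) / W ).

    Returns NaN when the within-segment variance is zero (undefined).
    """
    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need (n_chains >= 2, n_draws) samples")
    n = arr.shape[1] // 2
    if n < 4:
        raise ValueError("need at least 4 draws per split segment")
    segments = np.concatenate([arr[:, :n], arr[:, n : 2 * n]], axis=0)
    w = segments.var(axis=1, ddof=1).mean()
    if w == 0:
        return float("nan")
    b_over_n = segments.mean(axis=1).var(ddof=1)
    var_plus = (n - 1) / n * w + b_over_n
    return float(np.sqrt(var_plus / w))


@dataclass
class PosteriorSamples:
    """Per-chain HMC draws of the bias-model parameters.

    Arrays are shaped ``(chains, draws)`` (``u``: ``(chains, draws, M)``).
    """

    alpha: np.ndarray
    beta: np.ndarray
    u: np.ndarray
    sigma_inter: np.ndarray
    sigma_intra: np.ndarray
    a_mean: float
    accept_rate: float
    n_divergent: int

    @property
    def n_chains(self) -> int:
        return self.alpha.shape[0]

    @property
    def n_draws(self) -> int:
        return self.alpha.shape[1]

    def flat(self, name: str) -> np.ndarray:
        return getattr(self, name).reshape(-1)

    def rhat(self) -> dict[str, float]:
        """Split-R-hat for every scalar parameter (u_m individually)."""
        out = {
            "alpha": gelman_rubin(self.alpha),
            "beta": gelman_rubin(self.beta),
            "sigma_inter": gelman_rubin(self.sigma_inter),
            "sigma_intra": gelman_rubin(self.sigma_intra),
        }
        for m in range(self.u.shape[2]):
            out[f"u[{m + 1}]"] = gelman_rubin(self.u[:, :, m])
        return out


class AreaBiasModel:
    """Hierarchical linear model of per-slice area differences.

    Parameters
    ----------
    area
        Consensus area ``a_n`` per observation (cm^2), strictly positive.
    diff
        Observed difference ``delta_nm`` per observation (cm^2).
    model_index
        0-based segmentation-model index per observation.
    """

    def __init__(self, area: np.ndarray, diff: np.ndarray, model_index: np.ndarray):
        self.area = np.asarray(area, dtype=float)
        self.diff = np.asarray(diff, dtype=float)
        self.model_index = np.asarray(model_index, dtype=int)
        if not (self.area.shape == self.diff.shape == self.model_index.shape):
            raise ValueError("area, diff and model_index must be aligned 1D arrays")
        if np.any(self.area <= 0):
            raise ValueError("consensus areas must be strictly positive")
        if np.unique(self.model_index).size < 2:
            raise ValueError("need observations from at least 2 models")
        if np.std(self.diff) == 0:
            raise ValueError("degenerate data: differences have zero variance")
        self.n_models = int(self.model_index.max()) + 1
        self.a_mean = float(self.area.mean())
        self.x = self.area - self.a_mean
        sd = float(np.std(self.diff))
        self.prior_sd_coef = 10.0 * sd
        self.prior_scale_sigma = 5.0 * sd

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        area_col: str = "area_cm2",
        diff_col: str = "diff_cm2",
        model_col: str = "model",
    ) -> "AreaBiasModel":
        """Build from a long table with one row per (slice, model) observation."""
        models = pd.Categorical(df[model_col])
        return cls(
            df[area_col].to_numpy(float),
            df[diff_col].to_numpy(float),
            models.codes.astype(int),
        )

    # -- log posterior ------------------------------------------------------

    def _unpack(self, theta: np.ndarray):
        M = self.n_models
        return theta[0], theta[1], theta[2 : 2 + M], theta[2 + M], theta[3 + M]

    def logp_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        """Log posterior (up to a constant) and its gradient."""
        alpha, beta, z, ls1, ls2 = self._unpack(theta)
        # reject absurd log-SDs before exp() can overflow (step-size search
        # probes very large steps)
        if not np.all(np.isfinite(theta)) or abs(ls1) > 40 or abs(ls2) > 40:
            return -np.inf, np.zeros_like(theta)
        s1 = np.exp(ls1)
        s2 = np.exp(ls2)
        m = self.model_index
        resid = self.diff - (alpha + beta * self.x + s1 * z[m])
        inv_v = 1.0 / (s2 * s2)
        n_obs = resid.size

        logp = (
            -0.5 * inv_v * np.dot(resid, resid)
            - n_obs * ls2
            - 0.5 * np.dot(z, z)
            - 0.5 * (alpha**2 + beta**2) / self.prior_sd_coef**2
            - 0.5 * (s1 / self.prior_scale_sigma) ** 2 + ls1
            - 0.5 * (s2 / self.prior_scale_sigma) ** 2 + ls2
        )

        r = inv_v * resid
        g_alpha = r.sum() - alpha / self.prior_sd_coef**2
        g_beta = np.dot(r, self.x) - beta / self.prior_sd_coef**2
        g_z = s1 * np.bincount(m, weights=r, minlength=self.n_models) - z
        g_ls1 = s1 * np.dot(r, z[m]) - (s1 / self.prior_scale_sigma) ** 2 + 1.0
        g_ls2 = inv_v * np.dot(resid, resid) - n_obs - (s2 / self.prior_scale_sigma) ** 2 + 1.0
        grad = np.concatenate([[g_alpha, g_beta], g_z, [g_ls1, g_ls2]])
        return float(logp), grad

    def _initial_point(self, rng: np.random.Generator) -> np.ndarray:
        X = np.column_stack([np.ones_like(self.x), self.x])
        coef, *_ = np.linalg.lstsq(X, self.diff, rcond=None)
        resid_sd = max(float(np.std(self.diff - X @ coef)), 1e-3)
        theta = np.concatenate(
            [
                coef + rng.normal(0, 0.1 * resid_sd, size=2),
                rng.normal(0, 0.1, size=self.n_models),
                [np.log(0.5 * resid_sd), np.log(resid_sd)] + rng.normal(0, 0.1, size=2),
            ]
        )
        return theta

    # -- fitting ------------------------------------------------------------

    def fit(
        self,
        chains: int = DEFAULT_CHAINS,
        draws: int = DEFAULT_DRAWS,
        warmup: int = DEFAULT_WARMUP,
        seed: int | np.random.SeedSequence | None = 0,
        target_accept: float = 0.9,
    ) -> "AreaBiasResults":
        """Sample the posterior by HMC and summarise it.

        Defaults follow the standard reporting configuration: 3 chains of
        1500 retained draws each after 500 warmup iterations, no thinning.
        Non-convergence (max split-R-hat >= 1.1) flags the result, it does
        not raise.
        """
        ss = (
            seed
            if isinstance(seed, np.random.SeedSequence)
            else np.random.SeedSequence(seed)
        )
        traces: list[HMCTrace] = []
        for child in ss.spawn(chains):
            rng = np.random.default_rng(child)
            x0 = self._initial_point(rng)
            traces.append(
                sample_chain(
                    self.logp_grad,
                    x0,
                    n_draws=draws,
                    n_warmup=warmup,
                    rng=rng,
                    target_accept=target_accept,
                )
            )
        M = self.n_models
        stacked = np.stack([t.draws for t in traces])  # (C, N, dim)
        s1 = np.exp(stacked[:, :, 2 + M])
        posterior = PosteriorSamples(
            alpha=stacked[:, :, 0],
            beta=stacked[:, :, 1],
            u=s1[:, :, None] * stacked[:, :, 2 : 2 + M],
            sigma_inter=s1,
            sigma_intra=np.exp(stacked[:, :, 3 + M]),
            a_mean=self.a_mean,
            accept_rate=float(np.mean([t.accept_rate for t in traces])),
            n_divergent=int(sum(t.n_divergent for t in traces)),
        )
        return AreaBiasResults(self, posterior)


@dataclass
class AreaBiasResults:
    """Posterior summary of a fitted :class:`AreaBiasModel`."""

    model: AreaBiasModel
    posterior: PosteriorSamples

    def __post_init__(self) -> None:
        self.rhat = self.posterior.rhat()
        self.max_rhat = float(np.nanmax(list(self.rhat.values())))
        self.converged = bool(self.max_rhat < RHAT_BAR)

    # -- scalar summaries ---------------------------------------------------

    def _ci(self, draws: np.ndarray) -> tuple[float, float, float]:
        flat = draws.reshape(-1)
        return (
            float(np.mean(flat)),
            float(np.percentile(flat, 2.5)),
            float(np.percentile(flat, 97.5)),
        )

    @property
    def params(self) -> dict[str, tuple[float, float, float]]:
        """(mean, 2.5%, 97.5%) for alpha, beta, sigma_inter, sigma_intra."""
        p = self.posterior
        return {
            "alpha": self._ci(p.alpha),
            "beta": self._ci(p.beta),
            "sigma_inter": self._ci(p.sigma_inter),
            "sigma_intra": self._ci(p.sigma_intra),
        }

    @property
    def percent_bias_at_mean_area(self) -> tuple[float, float, float]:
        """Bias at the mean consensus area as a percentage of that area."""
        return self._ci(100.0 * self.posterior.alpha / self.posterior.a_mean)

    @property
    def icc(self) -> tuple[float, float, float]:
        """Posterior ICC = sigma_intra^2 / (sigma_intra^2 + sigma_inter^2)."""
        v_in = self.posterior.sigma_intra**2
        v_btw = self.posterior.sigma_inter**2
        return self._ci(v_in / (v_in + v_btw))

    def icc_draws(self) -> np.ndarray:
        v_in = self.posterior.flat("sigma_intra") ** 2
        v_btw = self.posterior.flat("sigma_inter") ** 2
        return v_in / (v_in + v_btw)

    def summary(self) -> pd.DataFrame:
        """Posterior means, 95% credible intervals and split-R-hat."""
        rows = []
        for name, (mean, lo, hi) in self.params.items():
            rows.append(
                {"parameter": name, "mean": mean, "ci2.5": lo, "ci97.5": hi, "rhat": self.rhat[name]}
            )
        pb = self.percent_bias_at_mean_area
        rows.append(
            {"parameter": "bias_at_mean_area_pct", "mean": pb[0], "ci2.5": pb[1], "ci97.5": pb[2], "rhat": float("nan")}
        )
        icc = self.icc
        rows.append(
            {"parameter": "icc", "mean": icc[0], "ci2.5": icc[1], "ci97.5": icc[2], "rhat": float("nan")}
        )
        rows.append(
            {
                "parameter": "max_rhat",
                "mean": self.max_rhat,
                "ci2.5": float("nan"),
                "ci97.5": float("nan"),
                "rhat": self.max_rhat,
            }
        )
        return pd.DataFrame(rows)

    def predictive_band(
        self, a_grid: np.ndarray, seed: int | None = 0
    ) -> pd.DataFrame:
        """95% posterior predictive interval for a new difference at each area.

        For every posterior draw a new model effect ``u*`` and residual
        ``eps*`` are redrawn, so the band reflects parameter uncertainty plus
        both variance components; it always contains the fitted line.
        """
        return posterior_predictive_band(self.posterior, a_grid, seed=seed)

    def fitted_line(self, a_grid: np.ndarray) -> np.ndarray:
        a_grid = np.asarray(a_grid, dtype=float)
        alpha = float(np.mean(self.posterior.flat("alpha")))
        beta = float(np.mean(self.posterior.flat("beta")))
        return alpha + beta * (a_grid - self.posterior.a_mean)


def posterior_predictive_band(
    samples: PosteriorSamples, a_grid: np.ndarray, seed: int | None = 0
) -> pd.DataFrame:
    """Per-area 2.5/97.5% quantiles of the posterior predictive difference."""
    rng = np.random.default_rng(seed)
    a_grid = np.asarray(a_grid, dtype=float)
    alpha = samples.flat("alpha")
    beta = samples.flat("beta")
    s1 = samples.flat("sigma_inter")
    s2 = samples.flat("sigma_intra")
    n = alpha.size
    u_star = rng.standard_normal(n) * s1
    eps_star = rng.standard_normal(n) * s2
    mu = alpha[None, :] + beta[None, :] * (a_grid[:, None] - samples.a_mean)
    pred = mu + (u_star + eps_star)[None, :]
    lo = np.percentile(pred, 2.5, axis=1)
    hi = np.percentile(pred, 97.5, axis=1)
    return pd.DataFrame({"area_cm2": a_grid, "lower": lo, "upper": hi})


def fit_bias_model(
    obs: pd.DataFrame,
    chains: int = DEFAULT_CHAINS,
    draws: int = DEFAULT_DRAWS,
    warmup: int = DEFAULT_WARMUP,
    seed: int | None = 0,
    **from_df_kwargs,
) -> AreaBiasResults:
    """Convenience wrapper: build :class:`AreaBiasModel` from a table and fit."""
    model = AreaBiasModel.from_dataframe(obs, **from_df_kwargs)
    return model.fit(chains=chains, draws=draws, warmup=warmup, seed=seed)


def fit_by_group(
    obs: pd.DataFrame,
    group_col: str,
    chains: int = DEFAULT_CHAINS,
    draws: int = DEFAULT_DRAWS,
    warmup: int = DEFAULT_WARMUP,
    seed: int | None = 0,
    **from_df_kwargs,
) -> dict[str, AreaBiasResults]:
    """Independent fits per model group (e.g. CNN vs transformer); no pooling."""
    out: dict[str, AreaBiasResults] = {}
    ss = np.random.SeedSequence(seed)
    for child, (group, sub) in zip(ss.spawn(obs[group_col].nunique()), obs.groupby(group_col)):
        model = AreaBiasModel.from_dataframe(sub, **from_df_kwargs)
        out[str(group)] = model.fit(chains=chains, draws=draws, warmup=warmup, seed=child)
    return out
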