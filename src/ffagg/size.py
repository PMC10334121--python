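"""Lognormal aggregation-size model with a second proper-CAR field.

The logged surface area of aggregation a is Gaussian,

    log s_a ~ N(mu_a, sigma^2),
    mu_a = intercept + u2_k(a) + sum_l betaSize_l x_al,

with u2 a zero-centred proper CAR field over the coarse blocks and the same
covariate suite as the abundance model, evaluated at the aggregation's cell
and date.  There is no season term and no effort offset: sizes are
per-detected-aggregation quantities.  A single homoscedastic sigma is used
(no heteroscedasticity structure is specified by the model).

Conjugacy makes the sampler almost pure Gibbs: the regression block, the
CAR field, the residual precision and tau_CAR all have closed-form full
conditionals; only the spatial-dependence parameter gamma needs a
Metropolis step.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .car import car_structure
from .mcmc import (
    PosteriorSamples,
    ScalarAdaptive,
    graph_colors,
    spawn_rngs,
    summarize_effects,
)

RESERVED_COLUMNS = (
    "aggregation_id",
    "cell_id",
    "survey_id",
    "block",
    "area_m2",
    "log_area",
    "season",
    "effort_km2",
    "count",
)

DEFAULT_PRIORS = {
    "sd_beta": 10.0,
    "sigma_shape": 1.0,  # Gamma prior on the residual precision 1/sigma^2
    "sigma_rate": 0.01,
    "tau_shape": 1.0,
    "tau_rate": 0.01,
    "gamma_eps": 1e-3,
}


class LognormalSizeModel(BaseEstimator):
    """Bayesian lognormal model of aggregation surface area (m^2).

    Same interface conventions as :class:`ZINBAbundanceModel`; the fitting
    table needs the covariate columns plus ``block`` and either ``log_area``
    or ``area_m2`` (strictly positive).  ``back_transform`` controls the
    reporting scale: "median" (exp(mu), default) or "mean"
    (exp(mu + sigma^2/2)).
    """

    def __init__(
        self,
        covariates=None,
        n_chains=3,
        n_iter=20000,
        burnin_frac=0.5,
        thin=4,
        priors=None,
        gamma_support="nonneg",
        standardize=True,
        back_transform="median",
        random_state=0,
    ):
        self.covariates = covariates
        self.n_chains = n_chains
        self.n_iter = n_iter
        self.burnin_frac = burnin_frac
        self.thin = thin
        self.priors = priors
        self.gamma_support = gamma_support
        self.standardize = standardize
        self.back_transform = back_transform
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y=None, adjacency: dict | None = None):
        """Sample the posterior given the per-aggregation table.

        ``y`` may be log areas; if omitted, taken from ``log_area`` or
        ``log(area_m2)`` in ``X``.
        """
        if self.n_chains < 2:
            raise ValueError("need at least 2 chains for convergence checks")
        if y is None:
            if "log_area" in X.columns:
                y = X["log_area"].to_numpy(dtype=float)
            elif "area_m2" in X.columns:
                area = X["area_m2"].to_numpy(dtype=float)
                if np.any(area <= 0):
                    raise ValueError("area_m2 must be strictly positive")
                y = np.log(area)
            else:
                raise ValueError("pass y or include log_area / area_m2")
        y = np.asarray(y, dtype=float)
        if np.any(~np.isfinite(y)):
            raise ValueError("log sizes must be finite")

        covs = self._resolve_covariates(X)
        raw = X[covs].to_numpy(dtype=float)
        if self.standardize:
            self.x_mean_ = raw.mean(axis=0)
            self.x_sd_ = raw.std(axis=0, ddof=1)
            if np.any(self.x_sd_ == 0):
                raise ValueError("constant covariate column(s)")
            Xc = (raw - self.x_mean_) / self.x_sd_
        else:
            self.x_mean_ = np.zeros(raw.shape[1])
            self.x_sd_ = np.ones(raw.shape[1])
            Xc = raw
        block = X["block"].to_numpy(dtype=int)
        if adjacency is None:
            adjacency = {k: [] for k in range(int(block.max()) + 1)}
        structure = car_structure(adjacency)
        if block.min() < 0 or block.max() >= structure.n_blocks:
            raise ValueError("block indices out of range for the adjacency")

        from .abundance import _gamma_range

        self.priors_ = dict(DEFAULT_PRIORS, **(self.priors or {}))
        self.gamma_range_ = _gamma_range(
            structure, self.priors_["gamma_eps"], self.gamma_support
        )
        colors = graph_colors(structure.neighbors)
        # per-block row lists and sufficient statistics
        n_k = np.bincount(block, minlength=structure.n_blocks).astype(float)

        n_keep = (self.n_iter - int(self.n_iter * self.burnin_frac)) // self.thin
        if n_keep < 1:
            raise ValueError("MCMC protocol retains no draws")
        chains = [
            self._run_chain(y, Xc, block, n_k, structure, colors, rng)
            for rng in spawn_rngs(self.random_state, self.n_chains)
        ]
        names = (
            ["intercept", "sigma", "tau_car", "gamma"]
            + [f"beta[{c}]" for c in covs]
            + [f"u[{k}]" for k in range(structure.n_blocks)]
        )
        self.samples_ = PosteriorSamples(
            np.stack(chains),
            names,
            meta={
                "model": "size",
                "n_iter": self.n_iter,
                "burnin": int(self.n_iter * self.burnin_frac),
                "thin": self.thin,
                "seed": self.random_state,
                "covariates": covs,
            },
        )
        self.covariates_ = covs
        self.car_structure_ = structure
        self.n_blocks_ = structure.n_blocks
        self.coef_summary_ = summarize_effects(
            self.samples_,
            ["intercept", "sigma", "tau_car", "gamma"] + [f"beta[{c}]" for c in covs],
        )
        return self

    def _resolve_covariates(self, X):
        if self.covariates is not None:
            covs = list(self.covariates)
        else:
            covs = [c for c in X.columns if c not in RESERVED_COLUMNS]
        if "block" not in X.columns:
            raise ValueError("fitting table lacks the 'block' column")
        absent = [c for c in covs if c not in X.columns]
        if absent:
            raise ValueError(f"covariate column(s) not in table: {absent}")
        return covs

    def _run_chain(self, y, Xc, block, n_k, structure, colors, rng):
        pr = self.priors_
        n, p = Xc.shape
        burn = int(self.n_iter * self.burnin_frac)
        n_keep = (self.n_iter - burn) // self.thin
        out = np.empty((n_keep, 4 + p + structure.n_blocks))

        # design with explicit intercept column for the joint Gibbs block
        D = np.column_stack([np.ones(n), Xc])
        DtD = D.T @ D
        prior_prec = np.eye(p + 1) / pr["sd_beta"] ** 2

        coef = np.zeros(p + 1)
        coef[0] = y.mean()
        u = np.zeros(structure.n_blocks)
        tau_lik = 1.0 / max(y.var(), 1e-6)  # residual precision 1/sigma^2
        tau_car = 1.0
        gamma = 0.5 * (self.gamma_range_[0] + self.gamma_range_[1])
        gam_blk = ScalarAdaptive(init_scale=0.1)

        kept = 0
        for it in range(self.n_iter):
            # --- regression block | u, sigma : conjugate Gaussian
            resid_target = y - u[block]
            prec = tau_lik * DtD + prior_prec
            L = np.linalg.cholesky(prec)
            mean = np.linalg.solve(prec, tau_lik * (D.T @ resid_target))
            coef = mean + np.linalg.solve(L.T, rng.standard_normal(p + 1))

            # --- CAR field | rest : Gaussian full conditionals by colour
            fitted = D @ coef
            r_blocksum = np.bincount(
                block, weights=y - fitted, minlength=structure.n_blocks
            )
            for blocks in colors:
                Wu = structure.W @ u
                prec_k = tau_lik * n_k[blocks] + tau_car * structure.d_eff[blocks]
                mean_k = (
                    tau_lik * r_blocksum[blocks] + tau_car * gamma * Wu[blocks]
                ) / prec_k
                u[blocks] = mean_k + rng.standard_normal(blocks.size) / np.sqrt(prec_k)

            # --- likelihood-invariant recentering (intercept vs field mean):
            # Gibbs draw of the shift along the confounded direction
            q_ones = structure.d_eff - gamma * structure.m
            prec_d = 1.0 / pr["sd_beta"] ** 2 + tau_car * float(q_ones.sum())
            lin_d = -coef[0] / pr["sd_beta"] ** 2 + tau_car * float(q_ones @ u)
            delta = lin_d / prec_d + rng.standard_normal() / np.sqrt(prec_d)
            coef[0] += delta
            u -= delta
            fitted = fitted + delta

            # --- residual precision | rest : conjugate Gamma
            resid = y - fitted - u[block]
            tau_lik = rng.gamma(
                pr["sigma_shape"] + 0.5 * n,
                1.0 / (pr["sigma_rate"] + 0.5 * np.sum(resid**2)),
            )

            # --- tau_CAR | u, gamma : conjugate Gamma
            quad_d, quad_w = structure.quad_form(u, 0.0)
            tau_car = rng.gamma(
                pr["tau_shape"] + 0.5 * structure.n_blocks,
                1.0 / (pr["tau_rate"] + 0.5 * max(quad_d - gamma * quad_w, 1e-12)),
            )

            # --- gamma : random-walk MH on the CAR prior of u
            prop_g = gam_blk.propose_scalar(gamma, rng)
            if self.gamma_range_[0] <= prop_g <= self.gamma_range_[1]:
                d_logdet = 0.5 * (
                    np.log1p(-prop_g * structure.eigs).sum()
                    - np.log1p(-gamma * structure.eigs).sum()
                )
                acc = np.log(rng.random()) < d_logdet + 0.5 * tau_car * (
                    prop_g - gamma
                ) * quad_w
                if acc:
                    gamma = prop_g
            else:
                acc = False
            gam_blk.adapt_scalar(float(acc))

            if it >= burn and (it - burn) % self.thin == 0 and kept < n_keep:
                out[kept, 0] = coef[0]
                out[kept, 1] = 1.0 / np.sqrt(tau_lik)
                out[kept, 2] = tau_car
                out[kept, 3] = gamma
                out[kept, 4 : 4 + p] = coef[1:]
                out[kept, 4 + p :] = u
                kept += 1
        return out

    # ------------------------------------------------------------- predict

    def _check_fitted(self):
        if not hasattr(self, "samples_"):
            raise RuntimeError("model is not fitted")

    def mu_draws(self, X: pd.DataFrame, max_draws: int | None = None) -> np.ndarray:
        """Posterior draws of the log-scale mean mu, shape (n_draws, n_rows)."""
        self._check_fitted()
        s = self.samples_ if max_draws is None else self.samples_.thin_to(
            max(1, max_draws // self.n_chains)
        )
        Xc = (X[self.covariates_].to_numpy(dtype=float) - self.x_mean_) / self.x_sd_
        if "block" in X.columns:
            b = X["block"].to_numpy(dtype=int)
            b = np.where((b >= 0) & (b < self.n_blocks_), b, -1)
        else:
            b = np.full(len(X), -1, dtype=int)
        icpt = s.stacked(["intercept"])[:, 0]
        beta = s.stacked([f"beta[{c}]" for c in self.covariates_])
        u = s.stacked([f"u[{k}]" for k in range(self.n_blocks_)])
        u_row = np.where(b[None, :] >= 0, u[:, np.clip(b, 0, None)], 0.0)
        return icpt[:, None] + beta @ Xc.T + u_row

    def size_draws(self, X: pd.DataFrame, max_draws: int | None = None) -> np.ndarray:
        """Posterior draws of the back-transformed size (m^2), always > 0."""
        mu = self.mu_draws(X, max_draws)
        if self.back_transform == "mean":
            sig = self.samples_.thin_to(
                max(1, (max_draws or self.samples_.n_draws * self.n_chains) // self.n_chains)
            ).stacked(["sigma"])[:, 0]
            return np.exp(mu + 0.5 * sig[: mu.shape[0], None] ** 2)
        return np.exp(mu)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Posterior-median back-transformed size (m^2) per row."""
        return np.median(self.size_draws(X, max_draws=600), axis=0)

    def replicate(
        self, X: pd.DataFrame, n_draws: int = 200, rng=None
    ) -> tuple[np.ndarray, np.ndarray]:
        """Posterior-predictive replicated sizes and expected sizes (m^2).

        Replicates are drawn from the full lognormal observation model and
        reported on the strictly positive m^2 scale, so count-style
        discrepancies (Freeman-Tukey) apply directly.
        """
        self._check_fitted()
        rng = np.random.default_rng(rng)
        s = self.samples_.thin_to(max(1, n_draws // self.n_chains))
        mu = self.mu_draws(X, max_draws=s.n_draws * self.n_chains)
        sig = s.stacked(["sigma"])[:, 0][: mu.shape[0]]
        y_rep = np.exp(mu + sig[:, None] * rng.standard_normal(mu.shape))
        return y_rep, np.exp(mu)
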