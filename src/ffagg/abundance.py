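"""Zero-inflated negative binomial abundance model with a proper-CAR field.

The expected count in cell i on survey j is

    E[y_ij] = psi_ij * lambda_ij,
    log lambda_ij = intercept + u_k(i) + sum_l beta_l x_ijl + log e_ij,
    logit psi_ij  = alpha1 + beta_sea . x_sea(ij),

with u a zero-centred proper CAR field over the coarse blocks, e_ij the
surveyed area (km^2) entering as a log offset, and NB dispersion r from the
Gamma(r, r) mixing of the Poisson rate.  Season enters only the presence
probability psi (reference level: summer).  The CAR mean acts as the global
intercept; it is sampled as a separate scalar with the field kept
zero-centred (an exact reparameterisation that mixes better).

Fitting is Metropolis-within-Gibbs with the latents (rho, z) marginalised
into the closed-form ZINB likelihood by default; a data-augmentation mode
that samples rho and z explicitly is available (``marginalize=False``) and
targets the same posterior.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln
from sklearn.base import BaseEstimator

from .car import CARStructure, car_structure
from .likelihoods import SEASON_COEF_ORDER, season_design
from .mcmc import (
    AdaptiveBlock,
    PosteriorSamples,
    ScalarAdaptive,
    graph_colors,
    spawn_rngs,
    summarize_effects,
)

RESERVED_COLUMNS = ("season", "effort_km2", "block", "cell_id", "survey_id", "count")

DEFAULT_PRIORS = {
    "sd_beta": 10.0,  # Normal sd for beta, beta_sea, alpha1, intercept
    "r_scale": 10.0,  # half-Normal scale for the NB dispersion r
    "tau_shape": 1.0,  # Gamma prior on tau_CAR
    "tau_rate": 0.01,
    "gamma_eps": 1e-3,  # keep gamma strictly inside the propriety interval
}


def _gamma_range(structure, eps: float, support: str) -> tuple[float, float]:
    """Sampling interval for gamma; edgeless graphs (no spatial dependence
    to estimate) fall back to the canonical (0, 1) interval."""
    lo, hi = structure.gamma_bounds
    hi = hi - eps if np.isfinite(hi) else 1.0 - eps
    lo = lo + eps if np.isfinite(lo) else -1.0 + eps
    return (0.0, hi) if support == "nonneg" else (lo, hi)


class _Data:
    """Design arrays extracted from the fitting table, aligned row-wise."""

    def __init__(self, X, y, covariates, standardize):
        self.y = np.asarray(y, dtype=float)
        if np.any(self.y < 0) or np.any(self.y != np.floor(self.y)):
            raise ValueError("counts must be non-negative integers")
        self.n = self.y.size
        if len(X) != self.n:
            raise ValueError("X and y must have the same number of rows")
        effort = X["effort_km2"].to_numpy(dtype=float)
        if np.any(~np.isfinite(effort)) or np.any(effort <= 0):
            raise ValueError(
                "effort_km2 must be positive and finite for every row entering "
                "the likelihood; drop zero-effort rows first"
            )
        self.log_effort = np.log(effort)
        self.Xs = season_design(X["season"].to_numpy())
        self.block = X["block"].to_numpy(dtype=int)
        raw = X[covariates].to_numpy(dtype=float)
        if np.any(~np.isfinite(raw)):
            raise ValueError("covariates contain missing or non-finite values")
        if standardize:
            self.x_mean = raw.mean(axis=0)
            self.x_sd = raw.std(axis=0, ddof=1)
            if np.any(self.x_sd == 0):
                bad = [c for c, s in zip(covariates, self.x_sd) if s == 0]
                raise ValueError(f"constant covariate column(s): {bad}")
            self.Xc = (raw - self.x_mean) / self.x_sd
        else:
            self.x_mean = np.zeros(raw.shape[1])
            self.x_sd = np.ones(raw.shape[1])
            self.Xc = raw
        self.zero = self.y == 0
        self.gl_y1 = gammaln(self.y + 1.0)


class ZINBAbundanceModel(BaseEstimator):
    """Hierarchical Bayesian ZINB abundance model (scikit-learn style).

    Parameters
    ----------
    covariates : list of str, optional
        Covariate columns of the fitting table; default: every column not in
        ``{season, effort_km2, block, cell_id, survey_id, count}``.
    n_chains, n_iter, burnin_frac, thin
        MCMC protocol.  Defaults (3 x 20,000, 50% burn-in, thin 4) are a
        desk-scale version of the full survey protocol (3 x 400,000,
        250,000 burn-in, thin 20), which remains available via these knobs.
    priors : dict, optional
        Overrides for ``DEFAULT_PRIORS``.
    gamma_support : "nonneg" (default) restricts the spatial-dependence
        parameter to [0, gamma_max); "full" allows the whole propriety
        interval.
    marginalize : bool
        If True (default) use the exact marginal ZINB likelihood; if False
        run the data-augmentation sampler over the latent (rho, z).
    standardize : bool
        Standardize covariates to mean 0, sd 1 over the training rows
        (stored for prediction); default True.
    random_state : int
        Seed for all chains; fits are reproducible bit-for-bit.

    Attributes
    ----------
    samples_ : PosteriorSamples
    coef_summary_ : DataFrame of medians / 50% / 95% CIs / significance.
    car_structure_ : CARStructure over the coarse blocks.
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
        marginalize=True,
        standardize=True,
        random_state=0,
    ):
        self.covariates = covariates
        self.n_chains = n_chains
        self.n_iter = n_iter
        self.burnin_frac = burnin_frac
        self.thin = thin
        self.priors = priors
        self.gamma_support = gamma_support
        self.marginalize = marginalize
        self.standardize = standardize
        self.random_state = random_state

    # ------------------------------------------------------------------ fit

    def fit(self, X: pd.DataFrame, y=None, adjacency: dict | None = None):
        """Sample the posterior given the (cell x survey) table.

        ``X`` must carry the covariate columns plus ``season``,
        ``effort_km2`` and ``block``; ``y`` the counts (or a ``count``
        column in ``X``).  ``adjacency`` gives the coarse-block neighbour
        lists for the CAR field.
        """
        if self.n_chains < 2:
            raise ValueError("need at least 2 chains for convergence checks")
        if y is None:
            if "count" not in X.columns:
                raise ValueError("pass y or include a 'count' column")
            y = X["count"].to_numpy()
        covs = self._resolve_covariates(X)
        data = _Data(X, y, covs, self.standardize)
        if adjacency is None:
            adjacency = {k: [] for k in range(int(data.block.max()) + 1)}
        structure = car_structure(adjacency)
        if data.block.min() < 0 or data.block.max() >= structure.n_blocks:
            raise ValueError("block indices out of range for the adjacency")

        self.priors_ = dict(DEFAULT_PRIORS, **(self.priors or {}))
        self.gamma_range_ = _gamma_range(
            structure, self.priors_["gamma_eps"], self.gamma_support
        )
        colors = graph_colors(structure.neighbors)
        rows_by_color = [np.flatnonzero(np.isin(data.block, c)) for c in colors]

        n_keep = (self.n_iter - int(self.n_iter * self.burnin_frac)) // self.thin
        if n_keep < 1:
            raise ValueError("MCMC protocol retains no draws")
        chains = []
        for rng in spawn_rngs(self.random_state, self.n_chains):
            runner = (
                self._run_chain_marginal if self.marginalize else self._run_chain_latent
            )
            chains.append(runner(data, structure, colors, rows_by_color, rng))

        names = self._param_names(covs, structure.n_blocks)
        self.samples_ = PosteriorSamples(
            np.stack(chains),
            names,
            meta={
                "model": "abundance",
                "n_iter": self.n_iter,
                "burnin": int(self.n_iter * self.burnin_frac),
                "thin": self.thin,
                "seed": self.random_state,
                "marginalized": self.marginalize,
                "covariates": covs,
            },
        )
        self.covariates_ = covs
        self.x_mean_ = data.x_mean
        self.x_sd_ = data.x_sd
        self.car_structure_ = structure
        self.n_blocks_ = structure.n_blocks
        self.coef_summary_ = summarize_effects(
            self.samples_,
            ["intercept", "alpha1", "r", "tau_car", "gamma"]
            + [f"beta_sea[{s}]" for s in SEASON_COEF_ORDER]
            + [f"beta[{c}]" for c in covs],
        )
        return self

    def _resolve_covariates(self, X):
        if self.covariates is not None:
            covs = list(self.covariates)
        else:
            covs = [c for c in X.columns if c not in RESERVED_COLUMNS]
        missing = [c for c in ("season", "effort_km2", "block") if c not in X.columns]
        if missing:
            raise ValueError(f"fitting table lacks required column(s) {missing}")
        absent = [c for c in covs if c not in X.columns]
        if absent:
            raise ValueError(f"covariate column(s) not in table: {absent}")
        return covs

    @staticmethod
    def _param_names(covs, n_blocks):
        return (
            ["intercept", "alpha1", "r", "tau_car", "gamma"]
            + [f"beta_sea[{s}]" for s in SEASON_COEF_ORDER]
            + [f"beta[{c}]" for c in covs]
            + [f"u[{k}]" for k in range(n_blocks)]
        )

    # ------------------------------------------------- likelihood internals

    @staticmethod
    def _row_ll(data, log_lam, psi, r, gl_yr, log_r):
        """Per-row marginal ZINB log-pmf given cached gammaln(y + r)."""
        log_r_lam = np.logaddexp(log_r, log_lam)
        with np.errstate(divide="ignore"):
            log_psi = np.log(psi)
            log_1mpsi = np.log1p(-psi)
        out = (
            log_psi
            + gl_yr
            - gammaln(r)
            - data.gl_y1
            + r * (log_r - log_r_lam)
            + data.y * (log_lam - log_r_lam)
        )
        z = data.zero
        out[z] = np.logaddexp(log_1mpsi[z], log_psi[z] + r * (log_r - log_r_lam[z]))
        return out

    def _init_state(self, data, structure, rng):
        rate = data.y.sum() / np.exp(data.log_effort).sum()
        state = {
            "intercept": float(np.log(rate + 1e-3)),
            "beta": np.zeros(data.Xc.shape[1]),
            "alpha1": 0.0,
            "beta_sea": np.zeros(3),
            "r": 1.0,
            "u": np.zeros(structure.n_blocks),
            "tau": 1.0,
            "gamma": 0.5 * (self.gamma_range_[0] + self.gamma_range_[1]),
        }
        return state

    def _record(self, state, out, idx):
        out[idx, 0] = state["intercept"]
        out[idx, 1] = state["alpha1"]
        out[idx, 2] = state["r"]
        out[idx, 3] = state["tau"]
        out[idx, 4] = state["gamma"]
        out[idx, 5:8] = state["beta_sea"]
        p = state["beta"].size
        out[idx, 8 : 8 + p] = state["beta"]
        out[idx, 8 + p :] = state["u"]

    def _run_chain_marginal(self, data, structure, colors, rows_by_color, rng):
        pr = self.priors_
        sd2 = pr["sd_beta"] ** 2
        burn = int(self.n_iter * self.burnin_frac)
        n_keep = (self.n_iter - burn) // self.thin
        p = data.Xc.shape[1]
        out = np.empty((n_keep, 8 + p + structure.n_blocks))

        st = self._init_state(data, structure, rng)
        beta_blk = AdaptiveBlock(p, init_scale=0.05)
        icpt_blk = ScalarAdaptive(init_scale=0.1)
        psi_blk = AdaptiveBlock(4, init_scale=0.2)
        r_blk = ScalarAdaptive(init_scale=0.3)
        gam_blk = ScalarAdaptive(init_scale=0.1)
        u_blks = [ScalarAdaptive(init_scale=0.3) for _ in colors]

        log_theta = st["intercept"] + data.Xc @ st["beta"] + st["u"][data.block]
        log_lam = log_theta + data.log_effort
        psi = expit(st["alpha1"] + data.Xs @ st["beta_sea"])
        gl_yr = gammaln(data.y + st["r"])
        log_r = np.log(st["r"])
        row_ll = self._row_ll(data, log_lam, psi, st["r"], gl_yr, log_r)
        if not np.isfinite(row_ll.sum()):
            raise RuntimeError(
                f"non-finite likelihood at initialization; state={st}"
            )
        Wu = structure.W @ st["u"]

        kept = 0
        for it in range(self.n_iter):
            # --- covariate effects, joint adaptive MH (intercept separate:
            # its recentering jumps would contaminate the block covariance)
            cur = st["beta"]
            prop = beta_blk.propose(cur, rng)
            new_log_lam = st["intercept"] + data.Xc @ prop + st["u"][data.block] + data.log_effort
            new_ll = self._row_ll(data, new_log_lam, psi, st["r"], gl_yr, log_r)
            d_prior = 0.5 * (cur @ cur - prop @ prop) / sd2
            acc = np.log(rng.random()) < new_ll.sum() - row_ll.sum() + d_prior
            if acc:
                st["beta"] = prop
                log_lam, row_ll = new_log_lam, new_ll
            beta_blk.adapt(st["beta"], float(acc))

            # --- intercept, scalar adaptive MH
            prop_i = icpt_blk.propose_scalar(st["intercept"], rng)
            new_log_lam = log_lam + (prop_i - st["intercept"])
            new_ll = self._row_ll(data, new_log_lam, psi, st["r"], gl_yr, log_r)
            d_prior = 0.5 * (st["intercept"] ** 2 - prop_i**2) / sd2
            acc = np.log(rng.random()) < new_ll.sum() - row_ll.sum() + d_prior
            if acc:
                st["intercept"] = prop_i
                log_lam, row_ll = new_log_lam, new_ll
            icpt_blk.adapt_scalar(float(acc))

            # --- presence parameters (alpha1 + beta_sea)
            cur = np.concatenate([[st["alpha1"]], st["beta_sea"]])
            prop = psi_blk.propose(cur, rng)
            new_psi = expit(prop[0] + data.Xs @ prop[1:])
            new_ll = self._row_ll(data, log_lam, new_psi, st["r"], gl_yr, log_r)
            d_prior = 0.5 * (cur @ cur - prop @ prop) / sd2
            acc = np.log(rng.random()) < new_ll.sum() - row_ll.sum() + d_prior
            if acc:
                st["alpha1"], st["beta_sea"] = prop[0], prop[1:]
                psi, row_ll = new_psi, new_ll
            psi_blk.adapt(np.concatenate([[st["alpha1"]], st["beta_sea"]]), float(acc))

            # --- dispersion r, random walk on log r (half-Normal prior)
            prop_logr = r_blk.propose_scalar(np.log(st["r"]), rng)
            r_new = np.exp(prop_logr)
            gl_new = gammaln(data.y + r_new)
            new_ll = self._row_ll(data, log_lam, psi, r_new, gl_new, prop_logr)
            d_prior = 0.5 * (st["r"] ** 2 - r_new**2) / pr["r_scale"] ** 2
            d_jac = prop_logr - np.log(st["r"])  # log-scale random walk
            acc = np.log(rng.random()) < new_ll.sum() - row_ll.sum() + d_prior + d_jac
            if acc:
                st["r"], gl_yr, log_r, row_ll = r_new, gl_new, prop_logr, new_ll
            r_blk.adapt_scalar(float(acc))

            # --- CAR field, one sweep per graph colour
            for ci, (blocks, rows) in enumerate(zip(colors, rows_by_color)):
                eps = np.exp(u_blks[ci].log_scale) * rng.standard_normal(blocks.size)
                u_old = st["u"][blocks]
                u_new = u_old + eps
                new_log_lam_rows = log_lam[rows] + (u_new - u_old)[
                    np.searchsorted(blocks, data.block[rows])
                ]
                new_ll_rows = self._row_ll_rows(
                    data, rows, new_log_lam_rows, psi, st["r"], gl_yr, log_r
                )
                d_ll = np.zeros(structure.n_blocks)
                np.add.at(d_ll, data.block[rows], new_ll_rows - row_ll[rows])
                d_quad = (
                    structure.d_eff[blocks] * (u_new**2 - u_old**2)
                    - 2.0 * st["gamma"] * (u_new - u_old) * Wu[blocks]
                )
                log_acc = d_ll[blocks] - 0.5 * st["tau"] * d_quad
                accept = np.log(rng.random(blocks.size)) < log_acc
                if accept.any():
                    upd = blocks[accept]
                    st["u"][upd] = u_new[accept]
                    row_sel = np.isin(data.block[rows], upd)
                    log_lam[rows[row_sel]] = new_log_lam_rows[row_sel]
                    row_ll[rows[row_sel]] = new_ll_rows[row_sel]
                    Wu = structure.W @ st["u"]
                u_blks[ci].adapt_scalar(float(accept.mean()) if blocks.size else 0.0)

            # --- interweaved recentering: intercept + delta, field - delta.
            # The likelihood is invariant, so this is a prior-only MH move
            # along the otherwise nearly unidentified mean direction.
            delta = self._recenter_delta(st, structure, sd2, rng)
            if delta != 0.0:
                st["intercept"] += delta
                st["u"] -= delta
                Wu = structure.W @ st["u"]

            # --- tau_CAR, conjugate Gibbs
            quad_d, quad_w = structure.quad_form(st["u"], 0.0)
            quad = quad_d - st["gamma"] * quad_w
            st["tau"] = rng.gamma(
                pr["tau_shape"] + 0.5 * structure.n_blocks,
                1.0 / (pr["tau_rate"] + 0.5 * max(quad, 1e-12)),
            )

            # --- gamma, random-walk MH on the prior of u (uniform prior)
            prop_g = gam_blk.propose_scalar(st["gamma"], rng)
            if self.gamma_range_[0] <= prop_g <= self.gamma_range_[1]:
                d_logdet = 0.5 * (
                    np.log1p(-prop_g * structure.eigs).sum()
                    - np.log1p(-st["gamma"] * structure.eigs).sum()
                )
                d_quad = 0.5 * st["tau"] * (prop_g - st["gamma"]) * quad_w
                acc = np.log(rng.random()) < d_logdet + d_quad
                if acc:
                    st["gamma"] = prop_g
            else:
                acc = False
            gam_blk.adapt_scalar(float(acc))

            if it >= burn and (it - burn) % self.thin == 0 and kept < n_keep:
                self._record(st, out, kept)
                kept += 1
        return out

    @staticmethod
    def _recenter_delta(st, structure, sd2, rng) -> float:
        """Gibbs draw of the likelihood-invariant shift delta with
        intercept -> intercept + delta, u -> u - delta.  The conditional is
        Gaussian: both the intercept prior and the CAR prior are quadratic
        in delta."""
        q_ones = structure.d_eff - st["gamma"] * structure.m  # Q0 @ 1 (scaled)
        prec = 1.0 / sd2 + st["tau"] * float(q_ones.sum())
        lin = -st["intercept"] / sd2 + st["tau"] * float(q_ones @ st["u"])
        return float(lin / prec + rng.standard_normal() / np.sqrt(prec))

    @classmethod
    def _row_ll_rows(cls, data, rows, log_lam_rows, psi, r, gl_yr, log_r):
        """Marginal ZINB log-pmf restricted to a row subset."""
        y = data.y[rows]
        zero = data.zero[rows]
        log_r_lam = np.logaddexp(log_r, log_lam_rows)
        p = psi[rows] if np.ndim(psi) else np.full(rows.size, psi)
        with np.errstate(divide="ignore"):
            log_psi = np.log(p)
            log_1mpsi = np.log1p(-p)
        out = (
            log_psi
            + gl_yr[rows]
            - gammaln(r)
            - data.gl_y1[rows]
            + r * (log_r - log_r_lam)
            + y * (log_lam_rows - log_r_lam)
        )
        out[zero] = np.logaddexp(
            log_1mpsi[zero], log_psi[zero] + r * (log_r - log_r_lam[zero])
        )
        return out

    # ------------------------------------------ data-augmentation sampler

    def _run_chain_latent(self, data, structure, colors, rows_by_color, rng):
        """Sampler over the explicit latents rho ~ Gamma(r, r), z ~ Bern(psi).

        Targets the same posterior as the marginal sampler: z is drawn with
        rho integrated out (collapsed step), then rho | z, y is conjugate
        Gamma; the count likelihood for the remaining blocks is conditional
        Poisson(lambda * rho) on the z = 1 rows.
        """
        pr = self.priors_
        sd2 = pr["sd_beta"] ** 2
        burn = int(self.n_iter * self.burnin_frac)
        n_keep = (self.n_iter - burn) // self.thin
        p = data.Xc.shape[1]
        out = np.empty((n_keep, 8 + p + structure.n_blocks))

        st = self._init_state(data, structure, rng)
        beta_blk = AdaptiveBlock(p, init_scale=0.05)
        icpt_blk = ScalarAdaptive(init_scale=0.1)
        psi_blk = AdaptiveBlock(4, init_scale=0.2)
        r_blk = ScalarAdaptive(init_scale=0.3)
        gam_blk = ScalarAdaptive(init_scale=0.1)
        u_blks = [ScalarAdaptive(init_scale=0.3) for _ in colors]

        z = (data.y > 0).astype(float)
        rho = np.ones(data.n)
        kept = 0
        for it in range(self.n_iter):
            log_theta = st["intercept"] + data.Xc @ st["beta"] + st["u"][data.block]
            lam = np.exp(log_theta + data.log_effort)
            psi = expit(st["alpha1"] + data.Xs @ st["beta_sea"])

            # --- z | y, psi, r (rho collapsed), then rho | z, y
            p0 = (st["r"] / (st["r"] + lam[data.zero])) ** st["r"]
            pz = psi[data.zero] * p0 / (psi[data.zero] * p0 + 1.0 - psi[data.zero])
            z[data.zero] = rng.random(pz.size) < pz
            on = z > 0
            rho = rng.gamma(st["r"], 1.0 / st["r"], size=data.n)  # z = 0 rows: prior
            rho[on] = rng.gamma(st["r"] + data.y[on], 1.0 / (st["r"] + lam[on]))

            # --- Poisson part of the log-likelihood on z = 1 rows
            def pois_ll(log_lam_vec):
                ll = data.y[on] * log_lam_vec[on] - rho[on] * np.exp(log_lam_vec[on])
                return ll.sum()

            log_lam_full = log_theta + data.log_effort
            cur_ll = pois_ll(log_lam_full)

            # covariate effects, then intercept
            cur = st["beta"]
            prop = beta_blk.propose(cur, rng)
            new_log_lam = st["intercept"] + data.Xc @ prop + st["u"][data.block] + data.log_effort
            d_prior = 0.5 * (cur @ cur - prop @ prop) / sd2
            acc = np.log(rng.random()) < pois_ll(new_log_lam) - cur_ll + d_prior
            if acc:
                st["beta"] = prop
                log_lam_full = new_log_lam
                cur_ll = pois_ll(log_lam_full)
            beta_blk.adapt(st["beta"], float(acc))

            prop_i = icpt_blk.propose_scalar(st["intercept"], rng)
            new_log_lam = log_lam_full + (prop_i - st["intercept"])
            d_prior = 0.5 * (st["intercept"] ** 2 - prop_i**2) / sd2
            acc = np.log(rng.random()) < pois_ll(new_log_lam) - cur_ll + d_prior
            if acc:
                st["intercept"] = prop_i
                log_lam_full = new_log_lam
                cur_ll = pois_ll(log_lam_full)
            icpt_blk.adapt_scalar(float(acc))

            # presence parameters: Bernoulli likelihood of z
            cur = np.concatenate([[st["alpha1"]], st["beta_sea"]])
            prop = psi_blk.propose(cur, rng)
            eta_new = prop[0] + data.Xs @ prop[1:]
            eta_cur = st["alpha1"] + data.Xs @ st["beta_sea"]
            bern = lambda eta: np.sum(z * eta - np.logaddexp(0.0, eta))
            d_prior = 0.5 * (cur @ cur - prop @ prop) / sd2
            acc = np.log(rng.random()) < bern(eta_new) - bern(eta_cur) + d_prior
            if acc:
                st["alpha1"], st["beta_sea"] = prop[0], prop[1:]
            psi_blk.adapt(np.concatenate([[st["alpha1"]], st["beta_sea"]]), float(acc))

            # r | rho (Gamma(r, r) density of the mixing variables)
            prop_logr = r_blk.propose_scalar(np.log(st["r"]), rng)
            r_new = np.exp(prop_logr)

            def r_ll(r):
                return data.n * (r * np.log(r) - gammaln(r)) + (r - 1.0) * np.sum(
                    np.log(rho)
                ) - r * np.sum(rho)

            d_prior = 0.5 * (st["r"] ** 2 - r_new**2) / pr["r_scale"] ** 2
            d_jac = prop_logr - np.log(st["r"])
            acc = np.log(rng.random()) < r_ll(r_new) - r_ll(st["r"]) + d_prior + d_jac
            if acc:
                st["r"] = r_new
            r_blk.adapt_scalar(float(acc))

            # CAR field by colour sweeps (Poisson likelihood on z = 1 rows)
            Wu = structure.W @ st["u"]
            for ci, (blocks, rows) in enumerate(zip(colors, rows_by_color)):
                eps = np.exp(u_blks[ci].log_scale) * rng.standard_normal(blocks.size)
                u_old = st["u"][blocks]
                u_new = u_old + eps
                du_row = (u_new - u_old)[np.searchsorted(blocks, data.block[rows])]
                act = on[rows]
                ll_old = data.y[rows] * log_lam_full[rows] - rho[rows] * np.exp(
                    log_lam_full[rows]
                )
                ll_new = data.y[rows] * (log_lam_full[rows] + du_row) - rho[
                    rows
                ] * np.exp(log_lam_full[rows] + du_row)
                d_ll = np.zeros(structure.n_blocks)
                np.add.at(d_ll, data.block[rows], act * (ll_new - ll_old))
                d_quad = (
                    structure.d_eff[blocks] * (u_new**2 - u_old**2)
                    - 2.0 * st["gamma"] * (u_new - u_old) * Wu[blocks]
                )
                accept = np.log(rng.random(blocks.size)) < (
                    d_ll[blocks] - 0.5 * st["tau"] * d_quad
                )
                if accept.any():
                    upd = blocks[accept]
                    st["u"][upd] = u_new[accept]
                    row_sel = np.isin(data.block[rows], upd)
                    log_lam_full[rows[row_sel]] += du_row[row_sel]
                    Wu = structure.W @ st["u"]
                u_blks[ci].adapt_scalar(float(accept.mean()) if blocks.size else 0.0)

            # recentering, tau and gamma exactly as in the marginal sampler
            delta = self._recenter_delta(st, structure, sd2, rng)
            if delta != 0.0:
                st["intercept"] += delta
                st["u"] -= delta
            quad_d, quad_w = structure.quad_form(st["u"], 0.0)
            st["tau"] = rng.gamma(
                pr["tau_shape"] + 0.5 * structure.n_blocks,
                1.0 / (pr["tau_rate"] + 0.5 * max(quad_d - st["gamma"] * quad_w, 1e-12)),
            )
            prop_g = gam_blk.propose_scalar(st["gamma"], rng)
            if self.gamma_range_[0] <= prop_g <= self.gamma_range_[1]:
                d_logdet = 0.5 * (
                    np.log1p(-prop_g * structure.eigs).sum()
                    - np.log1p(-st["gamma"] * structure.eigs).sum()
                )
                acc = np.log(rng.random()) < d_logdet + 0.5 * st["tau"] * (
                    prop_g - st["gamma"]
                ) * quad_w
                if acc:
                    st["gamma"] = prop_g
            else:
                acc = False
            gam_blk.adapt_scalar(float(acc))

            if it >= burn and (it - burn) % self.thin == 0 and kept < n_keep:
                self._record(st, out, kept)
                kept += 1
        return out

    # ------------------------------------------------------------- predict

    def _check_fitted(self):
        if not hasattr(self, "samples_"):
            raise RuntimeError("model is not fitted")

    def _design(self, X):
        raw = X[self.covariates_].to_numpy(dtype=float)
        return (raw - self.x_mean_) / self.x_sd_

    def _blocks_for(self, X):
        """Block index per row; unseen/absent blocks -> -1 (field mean)."""
        if "block" not in X.columns:
            return np.full(len(X), -1, dtype=int)
        b = X["block"].to_numpy(dtype=int)
        return np.where((b >= 0) & (b < self.n_blocks_), b, -1)

    def expected_draws(self, X: pd.DataFrame, max_draws: int | None = None) -> np.ndarray:
        """Posterior draws of E[y] = psi * lambda, shape (n_draws, n_rows).

        Rows in blocks never seen in training take the CAR field at its
        marginal mean (zero on the centred scale).
        """
        self._check_fitted()
        s = self.samples_ if max_draws is None else self.samples_.thin_to(
            max(1, max_draws // self.n_chains)
        )
        Xc = self._design(X)
        Xs = season_design(X["season"].to_numpy())
        log_eff = np.log(X["effort_km2"].to_numpy(dtype=float))
        block = self._blocks_for(X)
        covs = self.covariates_
        icpt = s.stacked(["intercept"])[:, 0]
        beta = s.stacked([f"beta[{c}]" for c in covs])
        a1 = s.stacked(["alpha1"])[:, 0]
        bsea = s.stacked([f"beta_sea[{x}]" for x in SEASON_COEF_ORDER])
        u = s.stacked([f"u[{k}]" for k in range(self.n_blocks_)])
        u_row = np.where(block[None, :] >= 0, u[:, np.clip(block, 0, None)], 0.0)
        log_lam = icpt[:, None] + beta @ Xc.T + u_row + log_eff[None, :]
        psi = expit(a1[:, None] + bsea @ Xs.T)
        return psi * np.exp(log_lam)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Posterior-mean expected count per row (includes effort and psi)."""
        return self.expected_draws(X, max_draws=600).mean(axis=0)

    def replicate(
        self, X: pd.DataFrame, n_draws: int = 200, rng=None
    ) -> tuple[np.ndarray, np.ndarray]:
        """Posterior-predictive replicates and matching expected values.

        Returns ``(y_rep, expected)`` each of shape (n_draws, n_rows); draw
        d of ``y_rep`` is simulated from the full ZINB at posterior draw d.
        """
        from .likelihoods import zinb_rvs

        self._check_fitted()
        rng = np.random.default_rng(rng)
        s = self.samples_.thin_to(max(1, n_draws // self.n_chains))
        Xc = self._design(X)
        Xs = season_design(X["season"].to_numpy())
        log_eff = np.log(X["effort_km2"].to_numpy(dtype=float))
        block = self._blocks_for(X)
        covs = self.covariates_
        icpt = s.stacked(["intercept"])[:, 0]
        beta = s.stacked([f"beta[{c}]" for c in covs])
        a1 = s.stacked(["alpha1"])[:, 0]
        bsea = s.stacked([f"beta_sea[{x}]" for x in SEASON_COEF_ORDER])
        rs = s.stacked(["r"])[:, 0]
        u = s.stacked([f"u[{k}]" for k in range(self.n_blocks_)])
        n_total = icpt.size
        y_rep = np.empty((n_total, len(X)))
        expected = np.empty((n_total, len(X)))
        for d in range(n_total):
            u_row = np.where(block >= 0, u[d, np.clip(block, 0, None)], 0.0)
            log_lam = icpt[d] + Xc @ beta[d] + u_row + log_eff
            psi = expit(a1[d] + Xs @ bsea[d])
            expected[d] = psi * np.exp(log_lam)
            y_rep[d] = zinb_rvs(log_lam, rs[d], psi, rng)
        return y_rep, expected
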