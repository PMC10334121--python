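"""Observation-model likelihoods.

Counts follow a zero-inflated Poisson-Gamma mixture: y ~ Poisson(lambda *
rho * z) with rho ~ Gamma(r, r) (shape = rate, mean 1) and z ~
Bernoulli(psi).  Marginalising rho and z gives the zero-inflated negative
binomial with size r and mean lambda:

    P(0)    = (1 - psi) + psi * (r / (r + lambda))^r
    P(y>0)  = psi * NB(y; r, lambda)

which is what the abundance likelihood evaluates (exact, and it mixes far
better than sampling the latents).  Log sizes are Gaussian.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, gammaln

SEASONS = ("autumn", "spring", "winter", "summer")
#: order of the season coefficients; summer is the reference level
SEASON_COEF_ORDER = ("autumn", "spring", "winter")


def _nb_logpmf(y: np.ndarray, log_lam: np.ndarray, r: float) -> np.ndarray:
    """NB(y; size r, mean exp(log_lam)) on the log scale, vectorised."""
    lam = np.exp(log_lam)
    log_r_lam = np.log(r + lam)
    return (
        gammaln(y + r)
        - gammaln(r)
        - gammaln(y + 1.0)
        + r * (np.log(r) - log_r_lam)
        + y * (log_lam - log_r_lam)
    )


def zinb_logpmf(
    y: np.ndarray,
    log_mean: np.ndarray,
    r: float,
    psi: float | np.ndarray,
) -> np.ndarray:
    """Log-pmf of the marginalised zero-inflated negative binomial.

    Parameters
    ----------
    y : non-negative integer counts.
    log_mean : log of the NB mean lambda (linear predictor + offset).
    r : dispersion (> 0); Var(y | z=1) = lambda + lambda^2 / r.
    psi : presence probability in [0, 1]; scalar or per-observation.

    Stable for large lambda and extreme r: the zero mass is assembled with
    logaddexp/log1p, never by exponentiating and re-logging the pieces.
    """
    y = np.asarray(y)
    if np.any(y < 0) or not np.issubdtype(np.asarray(y).dtype, np.number):
        raise ValueError("y must be non-negative counts")
    if np.any(np.asarray(y) != np.floor(y)):
        raise ValueError("y must be integer-valued")
    if r <= 0:
        raise ValueError(f"r must be positive, got {r}")
    psi = np.asarray(psi, dtype=float)
    if np.any((psi < 0) | (psi > 1)):
        raise ValueError("psi must lie in [0, 1]")
    y = np.asarray(y, dtype=float)
    log_mean = np.asarray(log_mean, dtype=float)
    y, log_mean, psi = np.broadcast_arrays(y, log_mean, psi)

    out = np.empty(y.shape, dtype=float)
    with np.errstate(divide="ignore"):
        log_psi = np.log(psi)
        log_1mpsi = np.log1p(-psi)
    # positive counts: psi * NB(y)
    pos = y > 0
    out[pos] = log_psi[pos] + _nb_logpmf(y[pos], log_mean[pos], r)
    # zeros: (1 - psi) + psi * (r/(r+lambda))^r
    z = ~pos
    log_nb0 = r * (np.log(r) - np.logaddexp(np.log(r), log_mean[z]))
    out[z] = np.logaddexp(log_1mpsi[z], log_psi[z] + log_nb0)
    return out


def zinb_rvs(
    log_mean: np.ndarray,
    r: float,
    psi: float | np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Forward draw from the Poisson-Gamma-Bernoulli representation."""
    log_mean = np.asarray(log_mean, dtype=float)
    lam = np.exp(log_mean)
    z = rng.random(lam.shape) < psi
    rho = rng.gamma(shape=r, scale=1.0 / r, size=lam.shape)
    return rng.poisson(lam * rho * z)


def zinb_mean(log_mean: np.ndarray, psi: float | np.ndarray) -> np.ndarray:
    """E[y] = psi * lambda."""
    return np.asarray(psi) * np.exp(np.asarray(log_mean, dtype=float))


def zinb_pmf_quadrature(y: int, lam: float, r: float, psi: float) -> float:
    """Independent oracle: integrate Poisson(lam * rho) over rho ~ Gamma(r, r)
    numerically, then mix with the Bernoulli presence.  The substitution
    u = rho^r makes the Gamma(r, r) density exactly proportional to
    exp(-r u^(1/r)) du, removing the r < 1 singularity at zero before the
    adaptive quadrature.  Used only for testing the closed form."""
    from scipy import integrate, stats

    log_const = (r - 1.0) * np.log(r) - gammaln(r)

    def integrand(u):
        rho = u ** (1.0 / r)
        return np.exp(log_const - r * rho) * stats.poisson.pmf(y, lam * rho)

    p_present, _ = integrate.quad(integrand, 0.0, np.inf, limit=400, epsabs=1e-12)
    return psi * p_present + (1.0 - psi) * (1.0 if y == 0 else 0.0)


def season_design(seasons: np.ndarray) -> np.ndarray:
    """Indicator matrix over (autumn, spring, winter); summer is reference."""
    seasons = np.asarray(seasons)
    bad = ~np.isin(seasons, SEASONS)
    if bad.any():
        raise ValueError(f"unknown season label(s): {np.unique(seasons[bad])}")
    return np.column_stack([seasons == s for s in SEASON_COEF_ORDER]).astype(float)


def psi_linpred(
    seasons: np.ndarray, alpha1: float, beta_sea: np.ndarray
) -> np.ndarray:
    """Presence probability psi = logistic(alpha1 + beta_sea . x_sea).

    ``beta_sea`` is ordered (autumn, spring, winter); summer rows use
    ``alpha1`` alone.
    """
    beta_sea = np.asarray(beta_sea, dtype=float)
    if beta_sea.shape != (3,):
        raise ValueError("beta_sea must have length 3 (autumn, spring, winter)")
    X = season_design(seasons)
    return expit(alpha1 + X @ beta_sea)


def abundance_loglik(
    counts: np.ndarray,
    log_theta: np.ndarray,
    log_effort: np.ndarray,
    r: float,
    psi: np.ndarray,
) -> float:
    """Total ZINB log-likelihood with log lambda = log theta + log effort."""
    counts = np.asarray(counts)
    log_theta = np.asarray(log_theta, dtype=float)
    log_effort = np.asarray(log_effort, dtype=float)
    if not (counts.shape == log_theta.shape == log_effort.shape):
        raise ValueError("counts, log_theta and log_effort must be aligned")
    return float(zinb_logpmf(counts, log_theta + log_effort, r, psi).sum())


def size_loglik(
    log_sizes: np.ndarray, mu: np.ndarray, sigma: float
) -> float:
    """Gaussian log-likelihood of logged aggregation sizes."""
    log_sizes = np.asarray(log_sizes, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    if log_sizes.shape != mu.shape:
        raise ValueError("log_sizes and mu must be aligned")
    resid = log_sizes - mu
    n = log_sizes.size
    return float(
        -0.5 * n * np.log(2.0 * np.pi)
        - n * np.log(sigma)
        - 0.5 * np.sum(resid**2) / sigma**2
    )
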