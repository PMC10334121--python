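"""MCMC convergence diagnostics, posterior predictive checks and k-fold CV.

Convergence is gated on the split potential scale reduction factor
(split-Rhat < 1.1) and the autocorrelation-based effective sample size
(ESS > 400).  Model fit is assessed with a posterior predictive check using
the Freeman-Tukey discrepancy T = sum (sqrt(y) - sqrt(e))^2 and its Bayesian
p-value Pr(T_rep >= T_obs); values near 0 or 1 indicate misfit.  Predictive
skill is assessed by k-fold cross-validation scored with Pearson correlation
for abundance and Spearman (average ranks; robust to extreme outliers) for
size.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone

from .mcmc import PosteriorSamples

logger = logging.getLogger(__name__)


# ------------------------------------------------------------- convergence


def psrf(samples: PosteriorSamples | np.ndarray, parameter: str | None = None) -> float:
    """Split potential scale reduction factor (split-Rhat).

    Each chain is halved, and Rhat is the usual between/within variance
    ratio over the 2*n_chains half-chains; splitting additionally detects
    within-chain trends.  Zero total variance returns 1.0 by convention
    (with a warning).
    """
    x = _chains(samples, parameter)
    n_chains, n = x.shape
    if n_chains < 2:
        raise ValueError("PSRF needs at least 2 chains")
    if n < 10:
        raise ValueError("PSRF needs at least 10 iterations per chain")
    half = n // 2
    splits = np.concatenate([x[:, :half], x[:, half : 2 * half]], axis=0)
    m, n2 = splits.shape
    chain_means = splits.mean(axis=1)
    W = splits.var(axis=1, ddof=1).mean()
    B = n2 * chain_means.var(ddof=1)
    if W <= 0 or not np.isfinite(W):
        warnings.warn("zero within-chain variance; PSRF = 1.0 by convention", stacklevel=2)
        return 1.0
    var_plus = (n2 - 1) / n2 * W + B / n2
    return float(np.sqrt(var_plus / W))


def ess(samples: PosteriorSamples | np.ndarray, parameter: str | None = None) -> float:
    """Autocorrelation-based effective sample size.

    Chain-mean-centred autocorrelations are averaged across chains and
    summed with Geyer's initial-positive-sequence truncation (stop at the
    first non-positive sum of adjacent lag pairs).  A constant chain is
    reported as the total draw count with a warning.
    """
    x = _chains(samples, parameter)
    n_chains, n = x.shape
    total = n_chains * n
    if np.allclose(x.var(), 0):
        warnings.warn("zero-variance draws; ESS reported as total draws", stacklevel=2)
        return float(total)
    # per-chain autocovariance via FFT, averaged
    acov = np.zeros(n)
    for c in range(n_chains):
        d = x[c] - x[c].mean()
        f = np.fft.rfft(d, 2 * n)
        ac = np.fft.irfft(f * np.conj(f))[:n].real / n
        acov += ac
    acov /= n_chains
    rho = acov / acov[0]
    # Geyer initial positive sequence over pairs (rho[2t-1] + rho[2t])
    s = 0.0
    t = 1
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair <= 0:
            break
        s += pair
        t += 2
    return float(total / (1.0 + 2.0 * s))


def _chains(samples, parameter) -> np.ndarray:
    if isinstance(samples, PosteriorSamples):
        if parameter is None:
            raise ValueError("parameter name required with PosteriorSamples")
        return samples.get(parameter)
    x = np.asarray(samples, dtype=float)
    if x.ndim != 2:
        raise ValueError("expect draws with shape (chain, iteration)")
    return x


def convergence_table(
    samples: PosteriorSamples, parameters: list[str] | None = None
) -> pd.DataFrame:
    """PSRF and ESS per parameter, for report output."""
    parameters = parameters or samples.param_names
    return pd.DataFrame(
        {
            "parameter": parameters,
            "psrf": [psrf(samples, p) for p in parameters],
            "ess": [ess(samples, p) for p in parameters],
        }
    )


# ------------------------------------------------ posterior predictive check


def freeman_tukey(observed: np.ndarray, expected: np.ndarray) -> float:
    """Freeman-Tukey discrepancy T = sum (sqrt(y) - sqrt(e))^2."""
    y = np.asarray(observed, dtype=float)
    e = np.asarray(expected, dtype=float)
    if y.shape != e.shape:
        raise ValueError("observed and expected must be aligned")
    if np.any(y < 0) or np.any(e < 0):
        raise ValueError("Freeman-Tukey inputs must be non-negative")
    return float(np.sum((np.sqrt(y) - np.sqrt(e)) ** 2))


@dataclass
class PPCResult:
    """Posterior predictive check output."""

    t_obs: np.ndarray  # discrepancy of the observed data per draw
    t_rep: np.ndarray  # discrepancy of replicated data per draw
    bayesian_p: float  # Pr(T_rep >= T_obs)

    def __post_init__(self):
        if self.t_obs.shape != self.t_rep.shape:
            raise ValueError("t_obs and t_rep must have equal length")
        if not 0.0 <= self.bayesian_p <= 1.0:
            raise ValueError("bayesian_p outside [0, 1]")


def posterior_predictive_check(
    model, X: pd.DataFrame, y: np.ndarray, n_draws: int = 200, rng=None
) -> PPCResult:
    """Freeman-Tukey PPC against a fitted abundance or size model.

    For each retained posterior draw the model supplies the per-row expected
    value and a replicate dataset simulated from the full observation model
    (ZINB counts, or Gaussian log sizes); the Bayesian p-value is the
    fraction of draws with T_rep >= T_obs (ties favour the replicate side).
    """
    y = np.asarray(y, dtype=float)
    avail = model.samples_.n_chains * model.samples_.n_draws
    if n_draws > avail:
        warnings.warn(f"n_draws={n_draws} capped at {avail} retained draws", stacklevel=2)
        n_draws = avail
    y_rep, expected = model.replicate(X, n_draws=n_draws, rng=rng)
    return ppc_from_draws(y, y_rep, expected)


def ppc_from_draws(
    y: np.ndarray, y_rep: np.ndarray, expected: np.ndarray
) -> PPCResult:
    """PPC from precomputed replicate/expected draw matrices (draws x rows).

    All inputs must be non-negative: counts and expected counts for the
    abundance model, observed/replicated/expected sizes in m^2 for the size
    model.
    """
    if min(y.min(), y_rep.min(), expected.min()) < 0:
        raise ValueError("Freeman-Tukey PPC inputs must be non-negative")
    t_obs = np.sum((np.sqrt(y) - np.sqrt(expected)) ** 2, axis=1)
    t_rep = np.sum((np.sqrt(y_rep) - np.sqrt(expected)) ** 2, axis=1)
    return PPCResult(t_obs, t_rep, float(np.mean(t_rep >= t_obs)))


# --------------------------------------------------------- cross-validation


def kfold_cv(
    model,
    X: pd.DataFrame,
    y: np.ndarray,
    adjacency: dict,
    k: int = 5,
    scoring: str = "pearson",
    seed: int = 0,
) -> pd.DataFrame:
    """k-fold cross-validation of a (cloneable) abundance or size model.

    Rows are randomly permuted with ``seed`` then dealt into ``k`` folds
    whose sizes differ by at most one; each fold is predicted from a model
    fitted to the remaining folds.  Rows in coarse blocks absent from the
    training folds are predicted with the CAR field at its marginal mean.
    Returns per-fold in-sample and out-of-sample correlations plus a
    summary row with mean and (sample) SD across folds; a fold whose
    observations have zero variance scores NaN with a warning.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    y = np.asarray(y, dtype=float)
    n = len(X)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    fold_of = np.empty(n, dtype=int)
    fold_of[order] = np.arange(n) % k

    corr = stats.pearsonr if scoring == "pearson" else stats.spearmanr
    rows = []
    for fold in range(k):
        test = fold_of == fold
        train = ~test
        m = clone(model).fit(X.loc[train], y[train], adjacency=adjacency)
        train_blocks = set(X.loc[train, "block"]) if "block" in X.columns else set()
        unseen = (
            sorted(set(X.loc[test, "block"]) - train_blocks) if train_blocks else []
        )
        if unseen:
            logger.info("fold %d: blocks %s unseen in training; u at field mean", fold, unseen)
        rows.append(
            {
                "fold": fold,
                "n_test": int(test.sum()),
                "in_sample": _safe_corr(corr, y[train], m.predict(X.loc[train])),
                "out_of_sample": _safe_corr(corr, y[test], m.predict(X.loc[test])),
            }
        )
    res = pd.DataFrame(rows)
    summary = pd.DataFrame(
        [
            {
                "fold": "mean",
                "n_test": res["n_test"].sum(),
                "in_sample": res["in_sample"].mean(),
                "out_of_sample": res["out_of_sample"].mean(),
            },
            {
                "fold": "sd",
                "n_test": 0,
                "in_sample": res["in_sample"].std(ddof=1),
                "out_of_sample": res["out_of_sample"].std(ddof=1),
            },
        ]
    )
    return pd.concat([res, summary], ignore_index=True)


def _safe_corr(fn, obs, pred) -> float:
    if np.std(obs) == 0 or np.std(pred) == 0:
        warnings.warn("zero variance in a fold; correlation undefined", stacklevel=2)
        return float("nan")
    r = fn(obs, pred)
    return float(r[0] if isinstance(r, tuple) else r.statistic)
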