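"""Gridded seasonal prediction of abundance, size and surface availability.

Seasonal maps are built by pushing a per-cell covariate grid (typically
seasonal covariate means) through the posterior draws of the fitted models:
abundance as the expected FFA count per cell at a reference surveyed area
(one full cell, 16 km^2, by default), size as the back-transformed
lognormal location (m^2), and surface availability as their draw-wise
product (cumulative m^2).  Products are always taken draw-by-draw and only
then summarised — multiplying summaries would understate the tails.

Cells whose covariates fall outside the training range are flagged
(extrapolated=True); predictions there carry little value.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

QUANTILES = (0.025, 0.5, 0.975)


def _summarize(draws: np.ndarray, prefix: str) -> pd.DataFrame:
    lo, med, hi = np.quantile(draws, QUANTILES, axis=0)
    return pd.DataFrame({f"{prefix}": med, f"{prefix}_lo95": lo, f"{prefix}_hi95": hi})


def _extrapolation_flags(model, covariate_grid: pd.DataFrame) -> np.ndarray:
    """True where any standardized covariate leaves the training hull.

    The hull is approximated covariate-wise as +/- 4 training SDs (training
    covariates are standardized, so values beyond that did not occur)."""
    Xc = (
        covariate_grid[model.covariates_].to_numpy(dtype=float) - model.x_mean_
    ) / model.x_sd_
    return np.any(np.abs(Xc) > 4.0, axis=1)


def predict_abundance(
    model,
    covariate_grid: pd.DataFrame,
    season: str,
    reference_effort: float = 16.0,
    max_draws: int = 500,
) -> pd.DataFrame:
    """Seasonal abundance map: expected FFA count per cell.

    ``covariate_grid`` needs the fitted covariate columns and optionally
    ``block`` (cells in blocks unseen at fit time use the CAR field mean)
    and ``cell_id``.  ``reference_effort`` is the surveyed area (km^2) the
    prediction refers to — default one full 4 km cell, 16 km^2.
    """
    if reference_effort <= 0:
        raise ValueError("reference_effort must be positive")
    draws = abundance_draws(model, covariate_grid, season, reference_effort, max_draws)
    out = _summarize(draws, "abundance")
    out.insert(0, "season", season)
    if "cell_id" in covariate_grid.columns:
        out.insert(0, "cell_id", covariate_grid["cell_id"].to_numpy())
    out["extrapolated"] = _extrapolation_flags(model, covariate_grid)
    return out


def abundance_draws(
    model,
    covariate_grid: pd.DataFrame,
    season: str,
    reference_effort: float = 16.0,
    max_draws: int = 500,
) -> np.ndarray:
    """Posterior draws (draws x cells) of expected abundance at reference effort."""
    missing = [c for c in model.covariates_ if c not in covariate_grid.columns]
    if missing:
        raise ValueError(f"covariate grid lacks fitted column(s) {missing}")
    X = covariate_grid.copy()
    X["season"] = season
    X["effort_km2"] = float(reference_effort)
    return model.expected_draws(X, max_draws=max_draws)


def predict_size(
    model, covariate_grid: pd.DataFrame, max_draws: int = 500
) -> pd.DataFrame:
    """Size map: back-transformed aggregation surface area (m^2) per cell."""
    draws = size_draws(model, covariate_grid, max_draws)
    out = _summarize(draws, "size_m2")
    if "cell_id" in covariate_grid.columns:
        out.insert(0, "cell_id", covariate_grid["cell_id"].to_numpy())
    out["extrapolated"] = _extrapolation_flags(model, covariate_grid)
    return out


def size_draws(model, covariate_grid: pd.DataFrame, max_draws: int = 500) -> np.ndarray:
    missing = [c for c in model.covariates_ if c not in covariate_grid.columns]
    if missing:
        raise ValueError(f"covariate grid lacks fitted column(s) {missing}")
    return model.size_draws(covariate_grid, max_draws=max_draws)


def surface_availability(
    abundance: np.ndarray, size: np.ndarray
) -> pd.DataFrame:
    """Surface availability = abundance x size, combined draw-wise.

    ``abundance`` and ``size`` are draw matrices (draws x cells) over the
    same cells; the two models are fitted independently, so draws are
    paired by index after truncating to the shorter chain, preserving each
    posterior's spread without asserting cross-model correlation.
    Summaries are median and 95% CI of the per-draw product (cumulative
    m^2 per cell).
    """
    a = np.asarray(abundance, dtype=float)
    s = np.asarray(size, dtype=float)
    if a.ndim != 2 or s.ndim != 2 or a.shape[1] != s.shape[1]:
        raise ValueError("draw matrices must be (draws x cells) over the same cells")
    n = min(a.shape[0], s.shape[0])
    return _summarize(a[:n] * s[:n], "availability_m2")


def response_curve(
    model,
    covariate: str,
    observed_range: tuple[float, float],
    n_points: int = 50,
    season: str = "summer",
    reference_effort: float = 16.0,
    max_draws: int = 500,
) -> pd.DataFrame:
    """Environmental-gradient response of the fitted model to one covariate.

    The covariate sweeps ``observed_range`` (given on the raw covariate
    scale) over ``n_points`` equally spaced values; all other covariates sit
    at their training means, the CAR field at its marginal mean, and — for
    the abundance model — the season at ``season``.  Returns the median
    curve with a 95% credible band.
    """
    if covariate not in model.covariates_:
        raise ValueError(f"{covariate!r} is not a fitted covariate")
    xs = np.linspace(observed_range[0], observed_range[1], n_points)
    grid = pd.DataFrame(
        np.tile(model.x_mean_, (n_points, 1)), columns=model.covariates_
    )
    grid[covariate] = xs
    if hasattr(model, "size_draws"):  # size model
        draws = model.size_draws(grid, max_draws=max_draws)
        prefix = "size_m2"
    else:
        draws = abundance_draws(model, grid, season, reference_effort, max_draws)
        prefix = "abundance"
    out = _summarize(draws, prefix)
    out.insert(0, covariate, xs)
    return out
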