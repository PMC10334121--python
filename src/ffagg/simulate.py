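"""Synthetic seascape generator.

Emulates the statistical structure of an aerial strip-survey dataset of
surface forage-fish aggregations so the whole pipeline runs without any
external data: spatially smooth, partially cross-correlated environmental
covariates on the fine grid; parallel-strip survey footprints with partial
coverage (default 584 m strips, 7% coverage); counts from the full
generative model (CAR field, season-driven presence, Gamma-Poisson
overdispersion, effort offset); lognormal aggregation sizes with a second
CAR field; and planted community-type occurrence grids for the community
layer.  Everything is reproducible from (config, seed), and the true
parameters and latent fields are returned for recovery testing.

The default true parameters state a recoverable desk-scale world whose
seasonal presence ordering (summer >> autumn >> spring >> winter) mirrors
the strong seasonality of observed surface aggregations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import logit

from .car import car_sample, car_structure
from .grid import NestedGrid, build_nested_grid

#: covariate names of the aggregation models (static first, then dynamic)
COVARIATE_NAMES = (
    "bpi",
    "log_depth",
    "sediment",
    "chla",
    "chl_fprob",
    "fsle",
    "mld",
    "salinity",
    "sst_anom",
    "sst_fprob",
)
N_STATIC = 3

#: season presence probabilities stated by the default world
SEASON_PSI = {"summer": 0.7, "autumn": 0.5, "spring": 0.2, "winter": 0.05}


@dataclass
class SimulationConfig:
    """The stated synthetic world.

    Defaults give 2,500 fine 4-km cells in 25 coarse blocks (a 200 x 200 km
    extent with 10x10-cell blocks), eight surveys (two per season) of
    parallel 584-m strips at 7% coverage, ten smooth covariates (three
    static), and generative parameters: intercept -1, beta spanning
    [-1, 1], NB dispersion r = 1.5, CAR (gamma 0.8, tau 2), sigma_size 0.8,
    mean aggregation size exp(4.57) ~ 96.5 m^2, and seasonal presence
    summer 0.7 / autumn 0.5 / spring 0.2 / winter 0.05.
    """

    extent: tuple = (0.0, 0.0, 200.0, 200.0)
    fine_size: float = 4.0
    coarse_factor: int = 10
    n_covariates: int = len(COVARIATE_NAMES)
    smoothness_km: float = 16.0  # Gaussian correlation length of the fields
    cross_corr: tuple = ((0, 3, 0.5), (6, 7, 0.4))  # (i, j, target r) pairs
    surveys_per_season: int = 2
    coverage: float = 0.07
    strip_width_km: float = 0.584
    # generative truth
    intercept: float = -1.0
    beta: tuple = (-1.0, -0.5, 0.0, 0.5, 1.0, -0.75, -0.25, 0.25, 0.75, 0.5)
    r: float = 1.5
    gamma: float = 0.8
    tau_car: float = 2.0
    season_psi: dict = field(default_factory=lambda: dict(SEASON_PSI))
    size_intercept: float = float(np.log(96.5))
    beta_size: tuple = (0.5, -0.25, 0.75, -1.0, 0.25, 0.0, -0.5, 1.0, -0.75, 0.5)
    sigma_size: float = 0.8
    gamma2: float = 0.8
    tau_car2: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.coverage <= 1.0:
            raise ValueError("coverage must lie in (0, 1]")
        if self.r <= 0 or self.sigma_size <= 0 or self.tau_car <= 0 or self.tau_car2 <= 0:
            raise ValueError("r, sigma_size and CAR precisions must be positive")
        if len(self.beta) != self.n_covariates or len(self.beta_size) != self.n_covariates:
            raise ValueError("beta vectors must match n_covariates")

    @property
    def season_params(self) -> dict:
        """(alpha1, beta_sea) on the logit scale; summer is the reference."""
        a1 = float(logit(self.season_psi["summer"]))
        b = {s: float(logit(self.season_psi[s])) - a1 for s in ("autumn", "spring", "winter")}
        return {"alpha1": a1, "beta_sea": b}

    def grid(self) -> NestedGrid:
        return build_nested_grid(self.extent, self.fine_size, self.coarse_factor)


def _smooth_field(shape, sigma_cells, rng) -> np.ndarray:
    """Standardized Gaussian-smoothed white noise on the cell lattice."""
    f = gaussian_filter(rng.standard_normal(shape), sigma_cells, mode="wrap")
    return (f - f.mean()) / f.std()


def simulate_covariates(
    config: SimulationConfig,
    grid: NestedGrid | None = None,
    surveys: pd.DataFrame | None = None,
    include_collinear: bool = False,
) -> pd.DataFrame:
    """Smooth spatial covariates per cell (x survey for dynamic ones).

    Static covariates repeat across surveys; dynamic ones blend a
    persistent spatial component with an independent per-survey redraw in
    equal variance shares (sqrt(1/2) each), emulating daily fields without
    modelling ocean dynamics.  Requested cross-correlations are imposed by
    linear mixing on the persistent components.  With
    ``include_collinear=True`` an extra column nearly collinear with the
    first covariate is appended to exercise screening.

    Returns a tidy table: cell_id, survey_id (or the single label "static"
    if no surveys are given) and one column per covariate; fields are
    standardized to mean 0, sd 1 over cells.
    """
    grid = grid or config.grid()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    shape = (grid.ny, grid.nx)
    sigma = config.smoothness_km / grid.fine_size
    base = np.stack(
        [_smooth_field(shape, sigma, rng).ravel() for _ in range(config.n_covariates)]
    )
    # impose requested pairwise correlation on the persistent components
    for i, j, r in config.cross_corr:
        if not -1.0 < r < 1.0:
            raise ValueError(f"target correlation {r} for pair ({i},{j}) infeasible")
        mixed = r * base[i] + np.sqrt(1.0 - r**2) * base[j]
        base[j] = (mixed - mixed.mean()) / mixed.std()

    names = list(COVARIATE_NAMES[: config.n_covariates])
    if config.n_covariates > len(COVARIATE_NAMES):
        names += [f"cov{k}" for k in range(len(COVARIATE_NAMES), config.n_covariates)]

    survey_ids = ["static"] if surveys is None else list(surveys["survey_id"])
    frames = []
    for sid in survey_ids:
        vals = base.copy()
        if surveys is not None:
            for c in range(N_STATIC, config.n_covariates):
                redraw = _smooth_field(shape, sigma, rng).ravel()
                v = np.sqrt(0.5) * base[c] + np.sqrt(0.5) * redraw
                vals[c] = (v - v.mean()) / v.std()
        df = pd.DataFrame(vals.T, columns=names)
        df.insert(0, "survey_id", sid)
        df.insert(0, "cell_id", grid.fine_cell_ids)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    if include_collinear:
        noise = rng.standard_normal(len(out)) * 0.1
        out["collinear_with_bpi"] = out[names[0]] + noise
    return out


def simulate_surveys(config: SimulationConfig, grid: NestedGrid | None = None):
    """Seasonal strip surveys: per-survey metadata and per-cell effort.

    Each survey lays parallel North-South strips of width
    ``strip_width_km`` at a regular spacing chosen so the strip area is the
    coverage fraction of the extent, with a random phase per survey.
    Per-cell effort (km^2) is the exact strip-by-cell intersection area;
    strips are laid on a regular grid and never overlap, so no area is
    double-counted.

    Returns ``(surveys, effort)``: survey metadata (survey_id, season) and
    the effort table (cell_id, survey_id, effort_km2) for intersected cells.
    """
    grid = grid or config.grid()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 23]))
    xmin, ymin, xmax, ymax = grid.extent
    spacing = config.strip_width_km / config.coverage
    if spacing > (xmax - xmin):
        import warnings

        warnings.warn(
            "coverage target unattainable: strip spacing exceeds the extent; "
            "laying a single strip",
            stacklevel=2,
        )
        spacing = xmax - xmin
    seasons = [
        s for s in ("summer", "autumn", "spring", "winter")
        for _ in range(config.surveys_per_season)
    ]
    surveys = pd.DataFrame(
        {"survey_id": [f"S{i:02d}" for i in range(len(seasons))], "season": seasons}
    )
    edges = xmin + np.arange(grid.nx + 1) * grid.fine_size
    rows = []
    for sid in surveys["survey_id"]:
        phase = rng.uniform(0.0, spacing)
        starts = np.arange(xmin - spacing + phase, xmax, spacing)
        # overlap of each strip [s, s+w) with each cell column [e_i, e_{i+1})
        col_effort = np.zeros(grid.nx)
        for s in starts:
            lo = np.clip(s, edges[:-1], edges[1:])
            hi = np.clip(s + config.strip_width_km, edges[:-1], edges[1:])
            col_effort += np.maximum(hi - lo, 0.0)
        cells = np.flatnonzero(np.tile(col_effort, grid.ny) > 0)
        eff = np.tile(col_effort, grid.ny)[cells] * grid.fine_size
        rows.append(
            pd.DataFrame({"cell_id": cells, "survey_id": sid, "effort_km2": eff})
        )
    return surveys, pd.concat(rows, ignore_index=True)


def simulate_observations(
    config: SimulationConfig,
    covariates: pd.DataFrame,
    effort: pd.DataFrame,
    surveys: pd.DataFrame,
    grid: NestedGrid | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Forward-simulate counts and sizes from the full generative model.

    Per surveyed (cell, survey) row: psi from the survey's season, log
    theta = intercept + u1_block + x'beta, lambda = theta * effort,
    rho ~ Gamma(r, r), z ~ Bernoulli(psi), y ~ Poisson(lambda rho z); each
    of the y aggregations receives a size s ~ LogNormal(size_intercept +
    u2_block + x'beta_size, sigma_size).

    Returns ``(counts, sizes, truth)``; ``counts`` rows carry the
    covariates, season, effort and block (ready for fitting), ``truth``
    holds all parameters and latent fields.
    """
    grid = grid or config.grid()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 37]))
    structure = car_structure(grid.coarse_adjacency)
    u1 = car_sample(
        structure, 0.0, config.tau_car, config.gamma,
        rng=np.random.default_rng(np.random.SeedSequence([config.seed, 41])),
    )
    u2 = car_sample(
        structure, 0.0, config.tau_car2, config.gamma2,
        rng=np.random.default_rng(np.random.SeedSequence([config.seed, 43])),
    )

    names = [c for c in covariates.columns if c not in ("cell_id", "survey_id")][
        : config.n_covariates
    ]
    df = effort.merge(surveys, on="survey_id")
    key = "survey_id" if covariates["survey_id"].nunique() > 1 else None
    if key:
        df = df.merge(covariates, on=["cell_id", "survey_id"], how="left")
    else:
        df = df.merge(covariates.drop(columns="survey_id"), on="cell_id", how="left")
    if df[names].isna().any().any():
        raise ValueError("effort rows lack covariate values")
    df["block"] = grid.fine_to_coarse[df["cell_id"].to_numpy()]

    X = df[names].to_numpy(dtype=float)
    beta = np.asarray(config.beta, dtype=float)
    log_theta = config.intercept + X @ beta + u1[df["block"].to_numpy()]
    lam = np.exp(log_theta) * df["effort_km2"].to_numpy()
    psi = df["season"].map(config.season_psi).to_numpy(dtype=float)
    z = rng.random(len(df)) < psi
    rho = rng.gamma(config.r, 1.0 / config.r, size=len(df))
    y = rng.poisson(lam * rho * z)
    counts = df.copy()
    counts["count"] = y

    # one size per simulated aggregation, covariates from its (cell, survey)
    idx = np.repeat(np.arange(len(df)), y)
    beta_s = np.asarray(config.beta_size, dtype=float)
    mu = (
        config.size_intercept
        + X[idx] @ beta_s
        + u2[df["block"].to_numpy()[idx]]
    )
    s = np.exp(mu + config.sigma_size * rng.standard_normal(idx.size))
    sizes = df.iloc[idx][["cell_id", "survey_id", "season", "block"] + names].reset_index(
        drop=True
    )
    sizes.insert(0, "aggregation_id", np.arange(idx.size))
    sizes["area_m2"] = s
    sizes["log_area"] = np.log(s)

    truth = {
        "intercept": config.intercept,
        "beta": dict(zip(names, beta)),
        "r": config.r,
        "gamma": config.gamma,
        "tau_car": config.tau_car,
        "u1": u1,
        "alpha1": config.season_params["alpha1"],
        "beta_sea": config.season_params["beta_sea"],
        "size_intercept": config.size_intercept,
        "beta_size": dict(zip(names, beta_s)),
        "sigma_size": config.sigma_size,
        "gamma2": config.gamma2,
        "tau_car2": config.tau_car2,
        "u2": u2,
        "covariates": names,
    }
    return counts, sizes, truth


def simulate_dataset(config: SimulationConfig):
    """Convenience: grid, covariates, surveys, effort, counts, sizes, truth."""
    grid = config.grid()
    surveys, effort = simulate_surveys(config, grid)
    covariates = simulate_covariates(config, grid, surveys)
    counts, sizes, truth = simulate_observations(config, covariates, effort, surveys, grid)
    return {
        "grid": grid,
        "surveys": surveys,
        "effort": effort,
        "covariates": covariates,
        "counts": counts,
        "sizes": sizes,
        "truth": truth,
    }


def simulate_occurrence_grid(
    config: SimulationConfig,
    n_species: int = 14,
    n_types: int = 4,
    separation: float = 2.0,
    grid: NestedGrid | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Planted community-type occurrence grid with true labels.

    Cells are split into ``n_types`` spatially contiguous regions (k-means
    on cell coordinates); each type gets species prevalences
    expit(a_s + separation * b_ts) with a_s, b_ts standard normal, and the
    per-cell probabilities jitter around them (sd 0.03), clipped to
    [0.001, 0.999].  ``separation`` = 0 makes the types indistinguishable.
    """
    if n_types < 2:
        raise ValueError("n_types must be >= 2")
    from scipy.special import expit
    from sklearn.cluster import KMeans

    grid = grid or config.grid()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 53]))
    km = KMeans(n_clusters=n_types, n_init=5, random_state=config.seed).fit(
        grid.fine_cell_centers
    )
    labels = km.labels_
    a = rng.standard_normal(n_species)
    b = rng.standard_normal((n_types, n_species))
    prev = expit(a[None, :] + separation * b)
    P = prev[labels] + 0.03 * rng.standard_normal((grid.n_cells, n_species))
    P = np.clip(P, 0.001, 0.999)
    occ = pd.DataFrame(P, columns=[f"sp{k:02d}" for k in range(n_species)])
    occ.insert(0, "cell_id", grid.fine_cell_ids)
    return occ, labels
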