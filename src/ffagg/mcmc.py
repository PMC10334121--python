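"""Generic MCMC plumbing shared by the abundance and size samplers.

The samplers are Metropolis-within-Gibbs: fixed-effect blocks move under an
adaptive random-walk Metropolis kernel (Haario empirical covariance with
Robbins-Monro step-size tuning toward the 0.234/0.44 optimal acceptance
rates), variance-type parameters are Gibbs steps where conjugate, and the
CAR field updates block-by-block in graph-colour sweeps so that
conditionally independent blocks move simultaneously.

Adaptation uses diminishing step sizes (gain ~ t^-0.6), which preserves the
correct stationary distribution (diminishing adaptation + bounded
convergence conditions of adaptive MCMC).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class PosteriorSamples:
    """Labelled MCMC draws with shape (chain, draw, parameter).

    ``meta`` records the run protocol (iterations, burn-in, thinning, seed,
    model tag) so downstream summaries are self-describing.
    """

    values: np.ndarray  # (n_chains, n_draws, n_params)
    param_names: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be (chain, draw, parameter)")
        if self.values.shape[2] != len(self.param_names):
            raise ValueError("param_names length must match the parameter axis")
        self._index = {name: i for i, name in enumerate(self.param_names)}

    @property
    def n_chains(self) -> int:
        return self.values.shape[0]

    @property
    def n_draws(self) -> int:
        return self.values.shape[1]

    def get(self, name: str) -> np.ndarray:
        """Draws of one parameter, shape (chain, draw)."""
        return self.values[:, :, self._index[name]]

    def flat(self, name: str) -> np.ndarray:
        """Draws of one parameter pooled over chains."""
        return self.get(name).ravel()

    def stacked(self, names: list[str]) -> np.ndarray:
        """Pooled draws of several parameters, shape (total_draws, len(names))."""
        idx = [self._index[n] for n in names]
        return self.values[:, :, idx].reshape(-1, len(idx))

    def select(self, prefix: str) -> list[str]:
        return [n for n in self.param_names if n.startswith(prefix)]

    def to_frame(self) -> pd.DataFrame:
        """Tidy (chain, iteration, parameter, value) table."""
        n_c, n_d, n_p = self.values.shape
        return pd.DataFrame(
            {
                "chain": np.repeat(np.arange(n_c), n_d * n_p),
                "iteration": np.tile(np.repeat(np.arange(n_d), n_p), n_c),
                "parameter": np.tile(self.param_names, n_c * n_d),
                "value": self.values.ravel(),
            }
        )

    def thin_to(self, n: int) -> "PosteriorSamples":
        """Subsample at most ``n`` evenly spaced draws per chain."""
        if self.n_draws <= n:
            return self
        idx = np.linspace(0, self.n_draws - 1, n).astype(int)
        return PosteriorSamples(self.values[:, idx, :], self.param_names, dict(self.meta))


def summarize_effects(
    samples: PosteriorSamples, names: list[str] | None = None
) -> pd.DataFrame:
    """Quantile summary of fixed effects with a 95%-CI significance flag.

    Returns one row per parameter with the posterior median, 50% and 95%
    credible intervals, and ``significant`` true iff the 95% interval
    excludes zero.
    """
    if samples.n_chains * samples.n_draws < 100:
        raise ValueError("need at least 100 retained draws to summarise")
    names = list(names) if names is not None else list(samples.param_names)
    qs = [0.025, 0.25, 0.5, 0.75, 0.975]
    rows = []
    for name in names:
        v = samples.flat(name)
        q = np.quantile(v, qs)
        rows.append(
            {
                "parameter": name,
                "median": q[2],
                "ci50_lo": q[1],
                "ci50_hi": q[3],
                "ci95_lo": q[0],
                "ci95_hi": q[4],
                "significant": bool(q[0] > 0 or q[4] < 0),
            }
        )
    return pd.DataFrame(rows)


class AdaptiveBlock:
    """Adaptive random-walk Metropolis kernel for one parameter block."""

    def __init__(self, dim: int, init_scale: float = 0.1, target: float | None = None):
        self.dim = dim
        self.target = target if target is not None else (0.44 if dim == 1 else 0.234)
        self.log_scale = np.log(init_scale)
        self.mean = np.zeros(dim)
        self.cov = np.eye(dim)
        self._chol = np.eye(dim)
        self.t = 0

    def propose(self, x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        z = rng.standard_normal(self.dim)
        return x + np.exp(self.log_scale) * (self._chol @ z)

    def adapt(self, x: np.ndarray, accepted: float) -> None:
        self.t += 1
        g = (self.t + 10.0) ** -0.6
        self.log_scale += g * (accepted - self.target)
        d = x - self.mean
        self.mean += g * d
        self.cov += g * (np.outer(d, d) - self.cov)
        if self.t % 50 == 0 and self.t >= 100:
            try:
                self._chol = np.linalg.cholesky(
                    self.cov + 1e-9 * np.eye(self.dim)
                )
            except np.linalg.LinAlgError:
                pass


class ScalarAdaptive(AdaptiveBlock):
    """Univariate adaptive random-walk kernel."""

    def __init__(self, init_scale: float = 0.1):
        super().__init__(1, init_scale, target=0.44)

    def propose_scalar(self, x: float, rng: np.random.Generator) -> float:
        return x + np.exp(self.log_scale) * rng.standard_normal()

    def adapt_scalar(self, accepted: float) -> None:
        self.t += 1
        g = (self.t + 10.0) ** -0.6
        self.log_scale += g * (accepted - self.target)


def graph_colors(adjacency: dict[int, list[int]]) -> list[np.ndarray]:
    """Greedy colouring of the block graph into independent sets.

    Blocks of one colour share no edge, so their CAR full conditionals are
    mutually independent given the rest and can be updated in one
    vectorised sweep (two colours on a rook lattice).
    """
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(adjacency)
    for k, nbrs in adjacency.items():
        g.add_edges_from((k, l) for l in nbrs)
    coloring = nx.coloring.greedy_color(g, strategy="largest_first")
    n_colors = max(coloring.values()) + 1
    return [
        np.array(sorted(k for k, c in coloring.items() if c == col), dtype=int)
        for col in range(n_colors)
    ]


def spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Independent per-chain generators from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(s) for s in ss.spawn(n)]
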