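"""Proper Gaussian conditional autoregressive (CAR) model on an areal graph.

The coarse blocks of the nested grid carry a spatially correlated random
effect u ~ MVN(mu, Sigma) with Sigma = (I - gamma C)^{-1} M / tau, where C
is the row-normalised binary contiguity matrix (c_kl = w_kl / m_k), M is
the diagonal of conditional variances (M_kk = 1/m_k), tau > 0 a precision
scalar and gamma the degree of spatial dependence.  The precision

    Q = tau * M^{-1} (I - gamma C) = tau * (D - gamma W)

with D = diag(m) and W the binary adjacency matrix is symmetric, and is
positive definite exactly when gamma lies strictly between the reciprocal
extreme eigenvalues of D^{-1/2} W D^{-1/2}; the upper bound is always 1.

Blocks with no neighbours make M_kk = 1/m_k undefined; they are modelled as
independent N(mu, 1/tau) (a warning is issued once at structure build).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse


@dataclass
class CARStructure:
    """Precomputed graph quantities for a proper CAR distribution."""

    n_blocks: int
    neighbors: dict[int, list[int]]
    m: np.ndarray  # neighbour counts
    W: sparse.csr_matrix = field(repr=False)  # binary adjacency
    d_eff: np.ndarray = field(repr=False)  # diag(D) with isolated blocks -> 1
    eigs: np.ndarray = field(repr=False)  # eigenvalues of D^{-1/2} W D^{-1/2}
    gamma_bounds: tuple[float, float] = (0.0, 0.0)
    isolated: np.ndarray = field(default=None, repr=False)

    @property
    def C(self) -> sparse.csr_matrix:
        """Row-normalised weight matrix (rows of isolated blocks are zero)."""
        inv_m = np.where(self.m > 0, 1.0 / np.maximum(self.m, 1), 0.0)
        return sparse.diags(inv_m) @ self.W

    @property
    def M_diag(self) -> np.ndarray:
        """Conditional variances 1/m_k (1 for isolated blocks)."""
        return 1.0 / self.d_eff

    def precision(self, tau: float, gamma: float) -> sparse.csr_matrix:
        """Sparse precision Q = tau (D_eff - gamma W)."""
        return tau * (sparse.diags(self.d_eff) - gamma * self.W).tocsr()

    def logdet_precision(self, tau: float, gamma: float) -> float:
        """log det Q from the precomputed spectrum (O(n))."""
        # det(D - gamma W) = det(D) * prod(1 - gamma * eigs); isolated blocks
        # contribute their unit diagonal through d_eff and a zero eigenvalue.
        return float(
            self.n_blocks * np.log(tau)
            + np.log(self.d_eff).sum()
            + np.log1p(-gamma * self.eigs).sum()
        )

    def quad_form(self, u: np.ndarray, mu: float | np.ndarray) -> float:
        """(u - mu)' (D_eff - gamma W)/gamma-free pieces: returns (r'Dr, r'Wr)."""
        r = np.asarray(u, dtype=float) - mu
        return float(r @ (self.d_eff * r)), float(r @ (self.W @ r))


def car_structure(adjacency: dict[int, list[int]]) -> CARStructure:
    """Build the CAR structure from symmetric, irreflexive neighbour lists."""
    n = len(adjacency)
    if n == 0:
        raise ValueError("empty adjacency")
    keys = sorted(adjacency)
    if keys != list(range(n)):
        raise ValueError("adjacency keys must be 0..n-1")
    rows, cols = [], []
    for k, nbrs in adjacency.items():
        for l in nbrs:
            if l == k:
                raise ValueError(f"self-loop at block {k}")
            if k not in adjacency[l]:
                raise ValueError(f"asymmetric adjacency between {k} and {l}")
            rows.append(k)
            cols.append(l)
    W = sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    )
    m = np.asarray(W.sum(axis=1)).ravel()
    isolated = m == 0
    if isolated.any():
        warnings.warn(
            f"{int(isolated.sum())} isolated block(s) with no neighbours; "
            "modelled as independent N(mu, 1/tau)",
            stacklevel=2,
        )
    d_eff = np.where(isolated, 1.0, m)
    # spectrum of D_eff^{-1/2} W D_eff^{-1/2}; largest eigenvalue is 1 for any
    # non-trivial component, so the propriety interval is (1/min_eig, 1)
    s = 1.0 / np.sqrt(d_eff)
    A = (W.multiply(np.outer(s, s))).toarray()
    eigs = np.linalg.eigvalsh(A)
    lo = 1.0 / eigs[0] if eigs[0] < 0 else -np.inf
    hi = 1.0 / eigs[-1] if eigs[-1] > 0 else np.inf
    return CARStructure(
        n_blocks=n,
        neighbors={k: sorted(v) for k, v in adjacency.items()},
        m=m,
        W=W,
        d_eff=d_eff,
        eigs=eigs,
        gamma_bounds=(float(lo), float(hi)),
        isolated=isolated,
    )


def _check_params(structure: CARStructure, tau: float, gamma: float) -> None:
    if tau <= 0:
        raise ValueError(f"tau must be positive, got {tau}")
    lo, hi = structure.gamma_bounds
    if not (lo < gamma < hi):
        raise ValueError(
            f"gamma={gamma} outside the propriety interval ({lo:.4f}, {hi:.4f})"
        )


def car_logpdf(
    u: np.ndarray,
    structure: CARStructure,
    mu: float | np.ndarray = 0.0,
    tau: float = 1.0,
    gamma: float = 0.0,
) -> float:
    """Log-density (nats) of a proper CAR field evaluated via the sparse precision."""
    u = np.asarray(u, dtype=float)
    if u.shape != (structure.n_blocks,):
        raise ValueError(f"u must have shape ({structure.n_blocks},), got {u.shape}")
    _check_params(structure, tau, gamma)
    r = u - mu
    quad = tau * (r @ (structure.d_eff * r) - gamma * (r @ (structure.W @ r)))
    return 0.5 * (
        structure.logdet_precision(tau, gamma)
        - structure.n_blocks * np.log(2.0 * np.pi)
        - quad
    )


def car_sample(
    structure: CARStructure,
    mu: float | np.ndarray = 0.0,
    tau: float = 1.0,
    gamma: float = 0.0,
    size: int = 1,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Exact draw(s) from the CAR field via Cholesky of the precision.

    Returns an array of shape ``(n_blocks,)`` for ``size=1`` else
    ``(size, n_blocks)``.  Reproducible for a fixed seed.
    """
    _check_params(structure, tau, gamma)
    rng = np.random.default_rng(rng)
    Q = structure.precision(tau, gamma).toarray()
    L = np.linalg.cholesky(Q)
    z = rng.standard_normal((structure.n_blocks, size))
    # solve L' x = z  =>  cov(x) = Q^{-1}
    x = np.linalg.solve(L.T, z).T + mu
    return x[0] if size == 1 else x
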