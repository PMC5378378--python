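"""Hopfield binary network: Hebbian couplings, Glauber Monte Carlo, descent.

The model is the classic binary recurrent network: N units sigma_i = +/-1,
Hebbian couplings built from P stored patterns xi^mu,

    J_ij = (1/N) sum_mu xi_i^mu xi_j^mu   (i != j, J_ii = 0),

with energy H[sigma] = -(1/2) sigma^T J sigma and Gibbs equilibrium
p(sigma) ~ exp(-beta H[sigma]).  Under this normalization the critical
inverse temperature of the pure model is beta_c ~= 1, so beta = 0.83 sits in
the disordered (high-temperature) regime and beta = 1.3 in the ordered one.
With a few stored patterns at small N the landscape is glassy: many local
minima are mixtures or states uncorrelated with the patterns.

Sampling uses single-spin-flip Glauber (heat-bath) dynamics with random
sequential site selection; one Monte Carlo sweep (MCS) = N attempted flips.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .data import BinaryStateSeries

__all__ = [
    "PatternSet",
    "CouplingMatrix",
    "MCConfig",
    "generate_patterns",
    "hebbian_matrix",
    "energy",
    "local_fields",
    "simulate_mc",
    "overlap",
    "hamming",
    "zero_temperature_descent",
    "descend_many",
    "basin_check",
    "BasinReport",
]


@dataclass
class PatternSet:
    """P x N matrix of +/-1 stored patterns."""

    patterns: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.patterns)
        if arr.ndim != 2:
            raise ValueError("patterns must be a P x N matrix")
        if arr.size and not np.isin(np.unique(arr), (-1, 1)).all():
            raise ValueError("pattern entries must be +1 or -1")
        self.patterns = np.ascontiguousarray(arr, dtype=np.int8)

    @property
    def P(self) -> int:
        return self.patterns.shape[0]

    @property
    def N(self) -> int:
        return self.patterns.shape[1]


@dataclass
class CouplingMatrix:
    """Square matrix of pairwise couplings with zero diagonal."""

    J: np.ndarray
    symmetric: bool = True

    def __post_init__(self) -> None:
        J = np.asarray(self.J, dtype=np.float64)
        if J.ndim != 2 or J.shape[0] != J.shape[1]:
            raise ValueError("J must be square")
        if self.symmetric and not np.allclose(J, J.T):
            raise ValueError("J declared symmetric but is not")
        self.J = J

    @property
    def N(self) -> int:
        return self.J.shape[0]


@dataclass
class MCConfig:
    """Monte Carlo settings: inverse temperature, recorded sweeps, burn-in."""

    beta: float
    steps: int
    burn_in: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.steps <= 0:
            raise ValueError("steps must be positive")
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")


def generate_patterns(N: int, P: int, seed: int) -> PatternSet:
    """Draw P random uncorrelated +/-1 patterns of N spins."""
    if N < 1:
        raise ValueError("N must be >= 1")
    if P < 0:
        raise ValueError("P must be >= 0")
    rng = np.random.default_rng(seed)
    patterns = rng.choice(np.array([-1, 1], dtype=np.int8), size=(P, N))
    return PatternSet(patterns, seed=seed)


def hebbian_matrix(patterns: PatternSet) -> CouplingMatrix:
    """Hebbian couplings J_ij = (1/N) sum_mu xi_i xi_j with zero diagonal."""
    if patterns.P < 1:
        raise ValueError("need at least one pattern")
    xi = patterns.patterns.astype(np.float64)
    J = xi.T @ xi / patterns.N
    np.fill_diagonal(J, 0.0)
    return CouplingMatrix(J, symmetric=True)


def energy(state: np.ndarray, J: CouplingMatrix | np.ndarray) -> float:
    """Ising energy H[sigma] = -(1/2) sigma^T J sigma (zero-diagonal J)."""
    Jm = J.J if isinstance(J, CouplingMatrix) else np.asarray(J, dtype=np.float64)
    s = np.asarray(state, dtype=np.float64).ravel()
    if s.shape[0] != Jm.shape[0]:
        raise ValueError("state length does not match coupling matrix size")
    return float(-0.5 * s @ Jm @ s)


def local_fields(state: np.ndarray, J: CouplingMatrix | np.ndarray) -> np.ndarray:
    """h_i = sum_j J_ij sigma_j; flipping spin i changes H by 2 sigma_i h_i."""
    Jm = J.J if isinstance(J, CouplingMatrix) else np.asarray(J, dtype=np.float64)
    return Jm @ np.asarray(state, dtype=np.float64).ravel()


@njit(cache=True)
def _glauber_run(J, state, beta, n_sweeps, record_from, sites, uniforms, out):
    N = state.shape[0]
    h = J @ state.astype(np.float64)
    k = 0
    rec = 0
    for sweep in range(n_sweeps):
        for _ in range(N):
            i = sites[k]
            u = uniforms[k]
            k += 1
            # heat-bath: resample sigma_i from its conditional
            p_plus = 1.0 / (1.0 + np.exp(-2.0 * beta * h[i]))
            new = 1 if u < p_plus else -1
            if new != state[i]:
                delta = 2.0 * new  # new - old
                state[i] = new
                for j in range(N):
                    h[j] += J[j, i] * delta
                h[i] -= J[i, i] * delta  # J_ii = 0 guard
        if sweep >= record_from:
            out[rec] = state
            rec += 1
    return state


def simulate_mc(
    J: CouplingMatrix,
    cfg: MCConfig,
    initial_state: np.ndarray | None = None,
) -> BinaryStateSeries:
    """Sample the Gibbs distribution exp(-beta H) by Glauber dynamics.

    Records one row per sweep after discarding ``cfg.burn_in`` sweeps.
    Reproducible for a fixed seed.
    """
    N = J.N
    rng = np.random.default_rng(cfg.seed)
    if initial_state is None:
        state = rng.choice(np.array([-1, 1], dtype=np.int8), size=N)
    else:
        state = np.ascontiguousarray(initial_state, dtype=np.int8).copy()
        if state.shape[0] != N:
            raise ValueError("initial state length mismatch")
    n_sweeps = cfg.burn_in + cfg.steps
    sites = rng.integers(0, N, size=n_sweeps * N).astype(np.int64)
    uniforms = rng.random(n_sweeps * N)
    out = np.empty((cfg.steps, N), dtype=np.int8)
    _glauber_run(
        np.ascontiguousarray(J.J), state, float(cfg.beta), n_sweeps, cfg.burn_in, sites, uniforms, out
    )
    return BinaryStateSeries(out, bin_duration=1.0, origin=f"hopfield beta={cfg.beta} seed={cfg.seed}")


def overlap(a: np.ndarray, b: np.ndarray) -> float:
    """q = (1/N) sum_i a_i b_i; relates to Hamming distance by q = 1 - 2h/N."""
    a = np.asarray(a).ravel()
    b = np.asarray(b).ravel()
    if a.shape != b.shape:
        raise ValueError("overlap requires equal-length vectors")
    return float(np.dot(a.astype(np.float64), b.astype(np.float64)) / a.shape[0])


def hamming(a: np.ndarray, b: np.ndarray) -> int:
    """Number of coordinates where the two +/-1 vectors differ."""
    a = np.asarray(a).ravel()
    b = np.asarray(b).ravel()
    if a.shape != b.shape:
        raise ValueError("hamming requires equal-length vectors")
    return int(np.count_nonzero(a != b))


@njit(cache=True)
def _descent(J, state, max_sweeps, perm_buffer):
    """Strict zero-temperature descent; returns number of sweeps used (-1 if not converged)."""
    N = state.shape[0]
    h = J @ state.astype(np.float64)
    for sweep in range(max_sweeps):
        changed = False
        for idx in range(N):
            i = perm_buffer[sweep % perm_buffer.shape[0], idx]
            # flipping i changes H by 2 sigma_i h_i; accept only strict decreases
            if state[i] * h[i] < 0.0:
                delta = -2.0 * state[i]  # new - old
                state[i] = -state[i]
                for j in range(N):
                    h[j] += J[j, i] * delta
                h[i] -= J[i, i] * delta
                changed = True
        if not changed:
            return sweep + 1
    return -1


def zero_temperature_descent(
    state: np.ndarray,
    J: CouplingMatrix | np.ndarray,
    max_sweeps: int = 200,
    seed: int = 0,
) -> tuple[np.ndarray, bool]:
    """Deterministic (zero-temperature) dynamics to a local energy minimum.

    Spins are visited in random sequential order; a spin is flipped only when
    the flip strictly lowers the energy, so the dynamics terminates at a local
    minimum (ties are rejected).  Returns ``(final_state, converged)``.
    """
    Jm = np.ascontiguousarray(J.J if isinstance(J, CouplingMatrix) else J, dtype=np.float64)
    s = np.ascontiguousarray(state, dtype=np.int8).copy()
    if s.shape[0] != Jm.shape[0]:
        raise ValueError("state length does not match coupling matrix size")
    rng = np.random.default_rng(seed)
    n_perms = min(max_sweeps, 64)
    perms = np.empty((n_perms, s.shape[0]), dtype=np.int64)
    for p in range(n_perms):
        perms[p] = rng.permutation(s.shape[0])
    n = _descent(Jm, s, max_sweeps, perms)
    return s, n >= 0


@njit(cache=True)
def _descend_many(J, states, max_sweeps, perms):
    n_states, N = states.shape
    conv = np.ones(n_states, dtype=np.bool_)
    for k in range(n_states):
        n = _descent(J, states[k], max_sweeps, perms[k])
        if n < 0:
            conv[k] = False
    return conv


def descend_many(
    states: np.ndarray, J: CouplingMatrix | np.ndarray, max_sweeps: int = 200, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized zero-temperature descent of many configurations."""
    Jm = np.ascontiguousarray(J.J if isinstance(J, CouplingMatrix) else J, dtype=np.float64)
    out = np.ascontiguousarray(states, dtype=np.int8).copy()
    rng = np.random.default_rng(seed)
    n_perm = 16
    perms = np.empty((out.shape[0], n_perm, out.shape[1]), dtype=np.int64)
    base = np.arange(out.shape[1])
    for k in range(out.shape[0]):
        for p in range(n_perm):
            perms[k, p] = rng.permutation(base)
    conv = _descend_many(Jm, out, max_sweeps, perms)
    return out, conv


@dataclass
class BasinReport:
    """Per-cluster and pooled zero-temperature flow statistics."""

    per_cluster: np.ndarray  # success fraction per cluster
    cluster_sizes: np.ndarray
    pooled_mean: float  # mean over clusters
    pooled_sd: float  # dispersion over clusters
    excluded_clusters: list


def basin_check(
    series: BinaryStateSeries,
    clusters,
    J: CouplingMatrix | np.ndarray,
    seed: int = 0,
    max_sweeps: int = 200,
) -> BasinReport:
    """Do clusters behave like attractor basins?

    For every configuration assigned to a cluster, run the zero-temperature
    descent and count a success when the overlap between the descent endpoint
    and the assigned centroid strictly exceeds the initial overlap.  Reports
    the success fraction per cluster and its mean +/- sd across clusters.
    Samples left unassigned by mass filtering are excluded.
    """
    states = series.states
    assign = np.asarray(clusters.assignments)
    if assign.shape[0] != states.shape[0]:
        raise ValueError("cluster assignments do not cover the series")
    centroids = np.asarray(clusters.centroids, dtype=np.int8)
    mask = assign >= 0
    sub = states[mask]
    sub_assign = assign[mask]

    # identical (configuration, cluster) pairs descend identically: dedup
    keyed = np.concatenate([sub, sub_assign[:, None].astype(np.int8)], axis=1)
    uniq, inverse, counts = np.unique(keyed, axis=0, return_inverse=True, return_counts=True)
    u_states = np.ascontiguousarray(uniq[:, :-1], dtype=np.int8)
    u_assign = uniq[:, -1].astype(np.int64)

    finals, _ = descend_many(u_states, J, max_sweeps=max_sweeps, seed=seed)
    N = states.shape[1]
    cent = centroids[u_assign].astype(np.float64)
    q0 = np.einsum("ij,ij->i", u_states.astype(np.float64), cent) / N
    q1 = np.einsum("ij,ij->i", finals.astype(np.float64), cent) / N
    success = q1 > q0

    n_clusters = centroids.shape[0]
    frac = np.full(n_clusters, np.nan)
    sizes = np.zeros(n_clusters, dtype=np.int64)
    excluded = []
    for c in range(n_clusters):
        sel = u_assign == c
        w = counts[sel]
        if w.sum() == 0:
            excluded.append(c)
            continue
        sizes[c] = w.sum()
        frac[c] = float(np.sum(success[sel] * w) / w.sum())
    valid = ~np.isnan(frac)
    pooled_mean = float(np.mean(frac[valid])) if valid.any() else float("nan")
    pooled_sd = float(np.std(frac[valid])) if valid.any() else float("nan")
    return BasinReport(frac, sizes, pooled_mean, pooled_sd, excluded)
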