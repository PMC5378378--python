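"""Seeded synthetic datasets used throughout the tests and examples.

Each generator produces a dataset with a known ground truth, so every
pipeline stage has an oracle to be checked against: planted clusters for the
mean-shift recovery tests, exactly enumerable small Ising models for the
inference consistency tests, and first-/second-order Markov label chains for
the complexity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import BinaryStateSeries
from .hopfield import CouplingMatrix
from .symbolic_dynamics import LabelSequence

__all__ = [
    "planted_clusters",
    "small_ising_exact",
    "enumerate_gibbs",
    "markov_chain_fixture",
    "second_order_chain",
]


def planted_clusters(
    n_patterns: int = 2,
    n_units: int = 50,
    copies: int = 100,
    flip_prob: float = 0.05,
    seed: int = 0,
) -> tuple[BinaryStateSeries, np.ndarray, np.ndarray]:
    """Noisy copies of random planted +/-1 patterns.

    Returns (series, planted_patterns, true_labels); rows are shuffled so the
    planted groups are not contiguous in time.
    """
    rng = np.random.default_rng(seed)
    patterns = rng.choice(np.array([-1, 1], dtype=np.int8), size=(n_patterns, n_units))
    states = np.repeat(patterns, copies, axis=0).copy()
    flips = rng.random(states.shape) < flip_prob
    states[flips] = -states[flips]
    labels = np.repeat(np.arange(n_patterns), copies)
    perm = rng.permutation(states.shape[0])
    return (
        BinaryStateSeries(states[perm], origin="planted clusters"),
        patterns,
        labels[perm],
    )


def enumerate_gibbs(J: np.ndarray, beta: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """All 2^N states and their exact Boltzmann probabilities (N <= 20).

    Uses H = -(1/2) sigma^T J sigma.  Returns (states, probabilities).
    """
    J = J.J if isinstance(J, CouplingMatrix) else np.asarray(J, dtype=float)
    N = J.shape[0]
    if N > 20:
        raise ValueError("exact enumeration limited to N <= 20")
    states = np.array(
        [[1 if (s >> i) & 1 else -1 for i in range(N)] for s in range(2**N)], dtype=np.int8
    )
    X = states.astype(np.float64)
    H = -0.5 * np.einsum("si,ij,sj->s", X, J, X)
    logw = -beta * H
    logw -= logw.max()
    w = np.exp(logw)
    return states, w / w.sum()


def small_ising_exact(
    N: int = 4, beta: float = 1.0, n_samples: int = 5000, seed: int = 0, J: np.ndarray | None = None
) -> tuple[BinaryStateSeries, np.ndarray, np.ndarray, np.ndarray]:
    """iid samples from an exactly enumerable Ising model.

    Returns (series, J, states, probabilities) so tests can compare sample
    frequencies with the enumerated Boltzmann weights.
    """
    rng = np.random.default_rng(seed)
    if J is None:
        J = rng.normal(0, 1.0 / np.sqrt(N), size=(N, N))
        J = (J + J.T) / 2
        np.fill_diagonal(J, 0.0)
    states, p = enumerate_gibbs(J, beta)
    idx = rng.choice(states.shape[0], size=n_samples, p=p)
    return BinaryStateSeries(states[idx], origin="small ising"), J, states, p


def markov_chain_fixture(
    K: int = 4, length: int = 10000, seed: int = 0, concentration: float = 1.0
) -> tuple[LabelSequence, np.ndarray]:
    """A first-order Markov label sequence with a random transition matrix."""
    rng = np.random.default_rng(seed)
    P = rng.dirichlet(np.full(K, concentration), size=K)
    labels = np.empty(length, dtype=np.int64)
    labels[0] = rng.integers(K)
    cum = np.cumsum(P, axis=1)
    u = rng.random(length)
    for t in range(1, length):
        labels[t] = np.searchsorted(cum[labels[t - 1]], u[t])
    return LabelSequence(labels, K), P


def second_order_chain(
    length: int = 10000, seed: int = 0, memory: float = 0.9
) -> LabelSequence:
    """A binary chain whose next symbol depends on the symbol two steps back.

    ``memory`` in [0.5, 1): probability of repeating the symbol at t-2; at
    0.5 the chain is iid, approaching 1 the second-order dependence is
    strong while the first-order transition matrix stays near uniform.
    """
    rng = np.random.default_rng(seed)
    lab = np.empty(length, dtype=np.int64)
    lab[0], lab[1] = rng.integers(2, size=2)
    u = rng.random(length)
    for t in range(2, length):
        lab[t] = lab[t - 2] if u[t] < memory else 1 - lab[t - 2]
    return LabelSequence(lab, 2)
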