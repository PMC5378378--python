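"""Symbolic dynamics in centroid space and its complexity.

Once a multichannel binary time series has been clustered, each time bin can
be replaced by the label of the centroid its state vector belongs to; the
multidimensional dynamics becomes a symbolic sequence.  This module estimates
Markov transition structure from such sequences, generates memoryless
surrogates with the same transition probabilities, and quantifies memory
beyond first order through the normalized Lempel-Ziv (LZ76) complexity

    C_LZ = S_LZ * log|S| / ( |S| * log|A| ),

where S_LZ is the phrase count of the LZ76 exhaustive-history parsing, |S|
the sequence length and |A| the alphabet size (C_LZ -> 1 for long iid uniform
sequences), and the relative complexity index

    R = ( <C_LZ^Markov> - C_LZ^sample ) / <C_LZ^Markov>,

the relative complexity deficit of the sample with respect to the average of
its Markov surrogates.  R ~ 0 for a memoryless sequence; R > 0 signals
history dependence (e.g. spike-frequency adaptation in the generating
network).  Runs of repeated labels compress trivially and would blur the
comparison, so self-transitions are removed before the analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .data import BinaryStateSeries

__all__ = [
    "LabelSequence",
    "TransitionMatrix",
    "ComplexityResult",
    "label_series",
    "remove_self_transitions",
    "transition_matrix",
    "stationary_distribution",
    "markov_surrogate",
    "lz76_phrases",
    "lz76_complexity",
    "relative_complexity",
    "triplet_stats",
    "TripletReport",
    "merge_fuzzy_centroids",
    "FuzzyCentroidCatalog",
]


@dataclass
class LabelSequence:
    """Ordered sequence of centroid labels over a fixed alphabet."""

    labels: np.ndarray
    alphabet_size: int
    self_transitions_removed: bool = False

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= self.alphabet_size):
            raise ValueError("labels out of alphabet range")

    def __len__(self) -> int:
        return self.labels.shape[0]


@dataclass
class TransitionMatrix:
    """Row-stochastic first-order transition estimates with raw counts."""

    P: np.ndarray
    counts: np.ndarray
    empty_rows: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))


@dataclass
class ComplexityResult:
    S_LZ: int
    C_LZ: float
    R: float | None = None
    surrogate_C: list = field(default_factory=list)


def label_series(
    series: BinaryStateSeries | np.ndarray, clusters
) -> LabelSequence:
    """Replace each state vector by the label of its centroid.

    Samples carrying a cluster assignment keep it; samples left unassigned by
    mass filtering (or new data) are labeled by the nearest centroid in
    Hamming distance, ties broken in favor of the larger mass.
    """
    states = series.states if isinstance(series, BinaryStateSeries) else np.asarray(series)
    centroids = np.asarray(clusters.centroids, dtype=np.int8)
    if centroids.shape[0] == 0:
        raise ValueError("empty centroid set")
    masses = np.asarray(getattr(clusters, "masses", np.ones(centroids.shape[0])))
    assignments = getattr(clusters, "assignments", None)
    labels = np.full(states.shape[0], -1, dtype=np.int64)
    if assignments is not None and np.asarray(assignments).shape[0] == states.shape[0]:
        labels = np.asarray(assignments, dtype=np.int64).copy()
    todo = np.flatnonzero(labels < 0)
    if todo.size:
        # Hamming distance to every centroid; ties -> larger mass
        d = (states[todo][:, None, :] != centroids[None, :, :]).sum(axis=2)
        # stable tie-break: sort centroids by decreasing mass once
        order = np.argsort(-masses, kind="stable")
        pick = order[np.argmin(d[:, order], axis=1)]
        labels[todo] = pick
    return LabelSequence(labels, alphabet_size=centroids.shape[0])


def remove_self_transitions(seq: LabelSequence) -> LabelSequence:
    """Collapse runs of identical consecutive labels to a single occurrence."""
    lab = seq.labels
    if lab.shape[0] == 0:
        raise ValueError("empty sequence")
    keep = np.concatenate([[True], lab[1:] != lab[:-1]])
    return LabelSequence(lab[keep], seq.alphabet_size, self_transitions_removed=True)


def transition_matrix(seq: LabelSequence) -> TransitionMatrix:
    """Maximum-likelihood bigram transition probabilities."""
    lab = seq.labels
    if lab.shape[0] < 2:
        raise ValueError("need at least 2 symbols")
    K = seq.alphabet_size
    counts = np.zeros((K, K), dtype=np.int64)
    np.add.at(counts, (lab[:-1], lab[1:]), 1)
    row = counts.sum(axis=1)
    empty = np.flatnonzero(row == 0)
    P = np.zeros((K, K))
    nz = row > 0
    P[nz] = counts[nz] / row[nz, None]
    return TransitionMatrix(P, counts, empty)


def stationary_distribution(P: np.ndarray, tol: float = 1e-12, max_iter: int = 10000) -> np.ndarray:
    """Stationary distribution by power iteration (uniform start)."""
    K = P.shape[0]
    pi = np.full(K, 1.0 / K)
    for _ in range(max_iter):
        nxt = pi @ P
        s = nxt.sum()
        if s <= 0:
            break
        nxt /= s
        if np.abs(nxt - pi).max() < tol:
            return nxt
        pi = nxt
    return pi


@njit(cache=True)
def _sample_chain(cum_rows, first, uniforms, out):
    out[0] = first
    K = cum_rows.shape[1]
    for t in range(1, out.shape[0]):
        u = uniforms[t]
        row = cum_rows[out[t - 1]]
        k = 0
        while k < K - 1 and u > row[k]:
            k += 1
        out[t] = k


def markov_surrogate(
    tm: TransitionMatrix | np.ndarray, length: int, seed: int = 0, empirical_start: np.ndarray | None = None
) -> LabelSequence:
    """Generate a memoryless surrogate from first-order transition estimates.

    The first symbol is drawn from the stationary distribution of P (or from
    the empirical label frequencies when the chain is reducible / has
    unvisited rows).
    """
    P = tm.P if isinstance(tm, TransitionMatrix) else np.asarray(tm, dtype=float)
    K = P.shape[0]
    rng = np.random.default_rng(seed)
    bad_rows = np.flatnonzero(P.sum(axis=1) < 0.5)
    start = None
    if bad_rows.size:
        warnings.warn("transition matrix has unvisited rows; starting from empirical frequencies", stacklevel=2)
        start = empirical_start
    if start is None:
        pi = stationary_distribution(P)
        if not np.isfinite(pi).all() or pi.sum() <= 0:
            pi = np.full(K, 1.0 / K)
        start = pi
    start = np.asarray(start, dtype=float)
    start = start / start.sum()
    first = int(rng.choice(K, p=start))
    # patch unvisited rows with the start distribution so sampling never stalls
    Puse = P.copy()
    if bad_rows.size:
        Puse[bad_rows] = start
    cum = np.cumsum(Puse, axis=1)
    out = np.empty(length, dtype=np.int64)
    _sample_chain(cum, first, rng.random(length), out)
    return LabelSequence(out, alphabet_size=K)


@njit(cache=True)
def _lz76_phrases(s):
    """Phrase count of the LZ76 exhaustive-history parsing (Kaspar-Schuster)."""
    n = s.shape[0]
    c = 1
    l = 1
    i = 0
    k = 1
    k_max = 1
    while True:
        if s[i + k - 1] == s[l + k - 1]:
            k += 1
            if l + k > n:
                c += 1
                break
        else:
            if k > k_max:
                k_max = k
            i += 1
            if i == l:
                c += 1
                l += k_max
                if l + 1 > n:
                    break
                i = 0
                k = 1
                k_max = 1
            else:
                k = 1
    return c


def lz76_phrases(seq: LabelSequence | np.ndarray) -> int:
    lab = seq.labels if isinstance(seq, LabelSequence) else np.asarray(seq, dtype=np.int64)
    if lab.shape[0] == 0:
        raise ValueError("empty sequence")
    if lab.shape[0] == 1:
        return 1
    return int(_lz76_phrases(np.ascontiguousarray(lab, dtype=np.int64)))


def lz76_complexity(seq: LabelSequence | np.ndarray, alphabet_size: int | None = None) -> tuple[int, float]:
    """(S_LZ, C_LZ): LZ76 phrase count and its normalized complexity.

    C_LZ = S_LZ log|S| / (|S| log|A|); for a degenerate one-letter alphabet
    C_LZ is defined as 0.  The normalization makes long iid uniform sequences
    score close to 1.
    """
    if isinstance(seq, LabelSequence):
        lab = seq.labels
        A = alphabet_size if alphabet_size is not None else seq.alphabet_size
    else:
        lab = np.asarray(seq, dtype=np.int64)
        A = alphabet_size if alphabet_size is not None else (int(lab.max()) + 1 if lab.size else 0)
    n = lab.shape[0]
    if n < 2:
        raise ValueError("sequence too short for LZ76")
    S_LZ = lz76_phrases(lab)
    A_eff = max(int(np.unique(lab).shape[0]), 1) if A <= 1 else A
    if A_eff <= 1:
        return S_LZ, 0.0
    C = S_LZ * np.log(n) / (n * np.log(A_eff))
    return S_LZ, float(C)


def relative_complexity(
    sample: LabelSequence, n_surrogates: int = 10, seed: int = 0
) -> ComplexityResult:
    """Relative complexity index R of a label sequence.

    Fits the first-order transition matrix of the sample, generates
    ``n_surrogates`` equal-length Markov surrogates, and returns
    R = (<C_LZ surrogate> - C_LZ sample) / <C_LZ surrogate>.
    """
    tm = transition_matrix(sample)
    freqs = np.bincount(sample.labels, minlength=sample.alphabet_size).astype(float)
    freqs /= freqs.sum()
    S_LZ, C_sample = lz76_complexity(sample)
    if S_LZ < 10:
        warnings.warn("fewer than 10 LZ phrases; R is poorly determined", stacklevel=2)
    sur_C = []
    for k in range(n_surrogates):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sur = markov_surrogate(tm, len(sample), seed=seed + k, empirical_start=freqs)
        sur_C.append(lz76_complexity(sur, alphabet_size=sample.alphabet_size)[1])
    mean_sur = float(np.mean(sur_C))
    R = (mean_sur - C_sample) / mean_sur
    return ComplexityResult(S_LZ, C_sample, float(R), sur_C)


@dataclass
class TripletReport:
    """Observed vs Markov-predicted triplet statistics."""

    triplets: np.ndarray  # (n, 3) surviving label triplets
    observed: np.ndarray  # empirical probabilities (sample)
    predicted: np.ndarray  # pi(a) P(a->b) P(b->c)
    null_observed: np.ndarray  # same-length true-Markov chain estimates
    kl_sample_vs_surrogate: float
    kl_null_vs_surrogate: float


def _triplet_counts(lab: np.ndarray, K: int) -> dict:
    keys = (lab[:-2] * K + lab[1:-1]) * K + lab[2:]
    uniq, cnt = np.unique(keys, return_counts=True)
    return dict(zip(uniq.tolist(), cnt.tolist()))


def triplet_stats(
    seq: LabelSequence, min_count: int = 10, n_null: int = 1, seed: int = 0
) -> TripletReport:
    """Compare overlapping-triplet occurrence with the first-order prediction.

    For each label triplet (a, b, c) occurring more than ``min_count`` times,
    the observed probability is compared with the Markov prediction
    pi(a) P(a->b) P(b->c) (pi = empirical unigram distribution).  A
    same-length true-Markov chain quantifies the finite-sample spread, and
    the Kullback-Leibler distance between the observed triplet distribution
    and the surrogate-estimated one (add-one smoothed, restricted to the
    observed support) summarizes the departure from first-order structure.
    """
    lab = seq.labels
    if lab.shape[0] < 3:
        raise ValueError("need at least 3 symbols")
    K = seq.alphabet_size
    tm = transition_matrix(seq)
    pi = np.bincount(lab, minlength=K).astype(float)
    pi /= pi.sum()
    n_tri = lab.shape[0] - 2

    counts = _triplet_counts(lab, K)
    keys = np.array([k for k, c in counts.items() if c > min_count], dtype=np.int64)
    keys.sort()
    triplets = np.stack([keys // (K * K), (keys // K) % K, keys % K], axis=1)
    observed = np.array([counts[int(k)] for k in keys], dtype=float) / n_tri
    predicted = pi[triplets[:, 0]] * tm.P[triplets[:, 0], triplets[:, 1]] * tm.P[triplets[:, 1], triplets[:, 2]]

    rng = np.random.default_rng(seed)
    null_counts: dict = {}
    sur_counts: dict = {}
    for r in range(max(n_null, 1)):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sur = markov_surrogate(tm, lab.shape[0], seed=int(rng.integers(2**31)), empirical_start=pi)
        c = _triplet_counts(sur.labels, K)
        for k, v in c.items():
            sur_counts[k] = sur_counts.get(k, 0) + v
        if r == 0:
            null_counts = c
    null_observed = np.array([null_counts.get(int(k), 0) for k in keys], dtype=float) / n_tri

    # KL(sample || surrogate) over the observed support, add-one on the surrogate
    sur_tot = sum(sur_counts.values())
    q = np.array([sur_counts.get(int(k), 0) + 1.0 for k in keys])
    q /= sur_tot + keys.shape[0]
    def _kl(p_raw: np.ndarray) -> float:
        m = p_raw > 0
        if not m.any():
            return float("nan")
        p = p_raw[m] / p_raw[m].sum()
        qq = q[m] / q[m].sum()
        return float(np.sum(p * np.log(p / qq)))

    kl = _kl(observed)
    kl_null = _kl(null_observed)
    return TripletReport(triplets, observed, predicted, null_observed, kl, kl_null)


@dataclass
class FuzzyCentroidCatalog:
    """Complete-linkage grouping of centroids pooled across runs."""

    representatives: np.ndarray  # F x N +/-1, mass-weighted majority per group
    group_of: np.ndarray  # index of the group of each input centroid
    detection: np.ndarray  # F x n_runs booleans
    mass_share: np.ndarray  # F, total mass fraction
    recovery_threshold: float | None = None
    recovered: np.ndarray | None = None  # per reference centroid


def merge_fuzzy_centroids(
    centroid_sets: list,
    cut_distance: float,
    reference_centroids: np.ndarray | None = None,
    recovery_quantile: float = 0.95,
) -> FuzzyCentroidCatalog:
    """Group near-identical centroids found across parameter sweeps.

    All centroids from all runs are pooled and clustered hierarchically with
    complete linkage under Hamming distance; the dendrogram is cut at
    ``cut_distance``.  Each fuzzy centroid reports which runs detected it and
    its share of the total configuration mass.

    When ``reference_centroids`` is given, a reference centroid counts as
    *recovered* if some run centroid matches it with |overlap| above a
    data-derived threshold: the ``recovery_quantile`` quantile of all
    |overlaps| between pooled run centroids (so only atypically high
    similarity counts as a match).
    """
    if not centroid_sets:
        raise ValueError("need at least one centroid set")
    all_c, masses, run_id = [], [], []
    for r, cs in enumerate(centroid_sets):
        cent = np.asarray(getattr(cs, "centroids", cs), dtype=np.int8)
        m = np.asarray(getattr(cs, "masses", np.ones(cent.shape[0])), dtype=float)
        for i in range(cent.shape[0]):
            all_c.append(cent[i])
            masses.append(m[i])
            run_id.append(r)
    X = np.array(all_c, dtype=np.int8)
    masses = np.array(masses)
    run_id = np.array(run_id)
    n_runs = len(centroid_sets)

    if X.shape[0] == 1:
        groups = np.zeros(1, dtype=np.int64)
    else:
        d = pdist(X, metric="hamming") * X.shape[1]
        Z = linkage(d, method="complete")
        groups = fcluster(Z, t=cut_distance, criterion="distance") - 1
    F = int(groups.max()) + 1
    reps = np.empty((F, X.shape[1]), dtype=np.int8)
    detection = np.zeros((F, n_runs), dtype=bool)
    share = np.zeros(F)
    for g in range(F):
        sel = groups == g
        colsum = masses[sel] @ X[sel].astype(float)
        rep = np.where(colsum >= 0, 1, -1).astype(np.int8)
        reps[g] = rep
        detection[g, run_id[sel]] = True
        share[g] = masses[sel].sum()
    share /= masses.sum()
    order = np.argsort(-share, kind="stable")
    inv = np.empty_like(order)
    inv[order] = np.arange(F)
    catalog = FuzzyCentroidCatalog(reps[order], inv[groups], detection[order], share[order])

    if reference_centroids is not None:
        ref = np.asarray(reference_centroids, dtype=np.int8)
        N = X.shape[1]
        q_all = np.abs(X @ X.T.astype(np.float64)) / N
        iu = np.triu_indices(X.shape[0], k=1)
        thr = float(np.quantile(q_all[iu], recovery_quantile)) if iu[0].size else 0.0
        q_ref = np.abs(ref.astype(np.float64) @ X.T.astype(np.float64)) / N
        catalog.recovery_threshold = thr
        catalog.recovered = (q_ref > thr).any(axis=1)
    return catalog
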