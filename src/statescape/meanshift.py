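"""Modified mean-shift clustering of binary state-space time series.

Each time bin of a multichannel recording is one point on the {-1,+1}^N
hypercube; clustering finds the local maxima of the density of visited
configurations (the minima of an effective energy landscape).  The variant
implemented here:

* flat (step) kernel: a point is averaged over all neighbors within a radius;
* adaptive radius: for the point being updated, the radius is the distance to
  its n_min-th nearest neighbor, where n_min minimizes the standard deviation
  sigma(n) of the n nearest-neighbor distances over n >= n0;
* discrete update: the shifted point is the componentwise *sign* of the
  neighbor mean, so points never leave the hypercube; a coordinate whose
  neighbor mean is exactly zero is not shifted;
* stochastic sequential iteration: a random point is picked (uniformly, with
  replacement) and updated; iteration stops when the fraction of updates that
  changed a point, over a sliding window of M updates, drops below a
  threshold;
* second pass: the centroids found in the first pass are themselves
  mean-shifted with a fixed radius (Hamming distance 2 by default), each
  weighted by its mass, which makes the clustering more robust to noise;
* mass cutoff: clusters holding less than a minimal fraction of the samples
  are discarded as finite-sample density bumps.

Distances are Hamming distances (on +/-1 vectors, squared Euclidean distance
is 4x Hamming, so flat-kernel neighborhoods are identical).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .data import BinaryStateSeries

__all__ = [
    "MeanShiftParams",
    "ClusterResult",
    "adaptive_radius",
    "ms_step",
    "run_meanshift",
    "refine_centroids",
    "filter_clusters",
    "cluster_series",
    "mirror_pair_census",
]


@dataclass
class MeanShiftParams:
    """Tunable parameters of the modified mean-shift procedure.

    n0 : minimum neighbor count entering the adaptive-radius heuristic.
    convergence_fraction : stop when fewer than this fraction of the last M
        updates changed their point (M = number of samples).
    refine_radius : fixed Hamming radius of the second, mass-weighted pass.
    mass_cutoff : minimal cluster mass as a fraction of all samples.
    max_iterations : hard cap on total updates (default 200 * M).
    """

    n0: int = 10
    convergence_fraction: float = 0.01
    refine_radius: int = 2
    mass_cutoff: float = 0.01
    seed: int = 0
    max_iterations: int | None = None

    def __post_init__(self) -> None:
        if self.n0 < 1:
            raise ValueError("n0 must be >= 1")
        if not 0 < self.convergence_fraction < 1:
            raise ValueError("convergence_fraction must be in (0, 1)")
        if not 0 <= self.mass_cutoff < 1:
            raise ValueError("mass_cutoff must be in [0, 1)")


@dataclass
class ClusterResult:
    """Centroids, per-centroid masses and per-sample assignments.

    ``assignments[t] == -1`` marks a sample dropped by the mass cutoff.
    Before filtering, masses sum to the number of samples.
    """

    centroids: np.ndarray  # C x N int8
    masses: np.ndarray  # C int64
    assignments: np.ndarray  # M int64 (-1 = unassigned)
    params: MeanShiftParams | None = None
    converged: bool = True

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=np.int8)
        self.masses = np.asarray(self.masses, dtype=np.int64)
        self.assignments = np.asarray(self.assignments, dtype=np.int64)

    @property
    def n_clusters(self) -> int:
        return self.centroids.shape[0]


# ---------------------------------------------------------------------------
# bit-packing helpers: Hamming distances via XOR + popcount


def _pack(states: np.ndarray) -> np.ndarray:
    """Pack a (M, N) +/-1 int8 matrix into (M, W) uint64 bit words."""
    bits = (states > 0).astype(np.uint8)
    n_bytes = bits.shape[1] // 8 + (bits.shape[1] % 8 > 0)
    packed8 = np.packbits(bits, axis=1, bitorder="little")
    pad = (-n_bytes) % 8
    if pad:
        packed8 = np.concatenate(
            [packed8, np.zeros((packed8.shape[0], pad), dtype=np.uint8)], axis=1
        )
    return packed8.view(np.uint64)


def _hamming_to_all(packed: np.ndarray, key: np.ndarray) -> np.ndarray:
    """Hamming distances from one packed row to all packed rows."""
    return np.bitwise_count(packed ^ key[None, :]).sum(axis=1).astype(np.int64)


# ---------------------------------------------------------------------------
# public single-step operations (reference implementations, used by the
# engine on the deduplicated representation and directly in tests)


def _radius_from_sorted(dists: np.ndarray, n0: int) -> int:
    """Radius = distance to the n_min-th NN, n_min = argmin_{n>=n0} sigma(n)."""
    m = dists.shape[0]
    if m < n0:
        raise ValueError(f"need at least n0={n0} neighbors, have {m}")
    d = dists.astype(np.float64)
    cs = np.cumsum(d)
    cs2 = np.cumsum(d * d)
    n = np.arange(1, m + 1, dtype=np.float64)
    var = cs2 / n - (cs / n) ** 2
    sigma = np.sqrt(np.maximum(var, 0.0))
    # smallest n >= n0 attaining the minimum
    tail = sigma[n0 - 1 :]
    n_min = n0 + int(np.argmin(tail))
    return int(dists[n_min - 1])


def adaptive_radius(point_index: int, data: np.ndarray, n0: int = 10) -> int:
    """Adaptive flat-kernel radius for one point of a data snapshot.

    Computes the standard deviation sigma(n) of the distances between the
    selected point and its n nearest neighbors, picks
    n_min = argmin_{n >= n0} sigma(n) (ties to the smallest n), and returns
    the Hamming distance to the n_min-th nearest neighbor.
    """
    data = np.asarray(data)
    if data.shape[0] < n0 + 1:
        raise ValueError(f"need at least n0+1={n0 + 1} points")
    diffs = data != data[point_index]
    d = diffs.sum(axis=1)
    d = np.delete(d, point_index)
    d.sort()
    return _radius_from_sorted(d, n0)


def ms_step(
    point_index: int,
    data: np.ndarray,
    radius: int,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """One flat-kernel mean-shift update of a point on the hypercube.

    The new position is the componentwise sign of the (weighted) mean over
    all neighbors within ``radius`` (the point itself excluded); coordinates
    with exactly zero mean keep their previous value.  A point with no
    neighbors is left unchanged.
    """
    data = np.asarray(data)
    x = data[point_index]
    d = (data != x).sum(axis=1)
    mask = d <= radius
    mask[point_index] = False
    if weights is None:
        w = mask.astype(np.float64)
    else:
        w = np.where(mask, np.asarray(weights, dtype=np.float64), 0.0)
    if w.sum() == 0:
        return x.copy()
    colsum = w @ data.astype(np.float64)
    new = np.where(colsum > 0, 1, np.where(colsum < 0, -1, x)).astype(np.int8)
    return new


@njit(cache=True, inline="always")
def _popcount64(x):
    x = x - ((x >> 1) & np.uint64(0x5555555555555555))
    x = (x & np.uint64(0x3333333333333333)) + ((x >> 2) & np.uint64(0x3333333333333333))
    x = (x + (x >> 4)) & np.uint64(0x0F0F0F0F0F0F0F0F)
    return (x * np.uint64(0x0101010101010101)) >> 56


@njit(cache=True)
def _ms_update_kernel(packed, states, counts, ui, n0, new_out):
    """One adaptive-radius flat-kernel update on the deduplicated table.

    counts[ui] must already exclude the point being moved.  Writes the shifted
    position into new_out; returns (moved, radius).
    """
    U, W = packed.shape
    N = states.shape[1]
    d = np.empty(U, dtype=np.int64)
    hist = np.zeros(N + 2, dtype=np.int64)
    for u in range(U):
        acc = np.uint64(0)
        for w in range(W):
            acc += _popcount64(packed[u, w] ^ packed[ui, w])
        d[u] = np.int64(acc)
        hist[d[u]] += counts[u]

    # sigma(n) scan over the expanded sorted distances: incremental mean/var
    total = 0
    for v in range(N + 1):
        total += hist[v]
    s = 0.0
    s2 = 0.0
    n = 0
    best_var = np.inf
    n_min = n0
    radius = -1
    for v in range(N + 1):
        for _ in range(hist[v]):
            n += 1
            s += v
            s2 += v * v
            if n >= n0:
                var = s2 / n - (s / n) ** 2
                if var < best_var - 1e-12:
                    best_var = var
                    n_min = n
                    radius = v
    if radius < 0:
        return False, -1

    # weighted componentwise sign of in-radius neighbors
    colsum = np.zeros(N, dtype=np.float64)
    wsum = 0.0
    for u in range(U):
        if d[u] <= radius and counts[u] > 0:
            cu = counts[u]
            wsum += cu
            for j in range(N):
                colsum[j] += cu * states[u, j]
    if wsum == 0.0:
        return False, radius
    moved = False
    for j in range(N):
        if colsum[j] > 0:
            new_out[j] = 1
        elif colsum[j] < 0:
            new_out[j] = -1
        else:
            new_out[j] = states[ui, j]
        if new_out[j] != states[ui, j]:
            moved = True
    return moved, radius


# ---------------------------------------------------------------------------
# main engine


class _UniqueTable:
    """Mutable table of unique hypercube positions with multiplicities."""

    def __init__(self, states: np.ndarray):
        states = np.ascontiguousarray(states, dtype=np.int8)
        uniq, inverse, counts = np.unique(states, axis=0, return_inverse=True, return_counts=True)
        cap = max(2 * uniq.shape[0], 1024)
        self.n_units = states.shape[1]
        self.states = np.zeros((cap, self.n_units), dtype=np.int8)
        self.states[: uniq.shape[0]] = uniq
        self.packed = np.zeros((cap, _pack(uniq).shape[1]), dtype=np.uint64)
        self.packed[: uniq.shape[0]] = _pack(uniq)
        self.count = np.zeros(cap, dtype=np.int64)
        self.count[: uniq.shape[0]] = counts
        self.size = uniq.shape[0]
        self.index: dict[bytes, int] = {
            self.states[u].tobytes(): u for u in range(self.size)
        }
        self.point_u = inverse.astype(np.int64)

    def lookup_or_add(self, state: np.ndarray) -> int:
        key = state.tobytes()
        u = self.index.get(key)
        if u is not None:
            return u
        if self.size == self.states.shape[0]:
            self._grow()
        u = self.size
        self.states[u] = state
        self.packed[u] = _pack(state[None, :])[0]
        self.count[u] = 0
        self.index[key] = u
        self.size += 1
        return u

    def _grow(self) -> None:
        cap = 2 * self.states.shape[0]
        for name in ("states", "packed"):
            old = getattr(self, name)
            new = np.zeros((cap, old.shape[1]), dtype=old.dtype)
            new[: self.size] = old[: self.size]
            setattr(self, name, new)
        count = np.zeros(cap, dtype=np.int64)
        count[: self.size] = self.count[: self.size]
        self.count = count

    def move_point(self, point: int, new_state: np.ndarray) -> None:
        old_u = self.point_u[point]
        new_u = self.lookup_or_add(new_state)
        self.count[old_u] -= 1
        self.count[new_u] += 1
        self.point_u[point] = new_u

    def compact(self) -> None:
        live = np.flatnonzero(self.count[: self.size] > 0)
        remap = -np.ones(self.size, dtype=np.int64)
        remap[live] = np.arange(live.shape[0])
        self.states[: live.shape[0]] = self.states[live]
        self.packed[: live.shape[0]] = self.packed[live]
        self.count[: live.shape[0]] = self.count[live]
        self.count[live.shape[0] : self.size] = 0
        self.size = live.shape[0]
        self.point_u = remap[self.point_u]
        self.index = {self.states[u].tobytes(): u for u in range(self.size)}


def run_meanshift(
    data: BinaryStateSeries | np.ndarray,
    params: MeanShiftParams | None = None,
) -> ClusterResult:
    """First-pass modified mean-shift over a binary state series.

    Points are updated sequentially in random order with the adaptive
    flat-kernel radius recomputed, at every update, from the *current*
    (already shifted) positions.  Iteration stops when the fraction of
    position-changing updates over the last M updates falls below
    ``params.convergence_fraction``, or at ``max_iterations`` (the result is
    then flagged ``converged=False``).  Clusters are the groups of original
    samples absorbed by the same final point.
    """
    params = params or MeanShiftParams()
    states = data.states if isinstance(data, BinaryStateSeries) else np.asarray(data)
    M = states.shape[0]
    if M < 2:
        raise ValueError("mean-shift needs at least 2 samples")
    if M < params.n0 + 1:
        raise ValueError("fewer than n0+1 samples")
    max_iter = params.max_iterations if params.max_iterations is not None else 200 * M
    rng = np.random.default_rng(params.seed)

    table = _UniqueTable(states)
    n0 = params.n0
    changed_ring = np.ones(M, dtype=bool)  # start pessimistic: full window required anyway
    ring_pos = 0
    n_done = 0
    converged = False

    new_buf = np.empty(states.shape[1], dtype=np.int8)
    while n_done < max_iter:
        i = int(rng.integers(M))
        ui = int(table.point_u[i])
        U = table.size
        table.count[ui] -= 1  # exclude the point itself (j != i)
        moved, _ = _ms_update_kernel(
            table.packed[:U], table.states[:U], table.count[:U], ui, n0, new_buf
        )
        table.count[ui] += 1

        if moved:
            table.move_point(i, new_buf.copy())
        changed_ring[ring_pos] = moved
        ring_pos = (ring_pos + 1) % M
        n_done += 1

        if n_done >= M and ring_pos == 0:
            if changed_ring.mean() < params.convergence_fraction:
                converged = True
                break
            if table.size > 4 * np.count_nonzero(table.count[: table.size]):
                table.compact()

    table.compact()
    # clusters = groups of samples sharing a final position
    final_u, assignments = np.unique(table.point_u, return_inverse=True)
    centroids = table.states[final_u].copy()
    masses = np.bincount(assignments, minlength=final_u.shape[0]).astype(np.int64)
    return ClusterResult(centroids, masses, assignments.astype(np.int64), params, converged)


def refine_centroids(result: ClusterResult, radius: int | None = None) -> ClusterResult:
    """Second pass: mean-shift the centroid set itself at a fixed radius.

    Each centroid is weighted by its mass; unlike the first pass the moving
    centroid's own mass is kept in the weighted mean, so a heavy centroid is
    not dragged onto a light neighbor (merging then lands on the mass-weighted
    majority vector).  Centroids absorbed by the same final point pool their
    masses and the sample assignments are re-indexed.
    """
    if result.n_clusters == 0:
        raise ValueError("no centroids to refine")
    if radius is None:
        radius = result.params.refine_radius if result.params else 2
    pos = result.centroids.copy()
    masses = result.masses.astype(np.float64)
    C = pos.shape[0]
    for _ in range(200):
        any_change = False
        for i in range(C):
            d = (pos != pos[i]).sum(axis=1)
            mask = d <= radius  # self included: d[i] = 0
            w = np.where(mask, masses, 0.0)
            colsum = w @ pos.astype(np.float64)
            new = np.where(colsum > 0, 1, np.where(colsum < 0, -1, pos[i])).astype(np.int8)
            if not np.array_equal(new, pos[i]):
                pos[i] = new
                any_change = True
        if not any_change:
            break

    uniq, old_to_new = np.unique(pos, axis=0, return_inverse=True)
    new_masses = np.zeros(uniq.shape[0], dtype=np.int64)
    np.add.at(new_masses, old_to_new, result.masses)
    assignments = result.assignments.copy()
    assigned = assignments >= 0
    assignments[assigned] = old_to_new[assignments[assigned]]
    return ClusterResult(uniq.astype(np.int8), new_masses, assignments, result.params, result.converged)


def filter_clusters(result: ClusterResult, mass_cutoff: float | None = None) -> ClusterResult:
    """Drop clusters whose mass is below a fraction of all samples.

    Samples of dropped clusters become unassigned (-1); surviving masses are
    unchanged.  Small clusters are typically density bumps due to
    finite-sample fluctuations rather than genuine landscape features.
    """
    if mass_cutoff is None:
        mass_cutoff = result.params.mass_cutoff if result.params else 0.01
    if not 0 <= mass_cutoff < 1:
        raise ValueError("mass_cutoff must be in [0, 1)")
    total = result.assignments.shape[0]
    keep = result.masses / total >= mass_cutoff
    if not keep.any():
        import warnings

        warnings.warn("mass cutoff removed every cluster", stacklevel=2)
    remap = -np.ones(result.n_clusters, dtype=np.int64)
    remap[keep] = np.arange(int(keep.sum()))
    assignments = result.assignments.copy()
    assigned = assignments >= 0
    assignments[assigned] = remap[assignments[assigned]]
    return ClusterResult(
        result.centroids[keep], result.masses[keep], assignments, result.params, result.converged
    )


def cluster_series(
    data: BinaryStateSeries | np.ndarray, params: MeanShiftParams | None = None
) -> ClusterResult:
    """Full pipeline: first pass, mass-weighted refinement, mass cutoff."""
    params = params or MeanShiftParams()
    result = run_meanshift(data, params)
    result = refine_centroids(result, params.refine_radius)
    return filter_clusters(result, params.mass_cutoff)


def run_meanshift_continuous(
    data: np.ndarray,
    params: MeanShiftParams | None = None,
    displacement_threshold: float = 1e-6,
    merge_tolerance: float | None = None,
) -> ClusterResult:
    """Mean shift for real-valued data (secondary mode).

    Same stochastic sequential scheme with the adaptive flat-kernel radius,
    but positions move to the plain (unsigned) neighbor mean under Euclidean
    distance; convergence additionally requires the displacement to exceed
    ``displacement_threshold`` (in data units) for an update to count as a
    change.  Clusters are groups of points whose final positions coincide to
    within ``merge_tolerance`` (continuous trajectories stall near, not on,
    each other; default 1e-3, set it to a fraction of the typical mode
    separation for loose data).
    """
    params = params or MeanShiftParams()
    X = np.asarray(data, dtype=np.float64).copy()
    M = X.shape[0]
    if M < params.n0 + 1:
        raise ValueError("fewer than n0+1 samples")
    rng = np.random.default_rng(params.seed)
    max_iter = params.max_iterations if params.max_iterations is not None else 200 * M
    changed_ring = np.ones(M, dtype=bool)
    pos = 0
    converged = False
    for n_done in range(max_iter):
        i = int(rng.integers(M))
        d = np.linalg.norm(X - X[i], axis=1)
        d_others = np.delete(d, i)
        order = np.sort(d_others)
        radius = _radius_from_sorted_continuous(order, params.n0)
        mask = d <= radius
        mask[i] = False
        moved = False
        if mask.any():
            new = X[mask].mean(axis=0)
            if np.linalg.norm(new - X[i]) > displacement_threshold:
                X[i] = new
                moved = True
        changed_ring[pos] = moved
        pos = (pos + 1) % M
        if n_done >= M and pos == 0 and changed_ring.mean() < params.convergence_fraction:
            converged = True
            break
    # group final positions within the merge tolerance
    tol = merge_tolerance if merge_tolerance is not None else 1e-3
    assignments = -np.ones(M, dtype=np.int64)
    reps: list[np.ndarray] = []
    for i in range(M):
        for k, r in enumerate(reps):
            if np.linalg.norm(X[i] - r) <= tol:
                assignments[i] = k
                break
        else:
            assignments[i] = len(reps)
            reps.append(X[i])
    masses = np.bincount(assignments, minlength=len(reps)).astype(np.int64)
    return _continuous_result(np.array(reps), masses, assignments, params, converged)


def _continuous_result(centroids, masses, assignments, params, converged):
    res = ClusterResult.__new__(ClusterResult)
    res.centroids = centroids  # real-valued; bypasses the +/-1 coercion
    res.masses = np.asarray(masses, dtype=np.int64)
    res.assignments = np.asarray(assignments, dtype=np.int64)
    res.params = params
    res.converged = converged
    return res


def _radius_from_sorted_continuous(dists: np.ndarray, n0: int) -> float:
    m = dists.shape[0]
    if m < n0:
        raise ValueError(f"need at least n0={n0} neighbors, have {m}")
    cs = np.cumsum(dists)
    cs2 = np.cumsum(dists * dists)
    n = np.arange(1, m + 1, dtype=np.float64)
    var = cs2 / n - (cs / n) ** 2
    tail = var[n0 - 1 :]
    n_min = n0 + int(np.argmin(tail))
    return float(dists[n_min - 1])


def mirror_pair_census(centroids: np.ndarray) -> tuple[int, list[tuple[int, int]]]:
    """Count centroids that occur together with their global sign flip.

    Returns the number of centroids belonging to a mirror pair (c, -c) and
    the list of index pairs.
    """
    centroids = np.asarray(centroids)
    pairs = []
    seen = set()
    index = {centroids[i].tobytes(): i for i in range(centroids.shape[0])}
    for i in range(centroids.shape[0]):
        if i in seen:
            continue
        j = index.get((-centroids[i]).tobytes())
        if j is not None and j != i and j not in seen:
            pairs.append((i, j))
            seen.update((i, j))
    return 2 * len(pairs), pairs
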