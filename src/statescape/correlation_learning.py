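"""Pseudo-Boltzmann learning of inter-module couplings with Rprop.

Goal: choose the inter-module mean synaptic efficacies J_pq and per-module
external rates nu_p so that the binarized Up/Down dynamics of the modular
spiking network reproduces a prescribed set of spatial statistics — the
magnetizations m_p = <sigma_p> and connected correlations
c_pq = <sigma_p sigma_q> - m_p m_q of a reference system (typically a
Hopfield network whose binary neurons are mapped one-to-one onto the
modules).

True Boltzmann learning would move each coupling along the gradient of a
likelihood; for a spiking network no such explicit objective exists.  The
procedure instead assumes only a monotone relation between couplings and
correlations (and between external rates and magnetizations), i.e. that the
*sign* of the unknown gradient is the sign of the mismatch, and delegates
the step size to Rprop: a per-parameter step that is multiplied by eta_plus
(capped at delta_max) while the error keeps its sign, and by eta_minus
(floored at delta_min) when the sign flips:

    dJ_pq  = -sign(c_pq - c_pq^target) * Delta_pq,
    dnu_p  = -sign(m_p  - m_p^target ) * Delta_p.

Each iteration runs the network, discards the first 5 tau_SFA of activity,
binarizes, measures (m, c), and applies one Rprop step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data import BinaryStateSeries
from .spiking_net import ModuleArchitecture, SpikingNetwork, binarize, build_network, module_rates, simulate

__all__ = [
    "TargetStatistics",
    "RpropConfig",
    "LearningState",
    "target_statistics",
    "rprop_step",
    "learn",
    "LearningResult",
    "validate_learning",
    "ValidationReport",
]


@dataclass
class TargetStatistics:
    """Target magnetizations m_p and connected correlations c_pq."""

    m: np.ndarray
    c: np.ndarray

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m, dtype=np.float64)
        self.c = np.asarray(self.c, dtype=np.float64)
        if self.c.shape != (self.m.shape[0], self.m.shape[0]):
            raise ValueError("c must be square and match m")
        if np.abs(self.m).max(initial=0.0) > 1 + 1e-9:
            raise ValueError("|m| must be <= 1")


def target_statistics(series: BinaryStateSeries | np.ndarray) -> TargetStatistics:
    """Time-averaged magnetizations and connected pair correlations."""
    states = series.states if isinstance(series, BinaryStateSeries) else np.asarray(series)
    if states.shape[0] < 2:
        raise ValueError("need at least 2 time bins")
    X = states.astype(np.float64)
    m = X.mean(axis=0)
    c = X.T @ X / X.shape[0] - np.outer(m, m)
    return TargetStatistics(m, c)


@dataclass
class RpropConfig:
    """Rprop hyperparameters (couplings in mV, rates in kHz)."""

    eta_plus: float = 1.2
    eta_minus: float = 0.5
    delta_max_J: float = 0.05
    delta_min_J: float = 1e-4
    delta_init_J: float = 0.01
    delta_max_nu: float = 0.5
    delta_min_nu: float = 1e-3
    delta_init_nu: float = 0.1

    def __post_init__(self) -> None:
        if not 0 < self.eta_minus < 1 < self.eta_plus:
            raise ValueError("need 0 < eta_minus < 1 < eta_plus")


@dataclass
class LearningState:
    """Current parameters, per-parameter step sizes and previous errors."""

    J_pq: np.ndarray
    nu_ext: np.ndarray
    delta_J: np.ndarray
    delta_nu: np.ndarray
    prev_err_c: np.ndarray | None = None
    prev_err_m: np.ndarray | None = None
    config: RpropConfig = field(default_factory=RpropConfig)
    iteration: int = 0


def _rprop_update(delta, prev_err, err, eta_plus, eta_minus, dmin, dmax):
    if prev_err is not None:
        prod = prev_err * err
        delta = np.where(prod > 0, np.minimum(eta_plus * delta, dmax), delta)
        delta = np.where(prod < 0, np.maximum(eta_minus * delta, dmin), delta)
    return delta


def rprop_step(state: LearningState, err_c: np.ndarray, err_m: np.ndarray) -> LearningState:
    """One pseudo-Boltzmann iteration given the current statistic mismatches.

    ``err_c = c_measured - c_target`` (off-diagonal entries used; J_pp is not
    a parameter) and ``err_m = m_measured - m_target``.  A parameter with
    exactly zero current error keeps both its value and its step size.  The
    first call adapts no step sizes (there is no previous error yet).
    """
    cfg = state.config
    err_c = np.asarray(err_c, dtype=np.float64)
    err_m = np.asarray(err_m, dtype=np.float64)
    delta_J = _rprop_update(
        state.delta_J, state.prev_err_c, err_c, cfg.eta_plus, cfg.eta_minus, cfg.delta_min_J, cfg.delta_max_J
    )
    delta_nu = _rprop_update(
        state.delta_nu, state.prev_err_m, err_m, cfg.eta_plus, cfg.eta_minus, cfg.delta_min_nu, cfg.delta_max_nu
    )
    J = state.J_pq - np.sign(err_c) * delta_J
    np.fill_diagonal(J, 0.0)
    nu = np.maximum(state.nu_ext - np.sign(err_m) * delta_nu, 0.0)
    return LearningState(
        J_pq=J,
        nu_ext=nu,
        delta_J=delta_J,
        delta_nu=delta_nu,
        prev_err_c=err_c.copy(),
        prev_err_m=err_m.copy(),
        config=cfg,
        iteration=state.iteration + 1,
    )


@dataclass
class LearningResult:
    """Trajectory of a pseudo-Boltzmann run and the retained network.

    ``state`` (and the returned network) hold the *best* visited parameters —
    the iteration with the smallest mean absolute correlation error — rather
    than the last ones: the sign-driven updates can overshoot into a regime
    where modules freeze and the error signal degenerates, so plain
    last-iterate return is brittle.  ``last_state`` keeps the final iterate.
    """

    state: LearningState
    network: SpikingNetwork
    err_c_trace: list
    err_m_trace: list
    r2_trace: list
    final_stats: TargetStatistics | None
    completed: bool = True
    last_state: LearningState | None = None
    best_iteration: int = -1


def _offdiag(a: np.ndarray) -> np.ndarray:
    return a[~np.eye(a.shape[0], dtype=bool)]


def correlation_r2(measured: np.ndarray, target: np.ndarray) -> float:
    """R^2 between measured and target off-diagonal connected correlations."""
    x = _offdiag(np.asarray(target, float))
    y = _offdiag(np.asarray(measured, float))
    ssr = np.sum((y - x) ** 2)
    sst = np.sum((x - x.mean()) ** 2)
    return float(1.0 - ssr / sst) if sst > 0 else float("nan")


def learn(
    arch: ModuleArchitecture,
    targets: TargetStatistics,
    duration: float = 100_000.0,
    n_iterations: int = 300,
    seed: int = 0,
    config: RpropConfig | None = None,
    dt: float = 0.1,
    initial_J: np.ndarray | None = None,
    initial_nu: np.ndarray | None = None,
) -> LearningResult:
    """Run the pseudo-Boltzmann loop against the target statistics.

    Each iteration simulates ``duration`` ms of the current network after a
    burn-in of 5 tau_SFA (discarded before binarization), measures the
    binary-word statistics and applies one Rprop step to J_pq and nu_ext.
    The synaptic realization (connectivity graph and relative weight factors)
    is quenched once from ``seed``; only the module-level means move.
    """
    nm = arch.n_modules
    if targets.m.shape[0] != nm:
        raise ValueError("targets do not match the number of modules")
    cfg = config or RpropConfig()
    rng = np.random.default_rng(seed)
    if initial_J is None:
        initial_J = rng.normal(0.0, 1e-3 * arch.J_EE, size=(nm, nm))
        np.fill_diagonal(initial_J, 0.0)
    if initial_nu is None:
        initial_nu = np.full(nm, arch.nu_ext)
    state = LearningState(
        J_pq=np.asarray(initial_J, float).copy(),
        nu_ext=np.asarray(initial_nu, float).copy(),
        delta_J=np.full((nm, nm), cfg.delta_init_J),
        delta_nu=np.full(nm, cfg.delta_init_nu),
        config=cfg,
    )
    network = build_network(arch, inter_module_J=state.J_pq, seed=seed)
    burn_in = 5.0 * arch.tau_SFA
    err_c_trace: list[float] = []
    err_m_trace: list[float] = []
    r2_trace: list[float] = []
    stats = None
    completed = True
    best = (np.inf, state, None, -1)  # (mean |err_c|, state, stats, iteration)
    off = ~np.eye(nm, dtype=bool)
    for it in range(n_iterations):
        network.set_inter_module_couplings(state.J_pq)
        network.set_external_rates(state.nu_ext)
        try:
            raster = simulate(network, burn_in + duration, dt=dt, seed=int(rng.integers(2**31)))
        except RuntimeError:
            completed = False
            break
        rates = module_rates(raster, window=20.0, bin=20.0, n_E=arch.n_E)
        words = binarize(rates, arch.theta_bin)
        keep = int(np.ceil(burn_in / rates.bin))
        stats = target_statistics(words.states[keep:])
        err_c = stats.c - targets.c
        np.fill_diagonal(err_c, 0.0)
        err_m = stats.m - targets.m
        err_c_trace.append(float(np.abs(err_c[off]).mean()))
        err_m_trace.append(float(np.abs(err_m).mean()))
        r2_trace.append(correlation_r2(stats.c, targets.c))
        score = err_c_trace[-1] + 0.1 * err_m_trace[-1]
        if score < best[0]:
            best = (score, state, stats, it)
        state = rprop_step(state, err_c, err_m)
    best_state, best_stats, best_it = best[1], best[2], best[3]
    if best_stats is None:
        best_state, best_stats = state, stats
    # leave the network at the retained (best) parameters
    network.set_inter_module_couplings(best_state.J_pq)
    network.set_external_rates(best_state.nu_ext)
    return LearningResult(
        best_state,
        network,
        err_c_trace,
        err_m_trace,
        r2_trace,
        best_stats,
        completed,
        last_state=state,
        best_iteration=best_it,
    )


def proportional_mapping_baseline(reference_J: np.ndarray, scale: float) -> np.ndarray:
    """Naive baseline: inter-module means proportional to the reference couplings.

    Simply rescales the reference (e.g. Hopfield) coupling matrix onto the
    module level instead of learning.  Kept as a documented baseline: it
    performs poorly because Up and Down states are not dynamically equivalent
    (different stability and finite-size noise) and quenched synaptic
    realizations make modules heterogeneous, none of which a fixed linear
    mapping can compensate.
    """
    J = scale * np.asarray(reference_J, dtype=np.float64)
    np.fill_diagonal(J, 0.0)
    return J


@dataclass
class ValidationReport:
    """The three checks of a learned network against its reference system."""

    r2: float
    centroid_census: dict
    coupling_error_mean_abs: float | None


def _overlap_census(cent_a: np.ndarray, cent_b: np.ndarray) -> dict:
    """Max |overlap| of each centroid in A against all of B, with counts."""
    A = np.asarray(cent_a, float)
    B = np.asarray(cent_b, float)
    N = A.shape[1]
    q = np.abs(A @ B.T) / N
    best = q.max(axis=1)
    return {
        "n": A.shape[0],
        "best_abs_overlap": best,
        "n_exact": int(np.sum(best >= 1.0 - 1e-12)),
        "n_above_0.95": int(np.sum(best > 0.95)),
        "n_above_0.8": int(np.sum(best > 0.8)),
    }


def validate_learning(
    final_stats: TargetStatistics,
    targets: TargetStatistics,
    clusters_spiking=None,
    clusters_reference=None,
    inferred_J: np.ndarray | None = None,
    reference_J: np.ndarray | None = None,
) -> ValidationReport:
    """Quantify how well the learned network matches the reference system.

    (a) R^2 between achieved and target connected correlations; (b) census of
    best |overlap| between the two systems' cluster centroids, in both
    directions; (c) mean absolute relative error between module-level
    couplings inferred from the spiking words and the reference couplings.
    Missing inputs produce a partial report.
    """
    from .mpf_inference import coupling_error

    r2 = correlation_r2(final_stats.c, targets.c)
    census = {}
    if clusters_spiking is not None and clusters_reference is not None:
        cs = getattr(clusters_spiking, "centroids", clusters_spiking)
        ch = getattr(clusters_reference, "centroids", clusters_reference)
        if len(cs) and len(ch):
            census["reference_vs_spiking"] = _overlap_census(ch, cs)
            census["spiking_vs_reference"] = _overlap_census(cs, ch)
    err = None
    if inferred_J is not None and reference_J is not None:
        err = coupling_error(inferred_J, reference_J)["mean_abs"]
    return ValidationReport(r2, census, err)
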