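"""Multi-modular spiking network with spike-frequency adaptation.

The network is a collection of weakly interacting modules, each a small
recurrent population of leaky integrate-and-fire neurons (32 excitatory, 16
inhibitory) whose intra-module synapses make the isolated module approximately
bistable between a low ('Down') and a high ('Up') firing state.  Membrane
dynamics:

    dV_i/dt = -V_i / tau + sum_j J_ij sum_k delta(t - t_k^j - d_ij)
              - g_SFA c_i + I_i,
    dc_i/dt = -c_i / tau_SFA + sum_k delta(t - t_k^i),

with a spike recorded when V_i >= V_th, after which V_i is held at the reset
value H for a refractory period.  The calcium-like variable c_i integrates
the neuron's own spikes (unit increment per spike) and feeds back as an
activity-dependent self-inhibition (spike-frequency adaptation, SFA), which
slowly destabilizes whichever attractor state the network occupies.
Adaptation acts on the excitatory neurons.

External input to each neuron is a Poisson event stream of aggregate rate
nu_ext (the merged sum of its external afferent trains), each event a voltage
jump J_ext.  Inter-module synapses exist between excitatory neurons only,
with Bernoulli(0.5) connectivity and means given by a (learned) module-level
matrix; they may be of either sign.

Integration is clock-driven on a fixed grid (default dt = 0.1 ms):
exponential decay of V and c over each step, delta-function synaptic jumps
accumulated through a circular delay buffer, delays rounded to the grid.
Module activity is read out as the excitatory population rate smoothed over a
20 ms window and binarized at theta_bin (40 Hz) into +/-1 'Up/Down' words.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .data import BinaryStateSeries

__all__ = [
    "ModuleArchitecture",
    "SpikingNetwork",
    "SpikeRaster",
    "ModuleRateSeries",
    "build_network",
    "simulate",
    "module_rates",
    "binarize",
]


@dataclass
class ModuleArchitecture:
    """Architecture and single-neuron parameters of the modular network.

    Defaults are the calibrated working point of the bistable module:
    voltages in mV, times in ms, rates in kHz.  ``nu_ext`` is the aggregate
    rate of the merged external train seen by one excitatory neuron; the
    external train counts ``C_E_ext``/``C_I_ext`` are provenance metadata
    (inhibitory neurons receive the same aggregate rate through their own
    external efficacy).
    """

    n_modules: int = 64
    n_E: int = 32
    n_I: int = 16
    tau_E: float = 20.0
    tau_I: float = 10.0
    t_ref_E: float = 2.0
    t_ref_I: float = 1.0
    H_reset: float = 15.0
    V_th: float = 20.0
    c_EE: float = 0.5
    c_IE: float = 0.5
    c_EI: float = 1.0
    c_II: float = 1.0
    J_EE: float = 0.72
    J_IE: float = 1.0
    J_EI: float = -2.0
    J_II: float = -0.0012
    d_min: float = 0.1
    d_max_EE: float = 21.0
    d_max_IE: float = 21.0
    d_max_EI: float = 1.0
    d_max_II: float = 1.0
    inter_module_prob: float = 0.5
    d_max_inter: float = 50.0
    C_E_ext: int = 600
    C_I_ext: int = 400
    J_E_ext: float = 0.320
    J_I_ext: float = 0.111
    nu_ext: float = 3.4  # kHz, aggregate per neuron (calibrated working point)
    tau_SFA: float = 500.0
    g_SFA: float | None = None  # default 25 / tau_SFA
    calcium_increment: float = 0.4  # calcium jump per spike (calibrated)
    relative_sd: float = 0.25
    theta_bin: float = 40.0

    def __post_init__(self) -> None:
        if self.g_SFA is None:
            self.g_SFA = 25.0 / self.tau_SFA
        for p in (self.c_EE, self.c_IE, self.c_EI, self.c_II, self.inter_module_prob):
            if not 0 <= p <= 1:
                raise ValueError("connection probabilities must be in [0, 1]")
        if self.V_th <= self.H_reset:
            raise ValueError("V_th must exceed H_reset")
        if self.tau_E <= 0 or self.tau_I <= 0 or self.tau_SFA <= 0:
            raise ValueError("time constants must be positive")

    @property
    def n_per_module(self) -> int:
        return self.n_E + self.n_I

    @property
    def n_neurons(self) -> int:
        return self.n_modules * self.n_per_module


@dataclass
class SpikeRaster:
    """Time-ordered spike events with the neuron-to-module map."""

    times: np.ndarray  # ms
    ids: np.ndarray
    duration: float  # ms
    module_of: np.ndarray  # per neuron
    is_excitatory: np.ndarray  # per neuron

    @property
    def n_spikes(self) -> int:
        return self.times.shape[0]


@dataclass
class ModuleRateSeries:
    """Smoothed excitatory population rates per module (Hz)."""

    rates: np.ndarray  # T x n_modules
    bin: float  # ms
    window: float  # ms


@dataclass
class SpikingNetwork:
    """A concrete synaptic realization ready for simulation."""

    arch: ModuleArchitecture
    # per-neuron parameters
    tau: np.ndarray
    t_ref: np.ndarray
    g_sfa: np.ndarray
    nu_ext: np.ndarray  # kHz per neuron
    j_ext: np.ndarray
    module_of: np.ndarray
    is_excitatory: np.ndarray
    # CSR synapses: for presynaptic neuron i, targets syn_post[ptr[i]:ptr[i+1]]
    syn_ptr: np.ndarray
    syn_post: np.ndarray
    syn_weight: np.ndarray
    syn_delay: np.ndarray  # ms
    # bookkeeping for in-place updates during learning
    inter_slice: np.ndarray  # indices into syn arrays of inter-module synapses
    inter_pq: np.ndarray  # (len, 2) target-module p, source-module q
    inter_factor: np.ndarray  # frozen positive Gaussian factors
    seed: int = 0

    @property
    def n_neurons(self) -> int:
        return self.tau.shape[0]

    def set_inter_module_couplings(self, J_pq: np.ndarray) -> None:
        """Rescale inter-module synapses to new module-level means (mV).

        Each synapse keeps its frozen positive Gaussian factor (relative sd
        from the architecture), so the per-synapse weight tracks the sign of
        the module-level mean exactly.
        """
        self.syn_weight[self.inter_slice] = (
            J_pq[self.inter_pq[:, 0], self.inter_pq[:, 1]] * self.inter_factor
        )

    def set_external_rates(self, nu_per_module: np.ndarray) -> None:
        """Set the common external aggregate rate (kHz) of each module."""
        self.nu_ext = np.asarray(nu_per_module, dtype=np.float64)[self.module_of]


def _positive_factors(rng: np.random.Generator, n: int, rel_sd: float) -> np.ndarray:
    """1 + rel_sd * z, resampled until positive (keeps the mean's sign)."""
    f = rng.normal(1.0, rel_sd, size=n)
    bad = f <= 0
    while bad.any():
        f[bad] = rng.normal(1.0, rel_sd, size=int(bad.sum()))
        bad = f <= 0
    return f


def _trunc_exponential(rng: np.random.Generator, n: int, lo: float, hi: float) -> np.ndarray:
    """Exponential delays (scale = hi) truncated by rejection to [lo, hi]."""
    out = rng.exponential(hi, size=n)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.exponential(hi, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def build_network(
    arch: ModuleArchitecture,
    inter_module_J: np.ndarray | None = None,
    seed: int = 0,
) -> SpikingNetwork:
    """Draw a synaptic realization of the modular architecture.

    Intra-module synapses: Bernoulli connectivity per class, Gaussian weights
    with the architecture's relative sd (resampled if the sign flips), delays
    exponential truncated to [d_min, d_max] of the class.  Inter-module
    synapses: excitatory-to-excitatory across modules with probability
    ``inter_module_prob`` and module-level means from ``inter_module_J``
    (either sign), delays truncated to [d_min, d_max_inter].
    """
    rng = np.random.default_rng(seed)
    nm, nE, nI = arch.n_modules, arch.n_E, arch.n_I
    npm = nE + nI
    n = arch.n_neurons
    if inter_module_J is None:
        inter_module_J = np.zeros((nm, nm))
    inter_module_J = np.asarray(inter_module_J, dtype=np.float64)
    if inter_module_J.shape != (nm, nm):
        raise ValueError("inter_module_J must be n_modules x n_modules")

    module_of = np.repeat(np.arange(nm), npm)
    is_E = np.tile(np.concatenate([np.ones(nE, bool), np.zeros(nI, bool)]), nm)
    tau = np.where(is_E, arch.tau_E, arch.tau_I)
    t_ref = np.where(is_E, arch.t_ref_E, arch.t_ref_I)
    g_sfa = np.where(is_E, arch.g_SFA, 0.0)
    j_ext = np.where(is_E, arch.J_E_ext, arch.J_I_ext)
    nu_ext = np.full(n, arch.nu_ext)

    pre_list: list[np.ndarray] = []
    post_list: list[np.ndarray] = []
    w_list: list[np.ndarray] = []
    d_list: list[np.ndarray] = []
    flag_inter: list[np.ndarray] = []
    pq_list: list[np.ndarray] = []
    fac_list: list[np.ndarray] = []

    classes = [  # (pre is E, post is E, prob, mean J, d_max)
        (True, True, arch.c_EE, arch.J_EE, arch.d_max_EE),
        (True, False, arch.c_IE, arch.J_IE, arch.d_max_IE),
        (False, True, arch.c_EI, arch.J_EI, arch.d_max_EI),
        (False, False, arch.c_II, arch.J_II, arch.d_max_II),
    ]
    for m in range(nm):
        base = m * npm
        E_ids = base + np.arange(nE)
        I_ids = base + nE + np.arange(nI)
        for pre_E, post_E, prob, meanJ, dmax in classes:
            pre_ids = E_ids if pre_E else I_ids
            post_ids = E_ids if post_E else I_ids
            mask = rng.random((pre_ids.size, post_ids.size)) < prob
            np.fill_diagonal(mask, False) if pre_E == post_E else None
            pre_idx, post_idx = np.nonzero(mask)
            k = pre_idx.size
            if k == 0:
                continue
            w = meanJ * _positive_factors(rng, k, arch.relative_sd)
            d = _trunc_exponential(rng, k, arch.d_min, dmax)
            pre_list.append(pre_ids[pre_idx])
            post_list.append(post_ids[post_idx])
            w_list.append(w)
            d_list.append(d)
            flag_inter.append(np.zeros(k, bool))
            pq_list.append(np.zeros((k, 2), np.int64))
            fac_list.append(np.zeros(k))

    # inter-module E -> E
    if nm > 1:
        for q in range(nm):  # source module
            pre_ids = q * npm + np.arange(nE)
            for p in range(nm):  # target module
                if p == q:
                    continue
                post_ids = p * npm + np.arange(nE)
                mask = rng.random((nE, nE)) < arch.inter_module_prob
                pre_idx, post_idx = np.nonzero(mask)
                k = pre_idx.size
                if k == 0:
                    continue
                fac = _positive_factors(rng, k, arch.relative_sd)
                w = inter_module_J[p, q] * fac
                d = _trunc_exponential(rng, k, arch.d_min, arch.d_max_inter)
                pre_list.append(pre_ids[pre_idx])
                post_list.append(post_ids[post_idx])
                w_list.append(w)
                d_list.append(d)
                flag_inter.append(np.ones(k, bool))
                pq_list.append(np.stack([np.full(k, p), np.full(k, q)], axis=1))
                fac_list.append(fac)

    if pre_list:
        pre = np.concatenate(pre_list)
        post = np.concatenate(post_list)
        weight = np.concatenate(w_list)
        delay = np.concatenate(d_list)
        inter_flag = np.concatenate(flag_inter)
        pq = np.concatenate(pq_list)
        fac = np.concatenate(fac_list)
        order = np.argsort(pre, kind="stable")
        pre, post, weight, delay = pre[order], post[order], weight[order], delay[order]
        inter_flag, pq, fac = inter_flag[order], pq[order], fac[order]
        ptr = np.searchsorted(pre, np.arange(n + 1))
    else:
        post = np.zeros(0, np.int64)
        weight = np.zeros(0)
        delay = np.zeros(0)
        inter_flag = np.zeros(0, bool)
        pq = np.zeros((0, 2), np.int64)
        fac = np.zeros(0)
        ptr = np.zeros(n + 1, np.int64)

    return SpikingNetwork(
        arch=arch,
        tau=tau,
        t_ref=t_ref,
        g_sfa=g_sfa,
        nu_ext=nu_ext,
        j_ext=j_ext,
        module_of=module_of,
        is_excitatory=is_E,
        syn_ptr=ptr.astype(np.int64),
        syn_post=post.astype(np.int64),
        syn_weight=weight,
        syn_delay=delay,
        inter_slice=np.flatnonzero(inter_flag),
        inter_pq=pq[inter_flag],
        inter_factor=fac[inter_flag],
        seed=seed,
    )


@njit(cache=True)
def _simulate_kernel(
    n_steps,
    dt,
    decay_v,
    decay_c,
    g_sfa,
    lam_ext,
    j_ext,
    v_th,
    h_reset,
    ref_steps,
    syn_ptr,
    syn_post,
    syn_weight,
    syn_delay_steps,
    buf,
    spike_t,
    spike_i,
    alpha_c,
    seed,
):
    np.random.seed(seed)
    n = decay_v.shape[0]
    L = buf.shape[0]
    V = np.zeros(n)
    c = np.zeros(n)
    ref_until = np.full(n, -1, dtype=np.int64)
    n_spikes = 0
    cap = spike_t.shape[0]
    for t in range(n_steps):
        slot = t % L
        for i in range(n):
            arr = buf[slot, i]
            buf[slot, i] = 0.0
            c[i] *= decay_c[i]
            if t < ref_until[i]:
                continue  # clamped at reset; inputs during refractoriness discarded
            V[i] = V[i] * decay_v[i] - g_sfa[i] * c[i] * dt + arr
            if lam_ext[i] > 0.0:
                k = np.random.poisson(lam_ext[i])
                if k > 0:
                    V[i] += k * j_ext[i]
            if V[i] >= v_th:
                if n_spikes >= cap:
                    return -1
                spike_t[n_spikes] = t
                spike_i[n_spikes] = i
                n_spikes += 1
                V[i] = h_reset
                ref_until[i] = t + ref_steps[i]
                c[i] += alpha_c
                for s in range(syn_ptr[i], syn_ptr[i + 1]):
                    buf[(t + syn_delay_steps[s]) % L, syn_post[s]] += syn_weight[s]
    return n_spikes


def simulate(
    network: SpikingNetwork, duration: float, dt: float = 0.1, seed: int = 0
) -> SpikeRaster:
    """Clock-driven simulation of the network for ``duration`` ms.

    Delays are rounded to the grid (minimum one step so no same-step
    self-excitation); the external drive is one merged Poisson stream per
    neuron.  Reproducible for a fixed seed.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if dt > 0.5:
        raise ValueError("dt > 0.5 ms is refused on accuracy grounds")
    n_steps = int(round(duration / dt))
    delay_steps = np.maximum(1, np.round(network.syn_delay / dt).astype(np.int64))
    L = int(delay_steps.max()) + 1 if delay_steps.size else 1
    buf = np.zeros((L, network.n_neurons))
    decay_v = np.exp(-dt / network.tau)
    decay_c = np.exp(-dt / np.full(network.n_neurons, network.arch.tau_SFA))
    lam_ext = network.nu_ext * dt  # kHz * ms = expected events per step
    ref_steps = np.maximum(1, np.round(network.t_ref / dt)).astype(np.int64)
    cap = int(network.n_neurons * (duration / 1000.0) * 250 + 10000)
    spike_t = np.empty(cap, dtype=np.int64)
    spike_i = np.empty(cap, dtype=np.int64)
    ns = _simulate_kernel(
        n_steps,
        dt,
        decay_v,
        decay_c,
        network.g_sfa,
        lam_ext,
        network.j_ext,
        network.arch.V_th,
        network.arch.H_reset,
        ref_steps,
        network.syn_ptr,
        network.syn_post,
        network.syn_weight,
        delay_steps,
        buf,
        spike_t,
        spike_i,
        float(network.arch.calcium_increment),
        int(seed) % (2**31 - 1),
    )
    if ns < 0:
        raise RuntimeError("spike buffer overflow: firing rates far above the plausible ceiling")
    return SpikeRaster(
        times=spike_t[:ns] * dt,
        ids=spike_i[:ns],
        duration=float(n_steps * dt),
        module_of=network.module_of,
        is_excitatory=network.is_excitatory,
    )


def module_rates(
    raster: SpikeRaster, window: float = 20.0, bin: float = 20.0, n_E: int | None = None
) -> ModuleRateSeries:
    """Per-module excitatory population rates (Hz), smoothed over ``window`` ms.

    The rate sampled at the end of each window is the excitatory spike count
    inside the window divided by (window x n_E).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if bin <= 0:
        raise ValueError("bin must be positive")
    n_modules = int(raster.module_of.max()) + 1
    if n_E is None:
        n_E = int(raster.is_excitatory[raster.module_of == 0].sum())
    n_bins = int(np.floor(raster.duration / bin))
    if n_bins < 1:
        raise ValueError("duration shorter than one bin")
    counts = np.zeros((n_bins, n_modules))
    exc = raster.is_excitatory[raster.ids]
    t = raster.times[exc]
    m = raster.module_of[raster.ids[exc]]
    tb = np.minimum((t / bin).astype(np.int64), n_bins - 1)
    np.add.at(counts, (tb, m), 1.0)
    w_bins = max(1, int(round(window / bin)))
    cs = np.cumsum(counts, axis=0)
    sums = cs.copy()
    sums[w_bins:] = cs[w_bins:] - cs[:-w_bins]
    # windows shorter than w_bins at the start use the partial count
    eff_window = np.minimum(np.arange(1, n_bins + 1), w_bins) * bin
    rates = sums / (eff_window[:, None] / 1000.0) / n_E
    return ModuleRateSeries(rates=rates, bin=bin, window=window)


def binarize(rates: ModuleRateSeries, theta_bin: float = 40.0) -> BinaryStateSeries:
    """Threshold smoothed module rates into +/-1 Up/Down words."""
    states = np.where(rates.rates >= theta_bin, 1, -1).astype(np.int8)
    return BinaryStateSeries(states, bin_duration=rates.bin, origin="spiking binarized")
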