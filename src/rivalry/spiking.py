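"""Conductance-based spiking counterpart of the two-pool rate circuit.

Two pools of adaptive leaky integrate-and-fire neurons inhibit each
other through depressing synapses.  Each spike increments a
calcium-like variable that gates an outward (K+-reversal) adaptation
current — the spiking analogue of the rate model's local fatigue — and
transiently depresses the neuron's outgoing synaptic resources (the
nonlocal fatigue analogue, strength set by the release fraction).  The
stimulus protocol is mapped to an input current per pool, on top of a
small constant background current plus white current noise that plays
the role of the nonspecific background activity.

The point of this model is qualitative parity with the rate model at
small pool sizes: off-state memory held by the activity asymmetry,
dominance durations that grow with the frame interval, and habituation
from rest, all subject to finite-size spiking noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

try:  # pragma: no cover
    from numba import njit
except Exception:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(fn):
            return fn

        return wrap

from .readout import PerceptTrace, dominance_records

__all__ = ["SpikingParams", "SpikeRecord", "simulate_spiking", "rates_to_records"]


@dataclass(frozen=True)
class SpikingParams:
    """Adaptive-LIF two-pool network parameters (SI-ish units: mV, ms,
    pA, nS)."""

    neurons_per_pool: int = 20
    # membrane
    capacitance_pF: float = 200.0
    leak_nS: float = 10.0
    rest_mV: float = -70.0
    threshold_mV: float = -50.0
    reset_mV: float = -60.0
    refractory_ms: float = 2.0
    # calcium-activated adaptation current (local fatigue analogue)
    adapt_increment: float = 1.0
    adapt_tau_ms: float = 2000.0
    adapt_nS_per_ca: float = 0.03
    adapt_reversal_mV: float = -90.0
    # cross-pool inhibition with synaptic depression (nonlocal analogue)
    inhib_nS: float = 300.0
    inhib_reversal_mV: float = -75.0
    syn_tau_ms: float = 8.0
    depression_release_fraction: float = 0.0
    depression_tau_ms: float = 2000.0
    # drive mapping and background: the default operating point puts the
    # constant background current just above rheobase (200 pA), so pools
    # show low-rate nonspecific activity in off-states, and maps the
    # rate-model pulse S_on = 0.5 to ~150 pA of extra drive
    drive_pA_per_unit: float = 300.0
    background_pA: float = 210.0
    noise_pA: float = 30.0
    dt_ms: float = 0.1

    def __post_init__(self):
        if self.neurons_per_pool < 1:
            raise ValueError("need at least one neuron per pool")
        for name in ("capacitance_pF", "leak_nS", "adapt_tau_ms", "syn_tau_ms",
                     "depression_tau_ms", "dt_ms"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.depression_release_fraction < 1:
            raise ValueError("release fraction must be in [0, 1)")


@dataclass
class SpikeRecord:
    """Spike times per neuron (pool, neuron) and helpers for windowed
    pool rates."""

    spike_times: list  # list of (pool, neuron) -> np.ndarray of times (ms)
    n_pools: int
    neurons_per_pool: int
    t_span: tuple

    def pool_spike_times(self, pool: int) -> np.ndarray:
        out = [self.spike_times[pool * self.neurons_per_pool + j]
               for j in range(self.neurons_per_pool)]
        return np.sort(np.concatenate(out)) if out else np.array([])

    def pool_rate(self, pool: int, t_ms: float, window_ms: float) -> float:
        """Mean single-neuron rate (Hz) in [t - window, t]."""
        if window_ms <= 0:
            raise ValueError("window must be positive")
        st = self.pool_spike_times(pool)
        n = np.count_nonzero((st > t_ms - window_ms) & (st <= t_ms))
        return 1000.0 * n / (window_ms * self.neurons_per_pool)

    def to_frame(self):
        import pandas as pd

        rows = []
        for idx, times in enumerate(self.spike_times):
            pool, neuron = divmod(idx, self.neurons_per_pool)
            for t in times:
                rows.append((pool, neuron, t))
        return pd.DataFrame(rows, columns=["pool", "neuron", "time_ms"])


@njit(cache=False)
def _spiking_loop(drives, dt, M, C, gL, EL, Vth, Vreset, ref_steps,
                  dca, tau_ca, gA, EK, gI, EI, tau_syn, U, tau_d,
                  k_drive, I_bg, sigma, seed, spike_buf, spike_pool,
                  spike_neuron):  # pragma: no cover - numba-compiled
    np.random.seed(seed)
    n_steps = drives.shape[0]
    V = EL + 3.0 * np.random.randn(2, M)
    ca = np.zeros((2, M))
    d = np.ones((2, M))
    x = np.zeros(2)  # inhibitory conductance trace per postsynaptic pool
    refr = np.zeros((2, M), dtype=np.int64)
    n_spk = 0
    dec_syn = math.exp(-dt / tau_syn)
    dec_ca = math.exp(-dt / tau_ca)
    for step in range(n_steps):
        t = step * dt
        x[0] *= dec_syn
        x[1] *= dec_syn
        rel = np.zeros(2)
        for p in range(2):
            I_ext = k_drive * drives[step, p] + I_bg
            for j in range(M):
                ca[p, j] *= dec_ca
                d[p, j] += dt * (1.0 - d[p, j]) / tau_d
                if refr[p, j] > 0:
                    refr[p, j] -= 1
                    V[p, j] = Vreset
                    continue
                I_noise = sigma * np.random.randn() / math.sqrt(dt)
                dV = (
                    -gL * (V[p, j] - EL)
                    - gA * ca[p, j] * (V[p, j] - EK)
                    - gI * x[p] * (V[p, j] - EI)
                    + I_ext
                    + I_noise
                ) / C
                V[p, j] += dt * dV
                if V[p, j] >= Vth:
                    V[p, j] = Vreset
                    refr[p, j] = ref_steps
                    ca[p, j] += dca
                    rel[p] += d[p, j]
                    d[p, j] *= 1.0 - U
                    if n_spk < spike_buf.shape[0]:
                        spike_buf[n_spk] = t
                        spike_pool[n_spk] = p
                        spike_neuron[n_spk] = j
                        n_spk += 1
        # presynaptic release from pool p inhibits the other pool
        x[1] += rel[0] / M
        x[0] += rel[1] / M
    return n_spk


def simulate_spiking(params: SpikingParams, schedule, seed: int = 0,
                     t_span=None) -> SpikeRecord:
    """Simulate the spiking circuit under a drive schedule.

    ``schedule`` is any object with ``drive_array(times)`` returning the
    two-pool drive (same protocol objects as the rate model); the drive
    is mapped to a current ``drive_pA_per_unit * S_i(t)``.  Runs are
    deterministic given ``seed`` (initial-condition jitter and current
    noise come from one stream).
    """
    if t_span is None:
        t_span = schedule.span
    t0, t1 = float(t_span[0]), float(t_span[1])
    dt = params.dt_ms
    n_steps = int(math.ceil((t1 - t0) / dt - 1e-9))
    times = t0 + dt * np.arange(n_steps)
    drives = np.asarray(schedule.drive_array(times), dtype=float)
    if drives.shape[1] != 2:
        raise ValueError("spiking circuit is two-pool")

    M = params.neurons_per_pool
    max_spikes = int(2 * M * (t1 - t0) / 1000.0 * 200.0) + 1000  # 200 Hz cap
    spike_buf = np.empty(max_spikes)
    spike_pool = np.empty(max_spikes, dtype=np.int64)
    spike_neuron = np.empty(max_spikes, dtype=np.int64)
    n_spk = _spiking_loop(
        drives,
        float(dt),
        M,
        params.capacitance_pF,
        params.leak_nS,
        params.rest_mV,
        params.threshold_mV,
        params.reset_mV,
        int(round(params.refractory_ms / dt)),
        params.adapt_increment,
        params.adapt_tau_ms,
        params.adapt_nS_per_ca,
        params.adapt_reversal_mV,
        params.inhib_nS,
        params.inhib_reversal_mV,
        params.syn_tau_ms,
        params.depression_release_fraction,
        params.depression_tau_ms,
        params.drive_pA_per_unit,
        params.background_pA,
        params.noise_pA,
        int(seed) % (2 ** 31),
        spike_buf,
        spike_pool,
        spike_neuron,
    )
    if n_spk >= max_spikes:
        raise RuntimeError(
            "spike buffer overflow: runaway firing suggests numerical "
            "blow-up or unphysiological parameters"
        )
    t_arr = spike_buf[:n_spk] + t0
    key = spike_pool[:n_spk] * M + spike_neuron[:n_spk]
    spikes = [np.sort(t_arr[key == idx]) for idx in range(2 * M)]
    return SpikeRecord(
        spike_times=spikes, n_pools=2, neurons_per_pool=M, t_span=(t0, t1)
    )


def rates_to_records(record: SpikeRecord, decision_times, window_ms: float,
                     labels=("H", "V")):
    """Windowed-rate dominance readout bridging to the percept pipeline.

    The pool with the higher mean rate over the ``window_ms`` preceding
    each decision time is dominant; ties retain the previous label,
    exactly as in the rate-model readout.  Returns the run-length
    encoded dominance records.
    """
    decision_times = np.asarray(decision_times, dtype=float)
    if len(decision_times) == 0:
        raise ValueError("no decision times supplied")
    out_labels = []
    prev = None
    for t in decision_times:
        r = [record.pool_rate(p, t, window_ms) for p in range(record.n_pools)]
        if r[0] == r[1]:
            lab = prev if prev is not None else labels[0]
        else:
            lab = labels[int(np.argmax(r))]
        out_labels.append(lab)
        prev = lab
    trace = PerceptTrace(labels=out_labels, decision_times=decision_times)
    return dominance_records(trace), trace
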