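"""Conductance-based verification tier: Traub-Miles-type HH network.

Neurons are single-compartment Hodgkin-Huxley models in the Traub-Miles
formulation with an added slow potassium (M-type) spike-rate-adaptation
current; synapses follow a first-order kinetic scheme in which a
transmitter pulse of fixed duration is triggered by each presynaptic spike
(detected as an upward crossing of a detection voltage).  The network is
integrated with an adaptive embedded Dormand-Prince 5(4) Runge-Kutta scheme
with a capped maximal step, compiled with numba.

Units: mV, ms, nA, nF, uS throughout (so g * V is nA and C dV/dt is nA).

All neuron and synapse constants live in the two parameter dataclasses
below — a single authoritative table.  The values are standard
Traub-Miles / first-order-kinetics literature values, adjusted only to set
the operating point (bias currents, synaptic magnitudes) of a desk-scale
90 PN + 30 LN antennal-lobe-like network; every run records the active
table in its metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
from numba import njit
from scipy.ndimage import gaussian_filter1d
from scipy.stats import linregress

from . import netgen
from .netgen import ConnectivitySpec, PopulationSpec, RampProtocol

__all__ = [
    "HHNeuronParams",
    "KineticSynapseParams",
    "HHNetwork",
    "SpikeRecord",
    "SDFTrace",
    "build_hh_network",
    "run_hh",
    "run_ramp_experiment",
    "count_slope",
    "spike_density",
    "slope_map_hh",
    "synapse_drive",
    "hh_rhs",
    "hh_step",
]


# --------------------------------------------------------------------------
# parameter tables


@dataclass(frozen=True)
class HHNeuronParams:
    """Traub-Miles membrane constants plus M-type adaptation current."""

    C: float = 0.143          # nF
    g_Na: float = 7.15        # uS
    E_Na: float = 50.0        # mV
    g_K: float = 1.43         # uS
    E_K: float = -95.0        # mV
    g_L: float = 0.02672      # uS
    E_L: float = -63.563      # mV
    g_M: float = 0.0572       # uS, adaptation conductance (0 disables)
    tau_max_M: float = 200.0  # ms, peak M-current time constant
    V_T: float = -63.0        # mV, rate-function voltage offset

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("capacitance must be > 0")
        for name in ("g_Na", "g_K", "g_L", "g_M"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class KineticSynapseParams:
    """First-order kinetic synapse constants (transmitter-pulse model)."""

    E_rev_exc: float = 0.0     # mV
    E_rev_inh: float = -80.0   # mV
    alpha_exc: float = 1.1     # 1/ms, activation rate while transmitter present
    beta_exc: float = 0.19     # 1/ms, decay rate
    alpha_inh: float = 5.0     # 1/ms
    beta_inh: float = 0.18     # 1/ms
    t_rel_exc: float = 1.0     # ms, transmitter duration after a spike
    t_rel_inh: float = 1.0     # ms
    V_detect: float = -20.0    # mV, presynaptic spike-detection threshold
    lockout: float = 2.0       # ms, detection refractory separation
    jitter_frac: float = 0.1   # Gaussian sd of per-synapse conductance, relative

    def __post_init__(self) -> None:
        for name in ("alpha_exc", "beta_exc", "alpha_inh", "beta_inh",
                     "t_rel_exc", "t_rel_inh"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


#: Default bias currents (nA): PNs just above rheobase (spontaneously
#: active), LNs below it (driven by stimulus and PN input); each neuron
#: draws an individual uniform jitter of +-bias_jitter.
HH_BIAS = dict(bias_E=0.41, bias_I=0.25, bias_jitter=0.05)


# --------------------------------------------------------------------------
# network container and construction


@dataclass
class HHNetwork:
    """Realized HH network: dense weight matrix plus per-neuron attributes.

    ``W[i, j]`` is the (jittered) maximal conductance of the synapse from
    neuron j onto neuron i in uS; the sign of the synaptic current comes
    from the presynaptic reversal potential ``erev_pre[j]``.
    """

    pops: PopulationSpec
    W: np.ndarray
    is_exc: np.ndarray
    erev_pre: np.ndarray
    alpha_pre: np.ndarray
    beta_pre: np.ndarray
    trel_pre: np.ndarray
    bias: np.ndarray
    stim_mask: np.ndarray
    neuron: HHNeuronParams = field(default_factory=HHNeuronParams)
    syn: KineticSynapseParams = field(default_factory=KineticSynapseParams)
    meta: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.W.shape[0]


def build_hh_network(
    pops: PopulationSpec,
    conn: ConnectivitySpec,
    f: float,
    seed,
    neuron: Optional[HHNeuronParams] = None,
    syn: Optional[KineticSynapseParams] = None,
    bias_E: float = HH_BIAS["bias_E"],
    bias_I: float = HH_BIAS["bias_I"],
    bias_jitter: float = HH_BIAS["bias_jitter"],
) -> HHNetwork:
    """Realize a random HH network (excitatory block first) with per-synapse
    Gaussian conductance jitter and per-neuron uniform bias jitter."""
    neuron = neuron or HHNeuronParams()
    syn = syn or KineticSynapseParams()
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    ss = root.spawn(8)
    ne, ni = pops.N_E, pops.N_I
    n = ne + ni
    W = np.zeros((n, n))
    W[:ne, :ne] = netgen.sample_connectivity(ne, ne, conn.p_EE, conn.g_EE, ss[0], zero_diagonal=True)
    W[:ne, ne:] = netgen.sample_connectivity(ni, ne, conn.p_EI, conn.g_EI, ss[1])
    W[ne:, :ne] = netgen.sample_connectivity(ne, ni, conn.p_IE, conn.g_IE, ss[2])
    W[ne:, ne:] = netgen.sample_connectivity(ni, ni, conn.p_II, conn.g_II, ss[3], zero_diagonal=True)
    if syn.jitter_frac > 0:
        rng = np.random.default_rng(ss[4])
        jit = 1.0 + syn.jitter_frac * rng.standard_normal(W.shape)
        W *= np.clip(jit, 0.0, None)
    is_exc = np.zeros(n, dtype=np.bool_)
    is_exc[:ne] = True
    erev = np.where(is_exc, syn.E_rev_exc, syn.E_rev_inh).astype(float)
    alpha = np.where(is_exc, syn.alpha_exc, syn.alpha_inh).astype(float)
    beta = np.where(is_exc, syn.beta_exc, syn.beta_inh).astype(float)
    trel = np.where(is_exc, syn.t_rel_exc, syn.t_rel_inh).astype(float)
    rngb = np.random.default_rng(ss[5])
    bias = np.where(is_exc, bias_E, bias_I) + rngb.uniform(-bias_jitter, bias_jitter, n)
    stim = np.zeros(n)
    stim[netgen.select_stimulated(ne, f, ss[6])] = 1.0
    stim[ne + netgen.select_stimulated(ni, f, ss[7])] = 1.0
    meta = dict(seed=repr(root.entropy),
                f=f, conn=asdict(conn), neuron=asdict(neuron), syn=asdict(syn),
                bias_E=bias_E, bias_I=bias_I, bias_jitter=bias_jitter)
    return HHNetwork(pops, W, is_exc, erev, alpha, beta, trel, bias, stim,
                     neuron, syn, meta)


# --------------------------------------------------------------------------
# right-hand side (numpy reference; the numba kernel mirrors it)


def _vtrap(x, y):
    """x / (exp(x/y) - 1) with its limit y - x/2 near the removable singularity."""
    x = np.asarray(x, float)
    r = np.where(np.abs(x / y) < 1e-6, y - 0.5 * x, x / np.expm1(np.clip(x / y, -50, 50)))
    return r


def _gate_rates(V, V_T):
    v = V - V_T
    a_m = 0.32 * _vtrap(13.0 - v, 4.0)
    b_m = 0.28 * _vtrap(v - 40.0, 5.0)
    a_h = 0.128 * np.exp(np.clip((17.0 - v) / 18.0, -50, 50))
    b_h = 4.0 / (1.0 + np.exp(np.clip((40.0 - v) / 5.0, -50, 50)))
    a_n = 0.032 * _vtrap(15.0 - v, 5.0)
    b_n = 0.5 * np.exp(np.clip((10.0 - v) / 40.0, -50, 50))
    return a_m, b_m, a_h, b_h, a_n, b_n


def synapse_drive(s_values: np.ndarray, weights: np.ndarray,
                  E_rev: np.ndarray, V_post: np.ndarray) -> np.ndarray:
    """Summed synaptic current onto each postsynaptic neuron (nA).

    I_i = sum_j weights[i, j] * s_j * (E_rev[j] - V_i); excitatory and
    inhibitory reversal potentials are carried per presynaptic neuron.
    """
    s_values = np.asarray(s_values, float)
    if np.any((s_values < 0) | (s_values > 1)):
        raise ValueError("synaptic activations must lie in [0, 1]")
    if weights.shape[1] != s_values.size or weights.shape[0] != np.size(V_post):
        raise ValueError("shape mismatch between weights, s_values and V_post")
    return weights @ (s_values * E_rev) - np.asarray(V_post, float) * (weights @ s_values)


def hh_rhs(t: float, state: np.ndarray, net: HHNetwork, last_spike: np.ndarray,
           I_stim: float) -> np.ndarray:
    """Reference (numpy) derivative of the packed state [V, m, h, n, w, s]."""
    n = net.n
    V, m, h, nn, w, s = state.reshape(6, n)
    p = net.neuron
    a_m, b_m, a_h, b_h, a_n, b_n = _gate_rates(V, p.V_T)
    I_ion = (
        -p.g_Na * m**3 * h * (V - p.E_Na)
        - p.g_K * nn**4 * (V - p.E_K)
        - p.g_M * w * (V - p.E_K)
        - p.g_L * (V - p.E_L)
    )
    I_syn = synapse_drive(np.clip(s, 0.0, 1.0), net.W, net.erev_pre, V)
    dV = (I_ion + net.bias + I_stim * net.stim_mask + I_syn) / p.C
    dm = a_m * (1 - m) - b_m * m
    dh = a_h * (1 - h) - b_h * h
    dn = a_n * (1 - nn) - b_n * nn
    w_inf = 1.0 / (1.0 + np.exp(-(V + 35.0) / 10.0))
    tau_w = p.tau_max_M / (3.3 * np.exp((V + 35.0) / 20.0) + np.exp(-(V + 35.0) / 20.0))
    dw = (w_inf - w) / tau_w
    T = ((t - last_spike) <= net.trel_pre) & (last_spike >= 0)
    ds = net.alpha_pre * T * (1 - s) - net.beta_pre * s
    return np.concatenate([dV, dm, dh, dn, dw, ds])


# --------------------------------------------------------------------------
# numba kernel (Dormand-Prince 5(4))

# Butcher tableau
_DP_C = np.array([0.0, 1 / 5, 3 / 10, 4 / 5, 8 / 9, 1.0, 1.0])
_DP_A = np.array([
    [1 / 5, 0, 0, 0, 0, 0],
    [3 / 40, 9 / 40, 0, 0, 0, 0],
    [44 / 45, -56 / 15, 32 / 9, 0, 0, 0],
    [19372 / 6561, -25360 / 2187, 64448 / 6561, -212 / 729, 0, 0],
    [9017 / 3168, -355 / 33, 46732 / 5247, 49 / 176, -5103 / 18656, 0],
    [35 / 384, 0, 500 / 1113, 125 / 192, -2187 / 6784, 11 / 84],
])
_DP_B5 = np.array([35 / 384, 0, 500 / 1113, 125 / 192, -2187 / 6784, 11 / 84, 0])
_DP_B4 = np.array([5179 / 57600, 0, 7571 / 16695, 393 / 640, -92097 / 339200,
                   187 / 2100, 1 / 40])


@njit(cache=True)
def _kernel_rhs(t, y, dy, W, erev, alpha, beta, trel, last_spk, bias, stim_mask,
                I_stim, C, gNa, ENa, gK, EK, gM, gL, EL, VT, tau_max_M, n):
    V = y[0:n]
    m = y[n:2 * n]
    h = y[2 * n:3 * n]
    nv = y[3 * n:4 * n]
    w = y[4 * n:5 * n]
    s = y[5 * n:6 * n]
    # synaptic currents via two matvecs: I_i = a_i - V_i * b_i
    for i in range(n):
        a = 0.0
        b = 0.0
        for j in range(n):
            wij = W[i, j]
            if wij != 0.0:
                sj = s[j]
                if sj < 0.0:
                    sj = 0.0
                elif sj > 1.0:
                    sj = 1.0
                a += wij * sj * erev[j]
                b += wij * sj
        Isyn = a - V[i] * b
        v = V[i] - VT
        # Na/K rate functions with singularity-safe vtrap
        x = 13.0 - v
        a_m = 0.32 * (4.0 - 0.5 * x) if abs(x) < 1e-6 else 0.32 * x / (np.exp(x / 4.0) - 1.0)
        x = v - 40.0
        b_m = 0.28 * (5.0 - 0.5 * x) if abs(x) < 1e-6 else 0.28 * x / (np.exp(x / 5.0) - 1.0)
        a_h = 0.128 * np.exp((17.0 - v) / 18.0)
        b_h = 4.0 / (1.0 + np.exp((40.0 - v) / 5.0))
        x = 15.0 - v
        a_n = 0.032 * (5.0 - 0.5 * x) if abs(x) < 1e-6 else 0.032 * x / (np.exp(x / 5.0) - 1.0)
        b_n = 0.5 * np.exp((10.0 - v) / 40.0)
        I_ion = (-gNa * m[i] ** 3 * h[i] * (V[i] - ENa)
                 - gK * nv[i] ** 4 * (V[i] - EK)
                 - gM * w[i] * (V[i] - EK)
                 - gL * (V[i] - EL))
        dy[i] = (I_ion + bias[i] + I_stim * stim_mask[i] + Isyn) / C
        dy[n + i] = a_m * (1.0 - m[i]) - b_m * m[i]
        dy[2 * n + i] = a_h * (1.0 - h[i]) - b_h * h[i]
        dy[3 * n + i] = a_n * (1.0 - nv[i]) - b_n * nv[i]
        w_inf = 1.0 / (1.0 + np.exp(-(V[i] + 35.0) / 10.0))
        tau_w = tau_max_M / (3.3 * np.exp((V[i] + 35.0) / 20.0) + np.exp(-(V[i] + 35.0) / 20.0))
        dy[4 * n + i] = (w_inf - w[i]) / tau_w
        T = 1.0 if (last_spk[i] >= 0.0 and (t - last_spk[i]) <= trel[i]) else 0.0
        dy[5 * n + i] = alpha[i] * T * (1.0 - s[i]) - beta[i] * s[i]


@njit(cache=True)
def _ramp(t, t_settle, t_up, t_down, I_peak):
    if t < t_settle:
        return 0.0
    if t < t_settle + t_up:
        return I_peak * (t - t_settle) / t_up
    if t <= t_settle + t_up + t_down:
        return I_peak * (t_settle + t_up + t_down - t) / t_down
    return 0.0


@njit(cache=True)
def _integrate(y, W, erev, alpha, beta, trel, bias, stim_mask,
               t0, t_total, t_settle, t_up, t_down, I_peak,
               dt_max, dt_min, rtol, atol_V, atol_gate,
               V_detect, lockout,
               C, gNa, ENa, gK, EK, gM, gL, EL, VT, tau_max_M,
               A, B5, B4, Cc,
               spike_t, spike_id, trace_dt, trace):
    """Adaptive DP5(4) integration of the full network with spike detection.

    Returns (n_spikes, status, max_gate_violation, t_reached).
    status: 0 ok, 1 step-size underflow, 2 spike-buffer overflow.
    """
    n = W.shape[0]
    ndim = 6 * n
    last_spk = np.full(n, -1e9)
    last_det = np.full(n, -1e9)
    k = np.zeros((7, ndim))
    ytmp = np.zeros(ndim)
    y5 = np.zeros(ndim)
    y4 = np.zeros(ndim)
    t = t0
    dt = min(dt_max, 0.01)
    n_sp = 0
    max_viol = 0.0
    n_trace = trace.shape[0]
    while t < t_total - 1e-12:
        if dt > dt_max:
            dt = dt_max
        if dt > t_total - t:
            dt = t_total - t
        # stages
        _kernel_rhs(t, y, k[0], W, erev, alpha, beta, trel, last_spk, bias,
                    stim_mask, _ramp(t, t_settle, t_up, t_down, I_peak),
                    C, gNa, ENa, gK, EK, gM, gL, EL, VT, tau_max_M, n)
        for st in range(1, 7):
            for d in range(ndim):
                acc = 0.0
                for q in range(st):
                    acc += A[st - 1, q] * k[q, d]
                ytmp[d] = y[d] + dt * acc
            ts = t + Cc[st] * dt
            _kernel_rhs(ts, ytmp, k[st], W, erev, alpha, beta, trel, last_spk,
                        bias, stim_mask, _ramp(ts, t_settle, t_up, t_down, I_peak),
                        C, gNa, ENa, gK, EK, gM, gL, EL, VT, tau_max_M, n)
        err = 0.0
        for d in range(ndim):
            acc5 = 0.0
            acc4 = 0.0
            for q in range(7):
                acc5 += B5[q] * k[q, d]
                acc4 += B4[q] * k[q, d]
            y5[d] = y[d] + dt * acc5
            y4[d] = y[d] + dt * acc4
            atol = atol_V if d < n else atol_gate
            sc = atol + rtol * abs(y5[d])
            e = abs(y5[d] - y4[d]) / sc
            if e > err:
                err = e
        if err <= 1.0:
            # accept: spike detection on the voltage block
            t_new = t + dt
            for i in range(n):
                if y[i] < V_detect and y5[i] >= V_detect and (t_new - last_det[i]) > lockout:
                    frac = (V_detect - y[i]) / (y5[i] - y[i])
                    tspk = t + frac * dt
                    last_det[i] = tspk
                    last_spk[i] = tspk
                    if n_sp >= spike_t.shape[0]:
                        return n_sp, 2, max_viol, t_new
                    spike_t[n_sp] = tspk
                    spike_id[n_sp] = i
                    n_sp += 1
            for d in range(n, ndim):
                g = y5[d]
                v = -g if g < 0.0 else (g - 1.0 if g > 1.0 else 0.0)
                if v > max_viol:
                    max_viol = v
            for d in range(ndim):
                y[d] = y5[d]
            # voltage trace sampling on a fixed grid
            if n_trace > 0:
                idx = int(t_new / trace_dt)
                if idx < n_trace and trace[idx, 0] == -1e9:
                    for i in range(n):
                        trace[idx, i] = y[i]
            t = t_new
        fac = 0.9 * err ** (-0.2) if err > 1e-10 else 5.0
        if fac < 0.2:
            fac = 0.2
        elif fac > 5.0:
            fac = 5.0
        dt *= fac
        if dt < dt_min:
            return n_sp, 1, max_viol, t
    return n_sp, 0, max_viol, t


# --------------------------------------------------------------------------
# python-level driver and analyses


@dataclass
class SpikeRecord:
    """Spike times (ms) and neuron ids; excitatory ids are < N_E."""

    times: np.ndarray
    ids: np.ndarray
    N_E: int
    N_I: int
    t_total: float

    def population(self, which: str) -> "SpikeRecord":
        sel = self.ids < self.N_E if which == "E" else self.ids >= self.N_E
        return SpikeRecord(self.times[sel], self.ids[sel], self.N_E, self.N_I, self.t_total)

    def to_text(self, path) -> None:
        np.savetxt(path, np.column_stack([self.times, self.ids]),
                   fmt=("%.4f", "%d"), header="time_ms neuron_id")


@dataclass
class SDFTrace:
    t: np.ndarray
    rate: np.ndarray  # spikes/ms (population total)


def _initial_state(net: HHNetwork) -> np.ndarray:
    p = net.neuron
    n = net.n
    V0 = np.full(n, p.E_L)
    a_m, b_m, a_h, b_h, a_n, b_n = _gate_rates(V0, p.V_T)
    w0 = 1.0 / (1.0 + np.exp(-(V0 + 35.0) / 10.0))
    return np.concatenate([
        V0, a_m / (a_m + b_m), a_h / (a_h + b_h), a_n / (a_n + b_n), w0,
        np.zeros(n),
    ])


def run_hh(
    net: HHNetwork,
    protocol: Optional[RampProtocol] = None,
    t_total: Optional[float] = None,
    dt_max: float = 0.1,
    rtol: float = 1e-5,
    atol_V: float = 1e-4,
    atol_gate: float = 1e-6,
    record_trace: bool = False,
    trace_dt: float = 1.0,
    y0: Optional[np.ndarray] = None,
) -> dict:
    """Integrate the network; returns spikes, status and diagnostics.

    Without a protocol the network runs unstimulated for ``t_total`` ms
    (bias currents only).  Gating/synaptic variables leaving [0, 1] by more
    than 1e-3 raise an integration error, per the contract that bounds are
    maintained by the dynamics, not by projection.
    """
    if protocol is None and t_total is None:
        raise ValueError("give a protocol or t_total")
    if protocol is not None:
        t_end = protocol.t_total
        t_settle, t_up, t_down, I_peak = (protocol.t_settle, protocol.t_up,
                                          protocol.t_down, protocol.I_peak)
    else:
        t_end = float(t_total)
        t_settle, t_up, t_down, I_peak = t_end + 1.0, 1.0, 1.0, 0.0
    y = _initial_state(net) if y0 is None else np.array(y0, dtype=float)
    cap = int(net.n * t_end * 0.5) + 1000  # 500 Hz/neuron headroom
    spike_t = np.zeros(cap)
    spike_id = np.zeros(cap, dtype=np.int64)
    n_tr = int(t_end / trace_dt) + 1 if record_trace else 0
    trace = np.full((n_tr, net.n), -1e9)
    p = net.neuron
    n_sp, status, viol, t_reached = _integrate(
        y, net.W, net.erev_pre, net.alpha_pre, net.beta_pre, net.trel_pre,
        net.bias, net.stim_mask,
        0.0, t_end, t_settle, t_up, t_down, I_peak,
        dt_max, 1e-8, rtol, atol_V, atol_gate,
        net.syn.V_detect, net.syn.lockout,
        p.C, p.g_Na, p.E_Na, p.g_K, p.E_K, p.g_M, p.g_L, p.E_L, p.V_T,
        p.tau_max_M,
        _DP_A, _DP_B5, _DP_B4, _DP_C,
        spike_t, spike_id, trace_dt, trace,
    )
    if status == 1:
        raise RuntimeError(f"integration failure: step-size underflow at t={t_reached:.3f} ms")
    if status == 2:
        raise RuntimeError(f"spike buffer overflow at t={t_reached:.3f} ms")
    if viol > 1e-3:
        raise RuntimeError(f"gating variable left [0,1] by {viol:.2e}")
    spikes = SpikeRecord(spike_t[:n_sp].copy(), spike_id[:n_sp].copy(),
                         net.pops.N_E, net.pops.N_I, t_end)
    out = dict(spikes=spikes, status=status, gate_violation=float(viol),
               final_state=y)
    if record_trace:
        tgrid = np.arange(n_tr) * trace_dt
        ok = trace[:, 0] > -1e9
        out["trace_t"] = tgrid[ok]
        out["trace_V"] = trace[ok]
    return out


def hh_step(t: float, y: np.ndarray, net: HHNetwork, last_spike: np.ndarray,
            I_stim: float, dt_max: float = 0.1, rtol: float = 1e-5,
            atol_V: float = 1e-4, atol_gate: float = 1e-6,
            dt_init: float = 0.01) -> tuple:
    """One accepted adaptive DP5(4) step of the reference numpy dynamics.

    Returns ``(t_new, y_new, dt_used)``.  Used for step-level verification
    against the compiled kernel; production runs go through :func:`run_hh`.
    """
    n = net.n
    dt = min(dt_init, dt_max)
    atol = np.concatenate([np.full(n, atol_V), np.full(5 * n, atol_gate)])
    while True:
        k = np.zeros((7, y.size))
        k[0] = hh_rhs(t, y, net, last_spike, I_stim)
        for st in range(1, 7):
            ytmp = y + dt * (_DP_A[st - 1, :st] @ k[:st])
            k[st] = hh_rhs(t + _DP_C[st] * dt, ytmp, net, last_spike, I_stim)
        y5 = y + dt * (_DP_B5 @ k)
        y4 = y + dt * (_DP_B4 @ k)
        err = float(np.max(np.abs(y5 - y4) / (atol + rtol * np.abs(y5))))
        if err <= 1.0:
            return t + dt, y5, dt
        dt *= max(0.2, 0.9 * err ** -0.2)
        if dt < 1e-8:
            raise RuntimeError("step-size underflow")


def _window_counts(spikes: SpikeRecord, protocol: RampProtocol, window: float):
    """Per-window spike counts of one population over the up and down ramps."""
    n_up = int(round(protocol.t_up / window))
    n_down = int(round(protocol.t_down / window))
    t1 = protocol.t_settle
    edges_up = t1 + window * np.arange(n_up + 1)
    edges_down = t1 + protocol.t_up + window * np.arange(n_down + 1)
    c_up = np.histogram(spikes.times, edges_up)[0]
    c_down = np.histogram(spikes.times, edges_down)[0]
    I_up = netgen.ramp_current(edges_up[:-1] + window / 2, protocol)
    I_down = netgen.ramp_current(edges_down[:-1] + window / 2, protocol)
    return c_up, I_up, c_down, I_down


def run_ramp_experiment(
    net: HHNetwork,
    protocol: RampProtocol,
    window: float = 25.0,
    **run_kw,
) -> dict:
    """Ramp-drive experiment with windowed spike counting.

    Spikes are counted in fixed windows over the up- and down-ramp; windows
    with matching instantaneous input current (mirror-symmetric positions
    for equal ramp durations) are paired and their counts summed, averaging
    out adaptation-induced up/down hysteresis.  Returns the spike record,
    per-population paired counts and the current per paired window.
    """
    res = run_hh(net, protocol=protocol, **run_kw)
    spikes = res["spikes"]
    out = dict(spikes=spikes, status=res["status"])
    for pop in ("E", "I"):
        c_up, I_up, c_down, I_down = _window_counts(spikes.population(pop),
                                                    protocol, window)
        n = min(c_up.size, c_down.size)
        paired = c_up[:n] + c_down[::-1][:n]
        I_paired = 0.5 * (I_up[:n] + I_down[::-1][:n])
        out[f"counts_{pop}"] = paired
        out[f"counts_up_{pop}"] = c_up
        out[f"counts_down_{pop}"] = c_down
        out[f"current_{pop}"] = I_paired
    out["window"] = window
    return out


def count_slope(counts: np.ndarray, currents: np.ndarray,
                normalize_to: Optional[float] = None) -> float:
    """Least-squares slope of windowed spike counts versus input current."""
    counts = np.asarray(counts, float)
    currents = np.asarray(currents, float)
    if counts.size < 3:
        raise ValueError("need at least 3 windows")
    if np.ptp(currents) == 0:
        raise ValueError("degenerate regression: constant current")
    slope = float(linregress(currents, counts).slope)
    if normalize_to:
        slope /= normalize_to
    return slope


def spike_density(spikes: SpikeRecord, kernel_width: float,
                  dt: float = 1.0) -> SDFTrace:
    """Gaussian-kernel population rate estimate (spikes/ms), edge-corrected.

    The kernel mass lost outside the recording interval is restored by
    dividing by the smoothed support indicator, so the time integral of the
    SDF equals the total spike count.
    """
    if kernel_width <= 0:
        raise ValueError("kernel width must be > 0")
    t = np.arange(0.0, spikes.t_total + dt, dt)
    hist = np.histogram(spikes.times, np.append(t - dt / 2, t[-1] + dt / 2))[0].astype(float)
    sigma = kernel_width / dt
    # each spike's kernel is renormalized by its mass inside the recording
    # interval (edge correction), which conserves total mass exactly
    support = gaussian_filter1d(np.ones_like(hist), sigma, mode="constant", truncate=8.0)
    rate = gaussian_filter1d(hist / support, sigma, mode="constant", truncate=8.0) / dt
    return SDFTrace(t=t, rate=rate)


def slope_map_hh(
    p_EI_values: Sequence[float],
    g_I_values: Sequence[float],
    base_conn: ConnectivitySpec,
    pops: PopulationSpec,
    protocol: RampProtocol,
    f: float,
    reps: int = 1,
    seed: int = 0,
    window: float = 25.0,
    normalize: bool = True,
    **run_kw,
):
    """Slope of E-population windowed counts vs current over a (p_EI, g_I) grid.

    Each cell realizes ``reps`` networks (deterministic per-cell seeds),
    runs the ramp experiment and averages the regression slopes.  Failed
    cells are recorded as NaN, never interpolated over.  Returns a
    :class:`gainnet.maps.SlopeMap` with g_I on the y axis.
    """
    from .maps import SlopeMap

    p_EI_values = np.asarray(p_EI_values, float)
    g_I_values = np.asarray(g_I_values, float)
    slopes = np.full((g_I_values.size, p_EI_values.size), np.nan)
    errs = np.full_like(slopes, np.nan)
    for gi, g in enumerate(g_I_values):
        for pj, p in enumerate(p_EI_values):
            cell = []
            for rep in range(reps):
                ss = np.random.SeedSequence((seed, gi, pj, rep))
                conn = base_conn.replace(p_EI=float(p), g_EI=float(g), g_II=float(g))
                net = build_hh_network(pops, conn, f, ss)
                try:
                    exp = run_ramp_experiment(net, protocol, window=window, **run_kw)
                    cell.append(count_slope(exp["counts_E"], exp["current_E"]))
                except RuntimeError:
                    continue
            if cell:
                slopes[gi, pj] = np.mean(cell)
                errs[gi, pj] = (np.std(cell, ddof=1) / np.sqrt(len(cell))
                                if len(cell) > 1 else np.nan)
    meta = dict(tier="hh", f=f, reps=reps, seed=seed, window=window,
                protocol=asdict(protocol), conn=asdict(base_conn),
                N_E=pops.N_E, N_I=pops.N_I)
    if normalize:
        mx = np.nanmax(np.abs(slopes))
        if mx > 0:
            meta["normalization"] = float(mx)
            slopes = slopes / mx
            errs = errs / mx
    return SlopeMap("p_EI", p_EI_values, "g_I", g_I_values, slopes,
                    stderr=errs, meta=meta)
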