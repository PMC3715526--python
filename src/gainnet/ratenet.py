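"""Microscopic firing-rate network on realized random connectivity.

Each of the N_E + N_I neurons follows

    tau_X dr_i/dt = -r_i + G_X(u_i),
    u_i = sum_j W_XE[i,j] r_j^E - sum_j W_XI[i,j] r_j^I - theta_i + I * 1[i stimulated]

with threshold-linear gains and Bernoulli weight matrices from
:mod:`gainnet.netgen`.  The module integrates to steady state, detects
divergence (the lateral-excitation instability), and measures the slope of
the population-mean excitatory rate versus stimulus intensity — the
quantity whose zero defines gain control.

Thresholds are folded into the gain function (G_X(u) = beta*(u - theta)^+)
so the same convention as the mean field applies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.stats import linregress

from . import netgen
from .meanfield import GainParams
from .netgen import ConnectivitySpec, PopulationSpec

__all__ = [
    "RateNetwork",
    "RateTrajectory",
    "SteadyStateSummary",
    "build_rate_network",
    "rate_rhs",
    "integrate_to_steady_state",
    "intensity_sweep",
]


@dataclass
class RateNetwork:
    """Realized weight blocks (post x pre), thresholds, gains and stimulus sets.

    ``theta_E_i`` / ``theta_I_i`` hold per-neuron thresholds; by default
    they are uniform at the population values in ``gain`` (heterogeneity is
    offered for robustness checks only).
    """

    W_EE: np.ndarray
    W_EI: np.ndarray
    W_IE: np.ndarray
    W_II: np.ndarray
    stim_E: np.ndarray
    stim_I: np.ndarray
    gain: GainParams
    theta_E_i: Optional[np.ndarray] = None
    theta_I_i: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        ne, ni = self.N_E, self.N_I
        shapes = {
            "W_EE": (ne, ne), "W_EI": (ne, ni),
            "W_IE": (ni, ne), "W_II": (ni, ni),
        }
        for name, shape in shapes.items():
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} has shape {getattr(self, name).shape}, expected {shape}")

    @property
    def N_E(self) -> int:
        return self.W_EE.shape[0]

    @property
    def N_I(self) -> int:
        return self.W_II.shape[0]

    @property
    def N(self) -> int:
        return self.N_E + self.N_I

    def stim_mask(self) -> np.ndarray:
        m = np.zeros(self.N)
        m[self.stim_E] = 1.0
        m[self.N_E + self.stim_I] = 1.0
        return m


@dataclass
class RateTrajectory:
    t: np.ndarray
    rates: np.ndarray  # (time, neuron)


@dataclass
class SteadyStateSummary:
    mean_E_s: float
    mean_E_u: float
    mean_I_s: float
    mean_I_u: float
    mean_E: float
    mean_I: float
    max_drdt: float
    converged: bool
    diverged: bool


def build_rate_network(
    pops: PopulationSpec,
    conn: ConnectivitySpec,
    gain: GainParams,
    f: float,
    seed,
    self_connections: bool = False,
    threshold_jitter: float = 0.0,
) -> RateNetwork:
    """Realize connectivity and stimulated subsets from independent seed streams.

    Recurrent blocks (E<-E, I<-I) have their diagonals zeroed by default.
    ``threshold_jitter`` adds uniform +-jitter to per-neuron thresholds
    (robustness checks; the defaults are homogeneous).
    """
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    ss = root.spawn(7)
    th_E = th_I = None
    if threshold_jitter > 0:
        rng = np.random.default_rng(ss[6])
        th_E = gain.theta_E + rng.uniform(-threshold_jitter, threshold_jitter, pops.N_E)
        th_I = gain.theta_I + rng.uniform(-threshold_jitter, threshold_jitter, pops.N_I)
    zd = not self_connections
    return RateNetwork(
        W_EE=netgen.sample_connectivity(pops.N_E, pops.N_E, conn.p_EE, conn.g_EE, ss[0], zero_diagonal=zd),
        W_EI=netgen.sample_connectivity(pops.N_I, pops.N_E, conn.p_EI, conn.g_EI, ss[1]),
        W_IE=netgen.sample_connectivity(pops.N_E, pops.N_I, conn.p_IE, conn.g_IE, ss[2]),
        W_II=netgen.sample_connectivity(pops.N_I, pops.N_I, conn.p_II, conn.g_II, ss[3], zero_diagonal=zd),
        stim_E=netgen.select_stimulated(pops.N_E, f, ss[4]),
        stim_I=netgen.select_stimulated(pops.N_I, f, ss[5]),
        gain=gain,
        theta_E_i=th_E,
        theta_I_i=th_I,
    )


def rate_rhs(rates: np.ndarray, network: RateNetwork, I: float) -> np.ndarray:
    """Time derivative of all N_E + N_I rates (excitatory block first)."""
    if rates.shape != (network.N,):
        raise ValueError(f"rates has shape {rates.shape}, expected ({network.N},)")
    g = network.gain
    r_E = rates[: network.N_E]
    r_I = rates[network.N_E:]
    u_E = network.W_EE @ r_E - network.W_EI @ r_I
    u_I = network.W_IE @ r_E - network.W_II @ r_I
    u_E[network.stim_E] += I
    u_I[network.stim_I] += I
    th_E = network.theta_E_i if network.theta_E_i is not None else g.theta_E
    th_I = network.theta_I_i if network.theta_I_i is not None else g.theta_I
    dE = (-r_E + g.beta_E * np.maximum(u_E - th_E, 0.0)) / g.tau_E
    dI = (-r_I + g.beta_I * np.maximum(u_I - th_I, 0.0)) / g.tau_I
    return np.concatenate([dE, dI])


def _summarize(network: RateNetwork, r: np.ndarray, I: float,
               tol: float, diverged: bool, settled: bool = False) -> SteadyStateSummary:
    ne = network.N_E
    r_E, r_I = r[:ne], r[ne:]
    mask_E = np.zeros(ne, bool)
    mask_E[network.stim_E] = True
    mask_I = np.zeros(network.N_I, bool)
    mask_I[network.stim_I] = True
    mean = lambda v: float(v.mean()) if v.size else 0.0
    max_drdt = float(np.max(np.abs(rate_rhs(r, network, I)))) if not diverged else np.inf
    return SteadyStateSummary(
        mean_E_s=mean(r_E[mask_E]),
        mean_E_u=mean(r_E[~mask_E]),
        mean_I_s=mean(r_I[mask_I]),
        mean_I_u=mean(r_I[~mask_I]),
        mean_E=mean(r_E),
        mean_I=mean(r_I),
        max_drdt=max_drdt,
        converged=bool(not diverged and (settled or max_drdt < tol)),
        diverged=diverged,
    )


def integrate_to_steady_state(
    network: RateNetwork,
    I: float,
    T_max: float = 600.0,
    tol: float = 1e-7,
    ceiling: float = 1e7,
    r0: Optional[np.ndarray] = None,
    n_save: int = 50,
) -> tuple:
    """Integrate the network ODEs until the derivative norm falls below tol.

    Rates start at zero (or ``r0``) with the stimulus applied as a step at
    t = 0.  Returns ``(RateTrajectory, SteadyStateSummary)``; divergence
    (any rate exceeding ``ceiling``, the hallmark of supercritical lateral
    excitation) and plain non-convergence are flagged distinctly.
    """
    r0 = np.zeros(network.N) if r0 is None else np.asarray(r0, float)

    def rhs(t, r):
        return rate_rhs(r, network, I)

    def settled(t, r):
        return float(np.max(np.abs(rhs(t, r))) - tol)

    settled.terminal = True
    settled.direction = -1

    def blowup(t, r):
        return float(ceiling - np.max(np.abs(r)))

    blowup.terminal = True
    blowup.direction = -1

    sol = solve_ivp(
        rhs, (0.0, T_max), r0,
        method="RK45", rtol=1e-8, atol=1e-10,
        events=[settled, blowup],
        t_eval=np.linspace(0.0, T_max, n_save),
    )
    diverged = len(sol.t_events[1]) > 0 or not sol.success
    settled_flag = len(sol.t_events[0]) > 0
    t = sol.t
    y = sol.y.T
    if settled_flag:  # keep the terminal state in the trajectory
        t = np.append(t, sol.t_events[0][0])
        y = np.vstack([y, sol.y_events[0][0]])
    r_final = y[-1] if y.size else r0
    return RateTrajectory(t=t, rates=y), _summarize(network, r_final, I, tol, diverged, settled_flag)


def intensity_sweep(
    network: RateNetwork,
    I_values: Sequence[float],
    **integrate_kw,
) -> tuple:
    """Steady states across ascending intensities plus the fitted slope of the
    population-mean excitatory rate versus I.

    Returns ``(summaries, slope, valid)``; the sweep is invalid if any point
    diverged or failed to converge.  Each intensity is integrated from the
    previous steady state (warm start), which does not change the fixed
    point reached in the stable regime but shortens transients.
    """
    I_values = np.asarray(I_values, dtype=float)
    if I_values.size < 3 or np.any(np.diff(I_values) <= 0):
        raise ValueError("need >= 3 strictly ascending intensities")
    summaries = []
    r_prev = None
    for I in I_values:
        traj, summ = integrate_to_steady_state(network, float(I), r0=r_prev, **integrate_kw)
        summaries.append(summ)
        r_prev = traj.rates[-1] if not summ.diverged else None
    valid = all(s.converged and not s.diverged for s in summaries)
    slope = np.nan
    if valid:
        slope = float(linregress(I_values, [s.mean_E for s in summaries]).slope)
    return summaries, slope, valid
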