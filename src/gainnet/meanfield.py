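"""Mean-field reduction of the random E/I network and its gain-control theory.

The microscopic firing-rate network (see :mod:`gainnet.ratenet`) averages, in
the large-N limit, into four ordinary differential equations for the mean
rates of the stimulated/unstimulated excitatory and inhibitory
subpopulations.  With threshold-linear population transfer functions

    G_X(u) = beta_X * max(u - theta_X, 0),        X in {E, I}

and effective couplings

    J_XY = p_XY * N_Y * g_XY      (net drive onto X per unit mean rate of Y)

the four equations read (s = stimulated, u = unstimulated)

    tau_E dR_E_s/dt = -R_E_s + G_E(J_EE x - J_EI y + I)
    tau_E dR_E_u/dt = -R_E_u + G_E(J_EE x - J_EI y)
    tau_I dR_I_s/dt = -R_I_s + G_I(J_IE x - J_II y + I)
    tau_I dR_I_u/dt = -R_I_u + G_I(J_IE x - J_II y)

where x = f R_E_s + (1-f) R_E_u and y = f R_I_s + (1-f) R_I_u are the
population-mean excitatory and inhibitory rates (equivalently, the mean
synaptic drive per unit coupling from each population).  f-weighting the
four equations compresses them into a two-variable (x, y) system whose
vector fields are

    F_E(x, y) = f G_E(J_EE x - J_EI y + I) + (1-f) G_E(J_EE x - J_EI y)
    F_I(x, y) = f G_I(J_IE x - J_II y + I) + (1-f) G_I(J_IE x - J_II y)

Everything in this module — fixed points, the 2x2 Jacobian and its
stability, the implicit-differentiation response slopes dx/dI and dx/df, the
strict gain-control condition and its boundary in parameter space, and the
linear scaling of inhibitory activity under gain control — is derived from
these equations.  Key closed forms (threshold-linear gains, unstimulated
groups silenced by inhibition, stimulated groups supra-threshold):

* strict gain control (dx/dI = 0):   f * beta_I * (J_EI - J_II) = 1
* inhibitory scaling under it:       dy/dI = 1 / J_EI
* lateral-excitation stability edge: J_EE * D_E = 1 + J_EI J_IE D_E D_I / (1 + J_II D_I)

with D_E, D_I the f-weighted slopes of the vector fields at the fixed point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, root
from scipy.stats import linregress

from .netgen import ConnectivitySpec, PopulationSpec

__all__ = [
    "GainParams",
    "MeanFieldParams",
    "MeanFieldState",
    "FixedPoint",
    "StabilityResult",
    "gain_threshold_linear",
    "gain_softplus",
    "meanfield_rhs",
    "meanfield_rhs_xy",
    "solve_fixed_point",
    "jacobian_at",
    "stability",
    "lateral_excitation_boundary",
    "critical_lateral_excitation",
    "gain_slope_intensity",
    "response_slopes",
    "gain_control_residual",
    "analytic_gain_boundary",
    "gain_control_boundary",
    "inhibitory_scaling",
    "InhibitoryScaling",
    "sparseness_slope",
    "sparseness_condition",
    "find_sparseness_zero",
]


# --------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class GainParams:
    """Threshold-linear transfer slopes, thresholds and relaxation times."""

    beta_E: float = 1.0
    beta_I: float = 1.0
    theta_E: float = 1.0
    theta_I: float = 2.0
    tau_E: float = 10.0
    tau_I: float = 10.0

    def __post_init__(self) -> None:
        if self.beta_E <= 0 or self.beta_I <= 0:
            raise ValueError("gain slopes must be > 0")
        if self.tau_E <= 0 or self.tau_I <= 0:
            raise ValueError("time constants must be > 0")


@dataclass(frozen=True)
class MeanFieldParams:
    """Population sizes, connectivity and gains; couplings J_XY are derived.

    The effective couplings are never stored: they are recomputed from the
    primitive (p, g, N) triplets so the two descriptions cannot drift apart.
    """

    pops: PopulationSpec
    conn: ConnectivitySpec
    gain: GainParams = field(default_factory=GainParams)

    @property
    def J_EE(self) -> float:
        return self.conn.p_EE * self.pops.N_E * self.conn.g_EE

    @property
    def J_EI(self) -> float:
        return self.conn.p_EI * self.pops.N_I * self.conn.g_EI

    @property
    def J_IE(self) -> float:
        return self.conn.p_IE * self.pops.N_E * self.conn.g_IE

    @property
    def J_II(self) -> float:
        return self.conn.p_II * self.pops.N_I * self.conn.g_II

    def effective_inhibition(self, f: float) -> float:
        """f beta_I J_EI / (1 + f beta_I J_II); equals 1 on the strict
        gain-control manifold (simplified regime)."""
        b = f * self.gain.beta_I
        return b * self.J_EI / (1.0 + b * self.J_II)

    def effective_excitation(self, f: float) -> float:
        """f beta_E J_EE, the lateral-excitation measure entering the
        stability boundary."""
        return f * self.gain.beta_E * self.J_EE

    def with_conn(self, **kw) -> "MeanFieldParams":
        return MeanFieldParams(self.pops, self.conn.replace(**kw), self.gain)


@dataclass
class MeanFieldState:
    """Mean rates of the four subpopulations (stimulated/unstimulated x E/I)."""

    R_E_s: float = 0.0
    R_E_u: float = 0.0
    R_I_s: float = 0.0
    R_I_u: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.R_E_s, self.R_E_u, self.R_I_s, self.R_I_u])

    @classmethod
    def from_array(cls, R: np.ndarray) -> "MeanFieldState":
        return cls(*map(float, R))

    def mean_E(self, f: float) -> float:
        return f * self.R_E_s + (1.0 - f) * self.R_E_u

    def mean_I(self, f: float) -> float:
        return f * self.R_I_s + (1.0 - f) * self.R_I_u


@dataclass
class FixedPoint:
    state: MeanFieldState
    residual: float
    converged: bool
    I: float
    f: float


@dataclass
class StabilityResult:
    eigenvalues: np.ndarray
    is_stable: bool
    boundary_J_EE: float
    fixed_point: FixedPoint


# --------------------------------------------------------------------------
# vector fields


def gain_threshold_linear(u, beta: float, theta: float):
    """Threshold-linear transfer: 0 below theta, beta*(u-theta) above."""
    return beta * np.maximum(np.asarray(u, dtype=float) - theta, 0.0)


def gain_softplus(u, beta: float, theta: float, sharpness: float = 10.0):
    """Smooth (softplus) variant of the threshold-linear transfer.

    Converges to :func:`gain_threshold_linear` as ``sharpness`` grows.
    Offered for robustness checks of the threshold-linear results only; all
    solvers and conditions in this module use the threshold-linear form.
    """
    z = sharpness * (np.asarray(u, dtype=float) - theta)
    return beta / sharpness * np.logaddexp(0.0, z)


def _drives(x: float, y: float, p: MeanFieldParams, I: float):
    """Net input currents (before thresholding) to the four subpopulations."""
    u_E = p.J_EE * x - p.J_EI * y
    u_I = p.J_IE * x - p.J_II * y
    return u_E + I, u_E, u_I + I, u_I


def _gains(u_Es, u_Eu, u_Is, u_Iu, g: GainParams):
    GE = lambda u: gain_threshold_linear(u, g.beta_E, g.theta_E)
    GI = lambda u: gain_threshold_linear(u, g.beta_I, g.theta_I)
    return GE(u_Es), GE(u_Eu), GI(u_Is), GI(u_Iu)


def meanfield_rhs(state, params: MeanFieldParams, I: float, f: float,
                  smooth: Optional[float] = None) -> np.ndarray:
    """Time derivatives of the four subpopulation mean rates.

    ``state`` may be a :class:`MeanFieldState` or a length-4 array
    (R_E_s, R_E_u, R_I_s, R_I_u).  ``smooth`` replaces the threshold-linear
    transfer by its softplus variant with the given sharpness (robustness
    checks only; the analytic conditions assume the threshold-linear form).
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError("f outside [0, 1]")
    if I < 0.0:
        raise ValueError("stimulus intensity must be >= 0")
    R = state.as_array() if isinstance(state, MeanFieldState) else np.asarray(state, float)
    g = params.gain
    x = f * R[0] + (1.0 - f) * R[1]
    y = f * R[2] + (1.0 - f) * R[3]
    u_Es, u_Eu, u_Is, u_Iu = _drives(x, y, params, I)
    if smooth is None:
        G = _gains(u_Es, u_Eu, u_Is, u_Iu, g)
    else:
        G = (gain_softplus(u_Es, g.beta_E, g.theta_E, smooth),
             gain_softplus(u_Eu, g.beta_E, g.theta_E, smooth),
             gain_softplus(u_Is, g.beta_I, g.theta_I, smooth),
             gain_softplus(u_Iu, g.beta_I, g.theta_I, smooth))
    tau = np.array([g.tau_E, g.tau_E, g.tau_I, g.tau_I])
    return (np.array(G) - R) / tau


def meanfield_rhs_xy(xy, params: MeanFieldParams, I: float, f: float) -> np.ndarray:
    """Compressed two-variable dynamics of (x, y) = mean (E, I) rates."""
    x, y = float(xy[0]), float(xy[1])
    g = params.gain
    G_Es, G_Eu, G_Is, G_Iu = _gains(*_drives(x, y, params, I), g)
    F_E = f * G_Es + (1.0 - f) * G_Eu
    F_I = f * G_Is + (1.0 - f) * G_Iu
    return np.array([(F_E - x) / g.tau_E, (F_I - y) / g.tau_I])


def _slope_weights(fp_state: np.ndarray, params: MeanFieldParams, I: float, f: float):
    """f-weighted vector-field slopes D_E, D_I and the per-group gain slopes.

    D_X = f G_X'(u_X_s) + (1-f) G_X'(u_X_u), the composite derivative weight
    of the compressed system evaluated at the fixed point.  At the kink
    (u exactly at threshold) the sub-threshold one-sided derivative 0 is used.
    """
    g = params.gain
    x = f * fp_state[0] + (1.0 - f) * fp_state[1]
    y = f * fp_state[2] + (1.0 - f) * fp_state[3]
    u_Es, u_Eu, u_Is, u_Iu = _drives(x, y, params, I)
    gp_Es = g.beta_E * (u_Es > g.theta_E)
    gp_Eu = g.beta_E * (u_Eu > g.theta_E)
    gp_Is = g.beta_I * (u_Is > g.theta_I)
    gp_Iu = g.beta_I * (u_Iu > g.theta_I)
    D_E = f * gp_Es + (1.0 - f) * gp_Eu
    D_I = f * gp_Is + (1.0 - f) * gp_Iu
    return D_E, D_I, gp_Es, gp_Is, (u_Es, u_Eu, u_Is, u_Iu)


# --------------------------------------------------------------------------
# fixed points


def _uncoupled_state(params: MeanFieldParams, I: float) -> np.ndarray:
    g = params.gain
    return np.array(
        [
            gain_threshold_linear(I, g.beta_E, g.theta_E),
            0.0,
            gain_threshold_linear(I, g.beta_I, g.theta_I),
            0.0,
        ]
    )


def solve_fixed_point(
    params: MeanFieldParams,
    I: float,
    f: float,
    init: Optional[MeanFieldState] = None,
    tol: float = 1e-10,
) -> FixedPoint:
    """Equilibrium of the four-variable mean field at operating point (I, f).

    The root of ``meanfield_rhs`` is sought with a quasi-Newton solver
    initialized at the uncoupled closed-form solution (or ``init``).  If the
    residual does not reach ``tol`` the mean-field ODEs are integrated
    forward for many relaxation times and the solve is retried from the
    endpoint; a fixed point that still fails is returned with
    ``converged=False`` — never silently.
    """
    R0 = init.as_array() if init is not None else _uncoupled_state(params, I)

    def F(R):
        return meanfield_rhs(R, params, I, f)

    def _attempt(R_start):
        sol = root(F, R_start, method="hybr", tol=1e-13)
        R = np.maximum(sol.x, 0.0)
        return R, float(np.linalg.norm(F(R), ord=np.inf))

    R, res = _attempt(R0)
    if res > tol:
        T = 400.0 * max(params.gain.tau_E, params.gain.tau_I)
        # overflow here just means the trajectory escapes (no stable fixed
        # point); the re-solve below then reports non-convergence
        with np.errstate(over="ignore", invalid="ignore"):
            ivp = solve_ivp(
                lambda t, R: meanfield_rhs(R, params, I, f),
                (0.0, T),
                R0,
                rtol=1e-10,
                atol=1e-12,
                method="LSODA",
            )
            R, res = _attempt(np.maximum(np.nan_to_num(ivp.y[:, -1]), 0.0))
    return FixedPoint(
        state=MeanFieldState.from_array(R),
        residual=res,
        converged=bool(res <= tol),
        I=I,
        f=f,
    )


# --------------------------------------------------------------------------
# stability


def jacobian_at(fp: FixedPoint, params: MeanFieldParams, I: Optional[float] = None,
                f: Optional[float] = None) -> np.ndarray:
    """2x2 Jacobian of the compressed (x, y) dynamics at a converged fixed point."""
    if not fp.converged:
        raise ValueError("refusing to linearize at an unconverged fixed point")
    I = fp.I if I is None else I
    f = fp.f if f is None else f
    g = params.gain
    D_E, D_I, *_ = _slope_weights(fp.state.as_array(), params, I, f)
    return np.array(
        [
            [(-1.0 + params.J_EE * D_E) / g.tau_E, -params.J_EI * D_E / g.tau_E],
            [params.J_IE * D_I / g.tau_I, (-1.0 - params.J_II * D_I) / g.tau_I],
        ]
    )


def lateral_excitation_boundary(params: MeanFieldParams, D_E: float, D_I: float) -> float:
    """Critical J_EE at which the leading eigenvalue reaches zero.

    For threshold-linear gains with composite slopes D_E, D_I at the fixed
    point, a real eigenvalue crosses zero when det J = 0:

        J_EE D_E = 1 + J_EI J_IE D_E D_I / (1 + J_II D_I)

    and a complex pair crosses when tr J = 0:

        J_EE D_E = 1 + (tau_E / tau_I) (1 + J_II D_I).

    The smaller of the two critical couplings is returned (inf if D_E = 0,
    i.e. no active excitatory pathway to destabilize).
    """
    if D_E <= 0.0:
        return np.inf
    g = params.gain
    det_crit = (1.0 + params.J_EI * params.J_IE * D_E * D_I / (1.0 + params.J_II * D_I)) / D_E
    tr_crit = (1.0 + (g.tau_E / g.tau_I) * (1.0 + params.J_II * D_I)) / D_E
    return min(det_crit, tr_crit)


def critical_lateral_excitation(params: MeanFieldParams, I: float, f: float,
                                bracket: tuple = (0.0, 1.0)) -> float:
    """g_EE at which the leading eigenvalue of the fixed point crosses zero.

    Found by bracketing on the leading eigenvalue real part, with the fixed
    point (and hence its activation pattern) re-solved at every trial
    coupling — the analytic boundary formula of
    :func:`lateral_excitation_boundary` holds per activation pattern, and
    the pattern itself changes as lateral excitation grows.

    Whether the crossing is a real eigenvalue (divergent instability) or a
    complex pair (oscillatory) depends on tau_E/tau_I; the real crossing
    comes first when the excitatory population is slow relative to the
    inhibitory one.
    """

    def lead(g_EE):
        try:
            return float(np.max(stability(params.with_conn(g_EE=float(g_EE)), I, f)
                                .eigenvalues.real))
        except RuntimeError:
            # beyond the boundary the threshold-linear equilibrium escapes to
            # infinity (no root); treat as unstable for bracketing purposes
            return 1.0

    lo, hi = bracket
    if lead(lo) >= 0 or lead(hi) <= 0:
        raise ValueError("bracket does not straddle the stability boundary")
    return float(brentq(lead, lo, hi, xtol=1e-10))


def stability(params: MeanFieldParams, I: float, f: float,
              init: Optional[MeanFieldState] = None) -> StabilityResult:
    """Eigenvalues of the compressed Jacobian at the fixed point, plus the
    analytic lateral-excitation stability boundary for the fixed point's
    activation pattern."""
    fp = solve_fixed_point(params, I, f, init=init)
    if not fp.converged:
        raise RuntimeError(f"fixed point did not converge (residual {fp.residual:.2e})")
    J = jacobian_at(fp, params)
    eig = np.linalg.eigvals(J)
    D_E, D_I, *_ = _slope_weights(fp.state.as_array(), params, I, f)
    return StabilityResult(
        eigenvalues=eig,
        is_stable=bool(np.max(eig.real) < 0.0),
        boundary_J_EE=lateral_excitation_boundary(params, D_E, D_I),
        fixed_point=fp,
    )


# --------------------------------------------------------------------------
# response slopes by implicit differentiation


def _response_system(fp: FixedPoint, params: MeanFieldParams):
    D_E, D_I, gp_Es, gp_Is, us = _slope_weights(
        fp.state.as_array(), params, fp.I, fp.f
    )
    M = np.array(
        [
            [1.0 - params.J_EE * D_E, params.J_EI * D_E],
            [-params.J_IE * D_I, 1.0 + params.J_II * D_I],
        ]
    )
    return M, D_E, D_I, gp_Es, gp_Is, us


def response_slopes(params: MeanFieldParams, f: float, I: float,
                    fp: Optional[FixedPoint] = None) -> tuple:
    """(dx/dI, dy/dI) of the equilibrium mean rates, by implicit differentiation.

    Differentiating the equilibrium conditions x = F_E, y = F_I with respect
    to I gives the linear system M (dx/dI, dy/dI)^T = (f G_E'(u_E_s),
    f G_I'(u_I_s))^T with M = [[1 - J_EE D_E, J_EI D_E], [-J_IE D_I,
    1 + J_II D_I]].
    """
    if fp is None:
        fp = solve_fixed_point(params, I, f)
    if not fp.converged:
        raise RuntimeError("fixed point did not converge")
    M, D_E, D_I, gp_Es, gp_Is, _ = _response_system(fp, params)
    b = np.array([f * gp_Es, f * gp_Is])
    if abs(np.linalg.det(M)) < 1e-12:
        raise np.linalg.LinAlgError("degenerate operating point: response system singular")
    dx, dy = np.linalg.solve(M, b)
    return float(dx), float(dy)


def gain_slope_intensity(params: MeanFieldParams, f: float, I: float,
                         fp: Optional[FixedPoint] = None) -> float:
    """d(mean excitatory rate)/dI at equilibrium; zero under strict gain control."""
    return response_slopes(params, f, I, fp=fp)[0]


def sparseness_slope(params: MeanFieldParams, f: float, I: float,
                     fp: Optional[FixedPoint] = None) -> tuple:
    """(dx/df, dy/df) of the equilibrium mean rates.

    The explicit f-dependence of the compressed vector fields contributes
    dF_X/df = G_X(u_X_s) - G_X(u_X_u), the rate gap between stimulated and
    unstimulated groups.
    """
    if fp is None:
        fp = solve_fixed_point(params, I, f)
    if not fp.converged:
        raise RuntimeError("fixed point did not converge")
    M, D_E, D_I, _, _, us = _response_system(fp, params)
    G_Es, G_Eu, G_Is, G_Iu = _gains(*us, params.gain)
    b = np.array([G_Es - G_Eu, G_Is - G_Iu])
    if abs(np.linalg.det(M)) < 1e-12:
        raise np.linalg.LinAlgError("degenerate operating point: response system singular")
    dx, dy = np.linalg.solve(M, b)
    return float(dx), float(dy)


# --------------------------------------------------------------------------
# gain-control condition (intensity)


def _in_simplified_regime(fp: FixedPoint, params: MeanFieldParams) -> bool:
    """Stimulated groups strictly supra-threshold, unstimulated strictly silent."""
    g = params.gain
    st = fp.state.as_array()
    x = fp.f * st[0] + (1 - fp.f) * st[1]
    y = fp.f * st[2] + (1 - fp.f) * st[3]
    u_Es, u_Eu, u_Is, u_Iu = _drives(x, y, params, fp.I)
    return bool(u_Es > g.theta_E and u_Is > g.theta_I and u_Eu < g.theta_E and u_Iu < g.theta_I)


def gain_control_residual(params: MeanFieldParams, f: float,
                          I: Optional[float] = None) -> float:
    """Residual whose zero set is the strict gain-control manifold dx/dI = 0.

    With ``I`` given, the fixed point at (I, f) is solved and the regime is
    checked: if the unstimulated groups are silenced and the stimulated
    groups supra-threshold the simplified closed form

        residual = beta_E * (1 - f beta_I (J_EI - J_II))

    is used (no dependence on I, J_IE or J_EE); otherwise the general form —
    the numerator of dx/dI,

        residual = G_E'(u_E_s) (1 + J_II D_I) - J_EI D_E G_I'(u_I_s)

    — is evaluated at the fixed point.  Without ``I`` the simplified
    algebraic form is returned directly.  Sign convention: the intensity
    slope dx/dI has the sign of the residual (excess inhibition makes both
    negative).
    """
    g = params.gain
    simplified = g.beta_E * (1.0 - f * g.beta_I * (params.J_EI - params.J_II))
    if I is None:
        return float(simplified)
    fp = solve_fixed_point(params, I, f)
    if not fp.converged:
        raise RuntimeError("fixed point did not converge; residual unavailable")
    if _in_simplified_regime(fp, params):
        return float(simplified)
    _, D_E, D_I, gp_Es, gp_Is, _ = _response_system(fp, params)
    return float(gp_Es * (1.0 + params.J_II * D_I) - params.J_EI * D_E * gp_Is)


def analytic_gain_boundary(params: MeanFieldParams, f) -> np.ndarray:
    """Closed-form boundary p_EI*(f) = p_II g_II / g_EI + 1/(f beta_I N_I g_EI)."""
    f = np.asarray(f, dtype=float)
    c = params.conn
    if c.g_EI <= 0:
        raise ValueError("g_EI must be positive to place the boundary in p_EI")
    return (
        c.p_II * c.g_II / c.g_EI
        + 1.0 / (f * params.gain.beta_I * params.pops.N_I * c.g_EI)
    )


def gain_control_boundary(
    params: MeanFieldParams,
    f_grid: Sequence[float],
    I_ref: float = 5.0,
    bracket: tuple = (1e-3, 1.0),
    xtol: float = 1e-12,
    n_scan: int = 41,
) -> tuple:
    """For each f, the p_EI zeroing the equilibrium intensity slope dx/dI.

    The slope is positive below the boundary, negative above it, and
    collapses to an exact-zero plateau once inhibition silences the whole
    excitatory population; a coarse scan therefore locates the +/- sign
    change and brentq refines inside it.  Entries with no sign change in
    the bracket are returned as NaN, never extrapolated.

    Returns ``(f_values, p_EI_values)`` arrays.
    """
    f_grid = np.asarray(f_grid, dtype=float)
    if np.any((f_grid <= 0) | (f_grid > 1)):
        raise ValueError("f_grid must lie in (0, 1]")
    out = np.full(f_grid.shape, np.nan)

    def slope_at(p_EI, f):
        return gain_slope_intensity(params.with_conn(p_EI=float(p_EI)), f, I_ref)

    grid = np.linspace(bracket[0], bracket[1], n_scan)
    for i, f in enumerate(f_grid):
        s = np.array([slope_at(p, f) for p in grid])
        hit = np.flatnonzero((s[:-1] > 0) & (s[1:] < 0))
        if hit.size == 0:
            continue
        k = hit[0]
        out[i] = brentq(slope_at, grid[k], grid[k + 1], args=(f,), xtol=xtol)
    return f_grid, out


# --------------------------------------------------------------------------
# inhibitory scaling under gain control


@dataclass
class InhibitoryScaling:
    slope: float
    intercept: float
    r_squared: float
    predicted_slope: float
    I_used: np.ndarray


def inhibitory_scaling(params: MeanFieldParams, f: float,
                       I_range: Sequence[float]) -> InhibitoryScaling:
    """Linear regression of the mean inhibitory rate y on intensity I.

    Under the strict gain-control condition the equilibrium inhibitory
    activity grows exactly linearly, dy/dI = 1/J_EI: the inhibitory network
    scales its activity with the input to cancel the extra excitatory drive.
    Sub-threshold intensities (stimulated groups below threshold at the
    fixed point) are excluded with a warning.
    """
    g = params.gain
    I_vals, y_vals = [], []
    for I in np.asarray(I_range, dtype=float):
        fp = solve_fixed_point(params, float(I), f)
        if not fp.converged:
            raise RuntimeError(f"fixed point at I={I} did not converge")
        st = fp.state.as_array()
        x = f * st[0] + (1 - f) * st[1]
        y = f * st[2] + (1 - f) * st[3]
        u_Es, _, u_Is, _ = _drives(x, y, params, float(I))
        if u_Es <= g.theta_E or u_Is <= g.theta_I:
            warnings.warn(f"I={I} sub-threshold at equilibrium; excluded from fit")
            continue
        I_vals.append(float(I))
        y_vals.append(y)
    if len(I_vals) < 3:
        raise ValueError("fewer than 3 supra-threshold intensities; cannot fit")
    fit = linregress(I_vals, y_vals)
    return InhibitoryScaling(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        predicted_slope=1.0 / params.J_EI if params.J_EI > 0 else np.inf,
        I_used=np.asarray(I_vals),
    )


# --------------------------------------------------------------------------
# sparseness (f) condition


def sparseness_condition(params: MeanFieldParams, f: float, I: float) -> float:
    """Residual of the f-gain-control condition dx/df = 0 at the (I, f) fixed point.

    Setting dx/df = 0 in the implicit-differentiation system gives

        [G_E(u_E_s) - G_E(u_E_u)] (1 + J_II D_I)
            = J_EI D_E [G_I(u_I_s) - G_I(u_I_u)].

    Unlike the intensity condition, the rate gaps G(u_s) - G(u_u) grow with
    I, so no static parameter set zeroes this residual at all intensities:
    stimulus encoding by recruitment admits no strict gain control.
    dx/df has the sign of the returned residual.
    """
    fp = solve_fixed_point(params, I, f)
    if not fp.converged:
        raise RuntimeError("fixed point did not converge")
    M, D_E, D_I, _, _, us = _response_system(fp, params)
    G_Es, G_Eu, G_Is, G_Iu = _gains(*us, params.gain)
    return float((G_Es - G_Eu) * (1.0 + params.J_II * D_I) - params.J_EI * D_E * (G_Is - G_Iu))


def find_sparseness_zero(params: MeanFieldParams, f: float, I: float,
                         bracket: tuple = (1e-3, 1.0)) -> float:
    """p_EI zeroing the f-condition residual at one intensity (if bracketed).

    Used to demonstrate that the zero is intensity-specific: the same p_EI
    fails the condition at a different I.
    """
    def res(p_EI):
        return sparseness_condition(params.with_conn(p_EI=float(p_EI)), f, I)

    # scan for a strict +/- crossing so the trivial zero of the fully
    # silenced excitatory population (residual identically 0) is skipped
    grid = np.linspace(bracket[0], bracket[1], 41)
    r = np.array([res(p) for p in grid])
    hit = np.flatnonzero((r[:-1] > 0) & (r[1:] < 0))
    if hit.size == 0:
        raise ValueError("no sign change of the f-condition residual in the bracket")
    k = hit[0]
    return float(brentq(res, grid[k], grid[k + 1], xtol=1e-12))
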