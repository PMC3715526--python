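"""Mean-field fixed points, stability and the gain-control conditions."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from conftest import random_admissible_params
from gainnet import defaults
from gainnet.meanfield import (GainParams, MeanFieldParams, MeanFieldState,
                               analytic_gain_boundary,
                               critical_lateral_excitation,
                               find_sparseness_zero,
                               gain_control_boundary, gain_control_residual,
                               gain_slope_intensity, gain_softplus,
                               gain_threshold_linear,
                               inhibitory_scaling, jacobian_at, meanfield_rhs,
                               meanfield_rhs_xy, response_slopes,
                               solve_fixed_point, sparseness_condition,
                               sparseness_slope, stability)
from gainnet.netgen import PopulationSpec

I_REF, F_REF = defaults.I_REF, defaults.F_REF


# --------------------------------------------------------------------------
# independent oracles


def rhs_oracle(R, params, I, f):
    """Four-equation form written out term by term, independently of the
    vectorized implementation."""
    g = params.gain
    R_E_s, R_E_u, R_I_s, R_I_u = R
    x = f * R_E_s + (1 - f) * R_E_u
    y = f * R_I_s + (1 - f) * R_I_u

    def G_E(u):
        return g.beta_E * (u - g.theta_E) if u > g.theta_E else 0.0

    def G_I(u):
        return g.beta_I * (u - g.theta_I) if u > g.theta_I else 0.0

    exc_drive = params.conn.p_EE * params.pops.N_E * params.conn.g_EE * x
    inh_drive_E = params.conn.p_EI * params.pops.N_I * params.conn.g_EI * y
    exc_drive_I = params.conn.p_IE * params.pops.N_E * params.conn.g_IE * x
    inh_drive_I = params.conn.p_II * params.pops.N_I * params.conn.g_II * y
    return np.array([
        (-R_E_s + G_E(exc_drive - inh_drive_E + I)) / g.tau_E,
        (-R_E_u + G_E(exc_drive - inh_drive_E)) / g.tau_E,
        (-R_I_s + G_I(exc_drive_I - inh_drive_I + I)) / g.tau_I,
        (-R_I_u + G_I(exc_drive_I - inh_drive_I)) / g.tau_I,
    ])


def fixed_points_by_region_enumeration(params, I, f):
    """All fixed points of the threshold-linear system, found exactly.

    Each of the 16 on/off patterns of the four subpopulations defines a
    linear system for (x, y); solutions consistent with their pattern are
    fixed points.  Completely independent of the package's Newton solver.
    """
    g = params.gain
    J = np.array([[params.J_EE, -params.J_EI], [params.J_IE, -params.J_II]])
    sols = []
    for pat in range(16):
        on = [(pat >> k) & 1 for k in range(4)]  # E_s, E_u, I_s, I_u
        # R_k = beta*(u_k - theta) if on else 0; u depends linearly on (x, y)
        # x = f R_Es + (1-f) R_Eu ; y likewise. Build 2x2 system A [x,y] = b.
        A = np.eye(2)
        b = np.zeros(2)
        bet = [g.beta_E, g.beta_E, g.beta_I, g.beta_I]
        the = [g.theta_E, g.theta_E, g.theta_I, g.theta_I]
        ext = [I, 0.0, I, 0.0]
        wgt = [f, 1 - f, f, 1 - f]
        for k, row in enumerate([0, 0, 1, 1]):
            if on[k]:
                A[row] -= wgt[k] * bet[k] * J[row]
                b[row] += wgt[k] * bet[k] * (ext[k] - the[k])
        try:
            xy = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            continue
        u = J @ xy
        us = [u[0] + I, u[0], u[1] + I, u[1]]
        ok = all(
            (us[k] >= the[k] - 1e-12) if on[k] else (us[k] <= the[k] + 1e-12)
            for k in range(4)
        )
        if not ok:
            continue
        R = np.array([on[k] * bet[k] * max(us[k] - the[k], 0.0) for k in range(4)])
        if not any(np.allclose(R, S, atol=1e-10) for S in sols):
            sols.append(R)
    return sols


# --------------------------------------------------------------------------
# transfer function and rhs


class TestGainAndRhs:
    def test_threshold_linear_values(self):
        assert gain_threshold_linear(2.0, beta=1.0, theta=2.0) == 0.0
        assert gain_threshold_linear(4.0, beta=3.0, theta=2.0) == pytest.approx(6.0)

    def test_threshold_linear_monotone(self, rng):
        u = np.sort(rng.uniform(-5, 5, 2000))
        out = gain_threshold_linear(u, beta=1.7, theta=0.3)
        assert np.all(np.diff(out) >= 0)

    def test_softplus_converges_to_threshold_linear(self, rng):
        """The smooth robustness variant approaches the kinked transfer as
        sharpness grows, and the smooth mean-field flow stays close."""
        u = rng.uniform(-4, 4, 200)
        hard = gain_threshold_linear(u, 1.3, 0.5)
        soft = gain_softplus(u, 1.3, 0.5, sharpness=200.0)
        assert np.max(np.abs(soft - hard)) < 0.01
        p = MeanFieldParams(defaults.POPS, defaults.CONN, GainParams(**defaults.GAIN))
        R = rng.uniform(0, 2, 4)
        d_hard = meanfield_rhs(R, p, I_REF, 0.5)
        d_soft = meanfield_rhs(R, p, I_REF, 0.5, smooth=200.0)
        assert np.max(np.abs(d_hard - d_soft)) < 0.01

    def test_rest_is_fixed_point_when_uncoupled(self, mf_params):
        p = MeanFieldParams(mf_params.pops,
                            mf_params.conn.replace(g_EE=0, g_EI=0, g_IE=0, g_II=0),
                            GainParams(theta_E=0.0, theta_I=0.0))
        d = meanfield_rhs(np.zeros(4), p, I=0.0, f=0.5)
        assert np.allclose(d, 0.0)

    def test_uncoupled_forced_response(self, mf_params):
        g = GainParams(beta_E=2.0, theta_E=1.0, tau_E=10.0)
        p = MeanFieldParams(mf_params.pops,
                            mf_params.conn.replace(g_EE=0, g_EI=0, g_IE=0, g_II=0), g)
        d = meanfield_rhs(np.zeros(4), p, I=3.0, f=0.5)
        assert d[0] == pytest.approx(g.beta_E * (3.0 - g.theta_E) / g.tau_E)

    def test_rhs_matches_term_by_term_oracle(self, rng):
        for _ in range(50):
            p = random_admissible_params(rng, g_EE_max=0.003)
            R = rng.uniform(0, 5, 4)
            I, f = rng.uniform(0, 8), rng.uniform(0.05, 1.0)
            assert np.allclose(meanfield_rhs(R, p, I, f), rhs_oracle(R, p, I, f),
                               rtol=1e-12, atol=1e-14)

    def test_xy_compression_consistent_with_four_equations(self, rng):
        """f-weighted combinations of the 4-variable rhs equal the compressed
        2-variable rhs whenever the subpopulation rates equal their gains
        (i.e. on the slow manifold the compression assumes)."""
        for _ in range(20):
            p = random_admissible_params(rng)
            I, f = rng.uniform(0, 8), rng.uniform(0.05, 1.0)
            fp = solve_fixed_point(p, I, f)
            R = fp.state.as_array()
            xy = np.array([fp.state.mean_E(f), fp.state.mean_I(f)])
            d4 = meanfield_rhs(R, p, I, f)
            dxy = meanfield_rhs_xy(xy, p, I, f)
            assert np.allclose([f * d4[0] + (1 - f) * d4[1],
                                f * d4[2] + (1 - f) * d4[3]], dxy, atol=1e-9)

    def test_domain_errors(self, mf_params):
        with pytest.raises(ValueError):
            meanfield_rhs(np.zeros(4), mf_params, I=1.0, f=1.5)
        with pytest.raises(ValueError):
            meanfield_rhs(np.zeros(4), mf_params, I=-1.0, f=0.5)


# --------------------------------------------------------------------------
# fixed points


class TestFixedPoint:
    def test_uncoupled_closed_form(self, mf_params):
        p = MeanFieldParams(mf_params.pops,
                            mf_params.conn.replace(g_EE=0, g_EI=0, g_IE=0, g_II=0),
                            mf_params.gain)
        fp = solve_fixed_point(p, I_REF, 0.5)
        g = p.gain
        assert fp.converged
        assert fp.state.R_E_s == pytest.approx(g.beta_E * (I_REF - g.theta_E))
        assert fp.state.R_I_s == pytest.approx(g.beta_I * (I_REF - g.theta_I))
        assert fp.state.R_E_u == pytest.approx(0.0, abs=1e-12)

    def test_unstimulated_groups_silenced_by_inhibition(self, mf_params):
        """Strong stimulus with dominant inhibition shuts down the groups
        that receive only lateral input."""
        fp = solve_fixed_point(mf_params, 8.0, 0.5)
        assert fp.converged
        assert fp.state.R_E_u == pytest.approx(0.0, abs=1e-10)
        assert fp.state.R_I_u == pytest.approx(0.0, abs=1e-10)
        assert fp.state.R_E_s > 0 and fp.state.R_I_s > 0

    def test_matches_region_enumeration_oracle(self, rng):
        for _ in range(30):
            p = random_admissible_params(rng, g_EE_max=0.002)
            I, f = rng.uniform(3, 9), rng.uniform(0.2, 0.95)
            fp = solve_fixed_point(p, I, f)
            assert fp.converged
            sols = fixed_points_by_region_enumeration(p, I, f)
            assert any(np.allclose(fp.state.as_array(), S, atol=1e-8) for S in sols)

    def test_agrees_with_long_time_integration(self, rng):
        for _ in range(10):
            p = random_admissible_params(rng)
            I, f = rng.uniform(3, 9), rng.uniform(0.2, 0.95)
            fp = solve_fixed_point(p, I, f)
            sol = solve_ivp(lambda t, R: meanfield_rhs(R, p, I, f),
                            (0, 4000), np.zeros(4), rtol=1e-10, atol=1e-12)
            assert np.allclose(fp.state.as_array(), sol.y[:, -1], atol=1e-6)

    def test_rates_nonnegative_and_self_consistent(self, rng):
        for _ in range(30):
            p = random_admissible_params(rng)
            fp = solve_fixed_point(p, rng.uniform(0.5, 10), rng.uniform(0.05, 1.0))
            R = fp.state.as_array()
            assert np.all(R >= 0)
            assert fp.residual <= 1e-10


# --------------------------------------------------------------------------
# stability


class TestStability:
    def test_pure_relaxation_eigenvalues(self, mf_params):
        p = MeanFieldParams(mf_params.pops,
                            mf_params.conn.replace(g_EE=0, g_EI=0, g_IE=0, g_II=0),
                            mf_params.gain)
        fp = solve_fixed_point(p, 0.0, 0.5)
        J = jacobian_at(fp, p)
        assert np.allclose(np.diag(J), [-1 / p.gain.tau_E, -1 / p.gain.tau_I])
        assert np.allclose(J - np.diag(np.diag(J)), 0)
        res = stability(p, 0.0, 0.5)
        got = sorted(res.eigenvalues.real)
        want = sorted([-1 / p.gain.tau_E, -1 / p.gain.tau_I])
        assert np.allclose(got, want)
        assert np.allclose(res.eigenvalues.imag, 0)

    def test_jacobian_matches_finite_differences(self, rng):
        h = 1e-7
        checked = 0
        for _ in range(50):
            p = random_admissible_params(rng, g_EE_max=0.002)
            I, f = rng.uniform(3, 9), rng.uniform(0.2, 0.95)
            fp = solve_fixed_point(p, I, f)
            xy0 = np.array([fp.state.mean_E(f), fp.state.mean_I(f)])
            J = jacobian_at(fp, p)
            Jfd = np.zeros((2, 2))
            for c in range(2):
                e = np.zeros(2)
                e[c] = h
                Jfd[:, c] = (meanfield_rhs_xy(xy0 + e, p, I, f)
                             - meanfield_rhs_xy(xy0 - e, p, I, f)) / (2 * h)
            # skip draws whose fixed point sits exactly on a gain kink
            if np.max(np.abs(Jfd)) > 0 and np.max(np.abs(J - Jfd)) / np.max(np.abs(Jfd)) < 1e-5:
                checked += 1
        assert checked >= 45

    def test_no_lateral_excitation_always_stable(self, rng):
        for _ in range(200):
            p = random_admissible_params(rng, g_EE_max=0.0)
            res = stability(p, rng.uniform(1, 10), rng.uniform(0.05, 1.0))
            assert res.is_stable
            assert np.max(res.eigenvalues.real) < 0

    def test_critical_coupling_separates_stable_from_unstable(self, mf_params):
        """Bisected critical E->E strength: stable just below, unstable just
        above, and consistent with the per-pattern analytic boundary."""
        slow_E = GainParams(**{**defaults.GAIN, "tau_E": 20.0, "tau_I": 5.0})
        p = MeanFieldParams(mf_params.pops, mf_params.conn, slow_E)
        g_crit = critical_lateral_excitation(p, I_REF, F_REF)
        below = stability(p.with_conn(g_EE=0.99 * g_crit), I_REF, F_REF)
        assert below.is_stable
        # above the boundary the equilibrium is unstable or has escaped to
        # infinity (no root of the threshold-linear equilibrium equations)
        try:
            above = stability(p.with_conn(g_EE=1.01 * g_crit), I_REF, F_REF)
            assert not above.is_stable
        except RuntimeError:
            pass
        # analytic boundary evaluated at the marginal pattern agrees
        J_crit = p.conn.p_EE * p.pops.N_E * g_crit
        assert J_crit == pytest.approx(below.boundary_J_EE, rel=0.02)

    def test_divergence_onset_matches_eigenvalue_crossing(self, mf_params):
        """Forward integration of the mean-field ODEs diverges exactly where
        the leading (real) eigenvalue turns positive, within 1% in g_EE."""
        slow_E = GainParams(**{**defaults.GAIN, "tau_E": 20.0, "tau_I": 5.0})
        p = MeanFieldParams(mf_params.pops, mf_params.conn, slow_E)
        g_crit = critical_lateral_excitation(p, I_REF, F_REF)

        def diverges(g_EE):
            q = p.with_conn(g_EE=float(g_EE))
            hit = lambda t, R: 1e7 - np.max(R)
            hit.terminal = True
            with np.errstate(over="ignore", invalid="ignore"):
                sol = solve_ivp(lambda t, R: meanfield_rhs(R, q, I_REF, F_REF),
                                (0, 60000), np.full(4, 0.5), rtol=1e-8,
                                atol=1e-10, events=hit)
            return len(sol.t_events[0]) > 0

        lo, hi = 0.9 * g_crit, 1.1 * g_crit
        assert not diverges(lo) and diverges(hi)
        for _ in range(12):
            mid = 0.5 * (lo + hi)
            lo, hi = (mid, hi) if not diverges(mid) else (lo, mid)
        assert 0.5 * (lo + hi) == pytest.approx(g_crit, rel=0.01)


# --------------------------------------------------------------------------
# gain control in intensity


class TestGainControlIntensity:
    def test_uncoupled_slope_equals_beta(self, mf_params):
        p = MeanFieldParams(mf_params.pops,
                            mf_params.conn.replace(g_EE=0, g_EI=0, g_IE=0, g_II=0),
                            mf_params.gain)
        assert gain_slope_intensity(p, 1.0, I_REF) == pytest.approx(p.gain.beta_E)
        assert gain_slope_intensity(p, 0.4, I_REF) == pytest.approx(0.4 * p.gain.beta_E)

    def test_zero_slope_on_the_boundary(self, mf_params):
        """Default connectivity lies on the strict gain-control manifold."""
        assert abs(gain_slope_intensity(mf_params, F_REF, I_REF)) < 1e-8
        assert gain_control_residual(mf_params, F_REF, I_REF) == pytest.approx(0.0, abs=1e-12)

    def test_slope_matches_finite_differences(self, rng):
        h = 1e-6
        for _ in range(100):
            p = random_admissible_params(rng, g_EE_max=0.002)
            I, f = rng.uniform(3, 9), rng.uniform(0.2, 0.95)
            s = gain_slope_intensity(p, f, I)
            xm = solve_fixed_point(p, I - h, f).state.mean_E(f)
            xp = solve_fixed_point(p, I + h, f).state.mean_E(f)
            fd = (xp - xm) / (2 * h)
            assert s == pytest.approx(fd, rel=1e-5, abs=1e-9)

    def test_residual_sign_tracks_slope_and_monotone_in_inhibition(self, mf_params):
        slopes, residuals = [], []
        for pei in (0.4, 0.55, 0.7, 0.85):
            q = mf_params.with_conn(p_EI=pei)
            slopes.append(gain_slope_intensity(q, F_REF, I_REF))
            residuals.append(gain_control_residual(q, F_REF, I_REF))
        assert np.all(np.diff(residuals) < 0)  # monotone in p_EI
        for s, r in zip(slopes, residuals):
            if abs(r) > 1e-12:
                assert np.sign(s) == np.sign(r)

    def test_residual_independent_of_excitatory_to_inhibitory_coupling(self, mf_params):
        """In the silenced regime the condition carries no g_IE dependence."""
        base = gain_control_residual(mf_params, F_REF, I_REF)
        for scale in (0.5, 2.0, 4.0):
            q = mf_params.with_conn(g_IE=mf_params.conn.g_IE * scale)
            assert gain_control_residual(q, F_REF, I_REF) == pytest.approx(base, abs=1e-12)

    def test_boundary_matches_analytic_curve_and_shape(self, mf_params):
        f_grid = np.array([0.3, 0.45, 0.6, 0.75, 0.9])
        _, b = gain_control_boundary(mf_params, f_grid)
        expected = analytic_gain_boundary(mf_params, f_grid)
        assert np.allclose(b, expected, rtol=1e-8)
        assert np.all(np.diff(b) < 0)  # monotone non-increasing in f
        # flat at large f: last-step drop much smaller than first-step drop
        assert abs(b[-1] - b[-2]) < 0.3 * abs(b[1] - b[0])

    def test_boundary_point_has_tiny_slope(self, mf_params):
        f = 0.5
        _, b = gain_control_boundary(mf_params, [f])
        q = mf_params.with_conn(p_EI=float(b[0]))
        assert abs(gain_slope_intensity(q, f, I_REF)) < 1e-6

    def test_boundary_traces_pg_product_at_fixed_f(self, mf_params):
        """In the (p_EI, g_I) plane the boundary is near-hyperbolic: the
        product p*g varies far less than either coordinate."""
        f = 0.5
        gs = np.array([0.006, 0.01, 0.02, 0.04])
        ps = []
        for gI in gs:
            q = mf_params.with_conn(g_EI=float(gI), g_II=float(gI))
            _, b = gain_control_boundary(q, [f])
            ps.append(float(b[0]))
        ps = np.array(ps)
        pg = ps * gs
        assert np.all(np.isfinite(ps))
        assert np.all(np.diff(ps) < 0)
        assert pg.max() / pg.min() < 0.25 * (ps.max() / ps.min()) * (gs.max() / gs.min())


# --------------------------------------------------------------------------
# inhibitory scaling


class TestInhibitoryScaling:
    def test_linear_scaling_on_boundary(self, mf_params):
        res = inhibitory_scaling(mf_params, F_REF, np.linspace(3.5, 10, 20))
        assert res.r_squared > 0.999
        assert res.slope == pytest.approx(res.predicted_slope, rel=1e-8)

    def test_uncoupled_inhibitory_population_exactly_linear(self, mf_params):
        p = MeanFieldParams(mf_params.pops,
                            mf_params.conn.replace(g_EE=0, g_EI=0, g_IE=0, g_II=0),
                            mf_params.gain)
        res = inhibitory_scaling(p, 1.0, np.linspace(3, 9, 10))
        assert res.r_squared == pytest.approx(1.0)
        assert res.slope == pytest.approx(p.gain.beta_I)

    def test_subthreshold_intensities_excluded_with_warning(self, mf_params):
        with pytest.warns(UserWarning):
            inhibitory_scaling(mf_params, F_REF, [1.0, 4.0, 6.0, 8.0, 10.0])

    def test_off_boundary_scaling_mismatch(self, mf_params):
        """Away from the gain-control manifold the inhibitory response no
        longer compensates the drive: dy/dI departs from 1/J_EI."""
        on = inhibitory_scaling(mf_params, F_REF, np.linspace(3.5, 10, 12))
        off = inhibitory_scaling(mf_params.with_conn(p_EI=0.45), F_REF,
                                 np.linspace(3.5, 10, 12))
        err_on = abs(on.slope - on.predicted_slope) / on.predicted_slope
        err_off = abs(off.slope - off.predicted_slope) / off.predicted_slope
        assert err_on < 1e-10
        assert err_off > 0.1


# --------------------------------------------------------------------------
# sparseness condition


class TestSparsenessCondition:
    def test_zero_at_one_intensity_fails_at_double(self, mf_params, rng):
        for _ in range(20):
            f = rng.uniform(0.3, 0.8)
            I1 = rng.uniform(3.5, 6.0)
            pei = find_sparseness_zero(mf_params, f, I1)
            q = mf_params.with_conn(p_EI=pei)
            assert abs(sparseness_condition(q, f, I1)) < 1e-9
            assert abs(sparseness_condition(q, f, 2 * I1)) > 1e-9 * 10

    def test_df_slope_matches_finite_differences(self, rng):
        h = 1e-7
        for _ in range(50):
            p = random_admissible_params(rng, g_EE_max=0.002)
            I, f = rng.uniform(3, 9), rng.uniform(0.2, 0.9)
            s = sparseness_slope(p, f, I)[0]
            xm = solve_fixed_point(p, I, f - h).state.mean_E(f - h)
            xp = solve_fixed_point(p, I, f + h).state.mean_E(f + h)
            assert s == pytest.approx((xp - xm) / (2 * h), rel=1e-5, abs=1e-8)

    def test_uncoupled_limit_closed_form(self, mf_params):
        """Uncoupled network: x = f beta_E (I - theta_E), so dx/df is the
        per-group rate itself."""
        p = MeanFieldParams(mf_params.pops,
                            mf_params.conn.replace(g_EE=0, g_EI=0, g_IE=0, g_II=0),
                            mf_params.gain)
        s = sparseness_slope(p, 1.0, I_REF)[0]
        assert s == pytest.approx(p.gain.beta_E * (I_REF - p.gain.theta_E))
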