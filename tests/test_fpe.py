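"""Foot placement estimator: projection, solver, stepping outcomes."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from stsbalance.fpe import (
    FpePlanarInput,
    applicability_check,
    fpe_residual,
    post_contact_outcome,
    project_state,
    solve_fpe,
    travel_frame,
)
from stsbalance.kinematics import WholeBodyState

G = 9.81


def make_state(r=(0, 0, 0.9), v=(0.3, 0, 0.1), J=None, w=(0, 0.2, 0)):
    J = np.diag([8.0, 9.0, 2.0]) if J is None else np.asarray(J, float)
    r = np.asarray(r, float)
    w = np.asarray(w, float)
    st = WholeBodyState(r_C=r, v_C=np.asarray(v, float), J_C=J, H_C=J @ w, w_avg=w)
    st.mass = 75.0
    return st


class TestTravelFrame:
    def test_momentum_along_y_gives_s_along_x(self):
        fr = travel_frame(np.array([0.0, 5.0, 0.0]))
        np.testing.assert_allclose(fr.t, [0, 1, 0], atol=1e-15)
        np.testing.assert_allclose(fr.s, [1, 0, 0], atol=1e-15)

    def test_vertical_momentum_falls_back_to_velocity(self):
        fr = travel_frame(np.array([0.0, 0.0, 3.0]), v_C=np.array([0.5, 0.0, 0.1]))
        np.testing.assert_allclose(fr.s, [1, 0, 0], atol=1e-12)

    def test_degenerate_sample_flagged(self):
        fr = travel_frame(np.array([0.0, 0.0, 3.0]), v_C=np.array([0.0, 0.0, 0.1]))
        assert not fr.valid

    def test_rotation_about_z_equivariance(self):
        rng = np.random.default_rng(0)
        H = rng.normal(size=3)
        R = Rotation.from_euler("z", 1.1).as_matrix()
        fr0 = travel_frame(H)
        fr1 = travel_frame(R @ H)
        np.testing.assert_allclose(fr1.t, R @ fr0.t, atol=1e-12)
        np.testing.assert_allclose(fr1.s, R @ fr0.s, atol=1e-12)

    def test_fallback_carries_previous_frame_forward(self):
        H = np.array([[0.0, 5.0, 0.0], [0.0, 0.0, 0.0]])
        fr = travel_frame(H, v_C=np.zeros((2, 3)))
        np.testing.assert_allclose(fr.t[1], [0, 1, 0], atol=1e-15)


class TestProjectState:
    def test_velocity_along_s(self):
        st = make_state(v=(0.5, 0.0, 0.0), w=(0, 0.2, 0))
        fr = travel_frame(np.array([0.0, 5.0, 0.0]))
        inp = project_state(st, fr)
        assert inp.v_s1 == pytest.approx(0.5)
        assert inp.v_z1 == pytest.approx(0.0)

    def test_inertia_projection_picks_diagonal(self):
        st = make_state(J=np.diag([3.0, 7.0, 11.0]))
        fr = travel_frame(np.array([0.0, 5.0, 0.0]))
        assert project_state(st, fr).J == pytest.approx(7.0)

    def test_matches_dot_product_oracle(self):
        rng = np.random.default_rng(1)
        st = make_state(v=rng.normal(size=3), w=rng.normal(size=3))
        fr = travel_frame(rng.normal(size=3))
        inp = project_state(st, fr)
        assert inp.v_s1 == pytest.approx(st.v_C @ fr.s)
        assert inp.w1 == pytest.approx(st.w_avg @ fr.t)
        assert inp.J == pytest.approx(fr.t @ st.J_C @ fr.t)

    def test_nonpositive_height_errors(self):
        st = make_state(r=(0, 0, -0.1))
        with pytest.raises(ValueError):
            project_state(st, travel_frame(np.array([0.0, 5.0, 0.0])))


def point_mass_phi(vs, h, g=G):
    """Cardano closed form of v^2 c^3 = 2 g h (1 - c) for c = cos(phi)."""
    p = 2.0 * g * h / vs**2  # c^3 + p c - p = 0
    q = -p
    disc = np.sqrt((q / 2) ** 2 + (p / 3) ** 3)
    c = np.cbrt(-q / 2 + disc) + np.cbrt(-q / 2 - disc)
    return np.arccos(c)


def residual_oracle(phi, m, h, vs, vz, w1, J, g=G):
    """Independently coded, term-by-term evaluation of the balance residual."""
    c, s = np.cos(phi), np.sin(phi)
    momentum = m * h * (vs * c + vz * s) * c + J * w1 * c * c
    denom = m * h * h + J * c * c
    gravity = 2.0 * m * g * h * c * (c - 1.0)
    return momentum**2 / denom + gravity


class TestResidual:
    def test_static_body_balances_at_zero(self):
        assert fpe_residual(0.0, 75, 0.9, 0, 0, 0, 8.0) == pytest.approx(0.0)

    def test_closed_form_at_phi_zero(self):
        m, h, vs, J = 75.0, 0.9, 0.5, 8.0
        expected = (m * h * vs) ** 2 / (m * h * h + J)
        assert fpe_residual(0.0, m, h, vs, 0, 0, J) == pytest.approx(expected)

    def test_matches_double_implementation_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            phi = rng.uniform(-1.4, 1.4)
            args = (rng.uniform(40, 100), rng.uniform(0.7, 1.2),
                    rng.uniform(-2, 2), rng.uniform(-2, 2),
                    rng.uniform(-3, 3), rng.uniform(0, 15))
            assert fpe_residual(phi, *args) == pytest.approx(
                residual_oracle(phi, *args), rel=1e-12, abs=1e-12)


class TestSolver:
    def test_static_input_gives_origin(self):
        sol = solve_fpe(FpePlanarInput(m=75.0, h=np.float64(0.9), v_s1=0.0,
                                       v_z1=0.0, w1=0.0, J=8.0),
                        r_G=np.array([0.2, 0.3]), s_hat=np.array([0.0, 1.0, 0.0]))
        assert sol.phi == pytest.approx(0.0)
        np.testing.assert_allclose(sol.r_F, [0.2, 0.3], atol=1e-12)

    def test_point_mass_closed_form(self):
        # with J = 0 and purely horizontal velocity the residual reduces to
        # v^2 c^3 = 2 g h (1 - c), a depressed cubic in c = cos(phi) with a
        # Cardano closed form
        for vs in (0.2, 0.5, 1.0, 2.0):
            sol = solve_fpe(FpePlanarInput(m=70.0, h=np.float64(1.0), v_s1=vs,
                                           v_z1=0.0, w1=0.0, J=0.0))
            assert sol.phi == pytest.approx(point_mass_phi(vs, 1.0), abs=1e-10)

    def test_matches_grid_scan(self):
        m, h, vs, vz, w1, J = 70.0, 0.95, 0.4, 0.2, 0.5, 8.0
        sol = solve_fpe(FpePlanarInput(m=m, h=np.float64(h), v_s1=vs, v_z1=vz,
                                       w1=w1, J=J))
        grid = np.linspace(0, 1.3, 1_000_000)
        f = np.abs(fpe_residual(grid, m, h, vs, vz, w1, J))
        assert sol.phi == pytest.approx(grid[np.argmin(f)], abs=1e-6)

    def test_energy_balance_holds(self):
        rng = np.random.default_rng(3)
        n = 200
        inp = FpePlanarInput(m=rng.uniform(40, 100, n), h=rng.uniform(0.7, 1.2, n),
                             v_s1=rng.uniform(-2, 2, n), v_z1=rng.uniform(-2, 2, n),
                             w1=rng.uniform(-3, 3, n), J=rng.uniform(0, 15, n))
        sol = solve_fpe(inp)
        assert sol.valid.all()
        lhs = 0.5 * (inp.J + inp.m * sol.leg_length**2) * sol.w2**2
        rhs = inp.m * G * (sol.leg_length - inp.h)
        np.testing.assert_allclose(lhs, rhs, rtol=1e-9, atol=1e-9)

    def test_monotone_in_forward_speed(self):
        vs = np.linspace(0.1, 2.0, 50)
        sol = solve_fpe(FpePlanarInput(m=70.0, h=np.full_like(vs, 0.95), v_s1=vs,
                                       v_z1=np.zeros_like(vs), w1=np.zeros_like(vs),
                                       J=np.full_like(vs, 5.0)))
        assert np.all(np.diff(sol.phi) > 0)

    def test_point_mass_limit(self):
        vs = 0.8
        expected = point_mass_phi(vs, 0.9)
        for J in (1.0, 0.1, 0.01, 1e-4):
            sol = solve_fpe(FpePlanarInput(m=70.0, h=np.float64(0.9), v_s1=vs,
                                           v_z1=0.0, w1=0.0, J=J))
            err = abs(sol.phi - expected)
        assert err < 1e-6

    def test_nonfinite_sample_flagged(self):
        sol = solve_fpe(FpePlanarInput(m=70.0, h=np.array([0.9, np.nan]),
                                       v_s1=np.array([0.4, 0.4]),
                                       v_z1=np.zeros(2), w1=np.zeros(2),
                                       J=np.zeros(2)))
        assert sol.valid[0] and not sol.valid[1]
        assert np.isnan(sol.phi[1])


try:
    from hypothesis import given, settings, strategies as st

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(m=st.floats(40, 100), h=st.floats(0.7, 1.2),
           vs=st.floats(-2, 2), vz=st.floats(-2, 2),
           w1=st.floats(-3, 3), J=st.floats(0, 15))
    def test_solver_residual_property(m, h, vs, vz, w1, J):
        """Any physical planar state yields a valid root with tiny residual
        and a leg at least as long as the COM height."""
        sol = solve_fpe(FpePlanarInput(m=m, h=np.float64(h), v_s1=vs, v_z1=vz,
                                       w1=w1, J=J))
        assert sol.valid
        assert abs(sol.residual) <= 1e-8 * m * G * h
        assert sol.leg_length >= h - 1e-12
        assert abs(sol.phi) < np.pi / 2
except ImportError:  # pragma: no cover - hypothesis is an optional test dep
    pass


class TestPostContactOutcome:
    def _inp(self, **kw):
        d = dict(m=75.0, h=0.9, v_s1=0.5, v_z1=0.1, w1=0.4, J=6.0)
        d.update(kw)
        return FpePlanarInput(**d)

    def test_balances_at_fpe(self):
        inp = self._inp()
        sol = solve_fpe(inp)
        off = inp.h * np.tan(sol.phi)
        assert post_contact_outcome(inp, off, speed_tol=1e-4) == "balances"

    def test_stepping_behind_falls_forward(self):
        inp = self._inp()
        off = inp.h * np.tan(solve_fpe(inp).phi)
        assert post_contact_outcome(inp, off - 0.10) == "falls_forward"

    def test_stepping_ahead_falls_backward(self):
        inp = self._inp()
        off = inp.h * np.tan(solve_fpe(inp).phi)
        assert post_contact_outcome(inp, off + 0.10) == "falls_backward"


class TestApplicability:
    def test_zero_yaw_is_applicable(self):
        assert applicability_check(np.zeros(5), 0.1).all()

    def test_exceeding_bound_flagged(self):
        ok = applicability_check(np.array([0.0, 0.25]), 0.1)
        assert ok[0] and not ok[1]


def test_planar_trial_fully_applicable(noiseless_trial):
    """A sagittal-plane transfer has zero yaw angular momentum throughout."""
    gt = noiseless_trial.ground_truth
    wz = gt["metrics"]["wz"]
    assert applicability_check(wz, 1e-6).all()
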