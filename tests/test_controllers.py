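"""Control laws: PI arithmetic, MRAC adaptation, ADP-PI structure, presets."""

import math

import numpy as np
import pytest

from fesim.controllers import (
    ADPPIParams,
    ADPPIState,
    MRACParams,
    MRACState,
    OpenLoopSchedule,
    PIGains,
    PIState,
    adppi_basis,
    adppi_update,
    build_Ar,
    mrac_update,
    openloop_update,
    pi_update,
    solve_P,
)
from fesim.presets import ADPPI_PRESETS, MRAC_PRESETS, adppi_preset, mrac_preset


class TestPI:
    def test_zero_error_zero_effort(self):
        u, s = pi_update(PIState(), x=1e-3, xd=1e-3, dt=0.004,
                         gains=PIGains(kp=0.09, ki=0.4))
        assert u == 0.0
        assert s.integral == 0.0

    def test_pure_proportional_with_zero_ki(self):
        g = PIGains(kp=0.09, ki=0.0)
        u, _ = pi_update(PIState(), x=0.5e-3, xd=1e-3, dt=0.004, gains=g)
        # e = -0.5 mm, output sign -1 -> positive effort kp*|e|
        assert u == pytest.approx(0.09 * 0.5e-3)

    def test_printed_gains_one_second_of_constant_error(self):
        """kP = 0.090, kI = 0.40, |e| = 0.5 mm held 1 s ->
        |u| = 0.090*5e-4 + 0.40*5e-4*1 = 2.45e-4."""
        g = PIGains(kp=0.090, ki=0.40)
        s = PIState()
        dt = 1.0 / 250.0
        for _ in range(250):
            u, s = pi_update(s, x=0.5e-3, xd=1e-3, dt=dt, gains=g)
        assert abs(u) == pytest.approx(2.45e-4, rel=1e-12)

    def test_negative_gains_rejected(self):
        with pytest.raises(ValueError):
            PIGains(kp=-0.1)


class TestMRAC:
    def test_adaptation_freezes_at_zero_error(self):
        p = MRACParams(gamma_x=1e5, gamma_r=1e5)
        s0 = MRACState(theta_x=0.03, theta_r=0.1)
        u, s1 = mrac_update(s0, x=5e-4, xr=5e-4, r=1e-3, dt=0.004, params=p)
        assert s1.theta_x == s0.theta_x
        assert s1.theta_r == s0.theta_r
        assert u == pytest.approx(0.03 * 5e-4 + 0.1 * 1e-3)

    def test_adaptation_direction_raises_gains_when_lagging(self):
        # x below the reference (e_ad < 0) must push both gains up
        p = MRACParams(gamma_x=1e5, gamma_r=1e5)
        s0 = MRACState(theta_x=0.03, theta_r=0.1)
        _, s1 = mrac_update(s0, x=4e-4, xr=6e-4, r=1e-3, dt=0.004, params=p)
        assert s1.theta_x > s0.theta_x
        assert s1.theta_r > s0.theta_r

    def test_update_is_deterministic(self):
        p = MRACParams()
        s = MRACState()
        a = mrac_update(s, 1e-4, 2e-4, 1e-3, 0.004, p)
        b = mrac_update(s, 1e-4, 2e-4, 1e-3, 0.004, p)
        assert a[0] == b[0]
        assert a[1].theta_x == b[1].theta_x


class TestADPPIStructure:
    def test_basis_at_zero(self):
        assert np.allclose(adppi_basis(0.0), [0.0, 1.0, 0.0, 0.0])

    def test_basis_at_one(self):
        b = adppi_basis(1.0)
        assert b == pytest.approx([1.0, math.e, math.sin(1.0), 1.0])

    def test_basis_last_component_is_identity(self):
        for x in (-0.3, 0.7, 2.0):
            assert adppi_basis(x)[3] == x

    def test_solve_P_identity_example(self):
        P = solve_P(-np.eye(2), 2.0 * np.eye(2))
        assert np.allclose(P, np.eye(2), atol=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_solve_P_matches_direct_linear_solve(self, seed):
        """Residual check against solving the 3 unique entries directly."""
        rng = np.random.default_rng(seed)
        # random Hurwitz matrix: negative-definite symmetric part
        A = -np.diag(rng.uniform(0.5, 3.0, 2))
        T = rng.normal(size=(2, 2))
        A_r = np.linalg.solve(T, A @ T)
        Q = np.eye(2)
        P = solve_P(A_r, Q)
        residual = A_r.T @ P + P @ A_r + Q
        assert np.max(np.abs(residual)) <= 1e-10
        # brute force: unknowns p11, p12, p22
        a, b = A_r[0], A_r[1]
        M = np.array([
            [2 * a[0], 2 * b[0], 0.0],
            [a[1], a[0] + b[1], b[0]],
            [0.0, 2 * a[1], 2 * b[1]],
        ])
        p = np.linalg.solve(M, -np.array([Q[0, 0], Q[0, 1], Q[1, 1]]))
        assert P[0, 0] == pytest.approx(p[0], rel=1e-9)
        assert P[0, 1] == pytest.approx(p[1], rel=1e-9, abs=1e-12)
        assert P[1, 1] == pytest.approx(p[2], rel=1e-9)
        assert np.all(np.linalg.eigvalsh(P) > 0.0)

    def test_solve_P_rejects_unstable_matrix(self):
        A_r = np.array([[0.1, 0.0], [0.0, -1.0]])
        with pytest.raises(ValueError):
            solve_P(A_r, np.eye(2))

    def test_preset_Ar_is_hurwitz(self):
        for name in ADPPI_PRESETS:
            params = adppi_preset(name)
            eig = np.linalg.eigvals(params.A_r)
            assert np.all(eig.real < 0.0), name

    def test_zero_adaptation_reduces_to_pi_bit_identically(self):
        """Gamma = 0 and zero initial estimates: the adaptive law must
        reproduce the PI controller exactly, tick for tick."""
        adp = ADPPIParams(kp=0.090, ki=0.40, Gamma_K=np.zeros(2),
                          Gamma_W=np.zeros(4))
        pig = PIGains(kp=0.090, ki=0.40, output_sign=-1.0)
        s_adp, s_pi = ADPPIState(), PIState()
        xlin = np.zeros(2)
        dt = 1.0 / 250.0
        rng = np.random.default_rng(7)
        for k in range(200):
            x = float(rng.normal(5e-4, 2e-4))
            xd = 1e-3
            u_adp, s_adp = adppi_update(s_adp, x, xd, xlin, dt, adp)
            u_pi, s_pi = pi_update(s_pi, x, xd, dt, pig)
            assert u_adp == u_pi  # bit identical
            assert s_adp.xI == s_pi.integral

    def test_adaptation_moves_estimates(self):
        adp = adppi_preset("step_sim")
        s = ADPPIState()
        u, s1 = adppi_update(s, x=2e-4, xd=1e-3, xlin=np.array([4e-4, 0.0]),
                             dt=0.004, params=adp)
        assert np.any(s1.K_hat != 0.0) and np.any(s1.W_hat != 0.0)


class TestPresets:
    def test_mrac_step_sim_row(self):
        p, s = mrac_preset("step_sim")
        assert p.gamma_x == pytest.approx(1.45e5)
        assert s.theta_x == 0.035 and s.theta_r == 0.140
        assert p.reference.a_r == -2.0 and p.reference.b_r == 2.0

    def test_adppi_step_sim_row(self):
        p = adppi_preset("step_sim")
        assert (p.kp, p.ki, p.a_lin, p.b_lin) == (0.090, 0.40, -3.50, 8.50)
        assert np.allclose(p.Gamma_K, 0.010)
        assert np.allclose(p.Gamma_W, 1.0e-5)

    def test_all_rows_present(self):
        names = {f"{shape}_{kind}" for shape in
                 ("step", "sine", "ramp", "square") for kind in ("exp", "sim")}
        assert set(MRAC_PRESETS) == names
        assert set(ADPPI_PRESETS) == names


class TestOpenLoop:
    def test_zero_schedule(self):
        assert openloop_update(1.0, OpenLoopSchedule()) == 0.0

    def test_constant_after_onset(self):
        s = OpenLoopSchedule(effort=3e-4, onset=0.5)
        assert openloop_update(0.4, s) == 0.0
        assert openloop_update(0.6, s) == 3e-4

    def test_table_zero_order_hold(self):
        s = OpenLoopSchedule(table=[(0.0, 1e-4), (1.0, 2e-4), (2.0, 0.0)])
        assert openloop_update(0.5, s) == 1e-4
        assert openloop_update(1.5, s) == 2e-4
        assert openloop_update(2.5, s) == 0.0

    def test_ignores_feedback_by_construction(self):
        # the schedule has no state argument at all: same output regardless
        s = OpenLoopSchedule(effort=1e-4)
        assert openloop_update(3.0, s) == openloop_update(3.0, s) == 1e-4
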