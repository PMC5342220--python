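"""Muscle-tendon actuator: constitutive curves, contraction dynamics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from fesim.muscle import (
    MuscleParams,
    active_force_length,
    activation_rate,
    fiber_force,
    fiber_velocity,
    init_muscle_state,
    mtu_rates,
    muscle_tendon_force,
    passive_force_length,
    tendon_force,
)


class TestInit:
    def test_rest_state_sums_lengths(self):
        p = MuscleParams(l0M=5e-3, lsT=2e-3)
        s = init_muscle_state(p)
        assert s.lMT == pytest.approx(7e-3)
        assert s.a == 0.0
        assert s.lM == 5e-3

    def test_tendon_strain_zero_at_rest(self, muscle_params):
        s = init_muscle_state(muscle_params)
        strain = (s.lT - muscle_params.lsT) / muscle_params.lsT
        assert abs(strain) < 1e-12  # zero up to float resolution of the sum

    def test_default_fiber_length_matches_whole_muscle_ratio(self, muscle_params):
        # optimal fiber = 0.44 x mean whole-muscle length of 10.44 mm
        assert muscle_params.l0M == pytest.approx(0.44 * 10.44e-3, rel=1e-3)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            MuscleParams(l0M=-1.0)
        with pytest.raises(ValueError):
            MuscleParams(fiber_ratio=1.5)


class TestActivation:
    def test_fixed_point(self, muscle_params):
        assert activation_rate(0.3, 0.3, muscle_params) == 0.0

    def test_initial_rise_rate(self):
        p = MuscleParams(tau_act=0.01)
        # tau = tau_act * (0.5 + 1.5*0) -> rate = 1 / 0.005
        assert activation_rate(0.0, 1.0, p) == pytest.approx(200.0)

    def test_step_response_monotone_saturating(self, muscle_params):
        a, dt = 0.0, 1e-5
        prev = a
        for _ in range(200_000):
            a += dt * activation_rate(a, 1.0, muscle_params)
            assert a >= prev - 1e-12
            prev = a
        assert a == pytest.approx(1.0, abs=1e-6)

    def test_out_of_range_rejected(self, muscle_params):
        with pytest.raises(ValueError):
            activation_rate(-0.1, 0.5, muscle_params)
        with pytest.raises(ValueError):
            activation_rate(0.5, 1.5, muscle_params)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=50))
    def test_activation_bounded_for_any_excitation(self, excitations):
        """Activation stays in [0, 1] for arbitrary excitation sequences."""
        p = MuscleParams()
        a = 0.0
        dt = 1e-4
        for u in excitations:
            for _ in range(40):  # hold each excitation for one tick
                a += dt * activation_rate(a, u, p)
                assert 0.0 <= a <= 1.0


class TestTendon:
    def test_zero_at_and_below_slack(self, muscle_params):
        p = muscle_params
        assert tendon_force(p.lsT, p) == 0.0
        assert tendon_force(0.5 * p.lsT, p) == 0.0

    def test_negative_length_rejected(self, muscle_params):
        with pytest.raises(ValueError):
            tendon_force(-1e-6, muscle_params)

    def test_curve_matches_independent_evaluation(self, muscle_params):
        """Toe/linear piecewise curve against a direct transcription."""
        p = muscle_params
        for eps in np.linspace(1e-6, 2 * p.eps_toe, 101):
            got = tendon_force(p.lsT * (1 + eps), p)
            if eps < p.eps_toe:
                want = p.f_toe * (math.exp(p.k_toe * eps / p.eps_toe) - 1.0) / (
                    math.exp(p.k_toe) - 1.0
                )
            else:
                want = p.k_lin * (eps - p.eps_toe) + p.f_toe
            assert got == pytest.approx(want, rel=1e-12, abs=1e-15)

    def test_linear_region_slope_is_k_lin(self, muscle_params):
        p = muscle_params
        e1, e2 = 1.2 * p.eps_toe, 1.6 * p.eps_toe
        f1 = tendon_force(p.lsT * (1 + e1), p)
        f2 = tendon_force(p.lsT * (1 + e2), p)
        assert (f2 - f1) / (e2 - e1) == pytest.approx(p.k_lin, rel=1e-12)

    def test_continuous_and_monotone(self, muscle_params):
        p = muscle_params
        grid = np.linspace(0.0, p.lsT * 1.1, 2000)
        f = np.array([tendon_force(lT, p) for lT in grid])
        assert np.all(np.diff(f) >= 0.0)
        assert np.max(np.abs(np.diff(f))) < 0.05  # no jumps on a fine grid


class TestFiberForce:
    def test_isometric_optimum_is_unity(self, muscle_params):
        p = muscle_params
        assert fiber_force(1.0, p.l0M, 0.0, p) == pytest.approx(1.0)

    def test_passive_zero_at_optimum(self, muscle_params):
        p = muscle_params
        assert fiber_force(0.0, p.l0M, 0.0, p) == 0.0

    def test_force_length_gaussian_symmetry(self, muscle_params):
        p = muscle_params
        assert active_force_length(0.5, p) == pytest.approx(
            active_force_length(1.5, p), rel=1e-12
        )
        assert active_force_length(1.0, p) == 1.0

    def test_passive_rises_beyond_optimum(self, muscle_params):
        p = muscle_params
        assert passive_force_length(1.0, p) == 0.0
        assert passive_force_length(1.0 + p.eps0M, p) == pytest.approx(1.0)


class TestContractionDynamics:
    @staticmethod
    def _state_with_tendon_force(p, a, lM, f_target):
        """lMT such that the tendon transmits exactly f_target (normalized)."""
        if f_target <= p.f_toe:
            eps = brentq(
                lambda e: p.f_toe * math.expm1(p.k_toe * e / p.eps_toe)
                / math.expm1(p.k_toe) - f_target,
                1e-12, p.eps_toe,
            )
        else:
            eps = p.eps_toe + (f_target - p.f_toe) / p.k_lin
        return lM + p.lsT * (1.0 + eps)

    def test_isometric_equilibrium_zero_velocity(self, muscle_params):
        p = muscle_params
        a = 0.5
        lMT = self._state_with_tendon_force(p, a, p.l0M, a * 1.0)
        vM = fiber_velocity(a, p.l0M, lMT, p)
        assert abs(vM) < 1e-9 * p.vmax * p.l0M

    def test_shortening_when_tendon_below_capacity(self, muscle_params):
        p = muscle_params
        a = 1.0
        lMT = self._state_with_tendon_force(p, a, p.l0M, 0.4)  # < afl = 1
        assert fiber_velocity(a, p.l0M, lMT, p) < 0.0

    @pytest.mark.parametrize("a,lM_fac,f_fac", [
        (0.9, 1.0, 0.5), (0.5, 0.9, 0.8), (0.7, 1.1, 1.2),
        (1.0, 1.0, 0.05), (0.2, 0.95, 0.9), (0.6, 1.05, 1.05),
    ])
    def test_velocity_round_trip_reproduces_tendon_force(
        self, muscle_params, a, lM_fac, f_fac
    ):
        """fiber_velocity then fiber_force reproduces the tendon force."""
        p = muscle_params
        lM = lM_fac * p.l0M
        afl = a * active_force_length(lM / p.l0M, p)
        f_target = passive_force_length(lM / p.l0M, p) + f_fac * afl
        lMT = self._state_with_tendon_force(p, a, lM, f_target)
        vM = fiber_velocity(a, lM, lMT, p)
        back = fiber_force(a, lM, vM, p)
        assert back == pytest.approx(tendon_force(lMT - lM, p), rel=1e-8)

    @pytest.mark.parametrize("a,lM_fac,f_fac", [
        (0.9, 1.0, 0.5), (0.5, 0.9, 0.8), (0.7, 1.1, 1.2), (1.0, 1.0, 0.05),
    ])
    def test_analytic_inverse_matches_bracketing_solver(
        self, muscle_params, a, lM_fac, f_fac
    ):
        p = muscle_params
        lM = lM_fac * p.l0M
        afl = a * active_force_length(lM / p.l0M, p)
        f_target = passive_force_length(lM / p.l0M, p) + f_fac * afl
        lMT = self._state_with_tendon_force(p, a, lM, f_target)
        v_analytic = fiber_velocity(a, lM, lMT, p, method="analytic")
        v_brentq = fiber_velocity(a, lM, lMT, p, method="brentq")
        assert v_analytic == pytest.approx(v_brentq, rel=1e-9, abs=1e-15)

    def test_velocity_bounded_by_vmax(self, muscle_params):
        p = muscle_params
        vcap = p.vmax * p.l0M
        # slack tendon, full activation: maximal shortening, still bounded
        v = fiber_velocity(1.0, p.l0M, p.l0M + 0.5 * p.lsT, p)
        assert -vcap <= v <= vcap

    def test_steady_state_matches_algebraic_equilibrium(self, muscle_params):
        """Constant full excitation at fixed path length converges to the
        root of tendon force = isometric fiber force."""
        p = muscle_params
        s = init_muscle_state(p)
        lMT = s.lMT
        a, lM, dt = 0.0, p.l0M, 1e-5
        for _ in range(300_000):  # 3 s
            da, vM, _ = mtu_rates(a, lM, lMT, 1.0, p)
            a = min(1.0, a + dt * da)
            lM += dt * vM
        lM_eq = brentq(
            lambda l: tendon_force(lMT - l, p)
            - fiber_force(1.0, l, 0.0, p),
            0.5 * p.l0M, lMT - 1e-6,
        )
        assert lM == pytest.approx(lM_eq, rel=1e-5)
        assert mtu_rates(a, lM, lMT, 1.0, p)[1] == pytest.approx(0.0, abs=1e-8)


class TestMuscleTendonForce:
    def test_zero_at_rest(self, muscle_params):
        s = init_muscle_state(muscle_params)
        assert muscle_tendon_force(s, muscle_params) == 0.0

    def test_linear_region_closed_form(self, muscle_params):
        p = muscle_params
        s = init_muscle_state(p)
        eps = 1.5 * p.eps_toe
        s.lMT = s.lM + p.lsT * (1 + eps)
        want = p.F0M * (p.k_lin * (eps - p.eps_toe) + p.f_toe)
        assert muscle_tendon_force(s, p) == pytest.approx(want, rel=1e-12)

    def test_nonnegative_everywhere(self, muscle_params):
        p = muscle_params
        s = init_muscle_state(p)
        for lMT in np.linspace(0.8 * s.lMT, 1.1 * s.lMT, 50):
            s.lMT = lMT
            if s.lMT >= s.lM:
                assert muscle_tendon_force(s, p) >= 0.0

    def test_fused_rates_match_individual_operations(self, muscle_params):
        p = muscle_params
        a, lM = 0.4, 0.97 * p.l0M
        lMT = lM + p.lsT * 1.01
        da, vM, F = mtu_rates(a, lM, lMT, 0.8, p)
        assert da == pytest.approx(activation_rate(a, 0.8, p), rel=1e-12)
        assert vM == pytest.approx(fiber_velocity(a, lM, lMT, p), rel=1e-12)
        assert F == pytest.approx(p.F0M * tendon_force(lMT - lM, p), rel=1e-12)
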