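import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from rivaldyn import _kernels as K
from rivaldyn.forcing import (
    ForcingSpec,
    blank_gate,
    evaluate,
    flicker_component,
    forcing_period_ms,
    oscillator_rhs,
    square_sigmoid,
)

ALL_SPECS = [
    ForcingSpec(protocol="fixed", J_max=10.0),
    ForcingSpec(protocol="swap", f_s=1.5, J_max=10.0),
    ForcingSpec(protocol="flicker", f_s=1.5, J_max=10.0),
    ForcingSpec(protocol="flicker_and_swap", f_s=1.5, J_max=10.0),
    ForcingSpec(protocol="flicker_and_swap", f_s=1.5, J_max=10.0, raw_product=True),
    ForcingSpec(protocol="blank_and_swap", f_s=1.5, J_max=10.0, blank_ms=150.0),
]


class TestOscillator:
    def test_solution_is_unit_circle_sinusoid(self):
        f_s = 1.5
        sol = solve_ivp(
            lambda t, z: oscillator_rhs(t, z[0], z[1], f_s),
            (0.0, 2000.0), [0.0, 1.0], rtol=1e-10, atol=1e-12,
            dense_output=True,
        )
        t = np.linspace(0, 2000, 400)
        z = sol.sol(t)
        w = 2 * math.pi * f_s / 1000.0
        np.testing.assert_allclose(z[0], np.sin(w * t), atol=1e-7)
        np.testing.assert_allclose(z[1], np.cos(w * t), atol=1e-7)

    @pytest.mark.parametrize("r0", [0.2, 2.0])
    def test_unit_circle_attracts(self, r0):
        sol = solve_ivp(
            lambda t, z: oscillator_rhs(t, z[0], z[1], 1.5),
            (0.0, 50.0), [r0, 0.0], rtol=1e-10, atol=1e-12, dense_output=True,
        )
        t = np.linspace(0, 50, 100)
        r = np.hypot(*sol.sol(t))
        drift = np.abs(r - 1.0)
        assert drift[-1] < drift[0] and drift[-1] < 1e-3

    def test_origin_is_equilibrium(self):
        assert oscillator_rhs(0.0, 0.0, 0.0, 1.5) == (0.0, 0.0)


class TestSquareSigmoid:
    def test_midpoint(self):
        assert square_sigmoid(0.0) == 0.5

    def test_saturation_value(self):
        assert square_sigmoid(1.0, 10.0) == pytest.approx(1 / (1 + math.exp(-10)), abs=1e-12)

    @given(u=st.floats(-50, 50))
    @settings(max_examples=100, deadline=None)
    def test_complement_identity(self, u):
        assert square_sigmoid(u) + square_sigmoid(-u) == pytest.approx(1.0, abs=1e-12)


class TestFlickerComponent:
    def test_starts_at_one(self):
        assert flicker_component(0.0, 1.5) == pytest.approx(1.0, abs=1e-12)

    def test_de_moivre_identity(self):
        t = np.linspace(0.0, 2000.0, 1001)
        f_s = 1.5
        got = np.array([flicker_component(ti, f_s) for ti in t])
        want = np.cos(2 * math.pi * 12 * f_s * t / 1000.0)
        np.testing.assert_allclose(got, want, atol=1e-11)

    def test_fundamental_period(self):
        spec = ForcingSpec(protocol="flicker", f_s=1.5)
        assert forcing_period_ms(spec) == pytest.approx(1000.0 / 18.0)


class TestEvaluate:
    def test_fixed(self):
        spec = ForcingSpec(protocol="fixed", J_max=10.0)
        assert evaluate(spec, 123.4) == (10.0, 10.0)

    def test_swap_midpoint_at_swap_instant(self):
        spec = ForcingSpec(protocol="swap", f_s=1.5, J_max=10.0)
        J1, J2 = evaluate(spec, 0.0)
        assert J1 == pytest.approx(5.0) and J2 == pytest.approx(5.0)

    def test_subunit_channels_are_common(self):
        """Both populations of the modelled subunit receive the same signal:
        the swapped half-cycle drives the other (unmodelled) subunit."""
        for spec in ALL_SPECS:
            for t in np.linspace(0.0, 700.0, 113):
                J1, J2 = evaluate(spec, t)
                assert J1 == J2

    @pytest.mark.parametrize("spec", ALL_SPECS[1:], ids=lambda s: s.protocol + ("_raw" if s.raw_product else ""))
    def test_periodicity(self, spec):
        T = forcing_period_ms(spec)
        for t in np.linspace(0.0, T, 37):
            np.testing.assert_allclose(evaluate(spec, t), evaluate(spec, t + T), atol=1e-9)
            np.testing.assert_allclose(evaluate(spec, t), evaluate(spec, t + 5 * T), atol=1e-9)

    def test_range(self):
        for spec in ALL_SPECS:
            t = np.linspace(0.0, 1500.0, 2000)
            J = np.array([evaluate(spec, ti) for ti in t])
            assert J.min() >= 0.0 and J.max() <= spec.J_max + 1e-12

    def test_flicker_and_swap_off_half_cycle_is_dark(self):
        spec = ForcingSpec(protocol="flicker_and_swap", f_s=1.5, J_max=10.0)
        # middle of the swapped-away half-cycle, whatever the flicker phase
        T = forcing_period_ms(spec)
        for t in np.linspace(0.55 * T, 0.95 * T, 50):
            J1, _ = evaluate(spec, t)
            assert J1 < 0.02 * spec.J_max

    def test_blank_gate_duty(self):
        """The gate's half-height crossings delimit exactly blank_ms, so the
        on-duration per half swap cycle is 1000/(2 f_s) - blank_ms."""
        f_s, blank = 1.5, 150.0
        half = 500.0 / f_s
        t = np.linspace(0.0, half, 200_001)
        gate = np.array([blank_gate(ti, f_s, blank) for ti in t])
        on = np.trapezoid((gate > 0.5).astype(float), t)
        assert on == pytest.approx(half - blank, abs=0.5)

    def test_blank_is_dark_and_on_phase_is_bright(self):
        spec = ForcingSpec(protocol="blank_and_swap", f_s=1.5, J_max=10.0, blank_ms=150.0)
        assert evaluate(spec, 260.0)[0] < 1e-3          # mid-blank
        assert evaluate(spec, 100.0)[0] > 9.99          # mid on-phase

    def test_invalid_blank_duration_rejected(self):
        with pytest.raises(ValueError):
            ForcingSpec(protocol="blank_and_swap", f_s=1.5, blank_ms=400.0)

    def test_unknown_protocol_rejected(self):
        with pytest.raises(ValueError):
            ForcingSpec(protocol="strobe")


class TestKernelConsistency:
    def test_compiled_forcing_matches_closed_form(self):
        for spec in ALL_SPECS:
            code, fp = K.pack_forcing(spec)
            for t in np.linspace(0.0, 1500.0, 733):
                np.testing.assert_allclose(
                    K._forcing(t, code, fp), evaluate(spec, t), atol=1e-12,
                    err_msg=spec.protocol)

    def test_compiled_rhs_matches_reference(self, rng):
        from rivaldyn.model import ModelParams, rhs

        spec = ForcingSpec(protocol="swap", f_s=1.5, J_max=10.0)
        code, fp = K.pack_forcing(spec)
        for reduced in (False, True):
            for mode in ("smoothed", "hard_rectify"):
                p = ModelParams(g=3.0, h=2.0, gain_mode=mode,
                                instantaneous_inhibition=reduced)
                mp = K.pack_model(p)
                y = rng.uniform(0, 30, p.n_state)
                t = 123.0
                dy = np.empty_like(y)
                K._rhs(t, y, mp, code, fp, dy)
                ref = rhs(t, y, p, lambda tt: evaluate(spec, tt))
                np.testing.assert_allclose(dy, ref, rtol=1e-12, atol=1e-14)
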