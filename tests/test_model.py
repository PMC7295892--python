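import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rivaldyn.model import (
    ModelParams,
    asymptotic_rate,
    dgain,
    find_equilibria,
    gain,
    jacobian,
    lift_rates,
    rhs,
    swap_populations,
)
from rivaldyn.integrate import default_ic, settle


HARD = ModelParams(gain_mode="hard_rectify")
SMOOTH = ModelParams(gain_mode="smoothed")


class TestGain:
    def test_hard_rectifies_negative_drive(self):
        assert gain(-3.0, HARD) == 0.0
        assert gain(2.5, HARD) == 2.5

    def test_smoothed_half_value_at_threshold(self):
        # sigmoid equals 1/2 exactly at theta, so R(theta) = theta / 2
        assert gain(0.05, SMOOTH) == pytest.approx(0.025, abs=1e-15)

    def test_smoothed_is_transparent_well_above_threshold(self):
        assert gain(1.0, SMOOTH) == pytest.approx(1.0, abs=1e-10)

    def test_smoothed_clamped_below_zero(self):
        for x in (-0.01, -1.0, -140.0):
            assert gain(x, SMOOTH) == 0.0

    def test_hard_derivative_refuses_kink(self):
        with pytest.raises(ValueError):
            dgain(0.0, HARD)

    @given(x=st.floats(0.0, 50.0))
    @settings(max_examples=50, deadline=None)
    def test_gain_nonnegative_and_below_identity(self, x):
        for p in (HARD, SMOOTH):
            g = gain(x, p)
            assert 0.0 <= g <= x + 1e-12


class TestNakaRushton:
    def test_zero_drive_zero_rate(self):
        assert asymptotic_rate(0.0, 0.0, SMOOTH) == 0.0
        assert asymptotic_rate(0.0, 37.0, SMOOTH) == 0.0

    def test_half_saturation(self):
        # P equals semi-saturation + adaptation -> half the ceiling
        assert asymptotic_rate(10.0, 0.0, SMOOTH) == pytest.approx(50.0)

    def test_strong_drive(self):
        assert asymptotic_rate(30.0, 0.0, SMOOTH) == pytest.approx(90.0)

    @given(P=st.floats(0.0, 1e3), H=st.floats(0.0, 1e3))
    @settings(max_examples=100, deadline=None)
    def test_rate_in_range(self, P, H):
        r = asymptotic_rate(P, H, SMOOTH)
        assert 0.0 <= r < 100.0


class TestRhs:
    def test_origin_is_equilibrium_at_zero_input(self):
        for p in (SMOOTH, SMOOTH.with_(instantaneous_inhibition=True)):
            d = rhs(0.0, np.zeros(p.n_state), p, lambda t: (0.0, 0.0))
            assert np.all(d == 0.0)

    def test_population_exchange_symmetry(self, rng):
        p = SMOOTH.with_(g=1.5, h=4.0)
        y = rng.uniform(0, 30, 6)
        d1 = rhs(0.0, y, p, lambda t: (3.0, 7.0))
        d2 = rhs(0.0, swap_populations(y), p, lambda t: (7.0, 3.0))
        np.testing.assert_allclose(swap_populations(d1), d2, rtol=1e-14)

    def test_nonfinite_state_rejected(self):
        y = np.zeros(6)
        y[0] = np.nan
        with pytest.raises(FloatingPointError):
            rhs(0.0, y, SMOOTH, lambda t: (0.0, 0.0))

    def test_equilibria_are_rhs_zeros(self):
        p = SMOOTH.with_(g=1.5, h=1.0)
        for eq in find_equilibria(p, 10.0, 10.0):
            d = rhs(0.0, eq.state, p, lambda t: (10.0, 10.0))
            assert np.linalg.norm(d) < 1e-8


class TestJacobian:
    @pytest.mark.parametrize("reduced", [False, True])
    def test_matches_central_differences(self, reduced, rng):
        p = SMOOTH.with_(g=1.5, h=4.0, instantaneous_inhibition=reduced)
        n = p.n_state
        force = lambda t: (8.0, 6.0)
        for _ in range(5):
            y = rng.uniform(0, 30, n)
            J = jacobian(y, p, 8.0, 6.0)
            Jfd = np.zeros((n, n))
            eps = 1e-6
            for j in range(n):
                e = np.zeros(n)
                e[j] = eps
                Jfd[:, j] = (rhs(0, y + e, p, force) - rhs(0, y - e, p, force)) / (2 * eps)
            assert np.abs(J - Jfd).max() < 1e-5

    def test_origin_block_diagonal_eigenvalues(self):
        p = SMOOTH
        J = jacobian(np.zeros(6), p, 0.0, 0.0)
        eig = np.sort(np.linalg.eigvals(J).real)
        expected = np.sort([-1 / p.tau_E, -1 / p.tau_H, -1 / p.tau_I] * 2)
        np.testing.assert_allclose(eig, expected, rtol=1e-12)

    def test_commutes_with_exchange_at_symmetric_state(self):
        p = SMOOTH.with_(g=1.5, h=4.0)
        y = lift_rates(5.0, 5.0, p)
        J = jacobian(y, p, 10.0, 10.0)
        P = np.zeros((6, 6))
        P[:3, 3:] = np.eye(3)
        P[3:, :3] = np.eye(3)
        np.testing.assert_allclose(P @ J @ P, J, atol=1e-14)


class TestEquilibria:
    def test_zero_input_origin_stable(self):
        eqs = find_equilibria(SMOOTH.with_(g=1.5, h=1.0), 0.0, 0.0)
        assert len(eqs) == 1
        assert np.linalg.norm(eqs[0].state) < 1e-8
        assert eqs[0].stable

    def test_sim_regime_has_stable_symmetric_equilibrium(self):
        eqs = find_equilibria(SMOOTH.with_(g=1.5, h=15.0), 10.0, 10.0)
        sym = [e for e in eqs if e.symmetric]
        assert len(sym) == 1 and sym[0].stable

    def test_wta_regime_has_stable_asymmetric_pair(self):
        eqs = find_equilibria(SMOOTH.with_(g=1.5, h=1.0), 10.0, 10.0)
        stable_asym = [e for e in eqs if e.stable and not e.symmetric]
        sym = [e for e in eqs if e.symmetric]
        assert len(stable_asym) == 2
        assert len(sym) == 1 and not sym[0].stable
        # the pair is the mirror image of itself
        a, b = stable_asym
        np.testing.assert_allclose(swap_populations(a.state), b.state, atol=1e-6)

    def test_slaving_at_fixed_points(self):
        p = SMOOTH.with_(g=1.5, h=4.22842214)
        for eq in find_equilibria(p, 10.0, 10.0):
            E1, H1, I1, E2, H2, I2 = eq.state
            assert abs(H1 - p.h * E1) < 1e-7 and abs(H2 - p.h * E2) < 1e-7
            assert abs(I1 - E1) < 1e-7 and abs(I2 - E2) < 1e-7


class TestTrajectoryInvariants:
    def test_rates_bounded_on_trajectory(self, fixed_spec):
        p = ModelParams(g=1.5, h=4.3, gain_mode="smoothed")
        traj = settle(p, fixed_spec, default_ic(p), 5_000.0, 20_000.0)
        E = traj.E
        assert E.min() >= -1e-9 and E.max() < 100.0

    def test_symmetry_of_exchanged_solutions(self, fixed_spec):
        from rivaldyn.integrate import integrate

        p = ModelParams(g=1.5, h=4.3, gain_mode="smoothed")
        ic = np.array([30.0, 5.0, 30.0, 2.0, 1.0, 2.0])
        t1 = integrate(p, fixed_spec, ic, 2_000.0, record_stride=10)
        t2 = integrate(p, fixed_spec, swap_populations(ic), 2_000.0, record_stride=10)
        np.testing.assert_allclose(
            swap_populations(t1.states), t2.states, atol=1e-10)

    def test_reduced_model_is_small_tau_I_limit(self, fixed_spec):
        """Full-model trajectories converge to the instantaneous-inhibition
        variant as tau_I -> 0 (decreasing sup-norm gap on E and H)."""
        from rivaldyn.integrate import integrate

        pr = ModelParams(g=1.5, h=1.0, gain_mode="smoothed",
                         instantaneous_inhibition=True)
        icr = np.array([30.0, 5.0, 2.0, 1.0])
        ref = integrate(pr, fixed_spec, icr, 2_000.0, record_stride=10)
        gaps = []
        for tau_I in (3.0, 1.0, 0.3, 0.1):
            pf = pr.with_(instantaneous_inhibition=False, tau_I=tau_I)
            icf = np.array([30.0, 5.0, 30.0, 2.0, 1.0, 2.0])
            full = integrate(pf, fixed_spec, icf, 2_000.0, record_stride=10)
            sel = full.states[:, [0, 1, 3, 4]]
            gaps.append(np.abs(sel - ref.states).max())
        assert all(a > b for a, b in zip(gaps, gaps[1:]))
        assert gaps[-1] < 0.2
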