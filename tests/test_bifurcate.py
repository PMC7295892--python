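import numpy as np
import pytest
from scipy.optimize import brentq

from rivaldyn.bifurcate import (
    _max_complex_re,
    continue_equilibria,
    find_boundary,
    floquet,
    periodic_orbit,
    strobe_fixed_point,
    sweep_diagram,
)
from rivaldyn.forcing import forcing_period_ms
from rivaldyn.integrate import advance, commensurate_dt, default_ic, settle, strobe_map
from rivaldyn.model import ModelParams, find_equilibria

SMOOTH = ModelParams(g=1.5, gain_mode="smoothed")


def _scan_hopf(p, lo, hi):
    """Independent dense-scan + root-bracketing oracle for the symmetric-branch
    Hopf location (real part of the leading complex pair crossing zero)."""

    def f(h):
        eqs = [e for e in find_equilibria(p.with_(h=h), 10.0, 10.0) if e.symmetric]
        return _max_complex_re(eqs[0].eigenvalues)

    hs = np.linspace(lo, hi, 60)
    vals = [f(h) for h in hs]
    for a, b, fa, fb in zip(hs[:-1], hs[1:], vals[:-1], vals[1:]):
        if fa * fb < 0:
            return brentq(f, a, b, xtol=1e-8)
    raise AssertionError("scan found no crossing")


@pytest.fixture(scope="module")
def sym_branch():
    return continue_equilibria(SMOOTH, 10.0, (0.5, 15.0), ds=0.02)


@pytest.fixture(scope="module")
def asym_branch():
    return continue_equilibria(SMOOTH, 10.0, (0.5, 6.0), ds=0.02,
                               branch="asymmetric")


class TestEquilibriumContinuation:

    def test_symmetric_branch_carries_pitchfork(self, sym_branch):
        pf = [e for e in sym_branch.events
              if e.type == "PITCHFORK" and e.diagnostics.get("genuine")]
        assert len(pf) == 1
        # the symmetry-broken pair exists just above, not below, the pitchfork
        h_pf = pf[0].h
        above = find_equilibria(SMOOTH.with_(h=h_pf + 0.05), 10.0, 10.0)
        below = find_equilibria(SMOOTH.with_(h=h_pf - 0.5), 10.0, 10.0)
        assert sum(not e.symmetric for e in above) >= 2
        assert sum(not e.symmetric for e in below) >= 2  # WTA pair persists below

    def test_sim_hopf_matches_dense_scan(self, sym_branch):
        hops = [e for e in sym_branch.events
                if e.type == "HOPF" and e.diagnostics.get("genuine")]
        assert hops, "no genuine Hopf on the symmetric branch"
        h_cont = hops[-1].h
        h_scan = _scan_hopf(SMOOTH, 10.0, 15.0)
        assert abs(h_cont - h_scan) < 1e-4

    def test_asymmetric_branch_hopf_and_fold(self, asym_branch):
        hops = [e for e in asym_branch.events
                if e.type == "HOPF" and e.diagnostics.get("genuine")]
        folds = [e for e in asym_branch.events if e.type == "FOLD"]
        assert hops and folds
        # low-amplitude oscillations are born where the dominant branch loses
        # stability; the fold lies above, near the pitchfork region
        assert 4.0 < hops[0].h < 4.3
        assert folds[0].h > hops[0].h

    def test_hopf_pair_on_mirror_branches(self, asym_branch):
        """The population-exchange image of the continued branch carries the
        mirror Hopf, giving the pair that brackets the WTA -> LAWTA change."""
        from rivaldyn.model import jacobian, swap_populations

        hops = [e for e in asym_branch.events
                if e.type == "HOPF" and e.diagnostics.get("genuine")]
        h = hops[0].h
        pts = min(asym_branch.points, key=lambda q: abs(q.h - h))
        p = SMOOTH.with_(h=pts.h)
        eig_mirror = np.linalg.eigvals(
            jacobian(swap_populations(pts.state), p, 10.0, 10.0))
        np.testing.assert_allclose(
            np.sort(eig_mirror.imag), np.sort(pts.eigenvalues.imag), atol=1e-8)

    def test_continuation_stability_matches_simulation(self, asym_branch, fixed_spec):
        rng = np.random.default_rng(7)
        stable_pts = [q for q in asym_branch.points if q.stable and q.h > 0.6]
        for q in rng.choice(len(stable_pts), size=3, replace=False):
            pt = stable_pts[q]
            p = SMOOTH.with_(h=pt.h)
            traj = settle(p, fixed_spec, pt.state + 1e-4, 2_000.0, 2_000.0)
            assert np.abs(traj.states[-1] - pt.state).max() < 1e-2

    def test_requires_smoothed_gain(self):
        with pytest.raises(ValueError):
            continue_equilibria(SMOOTH.with_(gain_mode="hard_rectify"),
                                10.0, (0.5, 2.0))


class TestFloquet:
    def test_autonomous_cycle_has_trivial_multiplier(self, riv_trajectory):
        from rivaldyn.classify import estimate_period

        p, traj = riv_trajectory
        per = estimate_period(traj)
        y, P, M = periodic_orbit(p, 10.0, traj.states[-1], per)
        mult = np.linalg.eigvals(M)
        closest = mult[np.argmin(np.abs(mult - 1.0))]
        assert abs(closest - 1.0) < 1e-3

    def test_stable_strobe_fixed_point_contracts(self, flicker_spec):
        p = SMOOTH.with_(h=6.0)
        T = forcing_period_ms(flicker_spec)
        seed = advance(p, flicker_spec, default_ic(p, "perturbed_symmetric"),
                       300 * T, dt=commensurate_dt(flicker_spec))
        y, M = strobe_fixed_point(p, flicker_spec, seed)
        # converged fixed point of the period map
        np.testing.assert_allclose(strobe_map(p, flicker_spec, y), y, atol=1e-8)
        assert np.abs(np.linalg.eigvals(M)).max() < 1.0

    def test_monodromy_matches_finite_difference_map(self, flicker_spec):
        p = SMOOTH.with_(h=6.0)
        T = forcing_period_ms(flicker_spec)
        seed = advance(p, flicker_spec, default_ic(p, "perturbed_symmetric"),
                       300 * T, dt=commensurate_dt(flicker_spec))
        y, M = strobe_fixed_point(p, flicker_spec, seed)
        eps = 1e-5
        Mfd = np.zeros((6, 6))
        for j in range(6):
            e = np.zeros(6)
            e[j] = eps
            Mfd[:, j] = (strobe_map(p, flicker_spec, y + e)
                         - strobe_map(p, flicker_spec, y - e)) / (2 * eps)
        assert np.abs(M - Mfd).max() < 1e-4

    def test_floquet_requires_smoothed_gain(self, flicker_spec):
        with pytest.raises(ValueError):
            floquet(SMOOTH.with_(gain_mode="hard_rectify"), flicker_spec,
                    np.zeros(6), forcing_period_ms(flicker_spec))


class TestBranchAndMap:
    def test_branch_frame_has_ordered_arclength(self, sym_branch):
        df = sym_branch.to_frame()
        assert {"arclength", "h", "stable", "max_re_eig"} <= set(df.columns)
        assert (df["arclength"].diff().dropna() >= 0).all()

    def test_floquet_returns_modulus_sorted_multipliers(self, flicker_spec):
        p = SMOOTH.with_(h=6.0)
        T = forcing_period_ms(flicker_spec)
        seed = advance(p, flicker_spec, default_ic(p, "perturbed_symmetric"),
                       300 * T, dt=commensurate_dt(flicker_spec))
        y, M = strobe_fixed_point(p, flicker_spec, seed)
        mult = floquet(p, flicker_spec, y, T)
        assert np.all(np.diff(np.abs(mult)) <= 1e-12)
        np.testing.assert_allclose(np.sort(np.abs(mult)),
                                   np.sort(np.abs(np.linalg.eigvals(M))),
                                   rtol=1e-8)

    def test_regime_map_grid_and_frames(self):
        from rivaldyn.bifurcate import regime_map

        hard = ModelParams(gain_mode="hard_rectify")
        kw = dict(t_transient=10_000.0, t_record=20_000.0)
        rmap = regime_map([1.5, 2.0], [1.0, 20.0], params_base=hard,
                          classify_kwargs=kw)
        df = rmap.to_frame()
        assert len(df) == 4
        labels = {(r.g, r.h): r.label for r in df.itertuples()}
        assert labels[(1.5, 1.0)] == "WTA" and labels[(1.5, 20.0)] == "SIM"

    def test_regime_map_rejects_unsorted_grids(self):
        from rivaldyn.bifurcate import regime_map

        with pytest.raises(ValueError):
            regime_map([2.0, 1.5], [1.0, 2.0])


class TestBoundaries:
    def test_no_sign_change_raises_with_bracket(self, flicker_spec):
        with pytest.raises(ValueError, match="bracket"):
            find_boundary(1.5, (6.5, 8.0), flicker_spec, "TORUS")

    def test_sweep_is_deterministic(self, fixed_spec):
        hs = [1.0, 4.3, 15.0]
        kw = dict(t_transient=10_000.0, t_record=20_000.0)
        a = sweep_diagram(1.5, hs, params_base=ModelParams(gain_mode="hard_rectify"),
                          classify_kwargs=kw)
        b = sweep_diagram(1.5, hs, params_base=ModelParams(gain_mode="hard_rectify"),
                          classify_kwargs=kw)
        assert [lab.label for _, lab in a] == [lab.label for _, lab in b]
        assert [lab.period_ms for _, lab in a] == [lab.period_ms for _, lab in b]
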