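"""Bifurcation machinery: equilibrium continuation, Floquet multipliers,
boundary location and regime maps in the adaptation--inhibition plane.

Equilibria are continued in the adaptation strength ``h`` by pseudo-arclength
on the slaved two-dimensional system (at a fixed point ``H_i = h E_i`` and
``I_i = E_i``, so ``(E1, E2)`` determines the state); stability and event
test functions use the full-state Jacobian.  Periodic solutions of the forced
model are represented as fixed points of the stroboscopic (one-forcing-period)
map found by Newton shooting, with Floquet multipliers from the monodromy
matrix of the variational flow.  Two-parameter boundaries are traced as
per-``g`` one-dimensional bisections on the relevant test function.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import _kernels as K
from .classify import (
    RegimeLabel,
    classify_fixed,
    classify_forced,
    estimate_period,
)
from .forcing import ForcingSpec, forcing_period_ms
from .integrate import advance, commensurate_dt, default_ic, settle
from .model import (
    ModelParams,
    _reduced_jacobian,
    _reduced_residual,
    find_equilibria,
    jacobian,
    lift_rates,
    rhs,
)

__all__ = [
    "Branch",
    "BranchPoint",
    "BifurcationEvent",
    "RegimeMap",
    "continue_equilibria",
    "strobe_fixed_point",
    "floquet",
    "periodic_orbit",
    "find_boundary",
    "sweep_diagram",
    "regime_map",
    "find_critical_h",
]

EVENT_TYPES = ("FOLD", "HOPF", "PITCHFORK", "PD", "TORUS")


@dataclass
class BranchPoint:
    h: float
    state: np.ndarray           # full lifted state
    eigenvalues: np.ndarray     # equilibrium eigenvalues or Floquet multipliers
    stable: bool
    period_ms: Optional[float] = None
    arclength: float = 0.0


@dataclass
class BifurcationEvent:
    type: str
    h: float
    diagnostics: dict = field(default_factory=dict)


@dataclass
class Branch:
    kind: str                   # equilibrium | periodic_orbit | stroboscopic_fixed_point
    points: List[BranchPoint]
    events: List[BifurcationEvent]
    meta: dict = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        rows = []
        for p in self.points:
            row = {"arclength": p.arclength, "h": p.h, "stable": p.stable,
                   "period_ms": p.period_ms}
            for i, s in enumerate(p.state):
                row[f"x{i}"] = s
            row["max_re_eig"] = float(np.max(p.eigenvalues.real))
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# symmetric/antisymmetric block decomposition (population-exchange symmetry)


def _exchange_blocks(J: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Split a Jacobian at a symmetric state into (A+B, A-B) blocks, where the
    swap permutation maps block A (self) and B (cross)."""
    n = J.shape[0] // 2
    A = J[:n, :n]
    B = J[:n, n:]
    return A + B, A - B


def _max_complex_re(eig: np.ndarray) -> float:
    cplx = eig[np.abs(eig.imag) > 1e-12]
    if len(cplx) == 0:
        return -np.inf
    return float(np.max(cplx.real))


# ---------------------------------------------------------------------------
# equilibrium continuation (pseudo-arclength in (E1, E2, h))


def _ext_residual(z: np.ndarray, params: ModelParams, J: float) -> np.ndarray:
    p = params.with_(h=z[2])
    return _reduced_residual(z[:2], p, J, J)


def _ext_jacobian(z: np.ndarray, params: ModelParams, J: float) -> np.ndarray:
    """2x3 Jacobian [dF/dE1, dF/dE2, dF/dh] of the slaved system."""
    p = params.with_(h=z[2])
    Ju = _reduced_jacobian(z[:2], p, J, J)
    dh = 1e-7 * max(1.0, abs(z[2]))
    hp = z[2] + dh
    hm = max(z[2] - dh, 0.0)
    Fp = _reduced_residual(z[:2], params.with_(h=hp), J, J)
    Fm = _reduced_residual(z[:2], params.with_(h=hm), J, J)
    return np.column_stack([Ju, (Fp - Fm) / (hp - hm)])


def _corrector(
    z_pred: np.ndarray,
    tangent: np.ndarray,
    z_anchor: np.ndarray,
    ds: float,
    params: ModelParams,
    J: float,
    tol: float = 1e-11,
    max_iter: int = 12,
) -> Optional[np.ndarray]:
    z = z_pred.copy()
    if z[2] < 0:
        return None  # h is a non-negative strength
    for _ in range(max_iter):
        F = _ext_residual(z, params, J)
        c = tangent @ (z - z_anchor) - ds
        res = np.concatenate([F, [c]])
        if np.linalg.norm(res) < tol:
            return z
        Jext = np.vstack([_ext_jacobian(z, params, J), tangent])
        try:
            z = z - np.linalg.solve(Jext, res)
        except np.linalg.LinAlgError:
            return None
        if not np.all(np.isfinite(z)) or z[2] < 0:
            return None
    return z if np.linalg.norm(np.concatenate([_ext_residual(z, params, J),
                                               [tangent @ (z - z_anchor) - ds]])) < 1e-8 else None


def _tangent(z: np.ndarray, params: ModelParams, J: float,
             prev: Optional[np.ndarray]) -> np.ndarray:
    Jext = _ext_jacobian(z, params, J)
    _, _, Vt = np.linalg.svd(Jext)
    t = Vt[-1]
    if prev is not None and t @ prev < 0:
        t = -t
    return t / np.linalg.norm(t)


def _branch_tests(z: np.ndarray, params: ModelParams, J: float,
                  symmetric: bool) -> Tuple[np.ndarray, dict]:
    """Lifted eigenvalues and event test-function values at a branch point."""
    p = params.with_(h=z[2])
    st = lift_rates(z[0], z[1], p)
    Jf = jacobian(st, p, J, J)
    eig = np.linalg.eigvals(Jf)
    tests = {"hopf": _max_complex_re(eig)}
    if symmetric:
        _, anti = _exchange_blocks(Jf)
        tests["pitchfork"] = float(np.linalg.det(anti))
    return eig, tests


def continue_equilibria(
    params: ModelParams,
    J: float,
    h_range: Tuple[float, float],
    ds: float = 0.01,
    branch: str = "symmetric",
    max_points: int = 5000,
    ds_min: float = 1e-6,
    ds_max: float = 0.05,
) -> Branch:
    """Pseudo-arclength continuation of an equilibrium branch in ``h``.

    ``branch="symmetric"`` follows the diagonal branch; ``"asymmetric"``
    starts from the dominant (E1 > E2) asymmetric equilibrium at the lower end
    of ``h_range`` and follows it through folds.  Events (FOLD by turning
    point, HOPF by a complex pair's real part crossing zero, PITCHFORK by a
    symmetry-breaking real eigenvalue of the antisymmetric block on the
    symmetric branch) are located by bisection along the secant between the
    bracketing points.
    """
    if params.gain_mode != "smoothed":
        raise ValueError("continuation requires the smoothed gain")
    h0, h1 = h_range
    p0 = params.with_(h=h0)
    eqs = find_equilibria(p0, J, J)
    if branch == "symmetric":
        cands = [e for e in eqs if e.symmetric]
    else:
        cands = [e for e in eqs if not e.symmetric and e.E[0] > e.E[1]]
        if not cands:
            raise ValueError(f"no asymmetric equilibrium at h={h0}")
        cands.sort(key=lambda e: -abs(e.E[0] - e.E[1]))
    if not cands:
        raise ValueError(f"no {branch} equilibrium found at h={h0}")
    e0 = cands[0]
    z = np.array([e0.E[0], e0.E[1], h0])
    symmetric = branch == "symmetric"

    points: List[BranchPoint] = []
    events: List[BifurcationEvent] = []
    eig, tests = _branch_tests(z, params, J, symmetric)
    points.append(BranchPoint(h=z[2], state=lift_rates(z[0], z[1], params.with_(h=z[2])),
                              eigenvalues=eig, stable=bool(np.max(eig.real) < 0)))
    prev_t = None
    prev_tests = tests
    s_acc = 0.0
    step = ds
    truncated = False
    while len(points) < max_points:
        t = _tangent(z, params, J, prev_t)
        if prev_t is None and t[2] < 0:
            t = -t  # start moving toward increasing h
        z_new = None
        while step >= ds_min:
            z_new = _corrector(z + step * t, t, z, step, params, J)
            if z_new is not None:
                break
            step *= 0.5
        if z_new is None:
            truncated = True
            break
        eig, tests = _branch_tests(z_new, params, J, symmetric)
        # events between z and z_new
        for name, key in (("HOPF", "hopf"), ("PITCHFORK", "pitchfork")):
            if key in prev_tests and key in tests:
                a, b = prev_tests[key], tests[key]
                if np.isfinite(a) and np.isfinite(b) and a * b < 0:
                    h_ev, diag = _locate_event(z, z_new, key, params, J, symmetric)
                    events.append(BifurcationEvent(name, h_ev, diag))
        if prev_t is not None and prev_t[2] * t[2] < 0:
            events.append(BifurcationEvent("FOLD", float(z[2]),
                                           {"state": z[:2].copy()}))
        s_acc += step
        points.append(BranchPoint(
            h=float(z_new[2]),
            state=lift_rates(z_new[0], z_new[1], params.with_(h=z_new[2])),
            eigenvalues=eig, stable=bool(np.max(eig.real) < 0), arclength=s_acc,
        ))
        # stop if the branch has looped back onto itself
        if len(points) > 20:
            e2_idx = 2 if points[0].state.size == 4 else 3
            past = np.array([[q.state[0], q.state[e2_idx], q.h]
                             for q in points[:-10]])
            cur = np.array([z_new[0], z_new[1], z_new[2]])
            if np.min(np.linalg.norm(past - cur, axis=1)) < 1e-7:
                break
        prev_t, prev_tests = t, tests
        z = z_new
        step = min(step * 1.3, ds_max)
        if z[2] <= max(0.0, min(h0, h1) - 0.5) and t[2] < 0:
            break  # branch has folded back below the window
        if z[2] > max(h0, h1):
            break
        if z[0] < -1.0 or z[1] < -1.0 or z[0] > 100.0 or z[1] > 100.0:
            break
    uniq: List[BifurcationEvent] = []
    seen = set()
    for ev in events:
        key = (ev.type, round(ev.h, 6))
        if key not in seen:
            seen.add(key)
            uniq.append(ev)
    return Branch(kind="equilibrium", points=points, events=uniq,
                  meta={"branch": branch, "J": J, "g": params.g,
                        "truncated": truncated})


def _locate_event(z1, z2, key, params, J, symmetric, tol=1e-8):
    """Bisection for a test-function zero along the secant, re-solving the
    equilibrium at each trial point."""
    d = z2 - z1
    nd = d / np.linalg.norm(d)

    def value(s: float):
        z = _corrector(z1 + s * d, nd, z1, s * np.linalg.norm(d), params, J)
        if z is None:
            return None, None
        _, tests = _branch_tests(z, params, J, symmetric)
        return tests[key], z

    a, b = 0.0, 1.0
    fa, _ = value(a)
    fb, _ = value(b)
    z_mid = z2
    if fa is None or fb is None or fa * fb > 0:
        return float(0.5 * (z1[2] + z2[2])), {"refined": False}
    fm = fb
    for _ in range(60):
        m = 0.5 * (a + b)
        fm, zm = value(m)
        if fm is None:
            break
        z_mid = zm
        if fa * fm <= 0:
            b, fb = m, fm
        else:
            a, fa = m, fm
        if abs(b - a) * abs(z2[2] - z1[2]) < tol:
            break
    # a genuine crossing refines the test function to ~0; a discontinuous
    # sign flip (e.g. a complex pair collapsing onto the real axis) does not
    genuine = fm is not None and abs(fm) < 1e-6 * max(1.0, abs(fa or 1.0))
    return float(z_mid[2]), {"refined": True, "state": z_mid[:2].copy(),
                             "residual": fm, "genuine": genuine}


# ---------------------------------------------------------------------------
# periodic solutions: stroboscopic fixed points and Floquet multipliers


def _monodromy(params: ModelParams, spec_or_fixed, y0: np.ndarray,
               t_span: float, dt: float, t0: float = 0.0):
    mp = K.pack_model(params)
    if isinstance(spec_or_fixed, ForcingSpec):
        code, fp = K.pack_forcing(spec_or_fixed)
    else:
        code, fp = K.pack_forcing(ForcingSpec(protocol="fixed", J_max=float(spec_or_fixed)))
    n_steps = int(round(t_span / dt))
    yT, M = K.rk4_monodromy(np.asarray(y0, dtype=float), t0, dt, n_steps, mp, code, fp)
    if not (np.all(np.isfinite(yT)) and np.all(np.isfinite(M))):
        raise FloatingPointError("variational integration blew up")
    return yT, M


def strobe_fixed_point(
    params: ModelParams,
    spec: ForcingSpec,
    y0: np.ndarray,
    n_periods: int = 1,
    tol: float = 1e-10,
    max_iter: int = 40,
    dt: float = 0.1,
) -> Tuple[np.ndarray, np.ndarray]:
    """Newton shooting for a fixed point of the ``n_periods``-fold
    stroboscopic map.  Returns (fixed point, monodromy matrix)."""
    if params.gain_mode != "smoothed":
        raise ValueError("Floquet shooting requires the smoothed gain")
    T = forcing_period_ms(spec) * n_periods
    dt = commensurate_dt(spec, dt)
    y = np.asarray(y0, dtype=float).copy()
    I = np.eye(params.n_state)
    for _ in range(max_iter):
        yT, M = _monodromy(params, spec, y, T, dt)
        F = yT - y
        if np.linalg.norm(F) < tol:
            return y, M
        try:
            dy = np.linalg.solve(M - I, -F)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError("singular shooting Jacobian (at a fold?)") from exc
        y = y + dy
        if not np.all(np.isfinite(y)):
            raise RuntimeError("shooting diverged")
    raise RuntimeError(f"stroboscopic Newton did not converge (|F|={np.linalg.norm(F):.2e})")


def floquet(
    params: ModelParams,
    spec_or_fixed,
    orbit_state: np.ndarray,
    period_ms: float,
    dt: float = 0.1,
) -> np.ndarray:
    """Floquet multipliers of a periodic solution, sorted by modulus
    (descending).  ``orbit_state`` must lie on the converged orbit and
    ``period_ms`` must be its period (a forcing-period multiple when forced).
    For an autonomous orbit the spectrum contains a trivial multiplier at +1.
    """
    if params.gain_mode != "smoothed":
        raise ValueError("Floquet analysis requires the smoothed gain")
    if isinstance(spec_or_fixed, ForcingSpec) and spec_or_fixed.is_periodic:
        dt = commensurate_dt(spec_or_fixed, dt)
        k = period_ms / forcing_period_ms(spec_or_fixed)
        if abs(k - round(k)) > 1e-6:
            raise ValueError("period must be an integer multiple of the forcing period")
    else:
        dt = period_ms / math.ceil(period_ms / dt)
    _, M = _monodromy(params, spec_or_fixed, orbit_state, period_ms, dt)
    mult = np.linalg.eigvals(M)
    return mult[np.argsort(-np.abs(mult))]


def periodic_orbit(
    params: ModelParams,
    J: float,
    y_guess: np.ndarray,
    period_guess: float,
    tol: float = 1e-9,
    max_iter: int = 30,
) -> Tuple[np.ndarray, float, np.ndarray]:
    """Newton shooting for an autonomous limit cycle at fixed inputs.

    Unknowns are the anchor state and the period; the phase is pinned by
    requiring the correction to be orthogonal to the flow at the anchor.
    Returns (anchor state, period_ms, monodromy matrix).
    """
    if params.gain_mode != "smoothed":
        raise ValueError("orbit shooting requires the smoothed gain")
    n = params.n_state
    y = np.asarray(y_guess, dtype=float).copy()
    P = float(period_guess)
    force = lambda t: (J, J)
    for _ in range(max_iter):
        dt = P / math.ceil(P / 0.1)
        yT, M = _monodromy(params, J, y, P, dt)
        f_end = rhs(0.0, yT, params, force)
        f0 = rhs(0.0, y, params, force)
        F = np.concatenate([yT - y, [0.0]])
        if np.linalg.norm(yT - y) < tol:
            return y, P, M
        Jac = np.zeros((n + 1, n + 1))
        Jac[:n, :n] = M - np.eye(n)
        Jac[:n, n] = f_end
        Jac[n, :n] = f0
        try:
            dz = np.linalg.solve(Jac, -F)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError("singular orbit-shooting Jacobian") from exc
        lam = 1.0
        y = y + lam * dz[:n]
        P = P + lam * dz[n]
        if P <= 0 or not np.all(np.isfinite(y)):
            raise RuntimeError("orbit shooting diverged")
    raise RuntimeError("periodic-orbit Newton did not converge")


# ---------------------------------------------------------------------------
# boundary location in h at fixed g


def _multiplier_tests(mult: np.ndarray) -> dict:
    real = mult[np.abs(mult.imag) < 1e-9].real
    cplx = mult[np.abs(mult.imag) >= 1e-9]
    return {
        "PD": float(real.min() + 1.0) if len(real) else np.inf,
        "FOLD": float(1.0 - real.max()) if len(real) else np.inf,
        "TORUS": float(1.0 - np.abs(cplx).max()) if len(cplx) else np.inf,
    }


def find_boundary(
    g: float,
    h_bracket: Tuple[float, float],
    spec: Optional[ForcingSpec],
    event_type: str,
    params_base: Optional[ModelParams] = None,
    J: float = 10.0,
    n_periods: int = 1,
    tol: float = 1e-6,
    settle_cycles: int = 120,
) -> float:
    """Bisection for the ``h`` at which a bifurcation test function crosses
    zero at fixed ``g``.

    Forced protocols use Floquet multipliers of the stroboscopic fixed point
    (PD: a real multiplier crossing -1; TORUS: a complex pair crossing the
    unit circle; FOLD: a real multiplier crossing +1).  ``spec=None`` handles
    the fixed-input equilibrium cases (HOPF: a complex eigenvalue pair's real
    part; PITCHFORK: symmetry-breaking eigenvalue of the antisymmetric block).
    """
    params_base = params_base or ModelParams()
    params_base = params_base.with_(g=g, gain_mode="smoothed")
    state_cache: dict = {}

    if spec is None:
        def test(h: float) -> float:
            p = params_base.with_(h=h)
            eqs = [e for e in find_equilibria(p, J, J) if e.symmetric]
            if not eqs:
                raise RuntimeError(f"no symmetric equilibrium at h={h}")
            e = eqs[0]
            if event_type == "HOPF":
                return _max_complex_re(e.eigenvalues)
            if event_type == "PITCHFORK":
                Jf = jacobian(e.state, p, J, J)
                _, anti = _exchange_blocks(Jf)
                return float(np.linalg.det(anti))
            raise ValueError(f"unsupported fixed-input event {event_type}")
    else:
        if event_type not in ("PD", "TORUS", "FOLD"):
            raise ValueError(f"unsupported forced event {event_type}")
        T = forcing_period_ms(spec)

        def test(h: float) -> float:
            p = params_base.with_(h=h)
            seed = state_cache.get("y")
            if seed is None:
                seed = advance(p, spec, default_ic(p, "perturbed_symmetric"),
                               settle_cycles * T, dt=commensurate_dt(spec))
            y, M = strobe_fixed_point(p, spec, seed, n_periods=n_periods)
            state_cache["y"] = y
            mult = np.linalg.eigvals(M)
            return _multiplier_tests(mult)[event_type]

    a, b = float(h_bracket[0]), float(h_bracket[1])
    if spec is not None:
        # seed the shooting from the stable (large-h) side and walk the fixed
        # point down the bracket so Newton tracks one branch throughout
        fb = test(b)
        for h_walk in np.linspace(b, a, 6)[1:-1]:
            try:
                test(float(h_walk))
            except RuntimeError:
                break
        fa = test(a)
    else:
        fa, fb = test(a), test(b)
    if not np.isfinite(fa) or not np.isfinite(fb) or fa * fb > 0:
        raise ValueError(
            f"test function does not change sign over bracket ({a}, {b}): "
            f"f(a)={fa:.3e}, f(b)={fb:.3e}"
        )
    while b - a > tol:
        m = 0.5 * (a + b)
        fm = test(m)
        if fa * fm <= 0:
            b, fb = m, fm
        else:
            a, fa = m, fm
    return 0.5 * (a + b)


# ---------------------------------------------------------------------------
# one-parameter sweeps and two-parameter maps


def sweep_diagram(
    g: float,
    h_grid: Sequence[float],
    spec: Optional[ForcingSpec] = None,
    params_base: Optional[ModelParams] = None,
    J: float = 10.0,
    direction: str = "up",
    classify_kwargs: Optional[dict] = None,
) -> List[Tuple[float, RegimeLabel]]:
    """Classification sweep along ``h`` with initial-condition inheritance.

    ``direction`` is "up", "down" or "both"; with "both" the result is a list
    of (h, label_up, label_down) and disagreements expose coexisting
    attractors (hysteresis).
    """
    params_base = params_base or ModelParams()
    params_base = params_base.with_(g=g)
    h_grid = list(h_grid)
    kw = dict(classify_kwargs or {})

    def one_direction(hs: Sequence[float]) -> List[Tuple[float, RegimeLabel]]:
        out = []
        ic = None
        for h in hs:
            p = params_base.with_(h=h)
            if spec is None:
                lab = classify_fixed(p, J, ic=ic, **kw)
            else:
                lab = classify_forced(p, spec, ic=ic, **kw)
            ic = lab.evidence.get("final_state")
            if ic is None:
                ic = _settle_final(p, spec, J, prev=out[-1][1] if out else None)
            out.append((h, lab))
        return out

    if direction == "up":
        return one_direction(h_grid)
    if direction == "down":
        return one_direction(h_grid[::-1])[::-1]
    if direction == "both":
        up = one_direction(h_grid)
        down = one_direction(h_grid[::-1])[::-1]
        return [(h, u, d) for (h, u), (_, d) in zip(up, down)]
    raise ValueError(f"unknown direction {direction!r}")


def _settle_final(p: ModelParams, spec: Optional[ForcingSpec], J: float,
                  prev=None) -> np.ndarray:
    s = spec or ForcingSpec(protocol="fixed", J_max=J)
    dt = commensurate_dt(s) if s.is_periodic else 0.1
    return advance(p, s, default_ic(p), 20_000.0, dt=dt)


@dataclass
class RegimeMap:
    g_grid: np.ndarray
    h_grid: np.ndarray
    labels: list                      # labels[i][j] = RegimeLabel at (g_i, h_j)
    boundaries: List[Tuple[str, float, float]] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        rows = []
        for i, g in enumerate(self.g_grid):
            for j, h in enumerate(self.h_grid):
                lab = self.labels[i][j]
                rows.append({
                    "g": g, "h": h, "label": lab.label,
                    "period_ms": lab.period_ms,
                    "lyapunov_per_ms": lab.lyapunov,
                    "skip_cycles": lab.skip_cycles,
                })
        return pd.DataFrame(rows)

    def boundary_frame(self):
        import pandas as pd

        return pd.DataFrame(self.boundaries, columns=["type", "g", "h_star"])


def regime_map(
    g_grid: Sequence[float],
    h_grid: Sequence[float],
    spec: Optional[ForcingSpec] = None,
    params_base: Optional[ModelParams] = None,
    J: float = 10.0,
    refine_boundaries: bool = False,
    classify_kwargs: Optional[dict] = None,
) -> RegimeMap:
    """Per-cell classification over a (g, h) grid with column-wise IC
    inheritance; label changes along ``h`` are optionally refined by
    bisection on the classification flip."""
    g_grid = np.asarray(list(g_grid), dtype=float)
    h_grid = np.asarray(list(h_grid), dtype=float)
    if np.any(np.diff(g_grid) <= 0) or np.any(np.diff(h_grid) <= 0):
        raise ValueError("grids must be strictly increasing")
    labels = []
    boundaries: List[Tuple[str, float, float]] = []
    for g in g_grid:
        row = sweep_diagram(g, h_grid, spec=spec, params_base=params_base, J=J,
                            direction="up", classify_kwargs=classify_kwargs)
        labels.append([lab for _, lab in row])
        if refine_boundaries:
            for (h1, l1), (h2, l2) in zip(row[:-1], row[1:]):
                if l1.label != l2.label:
                    h_star = _refine_label_flip(g, h1, h2, spec, params_base, J,
                                                classify_kwargs)
                    boundaries.append((f"{l1.label}->{l2.label}", float(g), h_star))
    return RegimeMap(g_grid=g_grid, h_grid=h_grid, labels=labels,
                     boundaries=boundaries)


def _refine_label_flip(g, h1, h2, spec, params_base, J, classify_kwargs,
                       n_iter: int = 8) -> float:
    params_base = params_base or ModelParams()
    kw = dict(classify_kwargs or {})
    p1 = params_base.with_(g=g, h=h1)
    lab1 = (classify_fixed(p1, J, **kw) if spec is None
            else classify_forced(p1, spec, **kw)).label
    a, b = h1, h2
    for _ in range(n_iter):
        m = 0.5 * (a + b)
        pm = params_base.with_(g=g, h=m)
        lm = (classify_fixed(pm, J, **kw) if spec is None
              else classify_forced(pm, spec, **kw)).label
        if lm == lab1:
            a = m
        else:
            b = m
    return 0.5 * (a + b)


# ---------------------------------------------------------------------------
# critical-h (period blow-up accumulation point)


def _attractor_period(
    params: ModelParams,
    J: float,
    ic: np.ndarray,
    period_cap: float,
    t_transient: float = 30_000.0,
    t_record_max: float = 300_000.0,
) -> Tuple[Optional[float], float, np.ndarray]:
    """(period or None, peak-to-trough amplitude, final state); the record is
    extended adaptively until three recurrences fit or the cap is reached."""
    spec = ForcingSpec(protocol="fixed", J_max=J)
    t_rec = 60_000.0
    y = advance(params, spec, ic, t_transient)
    while True:
        traj = settle(params, spec, y, t_transient=1.0, t_record=t_rec,
                      record_stride=10)
        amp = float((traj.E.max(axis=0) - traj.E.min(axis=0)).max())
        if amp < 1e-4:  # equilibrium
            return None, amp, traj.states[-1]
        per = estimate_period(traj)
        if per is not None and t_rec >= 3.2 * per:
            return per, amp, traj.states[-1]
        if per is not None and per > period_cap:
            return per, amp, traj.states[-1]
        if t_rec >= t_record_max:
            return per, amp, traj.states[-1]
        t_rec = min(t_rec * 2.0, t_record_max)


def find_critical_h(
    g: float,
    h_bracket: Tuple[float, float],
    J: float = 10.0,
    params_base: Optional[ModelParams] = None,
    period_cap: float = 60_000.0,
    tol: float = 2e-5,
    amp_split: float = 20.0,
) -> Tuple[float, float]:
    """Accumulation point of the oscillation-period blow-up at fixed ``g``.

    Marches toward the blow-up from both flanks of ``h_bracket`` with
    adaptive steps and initial-condition inheritance.  From below the tracked
    attractor is the small-amplitude (LAWTA / period-doubled) family; from
    above the large-amplitude (rivalry / mixed-mode) family; a step is
    rejected (and halved) when the period exceeds ``period_cap``, no
    recurrence is found, or the attractor jumps to the other amplitude family.
    Returns (h_critical, bracket width).
    """
    params_base = params_base or ModelParams()
    p = params_base.with_(g=g)
    lo, hi = float(h_bracket[0]), float(h_bracket[1])

    def acceptable(per: Optional[float], amp: float, want_low_amp: bool) -> bool:
        if (amp < amp_split) != want_low_amp:
            return False  # jumped to the other amplitude family
        if amp < 1e-4:
            return want_low_amp  # equilibrium precedes the low-amplitude cycles
        return per is not None and per <= period_cap

    def march(h_start: float, h_limit: float, sign: float, want_low_amp: bool) -> float:
        h = h_start
        per, amp, y = _attractor_period(p.with_(h=h), J, default_ic(p), period_cap)
        if not acceptable(per, amp, want_low_amp):
            raise RuntimeError(
                f"starting point h={h} is not on the expected attractor family")
        step = abs(h_limit - h_start) / 8.0
        while step > tol / 4.0:
            h_try = h + sign * step
            if (sign > 0 and h_try > h_limit) or (sign < 0 and h_try < h_limit):
                step *= 0.5
                continue
            per_t, amp_t, y_t = _attractor_period(p.with_(h=h_try), J, y, period_cap)
            if not acceptable(per_t, amp_t, want_low_amp):
                # discriminate genuine blow-up from a slow transient after a
                # branch jump: retry once with a longer settle
                per_t, amp_t, y_t = _attractor_period(
                    p.with_(h=h_try), J, y_t, period_cap, t_transient=90_000.0)
            if acceptable(per_t, amp_t, want_low_amp):
                h, y = h_try, y_t
            else:
                step *= 0.5
        return h

    h_lo = march(lo, hi, +1.0, want_low_amp=True)
    h_hi = march(hi, lo, -1.0, want_low_amp=False)
    if h_hi < h_lo:  # flanks crossed: blow-up zone thinner than tol
        h_lo, h_hi = h_hi, h_lo
    return 0.5 * (h_lo + h_hi), (h_hi - h_lo)
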