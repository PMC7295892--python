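"""Wilson monocular-subunit rivalry model: vector field, gain, equilibria.

Two excitatory populations (driven by the horizontal-left and vertical-right
gratings) compete through cross-inhibition ``g`` while spike-frequency
adaptation ``h`` provides slow negative feedback.  Each population carries
three variables: firing rate ``E`` (spikes/s), adaptation ``H`` and the
inhibitory rate ``I`` that it projects to its competitor.  The steady-state
rate is a Naka--Rushton function of the rectified net drive ``(J - g I)_+``.

State layout used throughout the package::

    full model    y = (E1, H1, I1, E2, H2, I2)
    reduced model y = (E1, H1, E2, H2)        # instantaneous inhibition, I_i = E_i

Time is in milliseconds everywhere internally; frequencies are accepted in Hz
at the interfaces and converted once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, replace
from typing import Callable, List, Tuple

import numpy as np

__all__ = [
    "ModelParams",
    "Equilibrium",
    "gain",
    "dgain",
    "asymptotic_rate",
    "rhs",
    "jacobian",
    "find_equilibria",
    "state_dim",
    "lift_rates",
    "swap_populations",
]

MAX_RATE = 100.0       # asymptotic rate ceiling (spikes/s)
SEMI_SAT = 10.0        # Naka-Rushton semi-saturation offset

#: kink tolerance below which the hard-rectified gain is non-differentiable
_HARD_KINK_TOL = 1e-9


@dataclass(frozen=True)
class ModelParams:
    """All constants of the rivalry subunit model.

    Parameters
    ----------
    tau_E, tau_H, tau_I : float
        Time constants (ms) of the rate, adaptation and inhibition variables.
    g : float
        Cross-inhibition strength (dimensionless).
    h : float
        Spike-frequency-adaptation strength (dimensionless).
    max_rate, semi_sat : float
        Naka-Rushton ceiling (spikes/s) and semi-saturation offset.
    gain_mode : str
        ``"smoothed"`` uses the sigmoid-smoothed rectifier
        ``R(x) = x / (1 + exp(-k (x - theta)))`` clamped at zero (required for
        continuation, Floquet and Lyapunov work); ``"hard_rectify"`` uses
        ``max(x, 0)``.
    k_gain, theta_gain : float
        Slope and threshold of the smoothing sigmoid.
    epsilon : float
        Small symmetry-breaking offset added to population 1's semi-saturation
        denominator (0 by default; 0.001 for torus-continuation workflows).
    instantaneous_inhibition : bool
        If True, inhibition is slaved (``I_i = E_i``) and the state is 4-D.
    """

    tau_E: float = 20.0
    tau_H: float = 900.0
    tau_I: float = 11.0
    g: float = 1.5
    h: float = 1.0
    max_rate: float = MAX_RATE
    semi_sat: float = SEMI_SAT
    gain_mode: str = "smoothed"
    k_gain: float = 30.0
    theta_gain: float = 0.05
    epsilon: float = 0.0
    instantaneous_inhibition: bool = False

    def __post_init__(self) -> None:
        if min(self.tau_E, self.tau_H, self.tau_I) <= 0:
            raise ValueError("all time constants must be positive")
        if self.g < 0 or self.h < 0 or self.epsilon < 0:
            raise ValueError("g, h and epsilon must be non-negative")
        if self.k_gain <= 0:
            raise ValueError("k_gain must be positive")
        if self.gain_mode not in ("smoothed", "hard_rectify"):
            raise ValueError(f"unknown gain_mode {self.gain_mode!r}")

    # -- config round trip -------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(**d)

    def with_(self, **kw) -> "ModelParams":
        return replace(self, **kw)

    @property
    def n_state(self) -> int:
        return 4 if self.instantaneous_inhibition else 6


def state_dim(params: ModelParams) -> int:
    return params.n_state


def gain(x: float, params: ModelParams) -> float:
    """Gain nonlinearity applied to the net drive ``x = J - g I``.

    Hard mode is the positive part ``(x)_+``; smoothed mode multiplies by a
    steep sigmoid and clamps the (machine-tiny) negative leak at zero.
    """
    if params.gain_mode == "hard_rectify":
        return x if x > 0.0 else 0.0
    a = -params.k_gain * (x - params.theta_gain)
    if a > 700.0:  # sigmoid underflows; x * sigma -> 0 from below
        return 0.0
    p = x / (1.0 + math.exp(a))
    return p if p > 0.0 else 0.0


def dgain(x: float, params: ModelParams) -> float:
    """Derivative of :func:`gain` with respect to the net drive.

    Raises at the hard-rectification kink where the derivative is undefined.
    """
    if params.gain_mode == "hard_rectify":
        if abs(x) < _HARD_KINK_TOL:
            raise ValueError("hard-rectified gain is not differentiable at the kink")
        return 1.0 if x > 0.0 else 0.0
    if x <= 0.0:  # clamped region
        return 0.0
    a = -params.k_gain * (x - params.theta_gain)
    s = 1.0 / (1.0 + math.exp(a)) if a <= 700.0 else 0.0
    return s * (1.0 + params.k_gain * x * (1.0 - s))


def asymptotic_rate(P: float, H: float, params: ModelParams, population: int = 2) -> float:
    """Naka-Rushton steady-state rate ``r_max P^2 / ((sigma + H [+ eps])^2 + P^2)``.

    ``population=1`` adds the symmetry-breaking ``epsilon`` to the
    semi-saturation denominator.
    """
    eps = params.epsilon if population == 1 else 0.0
    den = (params.semi_sat + H + eps) ** 2 + P * P
    if den == 0.0:
        return 0.0
    return params.max_rate * P * P / den


def _rate_partials(P: float, H: float, params: ModelParams, population: int) -> Tuple[float, float]:
    """(d rate / dP, d rate / dH) of the Naka-Rushton function."""
    eps = params.epsilon if population == 1 else 0.0
    sig = params.semi_sat + H + eps
    den = sig * sig + P * P
    dP = 2.0 * params.max_rate * P * sig * sig / (den * den)
    dH = -2.0 * params.max_rate * P * P * sig / (den * den)
    return dP, dH


def rhs(
    t: float,
    state: np.ndarray,
    params: ModelParams,
    forcing_eval: Callable[[float], Tuple[float, float]],
) -> np.ndarray:
    """Time derivative of the state under inputs ``(J1, J2) = forcing_eval(t)``.

    Reference (pure-Python) definition; the integration kernels reimplement it
    and are tested against this function.
    """
    state = np.asarray(state, dtype=float)
    if not np.all(np.isfinite(state)):
        raise FloatingPointError("non-finite state passed to rhs (integration blow-up?)")
    J1, J2 = forcing_eval(t)
    d = np.empty_like(state)
    if params.instantaneous_inhibition:
        E1, H1, E2, H2 = state
        I1, I2 = E1, E2
    else:
        E1, H1, I1, E2, H2, I2 = state
    P1 = gain(J1 - params.g * I2, params)
    P2 = gain(J2 - params.g * I1, params)
    r1 = asymptotic_rate(P1, H1, params, population=1)
    r2 = asymptotic_rate(P2, H2, params, population=2)
    if params.instantaneous_inhibition:
        d[0] = (-E1 + r1) / params.tau_E
        d[1] = (-H1 + params.h * E1) / params.tau_H
        d[2] = (-E2 + r2) / params.tau_E
        d[3] = (-H2 + params.h * E2) / params.tau_H
    else:
        d[0] = (-E1 + r1) / params.tau_E
        d[1] = (-H1 + params.h * E1) / params.tau_H
        d[2] = (-I1 + E1) / params.tau_I
        d[3] = (-E2 + r2) / params.tau_E
        d[4] = (-H2 + params.h * E2) / params.tau_H
        d[5] = (-I2 + E2) / params.tau_I
    return d


def jacobian(state: np.ndarray, params: ModelParams, J1: float, J2: float) -> np.ndarray:
    """Analytic Jacobian of :func:`rhs` at ``state`` with frozen inputs.

    Smoothed gain only away from hard kinks; in hard mode the call errors if
    either net drive sits at the rectification kink.
    """
    state = np.asarray(state, dtype=float)
    if params.instantaneous_inhibition:
        E1, H1, E2, H2 = state
        I1, I2 = E1, E2
    else:
        E1, H1, I1, E2, H2, I2 = state
    x1 = J1 - params.g * I2
    x2 = J2 - params.g * I1
    P1, P2 = gain(x1, params), gain(x2, params)
    dP1, dP2 = dgain(x1, params), dgain(x2, params)
    r1P, r1H = _rate_partials(P1, H1, params, population=1)
    r2P, r2H = _rate_partials(P2, H2, params, population=2)
    tE, tH, tI = params.tau_E, params.tau_H, params.tau_I
    g_ = params.g
    if params.instantaneous_inhibition:
        J = np.zeros((4, 4))
        J[0, 0] = -1.0 / tE
        J[0, 1] = r1H / tE
        J[0, 2] = -g_ * r1P * dP1 / tE
        J[1, 0] = params.h / tH
        J[1, 1] = -1.0 / tH
        J[2, 0] = -g_ * r2P * dP2 / tE
        J[2, 2] = -1.0 / tE
        J[2, 3] = r2H / tE
        J[3, 2] = params.h / tH
        J[3, 3] = -1.0 / tH
        return J
    J = np.zeros((6, 6))
    J[0, 0] = -1.0 / tE
    J[0, 1] = r1H / tE
    J[0, 5] = -g_ * r1P * dP1 / tE
    J[1, 0] = params.h / tH
    J[1, 1] = -1.0 / tH
    J[2, 0] = 1.0 / tI
    J[2, 2] = -1.0 / tI
    J[3, 3] = -1.0 / tE
    J[3, 4] = r2H / tE
    J[3, 2] = -g_ * r2P * dP2 / tE
    J[4, 3] = params.h / tH
    J[4, 4] = -1.0 / tH
    J[5, 3] = 1.0 / tI
    J[5, 5] = -1.0 / tI
    return J


# ---------------------------------------------------------------------------
# equilibria


@dataclass(frozen=True)
class Equilibrium:
    """A fixed point with its linearization."""

    state: np.ndarray
    eigenvalues: np.ndarray
    stable: bool

    @property
    def E(self) -> Tuple[float, float]:
        s = self.state
        return (s[0], s[3]) if s.size == 6 else (s[0], s[2])

    @property
    def symmetric(self) -> bool:
        e1, e2 = self.E
        return abs(e1 - e2) < 1e-6


def lift_rates(E1: float, E2: float, params: ModelParams) -> np.ndarray:
    """Lift rates to a full state using the equilibrium slaving H=hE, I=E."""
    h = params.h
    if params.instantaneous_inhibition:
        return np.array([E1, h * E1, E2, h * E2])
    return np.array([E1, h * E1, E1, E2, h * E2, E2])


def _reduced_residual(E: np.ndarray, params: ModelParams, J1: float, J2: float) -> np.ndarray:
    """Equilibrium residual on (E1, E2) after slaving H = hE, I = E."""
    E1, E2 = E
    P1 = gain(J1 - params.g * E2, params)
    P2 = gain(J2 - params.g * E1, params)
    return np.array(
        [
            -E1 + asymptotic_rate(P1, params.h * E1, params, population=1),
            -E2 + asymptotic_rate(P2, params.h * E2, params, population=2),
        ]
    )


def _reduced_jacobian(E: np.ndarray, params: ModelParams, J1: float, J2: float) -> np.ndarray:
    E1, E2 = E
    x1 = J1 - params.g * E2
    x2 = J2 - params.g * E1
    P1, P2 = gain(x1, params), gain(x2, params)
    r1P, r1H = _rate_partials(P1, params.h * E1, params, population=1)
    r2P, r2H = _rate_partials(P2, params.h * E2, params, population=2)
    return np.array(
        [
            [-1.0 + r1H * params.h, -params.g * r1P * dgain(x1, params)],
            [-params.g * r2P * dgain(x2, params), -1.0 + r2H * params.h],
        ]
    )


def solve_equilibrium(
    seed: Tuple[float, float],
    params: ModelParams,
    J1: float,
    J2: float,
    tol: float = 1e-10,
    max_iter: int = 50,
) -> np.ndarray | None:
    """Damped Newton on the reduced (E1, E2) equilibrium system.

    Returns the converged ``(E1, E2)`` pair or None.
    """
    E = np.array(seed, dtype=float)
    for _ in range(max_iter):
        F = _reduced_residual(E, params, J1, J2)
        if np.linalg.norm(F) < tol:
            return E
        try:
            step = np.linalg.solve(_reduced_jacobian(E, params, J1, J2), F)
        except np.linalg.LinAlgError:
            return None
        lam, base = 1.0, np.linalg.norm(F)
        for _ in range(8):  # backtracking damping
            Enew = E - lam * step
            if np.linalg.norm(_reduced_residual(Enew, params, J1, J2)) < base:
                E = Enew
                break
            lam *= 0.5
        else:
            E = E - lam * step
        if not np.all(np.isfinite(E)):
            return None
    F = _reduced_residual(E, params, J1, J2)
    return E if np.linalg.norm(F) < tol else None


#: deterministic seed grid covering the five-branch equilibrium structure
_SEED_RATES = (0.0, 5.0, 25.0, 50.0, 75.0, 95.0)


def find_equilibria(
    params: ModelParams,
    J1: float,
    J2: float,
    dedupe_tol: float = 1e-6,
) -> List[Equilibrium]:
    """All equilibria of the model at fixed inputs, with stability.

    Symmetric inputs get a bracketed scalar root scan along the diagonal
    ``E1 = E2`` (guaranteed to find the symmetric solutions); asymmetric
    equilibria come from damped Newton over a deterministic seed grid.
    Duplicates within ``dedupe_tol`` are merged.
    """
    found: List[np.ndarray] = []

    def _push(E: np.ndarray | None) -> None:
        if E is None or not np.all(np.isfinite(E)):
            return
        if np.any(E < -1e-6) or np.any(E > params.max_rate):
            return
        for prev in found:
            if np.linalg.norm(prev - E) < dedupe_tol:
                return
        found.append(E)

    if J1 == J2 and params.epsilon == 0.0:
        # scalar fixed-point scan on the diagonal
        grid = np.linspace(0.0, params.max_rate, 2001)
        vals = np.array(
            [_reduced_residual(np.array([e, e]), params, J1, J2)[0] for e in grid]
        )
        from scipy.optimize import brentq

        for i in range(len(grid) - 1):
            if vals[i] == 0.0:
                _push(np.array([grid[i], grid[i]]))
            elif vals[i] * vals[i + 1] < 0:
                e = brentq(
                    lambda e: _reduced_residual(np.array([e, e]), params, J1, J2)[0],
                    grid[i],
                    grid[i + 1],
                    xtol=1e-12,
                )
                _push(np.array([e, e]))

    for s1 in _SEED_RATES:
        for s2 in _SEED_RATES:
            _push(solve_equilibrium((s1, s2), params, J1, J2))

    out: List[Equilibrium] = []
    for E in sorted(found, key=lambda e: (round(e[0], 8), round(e[1], 8))):
        st = lift_rates(E[0], E[1], params)
        eig = np.linalg.eigvals(jacobian(st, params, J1, J2))
        out.append(Equilibrium(state=st, eigenvalues=eig, stable=bool(np.max(eig.real) < 0)))
    return out


def swap_populations(state: np.ndarray) -> np.ndarray:
    """Exchange the two populations' variables (the model's Z2 symmetry)."""
    state = np.asarray(state)
    n = state.shape[-1]
    half = n // 2
    return np.concatenate([state[..., half:], state[..., :half]], axis=-1)
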