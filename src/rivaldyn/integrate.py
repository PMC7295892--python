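"""Fixed-step RK4 integration, transient handling and stroboscopic sampling.

The integrator is classic RK4 with forcing evaluated in closed form at the
substage times.  The default step is 0.1 ms; for stroboscopic work on forced
protocols the step is adjusted per run to ``T / ceil(T / dt)`` so that an
integer number of steps spans one forcing period exactly (the adjustment is
recorded in the trajectory metadata).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
import numpy as np
import pandas as pd

from . import _kernels as K
from .forcing import ForcingSpec, forcing_period_ms
from .model import ModelParams

__all__ = [
    "Trajectory",
    "commensurate_dt",
    "integrate",
    "settle",
    "stroboscope",
    "default_ic",
]

DEFAULT_DT = 0.1  # ms


@dataclass
class Trajectory:
    """Uniformly sampled state history with the forcing samples alongside."""

    t: np.ndarray
    states: np.ndarray
    forcing: np.ndarray
    dt: float           # integration step (ms); samples are spaced dt*stride
    stride: int
    params: ModelParams
    spec: ForcingSpec

    def __post_init__(self) -> None:
        if len(self.t) < 2:
            raise ValueError("trajectory must hold at least two samples")
        if not (np.all(np.isfinite(self.t)) and np.all(np.isfinite(self.states))):
            raise ValueError("non-finite entries in trajectory")

    @property
    def sample_dt(self) -> float:
        return self.dt * self.stride

    @property
    def E(self) -> np.ndarray:
        """(n, 2) firing rates of the two populations."""
        if self.params.instantaneous_inhibition:
            return self.states[:, [0, 2]]
        return self.states[:, [0, 3]]

    # -- CSV round trip -----------------------------------------------------
    _FULL_COLS = ["t_ms", "E1", "H1", "I1", "E2", "H2", "I2", "J_HL", "J_VR"]
    _RED_COLS = ["t_ms", "E1", "H1", "E2", "H2", "J_HL", "J_VR"]

    def to_frame(self) -> pd.DataFrame:
        cols = self._RED_COLS if self.params.instantaneous_inhibition else self._FULL_COLS
        data = np.column_stack([self.t, self.states, self.forcing])
        return pd.DataFrame(data, columns=cols)

    def write_csv(self, path) -> None:
        # repr-roundtrip precision so the reader reproduces the arrays exactly
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def read_csv(cls, path, params: ModelParams, spec: ForcingSpec) -> "Trajectory":
        df = pd.read_csv(path, float_precision="round_trip")
        t = df["t_ms"].to_numpy()
        nstate = 4 if params.instantaneous_inhibition else 6
        states = df.iloc[:, 1 : 1 + nstate].to_numpy()
        forcing = df.iloc[:, 1 + nstate :].to_numpy()
        dts = np.diff(t)
        return cls(
            t=t, states=states, forcing=forcing,
            dt=float(dts[0]), stride=1, params=params, spec=spec,
        )


def default_ic(params: ModelParams, kind: str = "asymmetric") -> np.ndarray:
    """Deterministic initial conditions.

    ``asymmetric``: population 1 active (E1=40), population 2 silent —
    strongly off the symmetry plane.  ``symmetric``: both at E=20 with the
    slow variables slaved.  ``perturbed_symmetric``: symmetric plus 1e-3 on E1.
    """
    from .model import lift_rates

    if kind == "asymmetric":
        return lift_rates(40.0, 0.0, params)
    if kind == "symmetric":
        return lift_rates(20.0, 20.0, params)
    if kind == "perturbed_symmetric":
        ic = lift_rates(20.0, 20.0, params)
        ic[0] += 1e-3
        return ic
    raise ValueError(f"unknown IC kind {kind!r}")


def commensurate_dt(spec: ForcingSpec, dt: float = DEFAULT_DT) -> float:
    """Largest step <= dt such that an integer number of steps spans the
    forcing period exactly."""
    T = forcing_period_ms(spec)
    return T / math.ceil(T / dt)


def _run(params, spec, ic, t0, n_steps, dt, stride) -> Trajectory:
    mp = K.pack_model(params)
    code, fp = K.pack_forcing(spec)
    ic = np.asarray(ic, dtype=float)
    if ic.shape != (params.n_state,):
        raise ValueError(f"IC must have shape ({params.n_state},)")
    ts, ys, js, blowup = K.rk4_record(ic, t0, dt, n_steps, stride, mp, code, fp)
    if not math.isnan(blowup):
        raise FloatingPointError(f"integration blew up at t = {blowup:.3f} ms")
    return Trajectory(t=ts, states=ys, forcing=js, dt=dt, stride=stride,
                      params=params, spec=spec)


def integrate(
    params: ModelParams,
    spec: ForcingSpec,
    ic: np.ndarray,
    t_end: float,
    dt: float = DEFAULT_DT,
    record_stride: int = 1,
    t0: float = 0.0,
) -> Trajectory:
    """Integrate from ``t0`` to ``t0 + t_end`` (ms) and record the history."""
    if dt <= 0 or t_end < dt:
        raise ValueError("need dt > 0 and t_end >= dt")
    n_steps = int(round(t_end / dt))
    return _run(params, spec, ic, t0, n_steps, dt, record_stride)


def advance(
    params: ModelParams,
    spec: ForcingSpec,
    ic: np.ndarray,
    t_span: float,
    dt: float = DEFAULT_DT,
    t0: float = 0.0,
) -> np.ndarray:
    """Final state after ``t_span`` ms (no recording)."""
    mp = K.pack_model(params)
    code, fp = K.pack_forcing(spec)
    n_steps = int(round(t_span / dt))
    y = K.rk4_final(np.asarray(ic, dtype=float), t0, dt, n_steps, mp, code, fp)
    if not np.all(np.isfinite(y)):
        raise FloatingPointError("integration blew up during transient")
    return y


def settle(
    params: ModelParams,
    spec: ForcingSpec,
    ic: np.ndarray,
    t_transient: float = 20_000.0,
    t_record: float = 40_000.0,
    dt: float = DEFAULT_DT,
    record_stride: int = 10,
) -> Trajectory:
    """Discard ``t_transient`` ms, then record ``t_record`` ms rebased to 0.

    For periodic protocols the step is made commensurate with the forcing
    period and the transient is rounded up to a whole number of periods so the
    recorded segment starts at the protocol's zero phase.
    """
    if t_transient <= 0 or t_record <= 0:
        raise ValueError("t_transient and t_record must be positive")
    if spec.is_periodic:
        T = forcing_period_ms(spec)
        if t_record < T:
            raise ValueError("t_record must cover at least one forcing period")
        dt = commensurate_dt(spec, dt)
        t_transient = T * math.ceil(t_transient / T)
    y = advance(params, spec, ic, t_transient, dt=dt) if t_transient > 0 else np.asarray(ic, float)
    # record with time rebased to 0; the forcing phase is t_transient mod period = 0
    traj = _run(params, spec, y,
                t0=t_transient if spec.is_periodic else 0.0,
                n_steps=int(round(t_record / dt)), dt=dt, stride=record_stride)
    traj.t = traj.t - traj.t[0]
    return traj


def stroboscope(
    params: ModelParams,
    spec: ForcingSpec,
    ic: np.ndarray,
    n_periods: int,
    dt: float = DEFAULT_DT,
    t0: float = 0.0,
) -> np.ndarray:
    """States sampled once per forcing period starting at ``ic`` (included).

    Returns an ``(n_periods + 1, n_state)`` array.  The step is adjusted to be
    commensurate with the forcing period.
    """
    if not spec.is_periodic:
        raise ValueError("stroboscopic sampling requires a periodic protocol")
    T = forcing_period_ms(spec)
    dt = commensurate_dt(spec, dt)
    steps_per_period = int(round(T / dt))
    if abs(steps_per_period * dt - T) > 1e-9 * T:
        raise ValueError("dt is not commensurate with the forcing period")
    mp = K.pack_model(params)
    code, fp = K.pack_forcing(spec)
    y = np.asarray(ic, dtype=float).copy()
    out = np.empty((n_periods + 1, y.size))
    out[0] = y
    for n in range(n_periods):
        y = K.rk4_final(y, t0 + n * T, dt, steps_per_period, mp, code, fp)
        out[n + 1] = y
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("stroboscopic integration blew up")
    return out


def strobe_map(
    params: ModelParams,
    spec: ForcingSpec,
    y: np.ndarray,
    dt: float = DEFAULT_DT,
    n_periods: int = 1,
    phase_t0: float = 0.0,
) -> np.ndarray:
    """One application of the period-``n_periods`` stroboscopic map."""
    return stroboscope(params, spec, y, n_periods, dt=dt, t0=phase_t0)[-1]
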