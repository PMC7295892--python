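"""Compiled (numba) inner loops: RK4 stepping, variational flow, Benettin LE.

The pure-Python definitions in :mod:`rivaldyn.model` and
:mod:`rivaldyn.forcing` are the reference; these kernels reimplement them for
speed and are cross-checked against the reference in the test suite.

Parameter packing
-----------------
model params ``mp`` (float64[10])::

    0 tau_E   1 tau_H   2 tau_I   3 g   4 h   5 epsilon
    6 gain_mode (0 hard, 1 smoothed)   7 k_gain   8 theta_gain
    9 reduced (0 full 6-D, 1 instantaneous-inhibition 4-D)

forcing ``code``: 0 fixed, 1 swap, 2 flicker, 3 F&S, 4 B&S, 5 F&S raw product
forcing params ``fp`` (float64[5])::

    0 f_s (Hz)   1 flicker_multiple   2 k_square   3 J_max   4 blank_ms
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .model import ModelParams
from .forcing import ForcingSpec

__all__ = [
    "pack_model",
    "pack_forcing",
    "rk4_record",
    "rk4_final",
    "rk4_monodromy",
    "rk4_benettin",
]

_TWO_PI_OVER_1000 = 2.0 * math.pi / 1000.0


def pack_model(params: ModelParams) -> np.ndarray:
    return np.array(
        [
            params.tau_E,
            params.tau_H,
            params.tau_I,
            params.g,
            params.h,
            params.epsilon,
            0.0 if params.gain_mode == "hard_rectify" else 1.0,
            params.k_gain,
            params.theta_gain,
            1.0 if params.instantaneous_inhibition else 0.0,
        ]
    )


_PROTO_CODE = {
    "fixed": 0,
    "swap": 1,
    "flicker": 2,
    "flicker_and_swap": 3,
    "blank_and_swap": 4,
}


def pack_forcing(spec: ForcingSpec) -> tuple[int, np.ndarray]:
    code = _PROTO_CODE[spec.protocol]
    if spec.protocol == "flicker_and_swap" and spec.raw_product:
        code = 5
    fp = np.array(
        [spec.f_s, float(spec.flicker_multiple), spec.k_square, spec.J_max, spec.blank_ms]
    )
    return code, fp


@njit(cache=True)
def _forcing(t, code, fp):
    if code == 0:
        return fp[3], fp[3]
    fs, mult, k, J, blank = fp[0], fp[1], fp[2], fp[3], fp[4]
    w = _TWO_PI_OVER_1000 * fs
    xs = math.sin(w * t)
    if code == 1:  # swap: the modelled subunit is stimulated in-phase
        v = J / (1.0 + math.exp(-k * xs))
        return v, v
    if code == 2:  # flicker
        xf = math.cos(mult * w * t)
        v = J / (1.0 + math.exp(-k * xf))
        return v, v
    if code == 3:  # flicker & swap, squared components then product
        xf = math.cos(mult * w * t)
        v = (
            J
            / (1.0 + math.exp(-k * xf))
            / (1.0 + math.exp(-k * xs))
        )
        return v, v
    if code == 4:  # blank & swap (smooth gate, slope 50 on the cosine carrier)
        gate = 1.0
        if blank > 0.0:
            half = 500.0 / fs
            tc = half - 0.5 * blank
            u = math.cos(2.0 * math.pi * (t - tc) / half)
            u0 = math.cos(math.pi * blank / half)
            gate = 1.0 - 1.0 / (1.0 + math.exp(-50.0 * (u - u0)))
        v = gate * J / (1.0 + math.exp(-k * xs))
        return v, v
    # code == 5: raw-product F&S
    xf = math.cos(mult * w * t)
    v = J / (1.0 + math.exp(-k * xf * xs))
    return v, v


@njit(cache=True, inline="always")
def _gain(x, mp):
    if mp[6] == 0.0:  # hard rectify
        return x if x > 0.0 else 0.0
    p = x / (1.0 + math.exp(-mp[7] * (x - mp[8])))
    return p if p > 0.0 else 0.0


@njit(cache=True, inline="always")
def _dgain(x, mp):
    if mp[6] == 0.0:
        return 1.0 if x > 0.0 else 0.0
    if x <= 0.0:
        return 0.0
    s = 1.0 / (1.0 + math.exp(-mp[7] * (x - mp[8])))
    return s * (1.0 + mp[7] * x * (1.0 - s))


@njit(cache=True)
def _rhs(t, y, mp, code, fp, dy):
    j1, j2 = _forcing(t, code, fp)
    tE, tH = mp[0], mp[1]
    g, h, eps = mp[3], mp[4], mp[5]
    if mp[9] == 1.0:  # reduced: y = (E1, H1, E2, H2), I_i = E_i
        E1, H1, E2, H2 = y[0], y[1], y[2], y[3]
        p1 = _gain(j1 - g * E2, mp)
        p2 = _gain(j2 - g * E1, mp)
        s1 = 10.0 + H1 + eps
        s2 = 10.0 + H2
        r1 = 100.0 * p1 * p1 / (s1 * s1 + p1 * p1)
        r2 = 100.0 * p2 * p2 / (s2 * s2 + p2 * p2)
        dy[0] = (-E1 + r1) / tE
        dy[1] = (-H1 + h * E1) / tH
        dy[2] = (-E2 + r2) / tE
        dy[3] = (-H2 + h * E2) / tH
    else:
        tI = mp[2]
        E1, H1, I1, E2, H2, I2 = y[0], y[1], y[2], y[3], y[4], y[5]
        p1 = _gain(j1 - g * I2, mp)
        p2 = _gain(j2 - g * I1, mp)
        s1 = 10.0 + H1 + eps
        s2 = 10.0 + H2
        r1 = 100.0 * p1 * p1 / (s1 * s1 + p1 * p1)
        r2 = 100.0 * p2 * p2 / (s2 * s2 + p2 * p2)
        dy[0] = (-E1 + r1) / tE
        dy[1] = (-H1 + h * E1) / tH
        dy[2] = (-I1 + E1) / tI
        dy[3] = (-E2 + r2) / tE
        dy[4] = (-H2 + h * E2) / tH
        dy[5] = (-I2 + E2) / tI


@njit(cache=True)
def _jac(t, y, mp, code, fp, J):
    """Analytic Jacobian of _rhs w.r.t. y (smoothed gain)."""
    j1, j2 = _forcing(t, code, fp)
    tE, tH = mp[0], mp[1]
    g, h, eps = mp[3], mp[4], mp[5]
    n = y.shape[0]
    for a in range(n):
        for b in range(n):
            J[a, b] = 0.0
    if mp[9] == 1.0:
        E1, H1, E2, H2 = y[0], y[1], y[2], y[3]
        x1 = j1 - g * E2
        x2 = j2 - g * E1
        p1, p2 = _gain(x1, mp), _gain(x2, mp)
        s1, s2 = 10.0 + H1 + eps, 10.0 + H2
        d1 = s1 * s1 + p1 * p1
        d2 = s2 * s2 + p2 * p2
        r1P = 200.0 * p1 * s1 * s1 / (d1 * d1)
        r1H = -200.0 * p1 * p1 * s1 / (d1 * d1)
        r2P = 200.0 * p2 * s2 * s2 / (d2 * d2)
        r2H = -200.0 * p2 * p2 * s2 / (d2 * d2)
        J[0, 0] = -1.0 / tE
        J[0, 1] = r1H / tE
        J[0, 2] = -g * r1P * _dgain(x1, mp) / tE
        J[1, 0] = h / tH
        J[1, 1] = -1.0 / tH
        J[2, 0] = -g * r2P * _dgain(x2, mp) / tE
        J[2, 2] = -1.0 / tE
        J[2, 3] = r2H / tE
        J[3, 2] = h / tH
        J[3, 3] = -1.0 / tH
    else:
        tI = mp[2]
        E1, H1, I1, E2, H2, I2 = y[0], y[1], y[2], y[3], y[4], y[5]
        x1 = j1 - g * I2
        x2 = j2 - g * I1
        p1, p2 = _gain(x1, mp), _gain(x2, mp)
        s1, s2 = 10.0 + H1 + eps, 10.0 + H2
        d1 = s1 * s1 + p1 * p1
        d2 = s2 * s2 + p2 * p2
        r1P = 200.0 * p1 * s1 * s1 / (d1 * d1)
        r1H = -200.0 * p1 * p1 * s1 / (d1 * d1)
        r2P = 200.0 * p2 * s2 * s2 / (d2 * d2)
        r2H = -200.0 * p2 * p2 * s2 / (d2 * d2)
        J[0, 0] = -1.0 / tE
        J[0, 1] = r1H / tE
        J[0, 5] = -g * r1P * _dgain(x1, mp) / tE
        J[1, 0] = h / tH
        J[1, 1] = -1.0 / tH
        J[2, 0] = 1.0 / tI
        J[2, 2] = -1.0 / tI
        J[3, 2] = -g * r2P * _dgain(x2, mp) / tE
        J[3, 3] = -1.0 / tE
        J[3, 4] = r2H / tE
        J[4, 3] = h / tH
        J[4, 4] = -1.0 / tH
        J[5, 3] = 1.0 / tI
        J[5, 5] = -1.0 / tI


@njit(cache=True)
def _rk4_step(t, y, dt, mp, code, fp, k1, k2, k3, k4, tmp):
    n = y.shape[0]
    _rhs(t, y, mp, code, fp, k1)
    for i in range(n):
        tmp[i] = y[i] + 0.5 * dt * k1[i]
    _rhs(t + 0.5 * dt, tmp, mp, code, fp, k2)
    for i in range(n):
        tmp[i] = y[i] + 0.5 * dt * k2[i]
    _rhs(t + 0.5 * dt, tmp, mp, code, fp, k3)
    for i in range(n):
        tmp[i] = y[i] + dt * k3[i]
    _rhs(t + dt, tmp, mp, code, fp, k4)
    for i in range(n):
        y[i] = y[i] + (dt / 6.0) * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])


@njit(cache=True)
def rk4_record(y0, t0, dt, n_steps, stride, mp, code, fp):
    """RK4 from t0 over n_steps, recording every ``stride``-th step.

    Returns (t, states, forcings, blowup_time); blowup_time is NaN unless a
    non-finite state appeared, in which case arrays are truncated garbage and
    the caller must raise.
    """
    n = y0.shape[0]
    n_rec = n_steps // stride + 1
    ts = np.empty(n_rec)
    ys = np.empty((n_rec, n))
    js = np.empty((n_rec, 2))
    y = y0.copy()
    k1 = np.empty(n)
    k2 = np.empty(n)
    k3 = np.empty(n)
    k4 = np.empty(n)
    tmp = np.empty(n)
    ts[0] = t0
    ys[0] = y
    j1, j2 = _forcing(t0, code, fp)
    js[0, 0] = j1
    js[0, 1] = j2
    idx = 1
    blowup = np.nan
    for s in range(n_steps):
        t = t0 + s * dt
        _rk4_step(t, y, dt, mp, code, fp, k1, k2, k3, k4, tmp)
        if (s + 1) % stride == 0:
            tr = t0 + (s + 1) * dt
            ok = True
            for i in range(n):
                if not np.isfinite(y[i]):
                    ok = False
            if not ok:
                blowup = tr
                break
            ts[idx] = tr
            ys[idx] = y
            j1, j2 = _forcing(tr, code, fp)
            js[idx, 0] = j1
            js[idx, 1] = j2
            idx += 1
    return ts[:idx], ys[:idx], js[:idx], blowup


@njit(cache=True)
def rk4_final(y0, t0, dt, n_steps, mp, code, fp):
    """RK4 returning only the final state (transients, stroboscopic maps)."""
    n = y0.shape[0]
    y = y0.copy()
    k1 = np.empty(n)
    k2 = np.empty(n)
    k3 = np.empty(n)
    k4 = np.empty(n)
    tmp = np.empty(n)
    for s in range(n_steps):
        _rk4_step(t0 + s * dt, y, dt, mp, code, fp, k1, k2, k3, k4, tmp)
    return y


@njit(cache=True)
def _aug_rhs(t, z, mp, code, fp, dz, Jw):
    """State + tangent-matrix flow: z = (y, vec(M)), M' = J(t, y) M."""
    n = Jw.shape[0]
    y = z[:n]
    _rhs(t, y, mp, code, fp, dz[:n])
    _jac(t, y, mp, code, fp, Jw)
    for col in range(z.shape[0] // n - 1):
        base = n + col * n
        for a in range(n):
            acc = 0.0
            for b in range(n):
                acc += Jw[a, b] * z[base + b]
            dz[base + a] = acc


@njit(cache=True)
def _rk4_step_aug(t, z, dt, mp, code, fp, k1, k2, k3, k4, tmp, Jw):
    m = z.shape[0]
    _aug_rhs(t, z, mp, code, fp, k1, Jw)
    for i in range(m):
        tmp[i] = z[i] + 0.5 * dt * k1[i]
    _aug_rhs(t + 0.5 * dt, tmp, mp, code, fp, k2, Jw)
    for i in range(m):
        tmp[i] = z[i] + 0.5 * dt * k2[i]
    _aug_rhs(t + 0.5 * dt, tmp, mp, code, fp, k3, Jw)
    for i in range(m):
        tmp[i] = z[i] + dt * k3[i]
    _aug_rhs(t + dt, tmp, mp, code, fp, k4, Jw)
    for i in range(m):
        z[i] = z[i] + (dt / 6.0) * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])


@njit(cache=True)
def rk4_monodromy(y0, t0, dt, n_steps, mp, code, fp):
    """Integrate state and full variational matrix from the identity.

    Returns (final state, monodromy matrix over the integrated window).
    """
    n = y0.shape[0]
    z = np.zeros(n + n * n)
    z[:n] = y0
    for i in range(n):
        z[n + i * n + i] = 1.0  # identity, column-major blocks
    k1 = np.empty(z.shape[0])
    k2 = np.empty(z.shape[0])
    k3 = np.empty(z.shape[0])
    k4 = np.empty(z.shape[0])
    tmp = np.empty(z.shape[0])
    Jw = np.empty((n, n))
    for s in range(n_steps):
        _rk4_step_aug(t0 + s * dt, z, dt, mp, code, fp, k1, k2, k3, k4, tmp, Jw)
    M = np.empty((n, n))
    for col in range(n):
        for a in range(n):
            M[a, col] = z[n + col * n + a]
    return z[:n], M


@njit(cache=True)
def rk4_benettin(y0, v0, t0, dt, n_steps, renorm_steps, mp, code, fp):
    """Benettin largest-Lyapunov-exponent accumulator.

    Integrates the state together with one tangent vector, renormalizing the
    tangent every ``renorm_steps`` steps.  Returns (final state, sum of log
    growth factors, number of renormalizations).
    """
    n = y0.shape[0]
    z = np.empty(2 * n)
    z[:n] = y0
    z[n:] = v0
    k1 = np.empty(2 * n)
    k2 = np.empty(2 * n)
    k3 = np.empty(2 * n)
    k4 = np.empty(2 * n)
    tmp = np.empty(2 * n)
    Jw = np.empty((n, n))
    sum_log = 0.0
    n_renorm = 0
    for s in range(n_steps):
        _rk4_step_aug(t0 + s * dt, z, dt, mp, code, fp, k1, k2, k3, k4, tmp, Jw)
        if (s + 1) % renorm_steps == 0:
            nv = 0.0
            for i in range(n):
                nv += z[n + i] * z[n + i]
            nv = math.sqrt(nv)
            sum_log += math.log(nv)
            for i in range(n):
                z[n + i] /= nv
            n_renorm += 1
    return z[:n], sum_log, n_renorm
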