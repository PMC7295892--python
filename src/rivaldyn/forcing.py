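"""Stimulus protocols for the rivalry subunit: fixed, swap, flicker, F&S, B&S.

All protocols are available in closed form (the default for simulation, no
phase drift) and, for the periodic ones, as an autonomous normal-form
oscillator pair that can be appended to the model ODEs.  The phase convention
is ``x_s(t) = sin(2 pi f_s t)`` with ``t = 0`` at a swap instant and
population 1 (HL) receiving the first half-cycle.

Protocols
---------
``fixed``
    Constant ``(J_max, J_max)``.
``swap``
    Antiphase smoothed square waves at the swap frequency ``f_s``: the
    stimulus is on for one population while off for the other, swapping each
    half-period.
``flicker``
    In-phase on/off smoothed square waves at ``flicker_multiple * f_s``
    (18 Hz at the defaults).
``flicker_and_swap``
    The swap square wave gated by the flicker square wave (each component is
    squared through the sigmoid first, then multiplied, which reproduces a
    swap envelope chopped by on/off switches).  ``raw_product=True`` instead
    squares the raw product of the two sinusoidal carriers.
``blank_and_swap``
    The swap waveform gated to zero for ``blank_ms`` immediately preceding
    every swap instant; the overall period stays ``1/f_s``.  The blank gate is
    built the same way as the square waves — a steep sigmoid of a sinusoidal
    carrier at twice the swap frequency, with the sigmoid threshold set so the
    gate's half-height crossings delimit exactly ``blank_ms`` — keeping the
    stimulus smooth for fixed-step integration and Floquet analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, replace
from typing import Tuple

import numpy as np

__all__ = [
    "ForcingSpec",
    "PROTOCOLS",
    "oscillator_rhs",
    "square_sigmoid",
    "flicker_component",
    "evaluate",
    "forcing_period_ms",
]

PROTOCOLS = ("fixed", "swap", "flicker", "flicker_and_swap", "blank_and_swap")

#: slope of the blank-interval gate sigmoid (dimensionless, on a [-1, 1]
#: cosine carrier; 50 gives ~5 ms transitions at the default 1.5 Hz swap)
K_BLANK = 50.0


def blank_gate(t: float, f_s: float, blank_ms: float, k_blank: float = K_BLANK) -> float:
    """Smooth multiplicative gate that suppresses the stimulus during the
    ``blank_ms`` window ending at each swap instant (every half swap period)."""
    half = 500.0 / f_s
    if blank_ms <= 0.0:
        return 1.0
    tc = half - 0.5 * blank_ms  # centre of the blank window
    u = math.cos(2.0 * math.pi * (t - tc) / half)
    u0 = math.cos(math.pi * blank_ms / half)
    return 1.0 - square_sigmoid(u - u0, k_blank)


@dataclass(frozen=True)
class ForcingSpec:
    """Stimulus protocol and its parameters.

    ``f_s`` is the swap frequency in Hz; the flicker frequency is the integer
    multiple ``flicker_multiple * f_s``.  ``k_square`` is the slope of the
    sigmoid that turns the sinusoidal carriers into smooth square waves.
    """

    protocol: str = "fixed"
    f_s: float = 1.5
    flicker_multiple: int = 12
    k_square: float = 10.0
    J_max: float = 10.0
    blank_ms: float = 150.0
    phase_t0: float = 0.0
    representation: str = "closed_form"
    raw_product: bool = False

    def __post_init__(self) -> None:
        if self.protocol not in PROTOCOLS:
            raise ValueError(f"unknown protocol {self.protocol!r}")
        if self.f_s <= 0:
            raise ValueError("f_s must be positive")
        if int(self.flicker_multiple) != self.flicker_multiple or self.flicker_multiple < 1:
            raise ValueError("flicker_multiple must be a positive integer")
        if self.J_max <= 0:
            raise ValueError("J_max must be positive")
        if self.protocol == "blank_and_swap":
            half_period_ms = 500.0 / self.f_s
            if not (0.0 <= self.blank_ms < half_period_ms):
                raise ValueError("blank_ms must lie in [0, half swap period)")
        if self.representation not in ("closed_form", "oscillator_ode"):
            raise ValueError(f"unknown representation {self.representation!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ForcingSpec":
        return cls(**d)

    def with_(self, **kw) -> "ForcingSpec":
        return replace(self, **kw)

    @property
    def is_periodic(self) -> bool:
        return self.protocol != "fixed"

    @property
    def period_ms(self) -> float:
        return forcing_period_ms(self)


def forcing_period_ms(spec: ForcingSpec) -> float:
    """Fundamental period of the stimulus pair in ms (raises for ``fixed``)."""
    if spec.protocol == "fixed":
        raise ValueError("fixed protocol has no forcing period")
    if spec.protocol == "flicker":
        return 1000.0 / (spec.flicker_multiple * spec.f_s)
    return 1000.0 / spec.f_s


def oscillator_rhs(t: float, x_s: float, y_s: float, f_s: float) -> Tuple[float, float]:
    """Normal-form oscillator whose attracting unit circle carries
    ``(sin(2 pi f_s t), cos(2 pi f_s t))``.  ``t`` in ms, ``f_s`` in Hz."""
    w = 2.0 * math.pi * f_s / 1000.0  # rad per ms
    r2 = x_s * x_s + y_s * y_s
    return (x_s + w * y_s - x_s * r2, -w * x_s + y_s - y_s * r2)


def square_sigmoid(u: float, k_square: float = 10.0) -> float:
    """Smoothed step ``1 / (1 + exp(-k u))`` in (0, 1)."""
    return 1.0 / (1.0 + math.exp(-k_square * u))


def flicker_component(t: float, f_s: float, multiple: int = 12) -> float:
    """High-frequency carrier ``Re{(x_s + i y_s)^multiple} = cos(2 pi m f_s t)``."""
    w = 2.0 * math.pi * f_s / 1000.0
    z = complex(math.sin(w * t), math.cos(w * t)) ** int(multiple)
    return z.real


def _phase(t: float, spec: ForcingSpec) -> float:
    return t - spec.phase_t0


def evaluate(spec: ForcingSpec, t: float) -> Tuple[float, float]:
    """Inputs ``(J_HL, J_VR)`` at time ``t`` (ms), closed form."""
    tt = _phase(t, spec)
    J = spec.J_max
    k = spec.k_square
    if spec.protocol == "fixed":
        return (J, J)
    w = 2.0 * math.pi * spec.f_s / 1000.0
    xs = math.sin(w * tt)
    if spec.protocol == "swap":
        v = J * square_sigmoid(xs, k)
        return (v, v)
    if spec.protocol == "flicker":
        xf = math.cos(spec.flicker_multiple * w * tt)
        v = J * square_sigmoid(xf, k)
        return (v, v)
    if spec.protocol == "flicker_and_swap":
        xf = math.cos(spec.flicker_multiple * w * tt)
        if spec.raw_product:
            v = J * square_sigmoid(xf * xs, k)
            return (v, v)
        v = J * square_sigmoid(xs, k) * square_sigmoid(xf, k)
        return (v, v)
    if spec.protocol == "blank_and_swap":
        v = J * square_sigmoid(xs, k) * blank_gate(tt, spec.f_s, spec.blank_ms)
        return (v, v)
    raise ValueError(f"unknown protocol {spec.protocol!r}")


def evaluate_array(spec: ForcingSpec, t: np.ndarray) -> np.ndarray:
    """Vectorized :func:`evaluate`; returns an ``(len(t), 2)`` array."""
    out = np.empty((len(t), 2))
    for i, ti in enumerate(np.asarray(t, dtype=float)):
        out[i] = evaluate(spec, ti)
    return out
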