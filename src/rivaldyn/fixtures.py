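"""Deterministic fixture registry: exemplar parameter points and synthetic
test signals, generated programmatically (nothing is downloaded or stored).

``EXEMPLARS`` collects the published parameter points at which each dynamical
regime of the rivalry subunit is known to occur; the test suite and the
bundled experiment configs are built from this registry.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np

from .forcing import ForcingSpec
from .model import ModelParams

__all__ = ["ExemplarPoint", "EXEMPLARS", "fixture_suite", "two_scale_signal",
           "BUNDLED_CONFIGS"]


@dataclass(frozen=True)
class ExemplarPoint:
    """A (g, h, protocol) point with its expected regime label."""

    name: str
    g: float
    h: float
    protocol: str
    expected: str
    gain_mode: str = "hard_rectify"  # time-history exemplars use the hard gain
    J_max: float = 10.0

    @property
    def params(self) -> ModelParams:
        return ModelParams(g=self.g, h=self.h, gain_mode=self.gain_mode)

    @property
    def spec(self) -> ForcingSpec:
        return ForcingSpec(protocol=self.protocol, J_max=self.J_max)


_POINTS = [
    # fixed-input regimes
    ExemplarPoint("fixed_wta", 1.5, 1.0, "fixed", "WTA"),
    ExemplarPoint("fixed_riv", 1.5, 4.3, "fixed", "RIV"),
    ExemplarPoint("fixed_sim", 1.5, 15.0, "fixed", "SIM"),
    # mixed-mode oscillations: expected n_low per dominance segment 1..4
    ExemplarPoint("fixed_mmo_1", 1.5, 4.26, "fixed", "MMO"),
    ExemplarPoint("fixed_mmo_2", 1.5, 4.243, "fixed", "MMO"),
    ExemplarPoint("fixed_mmo_3", 1.5, 4.24, "fixed", "MMO"),
    ExemplarPoint("fixed_mmo_4", 1.5, 4.237, "fixed", "MMO"),
    # LAWTA / PD-cascade exemplar
    ExemplarPoint("fixed_lawta_pd3", 1.5, 4.22842214, "fixed", "LAWTA"),
    # flicker (18 Hz) regimes
    ExemplarPoint("flicker_wta_mod", 1.5, 0.5, "flicker", "WTA_Mod"),
    ExemplarPoint("flicker_riv_mod", 1.5, 2.0, "flicker", "RIV_Mod"),
    ExemplarPoint("flicker_sim_mod", 1.5, 6.0, "flicker", "SIM_Mod"),
    # swap (1.5 Hz) regimes
    ExemplarPoint("swap_cycle_skip", 25.0, 1.0, "swap", "CYCLE_SKIP"),
    ExemplarPoint("swap_multi_b", 25.0, 0.03, "swap", "MULTI_CYCLE_SKIP"),
    ExemplarPoint("swap_multi_c", 25.0, 0.02, "swap", "MULTI_CYCLE_SKIP"),
    ExemplarPoint("swap_multi_d", 25.0, 0.0185, "swap", "MULTI_CYCLE_SKIP"),
    ExemplarPoint("swap_multi_e", 25.0, 0.017, "swap", "MULTI_CYCLE_SKIP"),
    ExemplarPoint("swap_chaos", 25.0, 0.01663, "swap", "CHAOTIC"),
]

EXEMPLARS: Dict[str, ExemplarPoint] = {p.name: p for p in _POINTS}

#: expected small-oscillation counts for the MMO exemplars
MMO_EXPECTED_N_LOW = {"fixed_mmo_1": 1, "fixed_mmo_2": 2,
                      "fixed_mmo_3": 3, "fixed_mmo_4": 4}


def two_scale_signal(
    n: int = 4000,
    dt: float = 1.0,
    big_amp: float = 20.0,
    small_amp: float = 0.5,
    big_period: float = 1000.0,
    small_period: float = 120.0,
    seed: Optional[int] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic two-scale peak signal (big bumps + small ripples) used to
    exercise prominence-based peak splitting."""
    t = np.arange(n) * dt
    big = big_amp * np.maximum(np.sin(2 * np.pi * t / big_period), 0.0) ** 4
    small = small_amp * (1.0 + np.sin(2 * np.pi * t / small_period))
    y = big + small
    if seed is not None:
        y = y + 1e-9 * np.random.default_rng(seed).standard_normal(n)
    return t, y


BUNDLED_CONFIGS: Dict[str, dict] = {
    "fig_wta_timehistory": {
        "model": {"g": 1.5, "h": 1.0, "gain_mode": "hard_rectify"},
        "forcing": {"protocol": "fixed", "J_max": 10.0},
        "run": {"mode": "simulate", "g": 1.5, "h": 1.0,
                "t_transient": 20000.0, "t_record": 10000.0},
    },
    "swap_cycleskip_classify": {
        "model": {"g": 25.0, "h": 1.0, "gain_mode": "hard_rectify"},
        "forcing": {"protocol": "swap", "f_s": 1.5, "J_max": 10.0},
        "run": {"mode": "classify", "g": 25.0, "h": 1.0},
    },
    "critical_h": {
        "model": {"g": 1.5, "gain_mode": "hard_rectify"},
        "forcing": {"protocol": "fixed", "J_max": 10.0},
        "run": {"mode": "critical", "g": 1.5, "h": 4.25,
                "h_bracket": [4.2, 4.3]},
    },
}


def fixture_suite() -> dict:
    """The registry used by the test suite: exemplar points, expected MMO
    counts, bundled configs and signal generators.  Regeneration is
    deterministic."""
    return {
        "exemplars": dict(EXEMPLARS),
        "mmo_expected_n_low": dict(MMO_EXPECTED_N_LOW),
        "configs": {k: dict(v) for k, v in BUNDLED_CONFIGS.items()},
        "two_scale_signal": two_scale_signal,
    }
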