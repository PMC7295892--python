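"""Regime classification: turns settled trajectories into labelled regimes.

Fixed-input regimes
-------------------
``SIM``   stable symmetric equilibrium (both populations equally active)
``WTA``   stable asymmetric equilibria (one population persistently dominant)
``LAWTA`` small-amplitude limit cycles around the asymmetric equilibria
          (these undergo a period-doubling cascade)
``RIV``   large-amplitude relaxation oscillations with alternating dominance
``MMO``   mixed-mode oscillations: per dominance segment, one high-amplitude
          excursion plus ``m`` small oscillations near the symmetric state

Forced regimes
--------------
``SIM_Mod``/``WTA_Mod``/``RIV_Mod``  the modulated counterparts
``CYCLE_SKIP``        each population responds to every other stimulus cycle
                      (solution period twice the forcing period)
``MULTI_CYCLE_SKIP``  runs of ``m >= 2`` cycles between dominance switches
``CHAOTIC``           positive largest Lyapunov exponent

Amplitude thresholds are calibrated to the model's actual dynamic range at
J_max = 10 (the Naka--Rushton keeps rates below 50 spikes/s there: relaxation
peaks reach ~23--26 spikes/s and MMO small oscillations stay below ~7); all
are overridable per call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import find_peaks

from . import _kernels as K
from .forcing import ForcingSpec, forcing_period_ms
from .integrate import (
    Trajectory,
    advance,
    commensurate_dt,
    default_ic,
    settle,
    stroboscope,
)
from .model import ModelParams

__all__ = [
    "RegimeLabel",
    "detect_peaks",
    "estimate_period",
    "mmo_signature",
    "dominance_sequence",
    "classify_fixed",
    "classify_forced",
    "lyapunov_max",
]

# amplitude separating relaxation (high) excursions from MMO small loops
HIGH_PEAK_THRESH = 15.0
# prominence floor for counting small oscillations (well above RK4 noise,
# below the tiniest canard loops observed ~8e-4)
LOW_PROM_FLOOR = 1e-5
# peak-to-trough amplitude below which an oscillation counts as low-amplitude
LAWTA_AMP_THRESH = 20.0
# relative margin on cycle-integrated activity for declaring a cycle winner
DOMINANCE_MARGIN = 0.05
# largest-LE threshold for chaos (1/ms)
CHAOS_LE_THRESH = 1e-4
# peak-to-trough below which a trajectory counts as an equilibrium
EQUILIBRIUM_AMP = 1e-4


@dataclass
class RegimeLabel:
    """Classification outcome with its quantitative evidence."""

    label: str
    period_ms: Optional[float] = None
    n_high: Optional[int] = None
    n_low: Optional[int] = None
    skip_cycles: Optional[int] = None
    lyapunov: Optional[float] = None  # 1/ms
    evidence: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.label == "MMO" and not (self.n_high and self.n_low and self.n_low >= 1):
            raise ValueError("MMO requires n_high >= 1 and n_low >= 1")
        if self.label == "CYCLE_SKIP" and self.skip_cycles != 1:
            raise ValueError("CYCLE_SKIP means skip_cycles == 1")
        if self.label == "MULTI_CYCLE_SKIP" and (self.skip_cycles or 0) < 2:
            raise ValueError("MULTI_CYCLE_SKIP means skip_cycles >= 2")
        if self.label == "CHAOTIC" and not (self.lyapunov and self.lyapunov > 0):
            raise ValueError("CHAOTIC requires a positive Lyapunov exponent")

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "period_ms": self.period_ms,
            "n_high": self.n_high,
            "n_low": self.n_low,
            "skip_cycles": self.skip_cycles,
            "lyapunov_per_ms": self.lyapunov,
            "lyapunov_per_s": None if self.lyapunov is None else 1000.0 * self.lyapunov,
            "evidence": {k: _jsonable(v) for k, v in self.evidence.items()},
        }


def _jsonable(v):
    if isinstance(v, np.ndarray):
        return v.tolist()
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    return v


# ---------------------------------------------------------------------------
# signal-level helpers


def detect_peaks(
    series: np.ndarray,
    min_prominence: float,
    t: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Local maxima with parabolic sub-sample refinement.

    Returns (peak positions, refined amplitudes).  Positions are times if
    ``t`` is given, else fractional sample indices.
    """
    series = np.asarray(series, dtype=float)
    idx, _ = find_peaks(series, prominence=min_prominence)
    pos = np.empty(len(idx))
    amp = np.empty(len(idx))
    for j, k in enumerate(idx):
        if 0 < k < len(series) - 1:
            a, b, c = series[k - 1], series[k], series[k + 1]
            denom = a - 2.0 * b + c
            delta = 0.0 if denom == 0 else 0.5 * (a - c) / denom
            delta = float(np.clip(delta, -0.5, 0.5))
            amp[j] = b - 0.25 * (a - c) * delta
        else:
            delta = 0.0
            amp[j] = series[k]
        pos[j] = k + delta
    if t is not None:
        dt = t[1] - t[0]
        pos = t[0] + pos * dt
    return pos, amp


def estimate_period(
    traj: Trajectory,
    rel_tol: float = 1e-3,
    min_period_ms: Optional[float] = None,
) -> Optional[float]:
    """First recurrence time of the full state vector, or None.

    The state is normalized per component by its range; the reference sample
    is taken a quarter into the record and recurrence requires the normalized
    max-distance to first leave (exceed 20x ``rel_tol``) and then return
    below ``rel_tol`` at a local minimum.  Because the true recurrence
    generally falls between samples, each candidate minimum is refined by
    minimizing the distance to the linearly interpolated state on the
    adjacent segments before testing the tolerance.
    """
    X = traj.states
    scales = X.max(axis=0) - X.min(axis=0)
    if np.all(scales < EQUILIBRIUM_AMP):
        return None  # equilibrium
    active = scales > max(scales.max() * 1e-6, 1e-12)
    Z = (X[:, active] - X[:, active].min(axis=0)) / scales[active]
    i0 = len(Z) // 4
    ref = Z[i0]
    d = np.abs(Z - ref).max(axis=1)
    sample_dt = traj.sample_dt
    min_sep = 3
    if min_period_ms is not None:
        min_sep = max(min_sep, int(min_period_ms / sample_dt) - 1)
    escaped = False
    thresh_out = min(20.0 * rel_tol, 0.5)
    gate = min(50.0 * rel_tol, 0.45 * thresh_out) + rel_tol

    def _refine(k: int) -> Tuple[float, float]:
        """Min over frac in [-1, 1] of ||ref - Z(k + frac)|| (piecewise-linear
        interpolation; the objective is convex on each segment)."""
        best = (d[k], 0.0)
        for k0 in (k - 1, k):
            if k0 < 0 or k0 + 1 >= len(Z):
                continue
            lo, hi = 0.0, 1.0
            seg = Z[k0 + 1] - Z[k0]

            def val(f):
                return np.abs(ref - Z[k0] - f * seg).max()

            for _ in range(40):  # ternary search on a convex objective
                m1 = lo + (hi - lo) / 3.0
                m2 = hi - (hi - lo) / 3.0
                if val(m1) <= val(m2):
                    hi = m2
                else:
                    lo = m1
            f = 0.5 * (lo + hi)
            v = val(f)
            if v < best[0]:
                best = (v, k0 - k + f)
        return best

    for k in range(i0 + 1, len(d) - 1):
        if not escaped:
            if d[k] > thresh_out:
                escaped = True
            continue
        if k - i0 < min_sep:
            continue
        if d[k] < gate and d[k] <= d[k - 1] and d[k] <= d[k + 1]:
            v, delta = _refine(k)
            if v < rel_tol:
                return (k + delta - i0) * sample_dt
    return None


def _high_low_peaks(
    traj: Trajectory,
    high_thresh: float,
    low_band: Tuple[float, float],
) -> Tuple[list, list]:
    """Per-channel peak lists split into high excursions and small loops."""
    highs, lows = [], []
    for ch in (0, 1):
        e = traj.E[:, ch]
        pos, amp = detect_peaks(e, min_prominence=low_band[0], t=traj.t)
        for p_, a_ in zip(pos, amp):
            if a_ > high_thresh:
                highs.append((p_, ch, a_))
            else:
                lows.append((p_, ch, a_))
    highs.sort()
    lows.sort()
    return highs, lows


def mmo_signature(
    traj: Trajectory,
    high_thresh: float = HIGH_PEAK_THRESH,
    low_band: Tuple[float, float] = (LOW_PROM_FLOOR, HIGH_PEAK_THRESH),
) -> Tuple[int, int]:
    """Counts (n_high, n_low) per dominance segment of a periodic solution.

    A dominance segment runs between consecutive high-amplitude excursions
    (which alternate channels in a symmetric mixed-mode oscillation).  Each
    small loop near the symmetric state produces one sub-threshold peak in
    *each* channel, so the small peaks of both channels strictly between two
    high events are counted and halved.
    """
    period = estimate_period(traj)
    if period is None:
        raise ValueError("mmo_signature requires a periodic trajectory")
    highs, lows = _high_low_peaks(traj, high_thresh, low_band)
    if len(highs) < 3:
        raise ValueError("too few high-amplitude excursions in the record")
    counts = []
    for (t0, _, _), (t1, _, _) in zip(highs[:-1], highs[1:]):
        n_small = sum(1 for (tp, _, _) in lows if t0 < tp < t1)
        counts.append(n_small)
    # drop possibly clipped first/last segments when enough are available
    if len(counts) > 2:
        counts = counts[1:-1]
    n_low_each = int(round(np.median(counts) / 2.0))
    return (1, n_low_each)


def dominance_sequence(
    traj: Trajectory,
    spec: ForcingSpec,
    margin: float = DOMINANCE_MARGIN,
) -> np.ndarray:
    """Per-forcing-cycle winner sequence: 1, 2 or 0 (tie).

    The winner of a cycle is the population with the larger cycle-integrated
    firing rate, declared only when the integrals differ by more than
    ``margin`` times their sum.
    """
    T = forcing_period_ms(spec)
    spc = int(round(T / traj.sample_dt))
    if spc < 2:
        raise ValueError("sampling too coarse for per-cycle integration")
    E = traj.E
    n_cycles = len(E) // spc
    if n_cycles < 20:
        raise ValueError("record must span at least 20 forcing cycles")
    out = np.zeros(n_cycles, dtype=int)
    for c in range(n_cycles):
        a = E[c * spc : (c + 1) * spc, 0].sum()
        b = E[c * spc : (c + 1) * spc, 1].sum()
        tot = a + b
        if tot <= 0:
            continue
        if a - b > margin * tot:
            out[c] = 1
        elif b - a > margin * tot:
            out[c] = 2
    return out


def run_lengths(winners: Sequence[int]) -> List[Tuple[int, int]]:
    """(winner, run length) for consecutive strict-winner runs; ties never
    break a run."""
    runs: List[Tuple[int, int]] = []
    cur, n = 0, 0
    for w in winners:
        if w == 0:
            continue
        if w == cur:
            n += 1
        else:
            if cur != 0:
                runs.append((cur, n))
            cur, n = w, 1
    if cur != 0:
        runs.append((cur, n))
    return runs


# ---------------------------------------------------------------------------
# Lyapunov


def lyapunov_max(
    params: ModelParams,
    spec: ForcingSpec,
    ic: Optional[np.ndarray] = None,
    t_total: float = 200_000.0,
    t_transient: float = 20_000.0,
    renorm_every: float = 10.0,
    dt: float = 0.1,
    tangent_seed: int = 0,
) -> float:
    """Largest Lyapunov exponent (1/ms) by the Benettin method.

    Integrates one tangent vector along the flow with the analytic
    variational equations, renormalizing every ``renorm_every`` ms.  The
    hard-rectified gain has a derivative defined away from the kink, which
    the trajectory crosses on a measure-zero set, so both gain modes are
    accepted.
    """
    if ic is None:
        ic = default_ic(params)
    if spec.is_periodic:
        dt = commensurate_dt(spec, dt)
    y = advance(params, spec, ic, t_transient, dt=dt)
    mp = K.pack_model(params)
    code, fp = K.pack_forcing(spec)
    rng = np.random.default_rng(tangent_seed)
    v0 = rng.standard_normal(params.n_state)
    v0 /= np.linalg.norm(v0)
    n_steps = int(round(t_total / dt))
    renorm_steps = max(1, int(round(renorm_every / dt)))
    _, sum_log, n_renorm = K.rk4_benettin(
        y, v0, t_transient, dt, n_steps, renorm_steps, mp, code, fp
    )
    return sum_log / (n_renorm * renorm_steps * dt)


# ---------------------------------------------------------------------------
# classification: fixed inputs


def classify_fixed(
    params: ModelParams,
    J: float,
    ic: Optional[np.ndarray] = None,
    t_transient: float = 40_000.0,
    t_record: float = 60_000.0,
    high_thresh: float = HIGH_PEAK_THRESH,
    lawta_amp_thresh: float = LAWTA_AMP_THRESH,
) -> RegimeLabel:
    """Classify the attractor of the model under fixed inputs ``J``.

    Simulates from a perturbed symmetric and a strongly asymmetric initial
    condition (or from ``ic`` when given, e.g. for sweep inheritance) and
    applies the decision procedure: equilibria split into SIM/WTA by
    symmetry; oscillations split into LAWTA (small amplitude, unequal
    means), RIV (high excursions only) and MMO (high + small loops).
    """
    spec = ForcingSpec(protocol="fixed", J_max=J)
    ics = [ic] if ic is not None else [
        default_ic(params, "asymmetric"),
        default_ic(params, "perturbed_symmetric"),
    ]
    trajs = [
        settle(params, spec, x, t_transient=t_transient, t_record=t_record,
               record_stride=max(1, int(1.0 / 0.1)))
        for x in ics
    ]
    # prefer an oscillatory verdict if any IC finds one; else prefer asymmetric eq.
    best: Optional[RegimeLabel] = None
    for traj in trajs:
        lab = _classify_fixed_traj(traj, params, high_thresh, lawta_amp_thresh)
        lab.evidence["final_state"] = traj.states[-1]
        if lab.label in ("RIV", "MMO", "LAWTA"):
            return lab
        if best is None or (best.label == "SIM" and lab.label == "WTA"):
            best = lab
    if best is not None and best.label == "UNCLASSIFIED" and ic is not None:
        # an inherited state may still be in a slow transient; retry cold
        return classify_fixed(params, J, ic=None, t_transient=t_transient,
                              t_record=t_record, high_thresh=high_thresh,
                              lawta_amp_thresh=lawta_amp_thresh)
    return best  # type: ignore[return-value]


def _classify_fixed_traj(
    traj: Trajectory,
    params: ModelParams,
    high_thresh: float,
    lawta_amp_thresh: float,
) -> RegimeLabel:
    E = traj.E
    amp = float((E.max(axis=0) - E.min(axis=0)).max())
    e1m, e2m = E.mean(axis=0)
    # judge "equilibrium" on the record tail: a slowly converging transient
    # inflates the full-record amplitude long after oscillations have died
    tail = E[3 * len(E) // 4:]
    amp_tail = float((tail.max(axis=0) - tail.min(axis=0)).max())
    if amp_tail < EQUILIBRIUM_AMP:
        e1m, e2m = tail.mean(axis=0)
        if abs(e1m - e2m) < 1e-3:
            return RegimeLabel("SIM", evidence={"E": (e1m, e2m)})
        return RegimeLabel("WTA", evidence={"E": (e1m, e2m)})
    period = estimate_period(traj)
    # LAWTA: small oscillations around distinct asymmetric equilibria, so the
    # two populations' ranges never overlap (unlike RIV/MMO where both visit
    # near-zero and near-peak values)
    lo = max(E[:, 0].min(), E[:, 1].min())
    hi_sub = min(E[:, 0].max(), E[:, 1].max())
    ranges_disjoint = hi_sub < lo or E[:, 0].max() < E[:, 1].min() or E[:, 1].max() < E[:, 0].min()
    if amp < lawta_amp_thresh and ranges_disjoint:
        return RegimeLabel(
            "LAWTA", period_ms=period,
            evidence={"amplitude": amp, "means": (e1m, e2m)},
        )
    if period is None:
        return RegimeLabel("UNCLASSIFIED", evidence={"amplitude": amp})
    try:
        n_high, n_low = mmo_signature(traj, high_thresh=high_thresh)
    except ValueError:
        # near the Hopf the rivalry cycle is small; fall back on alternation
        diff = E[:, 0] - E[:, 1]
        if period is not None and diff.min() < 0 < diff.max():
            return RegimeLabel("RIV", period_ms=period, n_high=1, n_low=0,
                               evidence={"amplitude": amp, "small_cycle": True})
        return RegimeLabel("UNCLASSIFIED", period_ms=period, evidence={"amplitude": amp})
    if n_low >= 1:
        return RegimeLabel("MMO", period_ms=period, n_high=n_high, n_low=n_low,
                           evidence={"amplitude": amp})
    return RegimeLabel("RIV", period_ms=period, n_high=1, n_low=0,
                       evidence={"amplitude": amp})


# ---------------------------------------------------------------------------
# classification: periodic forcing


def _strobe_min_period(S: np.ndarray, tol: float = 1e-5, max_period: int = 64) -> Optional[int]:
    """Minimal period of a stroboscopic sequence, or None if aperiodic."""
    scale = np.abs(S).max() + 1e-300
    for m in range(1, max_period + 1):
        if len(S) <= m + 2:
            break
        if np.abs(S[m:] - S[:-m]).max() < tol * scale:
            return m
    return None


def classify_forced(
    params: ModelParams,
    spec: ForcingSpec,
    ic: Optional[np.ndarray] = None,
    n_transient_cycles: int = 200,
    n_record_cycles: Optional[int] = None,
    margin: float = DOMINANCE_MARGIN,
    le_kwargs: Optional[dict] = None,
) -> RegimeLabel:
    """Classify the attractor under a periodic stimulus protocol.

    Decision procedure on the stroboscopic (once-per-forcing-period) sequence:
    fixed point -> SIM_Mod or WTA_Mod by per-cycle dominance; 2-periodic with
    alternating winners -> CYCLE_SKIP; 2m-periodic with m-cycle runs ->
    MULTI_CYCLE_SKIP; aperiodic -> CHAOTIC if the largest Lyapunov exponent is
    positive, RIV_Mod if it is non-positive and dominance alternates slowly.
    """
    if not spec.is_periodic:
        raise ValueError("classify_forced requires a periodic protocol")
    T = forcing_period_ms(spec)
    if n_record_cycles is None:
        # enough cycles to see slow alternation even at the flicker period
        n_record_cycles = max(120, int(math.ceil(60_000.0 / T)))
    if ic is None:
        ic = default_ic(params)
    dt = commensurate_dt(spec)
    y = advance(params, spec, ic, n_transient_cycles * T, dt=dt)
    S = stroboscope(params, spec, y, n_record_cycles, dt=dt)
    m = _strobe_min_period(S[n_record_cycles // 3 :])

    # per-cycle dominance over the same window
    stride = max(1, int(round(1.0 / dt)))
    traj = settle(params, spec, y, t_transient=T, t_record=n_record_cycles * T,
                  record_stride=stride)
    winners = dominance_sequence(traj, spec, margin=margin)
    runs = run_lengths(winners)
    evidence = {
        "strobe_period": m,
        "winner_counts": np.bincount(winners, minlength=3).tolist(),
        "n_runs": len(runs),
        "final_state": traj.states[-1],
    }

    if m == 1:
        if np.all(winners == winners[0]) and winners[0] != 0:
            return RegimeLabel("WTA_Mod", period_ms=T, evidence=evidence)
        if np.all(winners == 0):
            return RegimeLabel("SIM_Mod", period_ms=T, evidence=evidence)
        return RegimeLabel("UNCLASSIFIED", period_ms=T, evidence=evidence)
    if m is not None and m % 2 == 0 and len(runs) >= 4:
        lens = [n for _, n in runs[1:-1]] or [n for _, n in runs]
        alternating = all(a[0] != b[0] for a, b in zip(runs[:-1], runs[1:]))
        if alternating and len(set(lens)) == 1 and lens[0] == m // 2:
            k = m // 2
            label = "CYCLE_SKIP" if k == 1 else "MULTI_CYCLE_SKIP"
            return RegimeLabel(label, period_ms=m * T, skip_cycles=k, evidence=evidence)
    if m is not None:
        return RegimeLabel("UNCLASSIFIED", period_ms=m * T, evidence=evidence)

    # aperiodic: decide by the largest Lyapunov exponent
    le = lyapunov_max(params, spec, ic=y, **(le_kwargs or {}))
    evidence["lyapunov_per_s"] = 1000.0 * le
    if le > CHAOS_LE_THRESH:
        return RegimeLabel("CHAOTIC", lyapunov=le, evidence=evidence)
    mean_run = float(np.mean([n for _, n in runs])) if runs else 0.0
    evidence["mean_run_cycles"] = mean_run
    if len(runs) >= 3 and mean_run > 1.5:
        return RegimeLabel("RIV_Mod", lyapunov=le, evidence=evidence)
    return RegimeLabel("UNCLASSIFIED", lyapunov=le, evidence=evidence)
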