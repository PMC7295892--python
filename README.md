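# rivaldyn

Dynamics of a minimal binocular-rivalry circuit under fixed and periodically
forced stimuli: simulation, automatic regime classification, and
bifurcation-boundary location in the adaptation–inhibition parameter plane.

## The problem

When the two eyes view incompatible images, perception alternates between
them every few seconds (binocular rivalry).  A classic way to probe *where*
this competition is resolved is to swap the two images between the eyes at
~1.5 Hz, optionally flickering them on and off at 18 Hz or inserting short
blanks before each swap: percepts that survive many swaps rule out a purely
eye-based competition.  `rivaldyn` implements the monocular competition
subunit of Wilson's hierarchical rivalry model and maps everything it can do
under these stimulus protocols.

Two populations with firing rates `E_1, E_2` (spikes/s) inhibit each other
and adapt:

    τ  dE_i/dt = -E_i + 100 (J_i(t) - g I_j)_+² / ((10 + H_i)² + (J_i(t) - g I_j)_+²)
    τ_H dH_i/dt = -H_i + h E_i
    τ_I dI_i/dt = -I_i + E_i            (j ≠ i)

with τ = 20 ms, τ_H = 900 ms, τ_I = 11 ms.  The steady-state rate is a
Naka–Rushton function of the rectified drive; `g` (mutual inhibition) and
`h` (spike-frequency adaptation) are the control parameters.  Depending on
`(g, h)` and the stimulus, the circuit produces winner-take-all dominance
(WTA), rivalry oscillations (RIV), simultaneous activity (SIM), small
low-amplitude WTA cycles with a period-doubling cascade (LAWTA), mixed-mode
oscillations (MMO), and — under 1.5 Hz swap forcing — modulated versions of
these plus cycle skipping, multi-cycle skipping and chaos.

The package is aimed at computational-neuroscience researchers who want to
check rivalry models against periodic-stimulation experiments, or to explore
forced mutual-inhibition circuits with proper dynamical-systems tooling:
fixed-step RK4 with stroboscopic sampling, equilibrium continuation with
fold/Hopf/pitchfork detection, Floquet multipliers by Newton shooting on the
period map, period-doubling/torus boundary bisection, and Benettin Lyapunov
exponents.

## Worked example

Classify the swap-forced circuit at strong inhibition (g = 25, h = 1):

```
$ rivaldyn classify --g 25 --h 1 --protocol swap --gain hard_rectify --out-dir out
CYCLE_SKIP
{
  "regime": "out/regime.json",
  "label": "CYCLE_SKIP"
}
```

with `out/regime.json` containing

```json
{
  "label": "CYCLE_SKIP",
  "period_ms": 1333.3333333333333,
  "skip_cycles": 1,
  ...
}
```

Each population responds to every other onset of its 1.5 Hz stimulus, so the
solution period (1.333 s) is twice the forcing period — the period-doubled
state born at the PD bifurcation of the modulated-SIM branch.  The same call
with `--h 0.02` returns `MULTI_CYCLE_SKIP` with `skip_cycles = 3` (each
population stays dominant for three stimulus cycles), and with
`--h 0.016705` returns `CHAOTIC` with a positive largest Lyapunov exponent.

From Python:

```python
from rivaldyn import ModelParams, ForcingSpec, classify_forced, find_boundary

p = ModelParams(g=1.5, h=2.0)                 # smoothed gain by default
flick = ForcingSpec(protocol="flicker", f_s=1.5, J_max=10.0)
print(classify_forced(p, flick).label)        # -> RIV_Mod

# torus bifurcation bounding modulated rivalry under flicker at g = 1.5
h_star = find_boundary(1.5, (4.0, 6.5), flick, "TORUS")
print(round(h_star, 3))                       # -> 5.682
```

Other entry points: `sweep_diagram` (one-parameter classification sweeps
with hysteresis detection), `regime_map` (two-parameter label maps),
`continue_equilibria` (pseudo-arclength continuation with event detection),
`find_critical_h` (the accumulation point of the oscillation-period
blow-up), `lyapunov_max`.  See `docs/methods.md` for the numerical choices
and classification thresholds.

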