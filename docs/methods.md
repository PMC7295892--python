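# Methods

## The model

`rivaldyn` studies a minimal firing-rate model of binocular rivalry: two
neural populations, each selective for one monocular grating (horizontal in
the left eye, HL, and vertical in the right eye, VR), coupled by mutual
inhibition and slowed by spike-frequency adaptation.  Each population `i`
carries three variables,

    tau   dE_i/dt = -E_i + 100 * P_i^2 / ((10 + H_i)^2 + P_i^2),
    tau_H dH_i/dt = -H_i + h * E_i,
    tau_I dI_i/dt = -I_i + E_i,          P_i = (J_i(t) - g * I_j)_+,

with `tau = 20 ms`, `tau_H = 900 ms`, `tau_I = 11 ms`.  The steady-state rate
is a Naka–Rushton function of the rectified net drive (stimulus minus
cross-inhibition); `g` scales inhibition and `h` adaptation, and these two
are the bifurcation parameters throughout.  Rates stay in `[0, 100)`
spikes/s.  A 4-variable variant slaves inhibition to the rates
(`tau_I -> 0`, `I_i = E_i`); it preserves every regime of the full model and
is exposed as `ModelParams(instantaneous_inhibition=True)`.

Two gain conventions coexist deliberately:

* **hard rectification** `(x)_+` — the model as originally written; used for
  all *time-history* results (regime exemplars, mixed-mode-oscillation
  counts, the period-doubling cascade, the critical adaptation strength).
  Cross-checking the printed exemplars showed the published trajectories
  correspond to this variant: the small-oscillation counts at
  `h = 4.26, 4.243, 4.24, 4.237` come out `1, 2, 3, 4` with the hard gain
  but `1, 2, 2, 3` with the smoothed one.
* **smoothed rectification** `R(x) = x / (1 + exp(-30 (x - 0.05)))`, clamped
  at zero — required by everything built on derivatives (Jacobians,
  continuation, Floquet multipliers, Lyapunov exponents via the variational
  flow).  Because the rate depends on the drive only through `P^2`, the
  clamp keeps the composed right-hand side C¹, so analytic Jacobians agree
  with finite differences everywhere.

The symmetry-breaking offset `epsilon` (added to population 1's
semi-saturation term) defaults to 0; it exists for torus-continuation
workflows where the exchange symmetry degenerates the defining system.

## Stimulus protocols

Both populations of the modelled subunit are stimulated **in phase**: when
the horizontal grating is in the left eye, the vertical grating is
simultaneously in the right eye, so HL and VR receive the same envelope; the
swapped half-cycle drives the other, unmodelled subunit.  (This follows the
model equations' `J_HL(t) = J_VR(t) = x(t)`; it is also the only reading
that reproduces cycle skipping and its 1.333 s period.)  Protocols, all
built from a steep sigmoid (`k = 10`) of sinusoidal carriers so the forcing
is smooth:

* `fixed` — constant `J_max` (default 10).
* `swap` — smoothed square wave at the swap frequency `f_s` (default 1.5 Hz).
* `flicker` — the same at `flicker_multiple * f_s` (18 Hz at defaults).
* `flicker_and_swap` — the swap square gated by the flicker square (each
  carrier squared through the sigmoid first, then multiplied; the literal
  raw product of the two sinusoids is retained as `raw_product=True`).
* `blank_and_swap` — the swap wave gated to zero for `blank_ms` (default
  150 ms) immediately preceding every swap instant, period preserved.  The
  gate is a sigmoid (slope 50) of a cosine at twice the swap frequency with
  its threshold set so the half-height crossings delimit exactly
  `blank_ms`; a hard 0/1 gate was rejected because the discontinuity makes
  fixed-step trajectories sensitive to the step grid at the 1e-3 level and
  breaks stroboscopic convergence.

The phase convention is `x_s(t) = sin(2 pi f_s t)` with `t = 0` at a swap
instant, so the subunit's on-phase is the first half-cycle.

## Numerics

* **Integration**: classic fixed-step RK4, `dt = 0.1 ms`, with the forcing
  evaluated in closed form at the substage times.  For stroboscopic work the
  step is adjusted per run to `T / ceil(T / 0.1)` so an integer number of
  steps spans the forcing period exactly.  Order-4 convergence is asserted
  by Richardson step-halving in the test suite.  The inner loops (state,
  state+variational matrix, state+tangent vector) are numba-compiled; the
  pure-Python right-hand side and Jacobian in `rivaldyn.model` are the
  reference definitions the kernels are tested against.
* **Transients**: default 20 s discarded, 40 s recorded; classification
  calls lengthen both (and classification sweeps inherit the final state of
  the previous parameter point) where slow canard-like transients demand it.
* **Equilibria**: at a fixed point `H_i = h E_i` and `I_i = E_i`, so
  equilibria solve a 2-D system in `(E1, E2)`: symmetric solutions by a
  bracketed scalar root scan on the diagonal, asymmetric ones by damped
  Newton (tolerance 1e-10, 50 iterations) from the seed grid
  `{0,5,25,50,75,95}^2`, de-duplicated at 1e-6.  Stability from the
  full-state Jacobian.
* **Continuation**: pseudo-arclength in `(E1, E2, h)` with adaptive step
  (`ds` in `[1e-6, 0.05]`).  Test functions: tangent `h`-component sign
  change (fold), leading complex-pair real part (Hopf), determinant of the
  antisymmetric block of the exchange-symmetric Jacobian (pitchfork).
  Events are refined by bisection along the secant; a refinement that fails
  to drive the test function to ~0 is flagged non-genuine (this filters
  spurious sign flips where a complex pair collapses onto the real axis).
* **Periodic solutions of the forced system**: fixed points of the
  stroboscopic map by Newton shooting, with the monodromy matrix from RK4 on
  the variational equations; unforced cycles by shooting on (state, period)
  with the flow direction as phase anchor.  Floquet-based boundary location
  bisects the relevant test function in `h` at fixed `g` (PD: most negative
  real multiplier through -1; torus: complex-pair modulus through 1; fold:
  real multiplier through +1), walking the fixed point down from the stable
  side so Newton tracks a single branch.  Two-parameter curves are traced as
  per-`g` bisections rather than by continuation of the bifurcation itself.
* **Lyapunov exponents**: Benettin's method — one tangent vector integrated
  with the flow, renormalized every 10 ms, log-growth averaged over 150–200 s
  after a 20 s transient.  Chaos threshold 1e-4 / ms.  The hard gain's
  derivative is defined away from the rectification kink, which trajectories
  cross on a measure-zero set, so both gain modes are accepted here.
* **Period estimation**: first recurrence of the range-normalized full state
  vector (reference sample a quarter into the record, must first leave the
  tolerance ball), refined parabolically; forced solutions use the strobe
  sequence's minimal period times the forcing period.
* **Critical adaptation strength** (`find_critical_h`): marches toward the
  period blow-up from both flanks with adaptive steps and state
  inheritance.  The low side tracks the small-amplitude (LAWTA /
  period-doubled) family, the high side the large-amplitude (rivalry /
  mixed-mode) family; a step is rejected when the estimated period exceeds
  the 60 s cap, no recurrence fits a 300 s record, or the attractor jumps to
  the other amplitude family (split at 20 spikes/s peak-to-trough); a
  rejected step is retried once after a longer settle to discriminate
  blow-up from slow transients.  Reported as the midpoint of the two flank
  endpoints with the bracket width.

## Classification thresholds

With `J_max = 10` the Naka–Rushton ceiling confines rates below 50 spikes/s
(relaxation peaks reach ~23–26; mixed-mode small loops stay below ~7 with
prominences down to ~8e-4).  Defaults, all overridable per call: high-peak
threshold 15 spikes/s; small-peak prominence floor 1e-5; low-amplitude-WTA
peak-to-trough bound 20 (plus the requirement that the two populations'
ranges are disjoint, which separates LAWTA from small rivalry cycles near
the Hopf); cycle-winner margin 5% of summed cycle-integrated activity; ties
never break a dominance run.

Mixed-mode signatures are counted per dominance segment (between consecutive
high-amplitude excursions, which alternate channels): each small loop near
the symmetric state produces one sub-threshold peak in *each* channel, so
the small peaks of both channels in the segment are counted and halved.
This convention reproduces the published `1:m` labels exactly.

## What the checks do and do not show

The acceptance checks regenerate everything from the model itself — there is
no external data.  Regime positions that are printed to many significant
figures *inside* window structures a few 1e-6 wide (the third
period-doubling window of the low-amplitude cascade, the chaotic band
between that cascade and the multi-cycle-skipping family) are reproduced as
windows located within 1e-4 of the printed values; their absolute positions
depend on floating-point library details at the 1e-5 level and are not
transferable across implementations.  One directional claim — that blank
insertion moves the cycle-skip/SIM-Mod boundary the same way as flicker —
does not reproduce here under any blank placement or gate convention tried
(the corresponding test documents the discrepancy by failing); all other
qualitative structure (regime sequences, bifurcation skeleton, multi-cycle
and chaotic dynamics, the flicker/swap contrast) reproduces.

## Known limitations

* No noise; all dynamics are deterministic.
* The binocular second stage of the hierarchical architecture is out of
  scope; only one monocular subunit pair is modelled.
* The "global bifurcation" terminating the rivalry branch is reported only
  as a change of stability; no homoclinic analysis is attempted.
* Boundaries are one-dimensional bisections per `g`, not two-parameter
  continuations of the bifurcation curves.
* Dominance statistics under noise (percept durations) are not modelled.
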