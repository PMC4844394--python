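# Methods

## The model

`elicitca` simulates cytosolic Ca²⁺ transients in elicitor-treated plant
cell cultures with a two-variable reduction of the De Young–Keizer
IP₃-receptor scheme (the Li–Rinzel reduction), adapted to a plant cell:
the internal Ca²⁺ store is the vacuole rather than the ER, and the gating
second messenger is an unidentified inositol phosphate, written IPx. The
state is the cytosolic Ca²⁺ concentration `Ci` (µM) and the slow
inactivation gate `h ∈ [0, 1]` (fraction of release channels not
inactivated by Ca²⁺):

    dCi/dt = J_chan + J_leak − J_pump (+ J_in)
    dh/dt  = a (Ci + d_inh) (d_inh/(Ci + d_inh) − h)

    J_chan = p_ipx · O · (C0 − (1 + c1) Ci)
    O      = (IPx/(IPx + d_ipx))³ (Ci/(Ci + d_act))³ h³
    J_leak = p_l · (C0 − (1 + c1) Ci)
    J_pump = v_store · Ci² / (k_store² + Ci²)

Total Ca²⁺ `C0 = Ci + c1·CER` is conserved, with `c1` the store/cytosol
volume ratio, so the store content is `CER = (C0 − Ci)/c1` and the
release driving force vanishes at `Ci = C0/(1 + c1)`. Cubic open-
probability factors encode cooperative IPx binding and Ca²⁺-induced
Ca²⁺ release (CICR); the slow gate `h` encodes Ca²⁺ inactivation and is
what produces single transients and refractoriness instead of sustained
oscillation.

Assumptions inherited with the reduction, kept deliberately:

* **No cytosolic buffering.** The fraction-of-free-Ca²⁺ scaling is
  omitted; concentrations are effective, in arbitrary units anchored to
  µM.
* **C0 constant even with `J_in > 0`.** A constant influx should slowly
  grow the total pool; the balance equations keep `C0` fixed. The
  inconsistency is harmless on the ~10-minute horizon simulated here
  (the `J_in` and no-`J_in` runs differ by ~3 % at the peak) and is kept
  so the equations match their source exactly.
* **The initial state is not a fixed point.** The defaults start at
  `(ci0, h0) = (2, 0.1562)`, from which the unstimulated system relaxes
  toward its resting point (`Ci* ≈ 0.94` µM with influx, `0.59` without).
  The initial values are prescribed as given; `simulate(...,
  equilibrate=True)` optionally relaxes to the resting state first.

### Parameters

Defaults (time in s, concentrations in µM): `p_ipx = 140`, `p_l = 0.05`,
`v_store = 0.5`, `k_store = 0.4`, `d_ipx = 0.1`, `d_act = 0.02`,
`d_inh = 0.04`, `a = 0.001`, `c0 = 7.5`, `c1 = 0.1` (the plant
vacuole/cytosol volume ratio), `j_in = 0.1`, `ci0 = 2`, `h0 = 0.1562`.
The most sensitive are `p_ipx` and `c0` (set the ~6 µM peak scale),
`a` and `d_act` (slow the gating enough to give a single transient), and
`d_inh` (controls refractoriness: larger values let `h` recover faster,
releasing the suppression of a second response). The two-pulse analyses
use `p_ipx = 200` and `j_in = 0`.

### Stimulus and transfer function

The receptor-to-store signaling chain is a black box: simulations are
driven by a normalized IPx amplitude in [0, 1] (used directly as the IPx
concentration in µM), shaped as rectangular pulses with an optional
linear edge ramp (default 0 s — the simplest form consistent with a
stimulus function; the ramp lets users smooth the discontinuity). Two
amplitude↔dose conversions coexist because their sources disagree:

* the fitted power law `y(x) = 8328.75 (x − 0.06)^3.57` (µM), clamped to
  0 at or below the threshold `x0 = 0.06`, with the algebraic inverse
  `x = x0 + (y/A)^(1/p)`;
* the caption anchor table (1 ↔ 480 µM, 0.5 ↔ 240 µM, 0.11 ↔ 480 nM,
  0.06 ↔ 480 pM), interpolated linearly in log-dose.

The power law gives `y(1) ≈ 6.7 mM`, not the 480 µM the anchors assign
to amplitude 1; the units/normalization that would reconcile them are
not stated, so neither is guessed. The anchor table is the default when
emulating experiments (it is what ties the two-pulse protocols to their
doses); the formula and its fitter are exposed for calibration work.
`fit_transfer` recovers `(A, x0, p)` by least squares in log-dose, with
a 200-point grid over the threshold (closed-form slope/intercept at each
candidate) seeding a bounded refinement — log space because doses span
six decades.

## Aequorin calibration

Luminometer counts are converted to Ca²⁺ with the ratiometric
discharge-normalized model: the remaining pool is
`L_max,i = L_tot − Σ_{j≤i} L_j` (inclusive of sample i, matching the
cumulative expression), `r_i = (L_i/L_max,i)^(1/n)`, and

    Ca (M) = (r + r·K_TR − 1) / (K_R (1 − r)),

with `K_R = 7.23×10⁶ M⁻¹`, `K_TR = 120`, `n = 2.99`. The formula itself
is cited rather than printed in the source experimental protocol, so the
implementation is verified structurally: it is the standard model-B
ratiometric form, it is exactly inverted by the synthetic generator's
forward model (round-trip to 0.1 %), and it is invariant under rescaling
of light units. `r < 1/(1+K_TR)` (possible for zero-count samples) is
clamped to Ca = 0 ("below detection"); `r ≥ 1` raises a saturation error
with the offending index. Counts are treated as per-interval totals with
the sampling interval recorded.

## The synthetic generator

No raw luminometer traces are deposited, so all data-facing stages run
on generated stand-ins with recorded ground truth. The generator is a
statistical emulation of the documented features of chitopentaose (Ch5)
responses in tobacco suspension cells, not a mechanistic aequorin model:

* **Transient kernel** — difference of exponentials with a dead-time
  lag: flat baseline (0.1 µM, a typical plant resting cytosolic Ca²⁺)
  until `onset + lag`, then
  `amp · (e^(−τ/decay_tau) − e^(−τ/rise_tau))`, peak-normalized. Defaults
  `lag = 50 s`, `rise_tau = 22 s`, `decay_tau = 120 s` were chosen once
  so the shape reproduces the documented morphology: analytic
  time-to-peak `t* = ln(d/r)·rd/(d−r) ≈ 45.7 s` after onset (≈ 96 s
  after elicitation, inside the one-to-two-minute window), decay to 10 %
  of peak ≈ 346 s after onset (total duration ≈ 6.6 min ≈ the
  seven-minute signal), rise faster than decay.
* **Dose–response** — peak amplitude is a Hill curve in dose
  (`dose_ec50 = 5 µM`, `dose_hill = 0.4`; the shallow exponent spreads
  the rise over the six-decade 48 pM–480 µM dose range), normalized by
  its value at 480 µM so the maximal dose yields exactly the 6 µM peak
  anchor. Because of that normalization the literal "half the maximum at
  ec50" property holds against the curve's large-dose asymptote, not
  against the 480 µM value — the exact 6 µM anchor was kept in
  preference, since every downstream peak check builds on it.
* **Desensitization** — a second response after a first dose `d` is
  scaled by `1/(1 + 15·(d/480 µM)^0.25)`. The exponent is deliberately
  below `dose_hill`, making a weak first elicitation cost a
  disproportionate share of the second response (the curves do not sum
  to a constant), and the strength puts the 480 µM → 240 µM pair at a
  multiplier of 0.0625 ≤ 0.1, i.e. near-complete suppression.
* **Luminescence forward model** — the exact inverse of the calibration:
  per sample the fraction `ratio = r(Ca)^n` of the *remaining* pool is
  emitted (`L_i = ratio·L_rem/(1 + ratio)`, so the discharge-normalized
  ratio is recovered identically), with optional Poisson counting noise
  and pool depletion by the realized counts (initial pool 5×10⁶ light
  units ⇒ ~15 counts/s at baseline, ~10⁵ at peak; a pool left with less
  than one light unit is flagged saturated). A Gaussian-on-Ca noise mode
  exists for tests needing additive noise.
* **Experiments** — a design table (dose₁, optional dose₂, interval;
  default interval 420 s, the "about seven minutes" separation) expands
  to three replicates per row with independent child seeds spawned from
  one master seed; single rows run 540 s, double rows 15 min. Ground
  truth (noise-free Ca²⁺ trace, onsets, amplitudes, analytic
  lag/time-to-peak/duration) is recorded per row. A `truth_source="model"`
  flag substitutes an adapted Li–Rinzel simulation (driven through the
  anchor table) for the kernel as the Ca²⁺ truth.

What the generator does **not** emulate — and hence what passing tests
do not establish about real data: aequorin reconstitution/consumption
kinetics beyond pool depletion, nuclear contamination of the cytosolic
signal, multiphasic or drifting baselines, dose-dependent lag or shape
changes, osmotic artifacts of repeated addition, and realistic
replicate-to-replicate variance (error bars in the source figures are
graphical only; generator variance is configurable, not calibrated).
Tests against it certify the pipeline's internal consistency, not
biological fidelity.

## Feature extraction

Operational definitions (the descriptive quantities have no standard
definition for these transients; thresholds are parameters):

* baseline = median of the pre-elicitation window; noise scale = its MAD;
* onset = first post-elicitation sample above
  `baseline + max(5 % of peak-above-baseline, 3·MAD)`; lag = onset −
  elicitation. On the noise-free default grid (1 s) the detected lag is
  51 s for a true 50 s dead time — the kernel needs one sample to clear
  the 5 % threshold;
* duration = elicitation to the first post-peak return below
  `baseline + 10 % of peak-above-baseline`;
* traces whose maximum never clears the threshold yield a no-response
  record (peak 0, timing features NaN) rather than an error;
* in double-elicitation runs the second response is measured against the
  median of the 30 s immediately before the second stimulus, because the
  first transient has almost but not exactly returned to baseline there;
  the first response is analyzed on the window ending at the second
  onset.

Perturbing the onset/return fractions by ±20 % moves the detected onset
by at most two samples on noise-free traces. Replicate aggregation is
mean ± population SD throughout (the experiments report descriptive
statistics only; no inferential testing is implemented).

## Numerics

* Integration: adaptive Dormand–Prince (scipy `RK45`), `rtol = 10⁻⁶`,
  `atol = 10⁻⁹`, restarted at every stimulus edge so no step straddles a
  discontinuity; dense output sampled on a uniform 0.5 s grid (0.1 s
  where spike timing matters). Halving both tolerances moves the
  reported peak by ~10⁻⁸ relative.
* Solver excursions outside `Ci ≥ 0`, `h ∈ [0, 1]` are clipped in the
  right-hand side and on output; a trajectory exceeding the store
  ceiling `C0/(1+c1)` by more than 0.1 % triggers a warning.
* The unstimulated resting state is found by bracketed root-finding
  (`brentq`) on `J_leak − J_pump (+ J_in)` over `[0, C0/(1+c1)]`.
* Peak agreement with the 6 µM scale is asserted at ±10 %: the target is
  stated qualitatively at that scale and the stimulus shape is
  under-specified, so a tighter band would be false precision.
* Ties and degenerate inputs: zero-dose transients are exactly flat;
  empty designs yield empty experiments; a full discharge in the last
  sample (L_max = 0) is a saturation error, not a division.

## Problem sizes

The test suite and the acceptance script run single-cell ODE
integrations of 600–1100 s at 0.5 s output resolution, synthetic
experiments of 6 doses × 3 replicates (540 s at 1 s sampling) and 3
double-elicitation rows × 3 replicates (15 min at 1 s), and a 600 s
oscillation run at 0.1 s — a few seconds of compute in total, matching
the scale of the experiments being emulated.

## Known limitations

* The model is a single well-mixed compartment: no spatial gradients, no
  K⁺/H⁺/Cl⁻ electrochemistry, no receptor kinetics.
* Parameters are in arbitrary units anchored to µM/s; they were not
  measured in vivo, and no fitting to real traces is provided.
* The two dose↔amplitude pathways are mutually inconsistent (above);
  results that depend on absolute doses should state which pathway they
  used.
* The desensitization law is phenomenological; its functional form and
  strength encode qualitative findings, not measured dose–inhibition
  data.
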