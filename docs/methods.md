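# Methods

This note documents the models, estimators and numerical choices behind
`optopace`, and what the synthetic-data validation does and does not show.

## Membrane model with light-driven capacitance

The membrane is modelled as a purely passive equivalent circuit: a
time-varying capacitance `C(t)` in parallel with the membrane resistance
`R_m` in series with the resting battery `V_rest`. Charge balance on the
membrane node gives

```
d(C(t)·V)/dt = (V_rest − V)/R_m
⇔  C·dV/dt = (V_rest − V)/R_m − V·dC/dt
```

`C(t)` is piecewise exponential: from `C_dark` toward `C_light` with time
constant `tau_C_on` while light is on, back with `tau_C_off` after offset,
continuous everywhere. Two analytic limits anchor the model: with no leak
(`R_m → ∞`) the charge `Q = C·V` is conserved, so an instantaneous drop
gives `V' = V₀·C_dark/C_light` (for small changes `ΔV/V ≈ −ΔC/C`, the
plane-capacitor relation); with slow kinetics (`tau_C_on ≫ R_m·C`) the leak
continuously re-equilibrates the charge and the deflection vanishes. The
kinetics scan in the tests and acceptance script makes this monotonicity an
assertable property: at fixed −12 % ΔC/C, the peak hyperpolarization
magnitude is non-increasing in `tau_C_on` over 0.1–100 ms and approaches
the step limit as `tau_C_on → 0`. This is why equal-amplitude capacitance
drops with different isomerization kinetics can produce voltage transients
differing several-fold.

Deliberate modelling choices:

- **No voltage-gated conductances.** The depolarizing rebound is only the
  passive overshoot of recovery plus capacitance restoration; AP generation
  itself is out of scope here. The circuit above is the minimal one
  consistent with the fixed-charge relation and should be read as an
  interpretation, not a fitted reconstruction of any particular cell.
- **Integrator.** Strang splitting of the two exactly solvable sub-flows —
  the charge-conserving capacitance ratio step `V ← V·C_n/C_{n+1}` and the
  exponential leak relaxation — which is unconditionally stable for this
  stiff problem (`tau_C_on` can be far below `R_m·C ≈ 20 ms`) and *exact*
  in both anchor limits. A precondition `dt ≤ tau_C_on/20` resolves the
  fast transient; step-halving changes the peak by < 0.1 %, and the tests
  cross-check the peak against an independent stiff (Radau) integration.
- **Kinetics presets.** `tau_C_on` defaults of 1 ms and 10 ms are
  illustrative values for the high- and low-concentration loading regimes;
  they are modelling choices, not measured constants.
- **Peak read-out.** Per pulse, the minimum and maximum voltage within
  350 ms of light onset, relative to the mean of the 100 ms before onset.
  The baseline definition is fixed here for reproducibility.

Units follow patch-clamp convention (pF, GΩ, mV, ms): `pF·GΩ = ms` and
`pF·mV/ms = pA`, so no hidden conversion factors appear in the equations.

## Capacitance and resistance from double-sinusoid clamp

The command is `V_hold + A₁sin(2πf₁t) + A₂sin(2πf₂t)`. For an ideal clamp
on a parallel-RC membrane, the current at each frequency separates into a
quadrature (capacitive) component `C_m·A·2πf` and an in-phase (resistive)
component `A/R_m`. The estimator:

1. **Lock-in demodulation** at each frequency (least-squares projection on
   sin/cos after mean removal; window ≥ 3 cycles) gives two independent
   single-frequency capacitance estimates.
2. **Joint fit**: linear least squares of `I(t)` on the analytic command
   derivative, the command offset and an intercept yields the reported
   `(C_m, R_m)`; the intercept absorbs DC offsets such as a holding current.
3. **Model diagnostic**: the two single-frequency estimates coincide iff
   the data-generating circuit really is a parallel RC behind a negligible
   access resistance. A relative disagreement > 5 % flags the fit instead
   of silently biasing it; the tests verify that a 10 MΩ series resistance
   trips the flag for typical cell parameters. Negative fitted parameters
   raise errors naming the offending component; a vanishing capacitive
   component is flagged as degenerate rather than fitted.

Default frequencies (200 and 401 Hz), amplitudes (5 mV) and windows are
package choices: the frequencies are high enough that a short light-pulse
window (pulse + 30 ms tail) still spans ≥ 3 cycles, and high enough that a
realistic access resistance produces a detectable inter-frequency
disagreement. Percent capacitance changes are reported exactly and rounded
to integer percent for display.

## Contraction tracking

The video algorithm avoids cell segmentation entirely — it works even when
the cell edge cannot be delineated or the extremities barely move:

1. The user supplies one bounding box per cell (half-open
   `[x0,x1)×[y0,y1)`, 0-based, origin top-left).
2. Shi-Tomasi corners (minimum-eigenvalue score ≥ `quality_level` × best,
   mutual distance ≥ 4 px, ≤ 100 per box) seed the tracker; fewer than 4
   corners is an error suggesting a larger box.
3. Pyramidal Lucas-Kanade (3 levels, 21×21 window, ≤ 20 iterations to
   0.01 px) tracks each corner between consecutive frames, with a
   forward-backward consistency check: a feature whose round-trip error
   exceeds 1 px is invalidated from that frame on, and once lost it stays
   lost. The tracker is implemented in-package (vectorized over features
   with bilinear resampling) since it is the core of the method.
4. The surviving motion field is averaged into one **similarity transform**
   (uniform scale + rotation + translation) by the closed-form
   least-squares (Umeyama) solve, with one robust refit dropping pairs
   whose residual exceeds 3× the median. Similarity, not affine, because
   the contraction of the cell body toward its centre is isotropic
   shrinkage — and because `scale²` then *is* the box-area ratio.
5. Transforms are composed cumulatively from frame 0 and applied to the
   box; a cumulative scale outside [0.3, 3] emits a drift warning.
6. Contractions are minima of the normalized area with topographic
   prominence ≥ 2 % and separation ≥ 300 ms. Amplitude is the percent area
   reduction relative to the median normalized area in the 1 s before the
   falling edge (a median so that neighbouring dips at fast rates do not
   bias the baseline); velocity is the peak derivative magnitude on the
   falling edge, computed by central differences on a 3-frame moving
   average because raw frame-to-frame differences are noise-dominated.
   Per-window metrics (frequency = events/duration, mean amplitude and
   velocity) use half-open windows; empty windows report 0 Hz with flagged
   undefined amplitude.

The prominence, refractory, KLT settings and the %/s velocity unit are
package choices, exposed in `KLTConfig` and the detector arguments.

## Synthetic data: what it emulates and what it does not

Every generator is bit-deterministic under its seed, and every stated
parameter is measurable on the noiseless output before any pipeline code
runs (pixel counting, direct waveform evaluation) — this is the basis of
all round-trip tests.

- **Contracting cell video**: a static multiscale speckle texture (so the
  tracker has corners) on an elliptical cell over a flat background, with
  one-pixel antialiased rim; contraction is a radial similarity scaling
  about the centroid with a raised-cosine dip profile reaching mask area
  `(1 − area_reduction)`× resting area at the minimum. Defaults — 128×128
  px, 8-bit, 50 fps, semi-axes 40×30 px, additive Gaussian noise of 2
  grey levels clipped to range — stand in for high-speed movies of single
  cells at moderate magnification, whose exact bit depth and frame rate are
  free parameters. Event times come from a fixed rate, explicit times, or
  light onsets plus a latency.
- **Clamp currents**: the parallel-RC current under the double-sinusoid
  command evaluated analytically (including the `V·dC/dt` term when a
  light protocol modulates C); a non-zero access resistance switches to
  exponential-Euler integration of the node equation and serves as the
  estimator stressor.
- **AP trains**: half-cosine upstroke (rise time 2 ms default) and
  plateau-free exponential repolarization whose rate places the 90 %
  repolarization crossing exactly APD90 after the maximal-upstroke time;
  baseline at MDP. Defaults MDP −42.8 mV, APA 70 mV, APD90 300 ms are
  typical for these cells at room temperature.
- **Calcium transients**: linear rise over `t_peak` to `CaD + amplitude`,
  monoexponential decay with `tau_decay`; events closer than the time to
  90 % recovery are rejected as overlapping.

What passing these tests does **not** show: real recordings have
non-stationary baselines, photobleaching, cell-shape changes that are not
pure similarity motions, overlapping cells, electrode drift and seal
instability — none of which the generators emulate. Parameter recovery on
synthetic data validates the estimators' correctness, not their robustness
to every experimental artefact.

## Feature-extraction conventions

- APD90 is measured from the time of `dV/dt_max` (unambiguous and standard)
  to the interpolated downward crossing of `peak − 0.9·APA`; truncated
  final APs are excluded with a flag.
- Instantaneous frequency is `1/inter-event interval`; the "frequency SD"
  clustering indicator is the sample SD of that quantity, and the APD SD
  the sample SD of per-AP APD90 — both shrink when a light train imposes
  fixed-period firing.
- CaD is the minimum over per-segment medians of the pre-onset diastoles
  (up to 500 ms each): the minimum rejects segments still riding a previous
  decay tail. `tau_decay` is a log-linear least-squares fit from the peak
  to 90 % recovery, avoiding the noise-dominated baseline; failures are
  flagged per transient with NaN.
- The responding fraction counts pulses followed by ≥ 1 event within a
  350 ms latency window. Latency histograms fit a gamma distribution by
  maximum likelihood (location 0) as a guide to the eye and report the mode
  `(shape−1)·scale`; degenerate (identical) latencies and n < 5 are flagged
  instead of fitted. The light-locking concentration index is the fraction
  of phase-folded events in the first 10 % of the stimulation cycle
  (≈ 0.10 for events unrelated to the light, 1.0 for perfect locking).
- Percent changes are computed exactly and rounded to integer percent only
  for display; frequencies are displayed at 2 decimals.

## Problem sizes used in validation

The contraction-recovery grid uses 12 videos (rates 0.1/0.25/0.5/1 Hz ×
area reductions 5/10/20 %) of 20 s at 50 fps plus one 40 s two-window
scenario; the estimator noise study uses 100 seeded replicates at 5 pA; the
latency and locking checks use 10⁴ events. These sizes give exact event
counts and sub-percent estimator statistics while keeping the full
validation suite runnable on a laptop in a few minutes.

## Known limitations

- The cumulative transform composition can drift over very long videos;
  re-detection of features is not implemented (the drift warning and the
  local-baseline amplitude definition mitigate this).
- The membrane model cannot produce the AP that follows the rebound in
  real cells, only the passive transient; mechanistic conclusions about
  the delayed depolarization are outside its scope.
- The capacitance fitter assumes an ideal clamp; it diagnoses, but does not
  correct, series-resistance contamination.
- Fura-2 ratios are analysed as ratios; no calibration to absolute calcium
  concentration is attempted.
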