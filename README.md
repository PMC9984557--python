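# optopace

Analysis toolkit for **optical pacing of cardiomyocytes with intramembrane
azobenzene photoswitches** (e.g. Ziapin2). Such molecules partition into the
sarcolemma, dimerize and thin the bilayer — raising membrane capacitance —
and a millisecond pulse of visible light isomerizes them, dropping the
capacitance again. On a beating human iPSC-derived cardiomyocyte this
produces a transient hyperpolarization, a depolarizing rebound that can
trigger an action potential, and ultimately light-locked calcium transients
and contractions.

`optopace` implements the full computational chain a lab needs to quantify
these experiments, together with synthetic ground-truth generators so every
stage can be validated without wet-lab recordings:

| Stage | Module | Core idea |
| --- | --- | --- |
| Membrane model | `optopace.membrane` | passive RC circuit with a light-driven time-varying capacitance: `d(C(t)·V)/dt = (V_rest − V)/R_m`; an instantaneous drop at fixed charge gives `V' = V₀·C₁/C₂` |
| Capacitance estimation | `optopace.capfit` | double-sinusoid voltage clamp: quadrature components give `C_m(f) = I_q/(A·2πf)`, in-phase gives `1/R_m`; a two-frequency disagreement flag diagnoses series-resistance contamination |
| Contraction tracking | `optopace.tracking` | Shi-Tomasi features + pyramidal Kanade-Lucas-Tomasi flow inside a user bounding box, averaged into one similarity transform per frame; the propagated box area has minima at contractions, and `scale²` is exactly the area ratio |
| Trace features | `optopace.features` | MDP / APA / dV/dt_max / APD90, Fura-2 ratio CaD / CaT amplitude / t_peak / τ_decay, pre–light–post window frequencies, responding fractions, latency histograms with gamma guide fits, phase-locking indices |
| Synthetic data | `optopace.synthetic` | contracting textured-cell movies, parallel-RC clamp currents, AP trains and calcium transients, all with known ground truth and bit-deterministic seeds |

## Worked example

Simulate the membrane response to a 20 ms light pulse that relaxes the
capacitance from 22.2 pF to 19.5 pF (a −12 % drop) with 1 ms kinetics, then
quantify the voltage transient:

```python
import optopace as op

params = op.CircuitParams(C_dark=22.2, C_light=19.5, R_m=1.0,
                          V_rest=-42.8, tau_C_on=1.0)
protocol = op.LightProtocol(onsets=(0.1,), pulse_duration=20.0)
trace = op.simulate_photoresponse(params, protocol, dt=2e-5, duration=0.8)
(resp,) = op.peak_light_response(trace, protocol)
print(f"hyperpolarization {resp.hyperpolarization:+.2f} mV, "
      f"rebound {resp.depolarization:+.2f} mV")
print(f"step limit: {op.step_limit_voltage(22.2, 19.5, -42.8):.2f} mV")
```

```
hyperpolarization -5.03 mV, rebound +0.76 mV
step limit: -48.73 mV
```

With 1 ms kinetics the cell transiently hyperpolarizes 5.0 mV below rest —
most of the 5.93 mV fixed-charge limit (−48.73 mV vs rest −42.8 mV). Slower
capacitance kinetics at the same −12 % amplitude produce progressively
smaller peaks, which is the model's explanation for why two loading
conditions with comparable capacitance drops can differ several-fold in
voltage response.

Track contractions in a synthetic movie (or any multi-page TIFF):

```python
spec = op.SyntheticVideoSpec(contraction_rate=0.5, area_reduction=0.10,
                             n_frames=1000, fps=50.0, texture_seed=3)
stack, truth = op.make_contraction_video(spec)
area, events = op.measure_contractions(stack, op.BoundingBox(20, 26, 108, 102))
print(len(events), f"{events[0].amplitude:.1f}%")
```

```
10 10.1%
```

Ten dips at 0.5 Hz, each read out as a ~10 % box-area reduction, matching
the generated ground truth.

The same operations are available from the shell:

```bash
optopace simulate video --config video.yaml --out movie.tiff --seed 3
optopace track --video movie.tiff --rois rois.csv --windows pre:0-10,light:10-20
optopace fit-cap --current I.csv --config patch.yaml --dark-window 0-0.5
```

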