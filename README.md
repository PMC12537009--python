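# ribbonphys

Analysis of inner-hair-cell (IHC) ribbon-synapse physiology, built as a
reusable, tested Python library. It implements the quantitative chain used
to characterize afferent IHC–spiral-ganglion-neuron synapses:

- **Whole-cell voltage clamp** — quality control, p/4 leak subtraction,
  offline liquid-junction-potential correction, IV extraction and Boltzmann
  fractional-activation fitting of Ca_V1.3 currents
  (`I(V) = G_max (V − V_rev) / (1 + exp((V_half − V)/k))`),
  exocytic capacitance jumps ΔC_m (400 ms segments, 100 ms skip), Ca²⁺
  charge Q_Ca, and Lindau–Neher-style membrane-capacitance estimation from
  the measured admittance of the three-element circuit.
- **Single-active-zone Ca²⁺ imaging** — ΔF images, hotspot/plane selection,
  background-subtracted 3×3 ΔF/F₀ traces, merging of two 5 ms-shifted
  voltage-ramp responses into a 5 mV-resolution fluorescence–voltage (FV)
  curve, and the staged modified-Boltzmann / G_max-line fractional-activation
  fit.
- **3D puncta morphometry** — two-channel segmentation (smoothing,
  background subtraction, noise-referenced threshold, watershed splitting),
  half-max volumetry, and one-to-one ribbon–PSD juxtaposition scoring.
- **ABR thresholds** — automated detection (peak-to-peak vs noise-SD
  criterion with an all-higher-levels consistency rule) and group threshold
  shifts.
- **Statistics** — the normality (Jarque–Bera) and variance (F-test) gated
  choice between Student's t and Mann–Whitney, plus Kruskal–Wallis with
  Dunn's post-hoc tests.

Because raw recordings of this kind are rarely shared, `ribbonphys.synth`
generates every input the pipeline consumes — Boltzmann-gated Ca²⁺ currents
with leak-pulse companions, indicator-saturated hotspot movies, pool-depletion
capacitance tracks, log-normal puncta stacks with a controllable pairing
fraction, and ABR level series — each carrying its ground truth, so every
stage is validated by parameter recovery.

Intended users: auditory/synaptic physiologists and methods developers who
want an open, scriptable version of this analysis chain, or a test bed for
evaluating it.

## Worked example

`examples/01_iv_activation.py` simulates one wild-type-like cell (20 ms
steps, 5 mV increments, −87 mV holding, 5 pA current noise), applies the
p/4 and LJP corrections, extracts the IV and fits the activation curve:

```
QC (ruptured): pass
IV: 30 points, minimum -210.9 pA at -17 mV
fit:   V_half = -29.49 mV (truth -29.4), k = 7.07 mV (truth 6.92)
       G_max = 3.94 nS, V_rev = 45.5 mV, |I_max| = 211 pA
```

The fitted `V_half` and `k` say where and how steeply the Ca²⁺ channels
open; their sub-mV agreement with the simulation truth shows the correction
and fitting chain is faithful. The other scripts in `examples/` walk through
the exocytosis (ΔC_m/Q_Ca), single-AZ FV, puncta-juxtaposition, ABR and
statistics capabilities, each printing the recovered quantities next to the
generator truth.

## Layout

```
src/ribbonphys/
  models.py      channel + indicator ground-truth models
  protocols.py   step / dual-ramp command protocols
  synth/         generators: currents, hotspot movies, capacitance,
                 puncta stacks, ABR series
  vclamp.py      IV, activation fits, dCm, Q_Ca, admittance inversion
  imaging.py     dF/F0 and FV analysis
  morpho.py      segmentation, volumetry, juxtaposition
  abr.py         threshold detection and shifts
  stats.py       gated tests, Kruskal-Wallis + Dunn
  io.py          HDF5 / TIFF / CSV round-trips
```

See `docs/methods.md` for the models, parameter choices, and limitations.
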