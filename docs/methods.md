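# Methods

This note documents the models behind `ribbonphys`, the defaults that
matter, what the synthetic generators do and do not emulate, and the
numerical choices made where the design was genuinely open.

## Channel model and whole-cell analysis

The whole-cell Ca²⁺ current is a Boltzmann-gated conductance with an ohmic
driving force,

    I(V) = G_max · P_o(V) · (V − V_rev),   P_o(V) = 1 / (1 + exp((V_half − V)/k)),

plus a linear leak `g_leak (V − V_hold)`. `P_o` *increases* with
depolarization — the physiological convention. Units: nS × mV = pA.

Defaults follow the biology of mature IHC Ca_V1.3 clusters: holding −87 mV,
`V_half ≈ −29 mV`, `k ≈ 7 mV`, and `V_rev = +45 mV`. No reversal potential
is directly measured by this analysis; +45 mV is a typical apparent reversal
for these recording solutions, and the activation fit treats `V_rev` as a
free parameter bounded to [+20, +80] mV (initialized at +45), so recovered
`V_half`/`k` do not hinge on the choice.

Analysis chain per cell:

1. **QC.** Ruptured patch: include iff R_s ≤ 14 MΩ, |leak| ≤ 50 pA at
   holding, rundown ≤ 25%. Perforated patch: |leak| < 30 pA, R_s < 30 MΩ.
2. **p/4 leak correction.** `I_corr = I_test − 4 × mean(leak sweeps)`; the
   generator emits four quarter-amplitude leak-pulse companions carrying
   leak current only (channels are taken as closed at quarter amplitude).
3. **LJP.** Command voltages minus 17 mV, applied offline. The synthetic
   protocols store true membrane potentials; `simulate_current(..., ljp=17)`
   records amplifier-convention commands so the correction is genuinely
   exercised.
4. **IV extraction.** Per step, the 5 ms sliding window inside the
   depolarization with the most inward mean current is averaged (earliest
   window on exact ties). Note this min-search has a small selection bias:
   with 5 pA sample noise it pulls every IV point ≈1–2 pA inward, which
   propagates to a ≈ +0.15 mV bias on the fitted `k` at the default noise.
   This is inherent to "maximal activation region" windowing, not a defect
   of the implementation; noiseless input is recovered exactly.
5. **Activation fit.** Nonlinear least squares of the equation above on the
   IV points. Deterministic initialization: conductances `G = I/(V − 45)`
   normalized to locate the half-activation voltage, `k₀ = 7 mV`. A flat IV
   raises a degenerate-fit error. `i_max` is reported as a magnitude with
   the inward-negative sign stored alongside, since printed conventions
   differ between groups.

**Exocytosis.** ΔC_m is the mean C_m over 400 ms starting 100 ms after the
pulse minus the mean over the 400 ms ending at pulse onset; C_m is undefined
(NaN) during the pulse. Q_Ca is the trapezoidal integral of the
leak-subtracted current over the pulse (pA·ms → pC). The exocytosis summary
reports the fast component (mean ΔC_m for durations ≤ 20 ms) and the
sustained slope (linear fit for durations > 20 ms).

**Capacitance from admittance.** For the series-conductance three-element
circuit (pipette conductance g_s in series with the parallel g_m‖C_m), given
the admittance Y = A + iB at angular frequency ω and the DC conductance
T = g_s g_m/(g_s+g_m), the unique inversion is

    g_s = (A² + B² − A·T)/(A − T),  g_m = T·g_s/(g_s − T),
    C_m = g_s² B / (ω ((g_s − A)² + B²)).

Inputs with B ≤ 0 or A ≤ T are physically inconsistent and rejected. The
forward model ships alongside and the tests verify inversion ∘ forward =
identity to < 0.1% on random circuits.

## Synthetic generators

All generators take an explicit seed (or `numpy` Generator) and are
bit-identical on re-run; there is no global random state. Population
defaults are the study conditions the package targets: whole-cell
populations draw `V_half`/`k` per cell around (−29.4, 6.92) mV for
wild-type-like and (−26.6, 6.98) mV for mutant-like groups with the
corresponding between-cell SDs (2.48/0.46 and 2.94/0.51 mV), peak currents
around 200 pA (SD ≈ 41 pA), and 5 pA current noise.

**Hotspot movies.** Frames at 100 Hz, 103 nm pixels. The local Ca²⁺
concentration at the hotspot is proportional to the instantaneous inward
Ca²⁺ current on the ramp (evaluated at the frame midpoint), shaped as an
isotropic Gaussian spot (σ = 2 px default) and passed through the
saturating indicator `F(c) = f_min + (f_max − f_min) c/(c + k_d)` with
`k_d = 10 µM` (a low-affinity dye). The frame is split into an in-cell
region (resting indicator fluorescence) and an out-of-cell margin at the
camera offset, so an out-of-cell background block is resolvable, as in real
recordings. The Ca²⁺-per-current scale is set so the analytic center-pixel
ΔF/F₀ at peak drive is 1.6 by default (a typical wild-type single-AZ
maximum). Ten baseline frames precede the ramp. Not emulated:
photobleaching, dye diffusion/loading kinetics, the microscope PSF beyond
the Gaussian spot, multiple hotspots per frame — so passing tests show the
*analysis chain* is faithful, not that it is robust to those artifacts.

**Capacitance tracks.** Pool model: ΔC_m(t) = RRP·(1 − e^{−t/τ}) +
r_sust·max(0, t − 20 ms) with defaults RRP = 15 fF, τ = 9 ms,
r_sust = 0.35 fF/ms — realistic IHC values chosen once (the corresponding
figure prints no numbers). Baseline 10 pF, 3 fF track noise, 0.2 ms
sampling.

**Puncta stacks.** Channel-A (ribbon-like) and channel-B (PSD-like) puncta
are spheres with log-normal volumes matching a requested (mean, SD); painting
is saturating (overlaps do not add). Centers sit on a jittered 3D grid that
guarantees same-channel separation ≥ 1.5 µm and keeps orphan-B puncta far
beyond the juxtaposition cutoff from every A punctum; each A punctum gets a
B partner at 0.3 µm offset with probability `pairing_fraction`. Default
voxel size (0.08, 0.08, 0.16) µm, amplitude 150 over noise SD 4.

**ABR series.** 0–120 dB in 5 dB steps. Waveforms have an 8 ms pre-stimulus
baseline; at/above threshold a stereotyped three-peak complex (waves I–III
analog) grows as `growth_rate · (level − threshold + 5)`. Noise is
band-limited (white noise smoothed with a 0.6 ms Gaussian, rescaled to
`noise_sd`), emulating the residual noise of averaged, filtered ABR traces.

## Imaging analysis choices

- The ΔF image subtracts the mean of the baseline frames from the mean of
  the 5 stimulation frames whose command voltage is nearest the expected
  peak-drive voltage (−17 mV default, configurable).
- Plane selection takes the maximal 3×3-smoothed ΔF; within a smoothing
  plateau the brightest raw pixel is the center; earliest plane on ties.
- The background is a 60×60 px block auto-placed maximally distant from the
  hotspot (and rejected if it touches the spot), or user-supplied. F₀ is
  the baseline mean after background subtraction; an F₀ indistinguishable
  from zero raises a "zero baseline" error rather than a division blow-up.
- Each frame is assigned the command voltage at its midpoint (frames
  integrate 10 ms of a moving ramp; the alternative — frame start — would
  shift all voltages by 5 mV). Two 5 ms-shifted 1 mV/ms ramps at 10 ms
  frames interleave to an exactly 5 mV merged grid.
- The "modified Boltzmann" FV model is sigmoid × linear driving force plus
  offset: ΔF(V) = a (V_rev − V) P_o(V) + c. The G_max line is fitted over
  voltages from (fitted FV peak + 10 mV) to (fitted V_rev − 10 mV). The
  lower margin matters: just above the FV peak P_o is still below 0.99, and
  including that region tilts the line and biases the recovered V_half;
  with the +10 mV margin, noiseless recovery is within 0.3 mV. Fractional
  activation is the FV fit divided by the line, clipped to the pre-reversal
  range, and refitted with a plain Boltzmann.
- ΔF/F₀_max is the mean of the 5 consecutive stimulation points centered on
  the trace maximum. Spatial 3×3 averaging reads ≈ 0.86 of the center-pixel
  peak for a σ = 2 px spot, so measured maxima sit slightly below the
  center-pixel analytic value; the generator records both.

## Morphometry choices

Closed-source surface-rendering parameters are mapped to an open pipeline:
"surface detail" 0.07 µm → FWHM of the Gaussian smoothing kernel (as a σ it
erodes the half-max boundary of ~0.3 µm objects by ~15%); "background
subtraction" 0.562 µm → scale of a large-Gaussian background estimate
subtracted before thresholding; "touching object size" 0.4 µm → minimum
separation of watershed markers. The detection threshold is
median + 4·(MAD-based SD) of the background-subtracted stack — a robust
noise reference that bright objects cannot inflate. Watershed markers are
local maxima of a split-scale-smoothed image (flat-topped objects otherwise
sprout spurious noise maxima and oversegment). Each object's volumetric
boundary is then refined at half its own peak intensity, making measured
volumes independent of brightness relative to the detection threshold;
volumes are voxel counts × voxel volume. Objects below 5 voxels are
discarded as noise specks. Juxtaposition uses greedy one-to-one
nearest-centroid matching (optimal assignment behind a flag) with a 0.8 µm
default cutoff — the criterion is centroid distance, not surface contact.

## ABR detection choices

A level is detectable when the response-window peak-to-peak exceeds
`criterion_sd ×` the noise SD estimated from the lowest-level waveform's
pre-stimulus window; the threshold is the lowest level at which that level
*and all higher levels* are detectable. The default multiplier is 6: the
statistic is a range, whose null expectation over the few effectively
independent samples of a band-limited response window is already ≈ 2.5
noise SDs, and the SD estimate itself carries ~25% error from the finite
baseline window — at 4× a sub-threshold false crossing occurs in a sizable
fraction of series, while 6× keeps it rare and a genuine evoked wave (SNR
≥ 10 at threshold) clears it by a wide margin. Raising the criterion can
only raise the detected threshold (monotonicity), which the tests assert.
This detector is a surrogate for expert visual scoring; agreement with
human raters is untested here.

## Statistics

Two-sample comparisons run Jarque–Bera on each sample and a two-tailed
F-test on the variance ratio; Student's t (pooled variance — the gate has
already required variance equality) only when all three p-values exceed
α = 0.05, otherwise Mann–Whitney (exact for n ≤ 25 without ties, else the
tie-corrected normal approximation). For ≥ 3 groups: Kruskal–Wallis with
tie correction, then Dunn's pairwise z tests on pooled mid-ranks with Holm
adjustment by default (Bonferroni and Šidák available). Jarque–Bera has low
power at small n, so the gate is permissive for small samples — exactly as
in common practice. Cells are pooled across animals; no hierarchical
modeling of cell-within-animal nesting is attempted.

## Problem sizes and limitations

The test and acceptance runs use desk-scale populations (14/25 whole cells,
50 AZ movies, ~300 puncta across 14 stack "cells", 200 ABR series), matching
the published group sizes where those exist. Known limitations: no R_s
compensation or capacitive-transient modeling (sweeps represent
post-compensation data); no GHK permeation or stochastic gating; no
deconvolution or PSF modeling; the ABR detector does not label waves I–V;
volumes below ~30 voxels carry voxelization error of several percent.
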