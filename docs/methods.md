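# Methods

`nanoecho` models the automatic echographic detection of halloysite clay
nanotubes (HNTs) dispersed in a layer of tissue-mimicking agarose gel,
imaged with a clinical 10 MHz linear probe whose raw radio-frequency (RF)
backscatter is analysed off-line.  The package covers four stages —
dosimetry, RF simulation, sliding-window feature extraction, rule-based
detection — plus the evaluation and orchestration around them.  This
note records the model, its assumptions, the defaults and why, and what
a green test does and does not establish.

## 1. Dosimetry

An HNT is modelled as a hollow circular cylinder of outer diameter
*d*ₒ = 50 nm, lumen diameter *d*ᵢ = 15 nm and representative length
*L* = 1000 nm, with halloysite mass density ρ = 2.55 g/cm³.  The wall
volume is V = π/4 · (*d*ₒ² − *d*ᵢ²) · *L* ≈ 1.787 × 10⁶ nm³, so the four
nominal doses 0.25 / 0.75 / 1.50 / 3.00 mg/mL correspond to 5.49 / 16.5
/ 32.9 / 65.8 × 10¹⁰ part/mL — within 0.3 % of the rounded values 5.5 /
16.5 / 33 / 66 × 10¹⁰ usually quoted for these doses.  *L* = 1000 nm is
the midpoint of the 500–1500 nm length polydispersity range and is the
only length consistent with all four quoted number concentrations;
length polydispersity itself is not modelled.  Loose outer
aluminosilicate sheets (1–2 nm) are gravimetrically negligible and
ignored.

Mean inter-particle spacing scales as *n*^(−1/3) for a uniform
dispersion; doubling the number density shrinks it by 2^(−1/3) ≈ 20.6 %.

## 2. RF simulation

### Geometry and acquisition chain

The phantom is three horizontal layers — ~8 mm pure gel, ~15 mm
HNT-loaded gel, ~8 mm pure gel — under a 10 mm water standoff
(interfaces at 10 / 18 / 33 / 41 mm depth by default).  The default
acquisition mirrors a clinical bench setup: 10 MHz Gaussian pulse with
60 % fractional bandwidth, RF digitized at 50 MHz / 16 bit, frames of
152 tracks × 2980 samples (0.25 mm track pitch), linear TGC of 1 dB/cm,
12 fps while the probe sweeps laterally at 12.5 mm/min, focus at 2 cm.

Each track is synthesized as a 1-D convolution of the depth-sampled
scatterer reflectivity with the pulse; scatterers contribute with a
Gaussian lateral beam weight (0.6 mm FWHM — the focal beam width of a
10 MHz array, *not* the 1.5 mm analysis-window resolution, which the
6-track window provides).  Frequency-dependent attenuation
(α·f·2z dB, α = 0.1 dB/cm/MHz) is applied in 50 %-overlap Hann depth
zones; white electronic noise is added at 30 dB SNR; TGC and 16-bit
quantization close the chain.  One ADC scale is shared by all frames of
a sweep.  **α = 0.1 dB/cm/MHz, not a soft-tissue 0.5:** 0.4 % wt/vol
agarose is a weakly attenuating, nearly water-like gel; a tissue-level
α at 10 MHz would impose a ~25 dB depth ramp and an ~0.8 MHz spectral
downshift *within* the loaded layer that the bench images do not show.

### Scatterer field

Background gel micro-heterogeneity: Poisson-placed scatterers at 30 per
resolution cell (beam FWHM × pulse −6 dB axial extent) with Gaussian
amplitudes scaled so the *power* per cell is fixed at 10 amplitude
units² — the density sets speckle statistics (30/cell gives fully
developed, Rayleigh-enveloped speckle), the power sets gel echogenicity,
and the two do not interact.

HNT scatterers are placed in the loaded layer with an effective count of
1 per cell per 10¹⁰ part/mL, capped at 50 per cell; under the cap the
per-scatterer amplitude is multiplied by √(cap ratio) so mean
(incoherent) backscattered power remains proportional to concentration.
Each HNT scatterer carries a Rayleigh tag: its echo is the pulse shaped
by (f/f_c)², the long-wavelength scattering law for deep-subwavelength
solid particles — the spectral signature that detection exploits.
`hnt_amplitude_scale = 0.5` makes the loaded layer a few dB brighter
than gel at 33 × 10¹⁰ part/mL: a modest, realistic enhancement (strong
enough to see, far too weak for trivial brightness thresholding — which
matches the observation that log compression makes brightness gains
marginal at these doses).

Clustering: with probability `clustering_coefficient · c / 33 × 10¹⁰`
an HNT scatterer is selected, and selected scatterers closer than half a
resolution cell are merged pairwise into a single scatterer with summed
(signed) amplitude that **loses the Rayleigh tag** — a cluster behaves
as one effectively larger particle outside the f² regime.  Random signs
mean merging conserves expected power, so increasing concentration
keeps increasing brightness while *diluting* the spectral signature:
this is the mechanism by which detectability peaks at an intermediate
concentration.  The default coefficient 0.25 is calibrated so the
66 × 10¹⁰ part/mL case visibly degrades.

Per-phantom echogenicity jitter (3 dB SD, log-normal) multiplies every
scatterer amplitude, emulating gel-batch, coupling and system-gain
variability between samples; it is drawn before anything else so equal
seeds share it across concentrations (paired comparisons stay clean).
Its role is to make *absolute* amplitude an unreliable discriminant
across replicate phantoms, as on a bench.

### What the simulator does not model

No diffraction or elevation dimension, no transducer element geometry,
no water-standoff reverberations (the bench's main specificity hazard),
no HNT sedimentation or spatial concentration gradients.  A green
end-to-end test therefore establishes that the *analysis chain* behaves
correctly on speckle with a known spectral contrast — not that the
bench accuracies are reproduced.

## 3. Features

Each analysis window (6 tracks × 70 samples ≈ 1.5 mm, translated with
configurable strides, assigned to its center pixel) yields 25 features:

* **f1–f10, spectral** — from a Welch periodogram (35-sample Hann
  sub-segments, 50 % overlap, zero-padded to 256 points, averaged over
  segments and tracks): linear-fit slope/intercept/midband value of the
  dB spectrum over the analysis band (the −30 dB pulse support,
  3.3–16.7 MHz), peak frequency, power-weighted centroid, −6 dB
  bandwidth, integrated backscatter, normalized spectral entropy,
  spectral flatness, low/high half-band energy ratio.  Spectra are
  normalized to window total power (no reference-phantom calibration),
  so absolute-gain effects cancel.
* **f11–f17, wavelet** — 4-level Daubechies-4 sub-band energies per
  track pooled over the window (relative energies d1–d4 and a4, their
  normalized entropy, d1/d4 ratio).  PyWavelets is not a dependency;
  the 8-tap filter bank is implemented directly (periodized, energies
  only).
* **f18–f25, envelope/statistics** — analytic-signal envelope mean, SD,
  SNR (mean/SD, capped at 10⁶ for degenerate windows), skewness, excess
  kurtosis, Nakagami shape m = E²[x²]/Var(x²) and scale Ω = E[x²]
  (method of moments), and the RF zero-crossing rate in MHz.

Welch averaging and the wider −30 dB band were chosen to cut the
variance of the spectral estimates (≈2× over one full-window
periodogram); with a 0.6 mm beam the six tracks contribute ≈2.5
independent looks.  All-zero windows are flagged degenerate (NaN).

## 4. Rule-based detection and training

A configuration is a subgroup of features with one acceptance interval
each; a pixel is colored iff every selected feature lies inside its
interval.  Widening an interval can only turn pixels on (monotone).

Training selects among the 22 gain-invariant features by default: the
three absolute-amplitude descriptors (envelope mean, envelope SD,
Nakagami scale Ω) are computed and classifiable but not thresholded in
training, because raw echo amplitude in ADC units is not calibrated
across phantoms or acquisitions — gain, coupling and gel echogenicity
all drift — and the reference workflow is a spectral/wavelet analysis.
(`TrainingConstraints.eligible_features` overrides this.)

Training emulates the bench's progressive manual optimization under its
three criteria — selective detection of the loaded layer, minimal false
positives outside it, minimal false coloring of a pure-gel control —
as a deterministic greedy search.  Candidate intervals per feature are
quantile ranges of the pooled in-layer distribution: central ranges at
coverages {0.95, 0.9, 0.8, 0.7, 0.6, 0.5} plus the matching one-sided
ranges (one-sided candidates lose no sensitivity on the side where the
background never lies).  Starting from "everything colored", steps are
added greedily; while the constraints (specificity ≥ 95 %, control
colored fraction ≤ 5 %, sensitivity ≥ 10 %) are unmet, the step
maximizing sensitivity − λ·(constraint gap) is taken, λ being swept
over a small grid with the most sensitive admissible result kept; once
admissible, selection stops, since any further conjunction loses
sensitivity.  The minimum-sensitivity floor rejects degenerate
configurations that satisfy the false-positive criteria by coloring
essentially nothing.  If no admissible configuration exists, training
fails explicitly; the experiment runner then records the all-false
detector (sensitivity 0, specificity 100, DSC 0) for that arm —
operationally, "no usable setting was found at this dose".

Corrected true positives subtract the mean number of pixels falsely
colored inside the *virtual layer region* of the control phantom
(floored at zero), the direct analog of the bench correction; both raw
and corrected sensitivity/DSC are computed, corrected being the
headline.  Specificity always uses the raw false positives of the
target phantom.

## 5. Evaluation

Confusion counts are taken on the feature grid inside a region of
interest spanning the full lateral extent and the phantom depth range,
with a 70-sample guard band at the frame edges.  Sensitivity,
specificity and DSC follow the standard formulas; undefined
denominators are flagged NaN and excluded from averages with a logged
count.  Averaging is two-stage: frames within a replicate sweep, then
across replicate phantoms; the reported dispersion is the SD across
replicates.

Frames are split alternately (even indices train, odd evaluate), so
training and evaluation frames come from the same slow sweep; at
12.5 mm/min and 12 fps consecutive frames are ~17 µm apart and strongly
correlated — as in the bench protocol, this evaluates the
configuration, not generalization to a new phantom.

## 6. Desk scale vs bench scale

The bench protocol (850-frame sweeps, 300 analysed frames, stride-1
windows, 3 replicates + 3 controls) is available via
`ExperimentConfig.paper_scale()` but takes hours.  The desk-scale
default — 20 frames per sweep, stride 2 tracks × 10 samples, 3
replicates + 1 control — runs the 33 × 10¹⁰ arm in ≈5 min on one CPU.
The four-concentration DSC-trend experiment is scaled further (2
replicates, 6 frames, stride 3 × 20) to stay within a desk-time budget;
at that scale the *trend* (DSC peaking at an intermediate
concentration) is the reproducible object, not the absolute values.

Seeds: every stage derives its generator from
`(master_seed, concentration index, replicate)` (controls use stage tag
99) via NumPy `SeedSequence`, so any subset of an experiment reruns
bit-identically in isolation.

## 7. Known limitations

* Bench accuracies measured on physical phantoms with proprietary
  analysis software and undisclosed parameter settings are not
  reproduction targets; only the qualitative structure — specificity
  ≥ 95 % at every dose and a DSC peak at 33 × 10¹⁰ part/mL rather than
  at the highest dose — is checked here.
* The 25-feature set is this package's documented substitute for an
  undisclosed parameter list; results are reproducible against *this*
  definition only.
* Interval rules are conjunctive only; no disjunctions, no learned
  classifiers.
* The simulator's concentration axis is an *effective* scatterer
  density (capped, power-conserving), not a particle-level model; its
  absolute sensitivity values depend on the chosen contrast defaults
  and should be read as a working point, not a prediction.
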