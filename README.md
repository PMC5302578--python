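# nanoecho

Simulation and automatic echographic detection of nanoparticle-loaded
tissue layers from raw radio-frequency (RF) ultrasound backscatter.

Halloysite clay nanotubes (HNTs) — hollow aluminosilicate cylinders
~50 nm wide and ~1 µm long — are candidate drug carriers that also act
as solid ultrasound contrast agents. At clinical frequencies they do not
resolve individually; instead they imprint a spectral signature on the
backscattered RF signal: as deep-subwavelength solid scatterers their
echo amplitude grows as f² (Rayleigh regime), up-shifting the local
spectrum. `nanoecho` builds the full analysis chain around that physics:

* **dosimetry** — convert HNT doses between mass (mg/mL) and particle
  number (part/mL) via the hollow-cylinder volume
  V = π/4·(d₀² − dᵢ²)·L and ρ = 2.55 g/cm³, and the n^(−1/3) scaling of
  mean inter-particle spacing;
* **rfsim** — a seeded point-scatterer speckle simulator of three-layer
  agarose phantoms (pure gel / HNT-loaded / pure gel) scanned by a
  10 MHz linear probe: Gaussian pulse, per-track convolution with
  lateral beam weighting, f-dependent attenuation, TGC, electronic
  noise, 16-bit quantization, slow lateral sweep; concentration-
  dependent clustering merges nearby particles into single bigger
  scatterers that lose the f² signature;
* **features** — a sliding analysis window (6 tracks × 70 samples
  ≈ 1.5 mm) summarized by 25 spectral / wavelet / envelope parameters
  (spectral slope, intercept, midband fit, centroid, Daubechies-4
  sub-band energies, Nakagami moments, ...);
* **rules** — per-pixel detection as a conjunction of per-feature
  acceptance intervals, trained per concentration by a deterministic
  greedy search under three criteria: selective detection of the loaded
  layer, minimal false positives outside it, minimal false coloring of
  a pure-gel control;
* **metrics / pipeline** — pixel confusion counts inside a region of
  interest, sensitivity = 100·TP/(TP+FN), specificity = 100·TN/(TN+FP),
  DSC = 100·2TP/(2TP+FN+FP), control-corrected TP, two-stage averaging
  (frames within replicate, then across replicates), and the end-to-end
  experiment over the four doses 5.5 / 16.5 / 33 / 66 × 10¹⁰ part/mL.

See `docs/methods.md` for the model details and assumptions, and
`examples/` for one narrative script per capability.

## Worked example

```sh
python examples/01_dosimetry.py
```

```
particle wall volume: 1.787e+06 nm^3
 0.25 mg/mL  ->    5.49 x 10^10 part/mL
 0.75 mg/mL  ->   16.46 x 10^10 part/mL
 1.50 mg/mL  ->   32.92 x 10^10 part/mL
 3.00 mg/mL  ->   65.84 x 10^10 part/mL

doubling the number density multiplies the mean inter-particle spacing by 0.7937 (a 20.6% decrease)
```

The four numbers reproduce the nominal dose table (5.5, 16.5, 33,
66 × 10¹⁰ part/mL) to better than 1%, confirming that a 1000 nm
representative tube length is consistent with all four doses at once.

A full detection run at the optimal dose (three replicate phantoms plus
a control, 20 frames each, ~5 min):

```python
from nanoecho import ExperimentConfig, run_experiment

cfg = ExperimentConfig(concentrations=(33e10,), replicates=3,
                       frames_per_acquisition=20, master_seed=42)
r = run_experiment(cfg).per_concentration[33e10]
print(r.metrics.sensitivity, r.metrics.specificity, r.metrics.dsc)
```

prints held-out sensitivity ≈ 59%, specificity ≈ 95% and DSC ≈ 72%: the
trained configuration colors most of the loaded layer while staying
within the 95% specificity and 5% control-coloring constraints.

Across the four doses, `examples/05_full_experiment.py` (one replicate
per dose, coarse stride, ~4 min) prints:

```
 conc (1e10/mL)   sens %   spec %    DSC %
            5.5      6.9     95.1     12.3
           16.5     38.6     95.4     53.8
           33.0     58.7     95.3     71.7
           66.0     41.6     95.0     56.6
```

DSC rises steeply to its peak at 33 × 10¹⁰ part/mL and falls again at
66 × 10¹⁰, where particle clustering merges neighbours into effectively
larger scatterers and erodes the f² spectral signature faster than the
extra particles add to it — the characteristic dose-response of
spectral nanoparticle detection at a fixed frequency.

## Acceptance script

```sh
python scripts/acceptance.py --seed 42 --out results/acceptance.json
```

re-runs the scaled-down end-to-end experiment at 33 × 10¹⁰ part/mL from
scratch (simulation → features → training → held-out evaluation) and
writes the measured held-out specificity (percent, two-stage averaged)
as target `t5`, with the number of evaluated frames.
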