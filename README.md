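# fibriq

Quantitative morphometry of fibrillin microfibrils and aortic
tissue-section analysis, built for studies of vascular extracellular-matrix
remodelling (e.g. in experimental diabetes).

Fibrillin microfibrils imaged by atomic force microscopy (AFM) appear as
"beads on a string" with a characteristic bead-to-bead repeat
(*periodicity*) near 56 nm. Damage to the microfibril shifts and splits
the periodicity distribution and fragments the chains, so two simple
numbers — the repeat distance and the number of beads per chain — act as
structural biomarkers. At the tissue scale, the same remodelling shows up
in stain area fractions, medial-layer thickness, regional protease
(gelatinase) activity and the local acoustic wave speed of the wall.

`fibriq` implements the full measurement chain:

* **`fibriq.synthetic`** — ground-truthed generators: periodicity samples
  from truncated Lorentzian (Cauchy) mixtures, chain-length samples from a
  moment-matched log-normal, AFM-like height images of beaded chains, and
  layered tissue sections with known lamellar geometry, stain coverage and
  regional wave-speed fields.
* **`fibriq.afm`** — height-image morphometry: per-scanline baseline
  compensation, artifact masking, bead detection with sub-pixel centroids,
  greedy chain linking, and periodicity/length measurement.
* **`fibriq.stats`** — the statistical layer: least-squares fits of
  k ∈ {1, 2} Lorentzian peaks A·γ²/((x−x₀)² + γ²) to the binned periodicity
  histogram, AIC-guarded modality selection, extension fractions with
  Wilson intervals, and Mann–Whitney / Kolmogorov–Smirnov / Kruskal–Wallis
  comparisons.
* **`fibriq.tissue`** — stain coverage as % tissue area, cubic-spline wall
  straightening, medial-thickness profiles, background-subtracted
  gelatinase intensity per μm², and the plane-wave relation
  υ_L = √(C11/ρ) with C11 = E(1−ν)/((1+ν)(1−2ν)) linking acoustic wave
  speed to Young's modulus.

Every routine is validated end-to-end against the synthetic generators,
whose defaults encode population values reported for healthy and
diabetic rat aorta (unimodal 56 nm control repeats; 51/73 nm bimodal
damaged repeats; chain lengths 21 ± SD 13 vs 18 ± SD 19 beads).

## Worked example

```python
import fibriq as fq

control  = fq.sample_periodicities(fq.CONTROL_PERIODICITY, 500, seed=1)
diabetic = fq.sample_periodicities(fq.DIABETIC_PERIODICITY, 500, seed=2)

fit_c = fq.fit_lorentzian(control, k=1, bin_width=2.0)
fit_d = fq.fit_lorentzian(diabetic, k=2, bin_width=2.0)
frac  = fq.fraction_above(diabetic, 65.0)
ks    = fq.compare_samples(control, diabetic, test="ks")

lengths = fq.sample_chain_lengths(*fq.CONTROL_LENGTH, 5, seed=7)
img, truth = fq.render_chain_image(
    fq.CONTROL_PERIODICITY, lengths, fq.ChainRenderConfig(rng_seed=5))
res = fq.analyze_image(img)
```

prints (via the obvious f-strings):

```
control centre : 55.7 nm  (R^2 = 0.98)
diabetic centres: 50.9 / 72.8 nm  (R^2 = 0.96)
modality        : control k=1, diabetic k=2
extended >65 nm : 31.8% (95% CI 27.9-36.0%)
KS test         : D = 0.29, p = 6.21e-19
image pipeline  : 5 chains, 79 beads (truth 79), mean periodicity 57.0 nm (truth 57.0 nm)
```

The unimodal fit recovers the 56 nm repeat; the two-component fit
recovers the 51/73 nm split; roughly 30% of damaged repeats sit extended
above 65 nm; the two periodicity distributions separate decisively; and
the image pipeline recovers every rendered bead and the true mean repeat
of the drawn chains.

A thin CLI mirrors the library
(`fibriq generate|afm|stats|tissue ... --help`).

## Documentation

`docs/methods.md` describes the models, the generator's assumptions and
limits, parameter defaults with units, and the numerical choices.
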