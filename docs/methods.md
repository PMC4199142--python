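# Methods

## Scope and model

The package quantifies two scales of vascular extracellular-matrix
structure:

1. **Molecular scale.** Fibrillin microfibrils are beaded polymers; the
   repeat between consecutive beads (periodicity, nm) and the bead count
   per chain (length) are the readouts. Periodicity populations are
   modelled as mixtures of Lorentzian (Cauchy-shaped) peaks
   A·γ²/((x−x₀)²+γ²) fitted to binned histograms; a healthy population is
   one peak near 56 nm, a damaged one splits into two resting
   populations (51 and 73 nm by default).
2. **Tissue scale.** The aortic media is an alternation of thin elastic
   lamellae and thicker inter-lamellar (smooth-muscle) spaces. Readouts:
   stain coverage as a percentage of tissue area, medial thickness
   perpendicular to the intima after spline straightening, regional
   fluorescence (gelatinase) intensity per μm², and per-region acoustic
   wave-speed statistics. Wave speed and Young's modulus are tied by the
   isotropic plane-wave relation υ_L = √(C11/ρ),
   C11 = E(1−ν)/((1+ν)(1−2ν)); the conversion is algebraic in both
   directions and valid for −1 < ν < 0.5.

All validation is by parameter recovery on synthetic data whose
generating parameters encode population values reported for healthy and
diabetic rat aorta.

## Synthetic generator: what it emulates, and what it does not

**Periodicity presets.** Truncated Lorentzian mixtures on [30, 120] nm.
The truncation bounds are a biological-plausibility choice: repeats
outside that window are not credible bead spacings, and published
periodicity histograms span roughly that range. Component half-widths
default to 3 nm — narrow enough that 51 vs 73 nm peaks are visually and
statistically distinct while a single 56 nm peak stays clean; the source
data do not constrain them directly, so they are a modelling choice
(configurable). The damaged-population mixture weight defaults to
0.7/0.3 (lower/upper), calibrated so that the mass above 65 nm is ≈ 30%,
the reported order of the extended fraction. Sampling is by component
choice then Cauchy draw, with rejection outside the truncation window;
accepted component frequencies therefore equal the
truncation-renormalized weights (verified by χ² test).

**Combed (tensioned) presets.** Molecular combing applies ~4 nN of
capillary tension and shifts mass to longer repeats. This is emulated
purely distributionally — single Lorentzians at 58 nm (γ = 5) and 60 nm
(γ = 6), putting roughly 38% and 52% of repeats above 60 nm — with no
mechanical model of combing.

**Chain lengths.** Log-normal moment-matched to a (mean, SD) pair,
rounded, with draws below 2 beads rejected. Positive skew is forced by
the data themselves: an SD of 19 beads at a mean of 18 is impossible for
any near-symmetric positive law. Defaults: (21, 13) control,
(18, 19) damaged. A `stratified=True` flag draws one value per
equal-probability quantile stratum (Latin hypercube; the unbounded top
stratum is represented by its conditional mean). The marginal law is
unchanged but the sample mean is pinned near the population mean
(SD ≈ 0.1 beads at n = 100 instead of 1.9); this is the right sampling
design when the lengths feed a recovery benchmark, where iid input noise
would otherwise dominate the quantity being measured.

**Chain images.** Beads are radially symmetric Gaussian bumps
(σ = bead_radius/2) laid along smooth random paths with bounded turn per
step (≤ 50°), so Euclidean bead spacing is the sampled repeat exactly.
Paths keep 200 nm clearance from other chains and 140 nm from their own
non-adjacent beads — above the 125 nm link ceiling, so ground-truth
chains can never be confused by proximity alone. Scanline offsets
(per-row constants), white pixel noise and optional large blob artifacts
are added; offset and noise fields are drawn from the RNG even at zero
amplitude, so two renders of one seed differ only in those terms.
Defaults: 4 nm/px, 1024² px, bead amplitude 10, bead radius 10 nm, noise
SD 1 (10% of amplitude), offset SD 2, no artifacts. Not emulated: AFM
tip convolution, cantilever dynamics, capillary forces, height
saturation, drift. Passing recovery tests on these images shows the
analysis chain is correct and unbiased under the stated noise model —
not that it is robust to every real-world AFM artifact.

**Tissue sections.** Straight-band or annular walls with n lamellae of
configurable thickness (defaults: 7 lamellae × 3 μm with 11.5 μm
inter-lamellar spaces → a 90 μm wall). The stain channel covers an exact
pixel count (a smoothed random field thresholded at the requested
quantile), so the realized fraction equals the request to within half a
pixel's worth of area. Fluorescence is flat per region plus Gaussian
noise; wave speed is drawn per region, with an optional mixture for the
inter-lamellar region to emulate bimodal behaviour. Voids can be carved
to exercise the tissue-only counting rules.

## AFM morphometry: algorithmic choices

* **Scanline compensation.** Order 0 removes per-row medians; order 1
  (default) fits a robust per-row line using only pixels within 3 robust
  σ of the row median, so beads do not drag the baseline, then pins the
  row median of the remainder to zero. The compensation is applied,
  artifacts are identified, and the compensation is applied again with
  artifact pixels excluded from the baseline estimate.
* **Artifact rule.** Blobs whose height exceeds median + 4 robust σ
  *and* whose connected area exceeds 200 px (far larger than a bead) are
  excluded, with a 2 px dilation for skirts. A zero-spread (saturated)
  raster is wholly excluded. The robust-threshold blob rule is this
  package's own replacement for the manual artifact marking of classical
  semi-automated routines.
* **Detection.** Gaussian smoothing at σ = 5 nm (half the default bead
  radius, clamped to ≥ 1 px with a warning), 3×3 local maxima above a
  prominence threshold (default 5 robust σ of the smoothed raster, with
  a 2%-of-peak floor for noise-free rasters), greedy suppression of
  peaks closer than 30 nm (below the smallest plausible repeat) in
  descending height order with row-major tie-break, and sub-pixel
  refinement by centre of mass of the positive 5×5 neighbourhood. Maxima
  within two smoothing σ of the frame edge are ignored (border
  reflection makes them unreliable). Detection operates on a polarity
  flag; the classical display inversion (dark beads on light ground) is
  provided but never changes coordinates.
* **Linking.** Candidate pairs within 125 nm are admitted shortest-first
  (ties to the smaller index pair) subject to: at most two links per
  bead, no cycles, and turn angles ≤ 60°. The 125 nm ceiling sits just
  above the 120 nm truncation bound of the repeat distribution; a
  ceiling below it would sever a few percent of genuine links (the
  Lorentzian tail) and fragment long chains, visibly biasing length
  recovery. Singletons are discarded.
* **Measurement.** Periodicity is the Euclidean distance between
  consecutive centroids; length is the bead count (repeats = count − 1;
  both views are recoverable). Chains with fewer than two beads are
  excluded and logged.

## Statistics

Fits are nonlinear least squares on binned counts (bin width 2 nm by
default; recovery is insensitive across 1–5 nm, which the test suite
checks) — histogram-domain fitting is deliberate, matching how such
periodicity histograms are conventionally modelled, rather than raw-value
maximum likelihood. Initialization takes the tallest histogram mode plus,
for k = 2, the farthest secondary mode ≥ 10% of the maximum; five
multistarts (first unjittered, the rest jittered with a fixed internal
seed, so fits are deterministic) guard against local minima; convergence
tolerances are 1e-8. R² is computed over bins and reported
dimensionless. Modality selection returns bimodal only when the
two-component fit lowers the binned-residual AIC *and* separates its
centres by more than 3 bin widths — the guard stops a second component
from merely re-fitting one peak's shoulders. Extension fractions use
strict inequality and a Wilson 95% interval. Group comparisons are the
standard two-sided Mann–Whitney, two-sample KS and Kruskal–Wallis tests
(scipy implementations); p-values are uncorrected, and summaries report
mean, SD (n−1), SEM and n, with SD/SEM undefined at n = 1. Pooled and
per-animal summaries can coexist in one table.

## Tissue quantification

Thresholds default to Otsu computed on the relevant channel (tissue
restricted where sensible); fixed thresholds are supported for exact
reproducibility; a constant channel degenerates to "on iff positive".
Straightening fits a cubic spline (periodic when the centerline closes)
through ≥ 4 control points, resamples at exact 1 px arc-length steps and
bilinearly interpolates along local normals; it refuses configurations
whose curvature radius falls below the sampling half-width (the normals
would self-intersect). Thickness is the per-column count of medial
tissue pixels × pixel scale — voids are simply absent from the mask —
with empty columns excluded and logged. Gelatinase intensity subtracts
the median of a user-designated off-tissue area (or a scalar), clips
negatives, and reports each region's mean divided by the pixel area;
zymography strips default to 100 px wide, spanning the medial depth
perpendicular to the intima (an alternative width is a parameter, not a
code path). Per-region wave-speed statistics reuse the modality
selector with 10 m/s bins; a constant region is unimodal by definition
and regions under 50 px get no call.

## Problem sizes and determinism

Recovery benchmarks use 500-value periodicity samples (a typical
per-animal sampling depth), 100 chains per group rendered five per
2048² field (8.2 × 8.2 μm at 4 nm/px), 20-seed repetition for
classification rates, 100 seeds for KS power and 200 for the
Kruskal–Wallis null. These sizes put Monte-Carlo error comfortably below
every tolerance asserted. All randomness flows through
`numpy.random.default_rng` seeds; a fixed seed reproduces samples,
images, truth tables and fits bit-for-bit.

## Known limitations

* The bead detector assumes approximately radially symmetric bumps and a
  roughly stationary background after flattening; strongly anisotropic
  tip artifacts would bias centroids.
* Greedy linking has no global objective; pathological bead
  configurations (crossings at shallow angles, spacing at the link
  ceiling) can split or merge chains. The generator's clearances mean
  such cases are absent from the validation data by construction.
* Lorentzian fitting on histograms inherits binning noise; centre
  recovery is ±1–2 nm at n = 500, not asymptotically exact.
* The wave-speed/modulus conversion assumes an isotropic, homogeneous,
  non-dispersive medium at the measurement frequency; no acoustic signal
  processing is included.
* Stain "colour" handling is single-channel thresholding; no colour
  deconvolution of real histology stains is attempted.
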