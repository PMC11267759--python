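# Methods

`stellaquant` reimplements, as one tested package, the quantitative layer of
a hepatic stellate cell (HSC) activation study: label-free holotomographic
(HT) imaging of lipid droplets, mitochondrial-network morphometry from
MitoTracker stacks, confocal Raman mapping of vitamin A and lipids,
2D fluorescence quantification, and the surrounding assay arithmetic and
statistics. Because the raw microscopy of such a study is not portable,
every analysis stage is paired with a seeded synthetic-data generator that
plants known objects and returns them as machine-readable ground truth, so
correctness is established by parameter recovery rather than inspection.

## Coordinate and unit conventions

Voxel indices are 0-based `(z, y, x)`; the physical position of a voxel is
its center, `(i + 0.5) · d` in µm. All lengths are µm, volumes µm³,
wavenumbers cm⁻¹. Refractive-index plateaus in the HT generator are medium
1.337, cytoplasm 1.350, lipid 1.380 — the ordering (lipid well above
cytoplasm) is what makes droplets conspicuous in HT imaging.

## Synthetic-data generators (`synth`)

Every generator is a pure function of `(params, seed)`; rerunning
reproduces byte-identical arrays.

**HT volumes.** One smooth ellipsoidal cell (semi-axes 0.84 of each
half-extent, sigmoid shoulder ≈ 2 voxels wide) on a flat background;
`n_droplets` (default 20) non-overlapping spheres packed wholly inside the
cell by rejection sampling, largest-first (draw-order placement stalls at
this density), with a 10 000-attempt cap that raises a `PackingError`.
Default grid 64³ at 0.25 µm isotropic (16 µm field), droplet radii uniform
in [0.5, 2] µm. Noise is additive Gaussian with
`sd = (cell − background) / snr`, default `snr = 5`; `snr = inf` gives the
noise-free mode used by exact tests. Real HT noise statistics are
instrument-specific and not public; the Gaussian model is a stand-in, so
passing recovery tests demonstrates correctness of the pipeline under this
noise model, not performance on any particular instrument.

**Mitochondria stacks.** Tubes are unit-step random walks dilated to
`tube_radius` (0.3 µm on a 0.2 µm grid), internally 26-connected and
pairwise separated by ≥ 2 voxels. Walks stay in one z-plane per tube by
default: the thinning stage is slice-wise 2D (below), and a tube drifting
in z can legitimately produce adjacent-slice skeleton lines more than one
voxel apart, fragmenting one mitochondrion; flat in-plane networks are also
what adherent cultured cells actually show. `in_plane=False` enables 3D
drift for stress tests; `split_tubes=True` cuts each tube in the middle,
doubling the component count at nearly constant signal — the fragmentation
phenotype.

**Raman scans.** Per-pixel spectrum = cubic fluorescence-like baseline + a
fixed cellular Raman signature + vitamin-A band + lipid band + white noise
+ sparse positive cosmic-ray spikes, on 1024 channels over 400–3200 cm⁻¹
(≈ 2.7 cm⁻¹/channel, typical of a 600 groove/mm grating). The cellular
signature (bands at 1004, 1260, 1450, 1660 and 3130 cm⁻¹, all outside the
two analysis windows) dominates the full-range integral the way cell
material does in real spectra; without it, unit-integral normalization
forces compositional closure between the two band maps and their
correlation saturates regardless of the planted value. Band amplitudes
`(a_VA, a_lip)` are jointly Gaussian (mean 1, sd 0.3) with correlation
`rho` (default 0.8), constructed so `rho = 1` is exactly degenerate.
Spikes are single-channel (optionally width-2) positive deltas ≥ 10× the
local signal, Poisson-placed at 1e-4 per channel per pixel (≈ 160 per
40×40 scan). Default scan size is 40×40 for desk-scale work; the full
200×200 geometry is reachable by parameters.

**UV / IF fields and assay tables.** Bimodal images are built by
thresholding a smoothed Gaussian random field at the requested quantile, so
the planted positive fraction is exact to pixel discreteness. Assay tables
draw `n` replicates per condition from the stated `(mean, sd)` (sd = 0
reproduces the mean exactly) and append planted outliers at recorded row
indices.

## HT segmentation (`htseg`)

Features per voxel: the absolute response of the 5-point 2D Laplacian
applied slice-wise (edge replication), plus, for each scale in `scales`
(default 0.5 and 1.0 µm), a Gaussian local average of that sharpness and a
Gaussian-smoothed copy of the intensity. The smoothed-intensity channels
matter: a perfectly smooth cell interior has the same zero sharpness as
smooth background, and the classifier needs the low-frequency contrast to
separate them.

Voxels pooled from all labeled volumes are split 60/20/20
(train/validation/test), stratified by class and seeded. The default
scorer is a histogram gradient-boosted tree ensemble; a logistic-regression
backend is selectable so nothing downstream depends on one ML library's
internals. The decision threshold maximizes F1 on the validation split,
scanned over every distinct score; when a plateau of candidate cuts ties,
the midpoint of the maximizing interval is returned (deterministic and
symmetric — in the separable case this is the midpoint of the gap between
classes). Test-split AUROC is computed by the midrank Mann–Whitney
formulation, which equals trapezoidal integration of the empirical ROC
exactly. Training labels come from synthetic ground truth; the original
hand-labeling step is replaced, not reimplemented, and the split is by
voxel (not by image) for small-fixture feasibility.

Applying a model thresholds the score map, keeps the largest 26-connected
component and fills holes (both default-on, configurable). An empty result
warns rather than raises.

## Lipid droplets (`droplets`)

Bright spheres are detected by multi-scale scale-normalized LoG: the
negated, σ²-scaled 3D Laplacian-of-Gaussian of the masked volume, with
per-axis sigmas `σ/voxel_size` (error below one voxel — resample instead).
Outside-mask voxels are filled with the in-mask median before filtering so
the mask edge does not ring, and the volume mean is subtracted first
because the truncated derivative kernel does not sum exactly to zero (a
raw offset leaks a constant into the response and breaks exact affine
equivariance). For a solid sphere of radius R the center response has the
closed form `4πR³ σ⁻³ exp(−R²/2σ²)` (up to contrast), maximized at
`σ = R/√3` — the radius calibration used throughout.

Scales form a geometric ladder of `n_scales` (default 6) sigmas covering
`radius_range`, plus one *guard rung* beyond each end: a genuine blob must
be a scale-space maximum interior to the scanned range, so structures whose
response still grows at the range edge (the cell body at large σ,
single-voxel noise below the range) refine out of bounds and are discarded
instead of piling up at the edge rungs. Peaks are 3×3×3×3 local maxima
above `peak_threshold` (default 0.5) of the maximum non-guard response.
The threshold is relative, making detection invariant under affine
intensity rescaling; 0.5 sits in a structural gap — measured on the
synthetic geometry, cell-shoulder responses reach ≈ 0.15 of a droplet's
response, small-scale sphere-edge sidelobes ≈ 0.40, and the weakest
genuine droplet ≈ 0.75, and these ratios are contrast-independent.

The radius comes from the quadratic vertex of the scale profile in log σ
(exact three-point fit; the ladder is non-uniform when the lower guard is
clamped to the one-voxel floor). In crowded cells a neighbor's negative
LoG sidelobe suppresses the large-scale profile samples and biases radii a
few percent low, which the cubic volume amplifies; with `refine_crowded`
(default) each detection's vertex is re-fit on a copy of the volume in
which every *other* detection is masked to the in-mask median. On the ten
default recovery fixtures this moves total lipid-volume error from ≈ −6%
(worst −11%) to ≈ +4% (worst 5%).

Overlapping detections are pruned greedily, strongest response first, when
centers are closer than `overlap_factor` (0.75) times the radius sum.
Detections with centers nearer the mask boundary than 0.25·r — spheres
mostly outside the cell, which cytoplasmic droplets cannot be — are
discarded; boundary-touching detections are kept and flagged. Droplet
volume uses the sphere model `4/3·π·r³` (robust to mask edge noise), and
the lipid fraction divides the summed sphere volumes by the mask's cell
volume. A droplet-free cell volume still yields nonzero detections at the
relative threshold (there is always a maximal response); absolute-scale
interpretation of "no droplets" is out of scope for a max-relative rule.

## Mitochondrial morphometry (`mito`)

The per-stack threshold maximizes between-class variance on a 256-bin
histogram of the whole stack (ties to the lowest bin; constant stacks are
degenerate — `mito_stats` returns zero statistics for them). Thresholded
voxels are restricted to the HT cell mask when one is supplied (otherwise
the whole-stack volume normalizes, with a warning). Each z-slice is then
thinned by the two-subiteration parallel thinning scheme (neighbor count
2–6, exactly one 0→1 transition, and the two directional products per
subiteration) iterated to convergence — written in-package and verified
against an independent pixel-by-pixel trace and against scikit-image's
implementation in tests. Note the parallel scheme erodes free line ends by
a couple of pixels (a 3×20 bar thins to a centered path of 17). Skeleton
voxels are labeled with 26-connectivity — faces, edges and corners all
connect — and the component count, per-component voxel counts, and both
quantities normalized by cell volume are reported. A minimum segment size
filter exists but defaults to 1 (keep everything).

## Raman pipeline (`raman`)

Order is enforced — despike → baseline → normalize → band-integrate — with
state flags on the scan object and explicit overrides.

**Despiking.** The replacement value is the running median (window 5).
Detection needs care on two counts. The running median is biased exactly at
band extrema (it clips smooth peaks slightly) and that bias scales with
band amplitude, not noise, so residuals are compared *per channel across
the scan's pixels*, where the bias is common mode and cancels; scans with
fewer than 8 pixels fall back to a per-spectrum scale. And the test is
one-sided positive: cosmic rays only add counts, while a spike pulls the
running median of its neighboring channels up, giving those victims
spuriously negative residuals that a two-sided rule would "fix". A channel
is flagged above `k = 10` × 1.4826 × the channel MAD (floored at the
scan-typical channel MAD, which otherwise collapses to zero on steep
locally-monotone flanks); k = 10 keeps the threshold ≈ 7 noise sd, outside
the Gaussian extreme-value range even of a full 200×200×1024 scan.

**Baseline.** Asymmetrically reweighted penalized least squares:
iterate `(W + λDᵀD) z = Wy` with second-difference D and logistic weights
`w = 1/(1 + exp(2(d − (2s_d − m_d))/s_d))` computed from the negative
residuals, until the weight-vector change falls below `ratio` or
`max_iter` (then warn and return the last iterate). Defaults λ = 1e5,
ratio = 1e-3, max_iter = 100 — conventional for spectra of this channel
density; λ → ∞ provably tends to a straight line, and a flat spectrum is a
fixed point, both asserted in tests. One baseline per scan is fitted on
the scan's mean spectrum and subtracted from every pixel (per-pixel
baselining is available but deliberately not the default).

**Normalization and bands.** Every pixel spectrum is rescaled to unit
trapezoidal integral over the full axis; non-positive-integral pixels are
flagged invalid and excluded downstream, never silently rescaled. Band
integrals are trapezoidal with linear interpolation at window edges, over
the vitamin-A window [1554, 1615] cm⁻¹ (conjugated C=C stretch of
retinoids) and the lipid CH-stretch window [2800, 3000] cm⁻¹. The spatial
co-localization statistic is the product-moment correlation of the two
maps over all valid pixels.

One caveat worth stating: unit-integral normalization divides both maps by
the same per-pixel total, which induces a small compositional correlation
even for independently planted amplitudes (measured ≈ −0.1 when the
cellular signature is weak, ≈ −0.03 at the default conditions). The
independence property is therefore exact on unnormalized maps and only
approximate after normalization; recovery of a planted ρ = 0.8 lands
within ±0.06 at the defaults.

## Fluorescence (`fluor`)

The UV threshold is the Triangle method on a 256-bin histogram: the bin
maximizing perpendicular distance to the line from the histogram peak to
the far end of the nonzero range (the longer-tail side), ties to the bin
nearer the peak. Positivity is strictly above threshold; per-image
thresholds are the default, with a pooled shared-threshold batch mode for
acquisitions made under identical settings. The α-SMA score restricts the
α-SMA channel to the PDGFR-β-positive mask (Otsu on that channel by
default, fixed threshold overridable) and reports mask area, integral, and
their ratio; field aggregation reports both the mean of per-field means and
the raw pooled integral/area so either convention can be recomputed.

## Assays and statistics (`assays`)

Protein normalization rescales to the 100 mg/mL reference
(`value × 100 / protein_conc`). Radiotracer arithmetic: uptake = CO₂ +
cell-associated counts; fractional oxidation = CO₂/uptake (null with a
warning at zero uptake). Extracellular-flux traces are expressed as % of
the Control condition's pre-injection baseline (first 5 measurement
cycles); basal respiration = baseline mean − post-rotenone/antimycin mean,
maximal = post-FCCP maximum − the same non-mitochondrial term (the
standard derivation; the subtraction is toggleable since raw %-of-baseline
variants are also in circulation). Rates are converted per 24 h; fold
changes divide group means by the Control mean.

Welch's t-test is authored from the closed forms (statistic,
Welch–Satterthwaite df, two-sided p from the t distribution; two zero
variance groups with equal means give p = 1 by convention) and is
cross-checked in tests against an independent quadrature of the t density
and against SciPy. Its type-I error at the study's typical n = 4 is
verified to sit in [0.03, 0.07] over 2000 null draws.

Outlier removal follows the robust-fit/FDR approach at Q = 1%: for a lone
sample the robust fit reduces to the median; the robust residual sd (RSDR)
is the 68.27th percentile of absolute residuals with the small-sample
correction `n/(n−1)`; points are tested from the most extreme inward
against the Benjamini–Hochberg ladder `(Q/100)·i/n` on two-tailed t-tail
probabilities (df = n−1), stopping at the first retained point. Measured
per-point false-removal on clean n = 20 normal samples is ≈ 0.1% at
Q = 1%. Samples under n = 4 are returned untouched with a warning.

z-score heatmap rows use the population-sd convention (sample-sd
switchable); zero-variance rows are flagged, not silently zeroed.
Five-number summaries use linear interpolation between order statistics,
with Tukey hinges as an option.

## Problem sizes

Defaults are desk-scale by design: 64³ HT volumes, 40×40×1024 scans,
four-volume training sets, 2000-draw null calibrations. The full test
suite runs in about a minute; `scripts/acceptance.py` in about half a
minute. All of these sizes are parameters, not limits.

## Known limitations

- The Gaussian HT noise model and ellipsoidal cell body are caricatures;
  no diffraction, refraction artifacts, or reconstruction bias is
  emulated, so recovery rates here bound algorithmic, not instrumental,
  error.
- Slice-wise 2D thinning is faithful to the cited algorithm but is not a
  3D medial axis; tubes oriented steeply through z can fragment. The
  generator's in-plane default documents exactly this boundary.
- Sphere-model droplet volumes ignore non-spherical droplets and
  under-resolve radii below ~2 voxels.
- The relative peak threshold cannot represent "no droplets at all" on a
  droplet-free cell; an absolute-units threshold would need instrument
  calibration.
- Unit-integral normalization's compositional coupling slightly attenuates
  band-map correlations (see above); this is a property of the method
  itself, reproduced deliberately.
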