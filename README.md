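# stellaquant

Quantitative image and assay analysis for hepatic stellate cell (HSC)
activation studies. HSCs store most of the body's vitamin A in cytoplasmic
lipid droplets and lose both when they activate into collagen-producing
myofibroblasts — the driving event of liver fibrosis. `stellaquant`
implements the measurement layer such a study needs, end to end:

- **`htseg`** — cell-vs-background segmentation of holotomographic
  (refractive-index) volumes from local 2D-Laplacian sharpness features,
  with a supervised voxel classifier (gradient-boosted trees or logistic
  regression), F1-selected decision threshold and held-out AUROC.
- **`droplets`** — lipid-droplet detection by scale-normalized multi-scale
  3D Laplacian of Gaussian (radius = σ√3), with crowding-corrected radius
  refinement, and the lipid-volume-per-cell-volume statistic.
- **`mito`** — mitochondrial-network fragmentation: per-stack Otsu
  threshold → slice-wise Zhang–Suen thinning → 26-connected ("connectivity
  of three") labeling → segment count and mean size per cell volume.
- **`raman`** — confocal Raman large-area-scan preprocessing (cosmic-ray
  removal by a local median filter, arPLS baseline fitted on the scan mean
  spectrum, per-pixel unit-integral normalization) and vitamin-A
  ([1554, 1615] cm⁻¹) vs lipid ([2800, 3000] cm⁻¹) band maps with their
  spatial Pearson correlation.
- **`fluor`** — UV-autofluorescence positivity by Triangle thresholding and
  α-SMA intensity within PDGFR-β-positive areas.
- **`assays`** — protein normalization, radiotracer uptake/fractional
  oxidation (CO₂/(CO₂+CA)), Seahorse %-of-baseline and basal/maximal
  respiration, per-24 h rates, fold changes, Welch's t-test, ROUT outlier
  removal (Q = 1%), z-score matrices, five-number summaries.
- **`synth`** — seeded generators for every input above, each returning a
  ground-truth sidecar of all planted objects, so the whole pipeline is
  testable by parameter recovery without any proprietary microscopy data.

## Worked example

```python
import stellaquant as sq
from stellaquant.types import CellMask

# a synthetic holotomography volume: one cell, 20 lipid droplets, SNR 5
vol, truth = sq.synth.gen_ht_volume(seed=0)
mask = CellMask(truth.objects["cell_mask"], vol.voxel_size)

dset = sq.droplets.detect_blobs(vol, mask, radius_range=(0.5, 2.0))
frac = sq.droplets.lipid_fraction(dset, mask)
print(f"{len(dset)} droplets, lipid fraction {frac.fraction:.4f} "
      f"(planted {truth.objects['total_lipid_volume_um3'] / mask.cell_volume:.4f})")

scan, rtruth = sq.synth.gen_raman_scan(seed=1)
maps = sq.raman.va_lipid_correlation(sq.raman.preprocess(scan))
print(f"vitamin A / lipid spatial correlation r = {maps.pearson_r:.3f} "
      f"(planted rho = {rtruth.objects['rho']})")

print(f"pHSC vitamin A is {sq.assays.percentage_ratio(0.4602, 1.290):.1f}% "
      "of the scHSC level")
```

prints

```
20 droplets, lipid fraction 0.1948 (planted 0.1909)
vitamin A / lipid spatial correlation r = 0.777 (planted rho = 0.8)
pHSC vitamin A is 35.7% of the scHSC level
```

The detected lipid fraction recovers the planted one within a few percent;
the band-map correlation recovers the planted amplitude correlation up to
the small attenuation that unit-integral normalization itself introduces;
and the vitamin-A content ratio of primary vs stem-cell-derived HSCs,
computed from the two ELISA group means (0.4602 and 1.290 µg/mL), rounds
to 36%.

A thin CLI mirrors the library: `stellaquant synth|droplets|mito|raman|
fluor|assays --help`.

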