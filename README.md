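# imcquant

Quantification pipeline for imaging mass cytometry (IMC) of drug
biodistribution in tissue sections — built around the question of where
platinum ends up after cisplatin treatment of tumor-bearing mice, and
how to compare its levels across images and animals despite instrument
sensitivity drift.

IMC ablates a stained tissue section spot by spot with a pulsed UV laser
and reads each plume with a mass cytometer, yielding one ion-count image
per metal-isotope channel: lineage markers (Pan-Keratin, E-cadherin for
epithelium; Collagen I, αSMA for stroma), functional probes (IdU via
¹²⁷I for DNA synthesis, EF5 for hypoxia, γH2AX for DNA damage), nuclear
stains (Ir intercalator, Histone H3), and the drug itself (¹⁹⁵Pt).

The package covers the full path from the instrument's raw export to
group statistics:

- **`raw_io`** — parse the transient-signal text export (push numbers in
  rows, mass channels in columns, values in ion counts), reconstruct
  images line scan by line scan (unidirectional or serpentine raster),
  compute total-ion-current (TIC) proxy images, render RGB overlays,
  read/write multichannel TIFF.
- **`normalization`** — ¹³⁴Xe⁺-based sensitivity correction. The xenon
  impurity of the argon plasma gives a spatially uniform signal whose
  level tracks instrument tuning. Per image: Xe intensity histogram →
  Gaussian fit (counting statistics) → fitted mean as *normalization
  value*; the *normalization factor* is the ratio of an image's value to
  an arbitrarily chosen reference image (factor 1). Region means are
  divided by the factor after segmentation, with first-order error
  propagation:
  (σ′/m′)² = (σ_m/m)² + (σ_Xe/x̄_Xe)² + (σ_Xe,ref/x̄_Xe,ref)².
- **`region_quant`** — transparent marker-score tissue classification
  (epithelium / collagen-positive stroma / other stroma / necrosis /
  background), nucleus segmentation, per-region per-channel means ± SD,
  positive-nucleus fractions, and paired collagen vs non-collagen
  viable-tissue records for the drug channel.
- **`stats`** — two-level error propagation (area-to-area within a
  mouse, mouse-to-mouse within a group; error bar =
  √(σ²_within + σ²_between)), one-way ANOVA and Student's/Welch's t-test
  with the mouse as experimental unit.
- **`synthetic`** — a ground-truth tissue simulator (glandular epithelium
  in fibrous stroma, Pt-enriched collagen fibers, necrotic cores with
  hypoxic rims, S-phase nuclei, per-image sensitivity drift, uniform Xe
  background, <2% spot cross-contamination, Poisson emission) so every
  stage is testable without instrument data.
- **`pipeline` / CLI** — config-driven orchestration with manifests
  (`imcquant run-all`), plus `simulate`, `reconstruct`, `overlay`,
  `normalize`, `segment`, `quantify`, `stats` subcommands.

## Worked example

Simulate a small cohort (2 groups × 2 mice × 2 images, 256×256 px),
fit the Xe channel of each image, and quantify the normalized ¹⁹⁵Pt
collagen/epithelium ratio in the treated group:

```python
import numpy as np
from imcquant import (SimulationConfig, classify_regions, default_panel,
                      normalization_factor, normalize_quant,
                      region_channel_means, simulate_cohort)
from imcquant.normalization import fit_xe

cfg = SimulationConfig(n_mice_per_group=2, n_images_per_mouse=2)
panel = default_panel()
cohort = simulate_cohort(cfg, seed=1)

ref_fit = None
norm_means = {"stroma_collagen": [], "epithelium": []}
for image, truth in cohort:
    fit = fit_xe(image, image_id=truth.image_id)
    ref_fit = ref_fit or fit
    nf = normalization_factor(fit, ref_fit)
    mask = classify_regions(image, panel)
    for rec in region_channel_means(image, mask, image_id=truth.image_id,
                                    mouse_id=truth.mouse_id, group=truth.group):
        if rec.channel == "195Pt" and rec.region in norm_means \
                and truth.group == "cisplatin":
            norm_means[rec.region].append(normalize_quant(rec, nf, ref_fit).mean)
    print(f"{truth.image_id}: drift={truth.drift_factor:.3f} "
          f"xe_mean={fit.mean:.1f} factor={nf.factor:.3f}")

ratio = np.mean(norm_means["stroma_collagen"]) / np.mean(norm_means["epithelium"])
print(f"normalized collagen/epithelium Pt ratio: {ratio:.2f}")
```

Output:

```
control_m1_img1: drift=1.581 xe_mean=632.2 factor=1.000
control_m1_img2: drift=1.327 xe_mean=530.6 factor=0.839
control_m2_img1: drift=1.579 xe_mean=631.5 factor=0.999
control_m2_img2: drift=1.770 xe_mean=707.5 factor=1.119
cisplatin_m1_img1: drift=0.795 xe_mean=317.9 factor=0.503
cisplatin_m1_img2: drift=1.913 xe_mean=764.7 factor=1.210
cisplatin_m2_img1: drift=0.593 xe_mean=237.1 factor=0.375
cisplatin_m2_img2: drift=1.449 xe_mean=579.3 factor=0.916
normalized collagen/epithelium Pt ratio: 4.65
```

Each image's fitted Xe mean is its true drift times the simulated
reference level (400 counts), so the factors track the drift exactly;
dividing region means by them removes the image-to-image sensitivity
variation. The recovered Pt ratio sits close to the simulated 5×
collagen enrichment (slightly diluted by spot cross-contamination and
boundary pixels).

The same run, end to end with all output tables, masks and overlays:

```sh
imcquant run-all --out demo_run --seed 1
```

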