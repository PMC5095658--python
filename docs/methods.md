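# Methods

This note documents the models, defaults and numerical choices behind
`imcquant`, and what the simulation-based tests do and do not establish
about real data.

## Raw format and reconstruction

The instrument exports one delimited text file per acquisition: a header
row of mass-channel names (canonicalised to `<mass><Element>`, e.g.
`195Pt`; variants like `Pt195`/`Pt-195` are accepted), then one row per
*push* — one time-of-flight cycle, i.e. one 1 µm laser spot — with ion
counts per channel. Counts may be non-integer because of the detector's
dual pulse/analog counting calibration; they are parsed as non-negative
reals. The file itself carries no geometry, so a flat key-value sidecar
(YAML) records width, height and raster pattern.

Reconstruction places push *k* on row ⌊k/width⌋; columns run
left-to-right on every row (unidirectional raster, the default) or
alternate direction on odd rows (serpentine, selectable in the sidecar —
both are supported because acquisition software varies and the export
does not say). Pixel (0, 0) is the first acquired spot; coordinates are
0-based (row, col). Aborted scans reconstruct with NaN as the missing
pixel sentinel, and every downstream mean/SD/histogram ignores NaN.

TIC (total ion current) is the per-pixel sum over channels, excluding
the `background` role (xenon) by default; it serves as a grayscale proxy
for tissue morphology. RGB overlays clip each channel at the 99th
percentile, min-max scale, multiply by the channel color and sum. A
constant positive channel renders at full intensity (the degenerate
min-max case).

## Xenon sensitivity normalization

**Model.** ¹³⁴Xe⁺ from the argon plasma impurity is spatially uniform
within an image, and its level scales with the overall detection
sensitivity. If drift acts as a single multiplicative factor per image
common to all channels, dividing region means by the image's Xe level
(relative to a reference image) removes the drift. That common-factor
assumption is exactly what the simulator implements, so the tests verify
the method under the conditions where it is valid; the synthetic drift
can also be applied per-channel to violate it deliberately.

**Procedure.** Per image: histogram of the Xe channel over all acquired
pixels (unit bins for integer-like data, Freedman–Diaconis otherwise;
tissue-only histograms are configurable but all-pixels is the default
since the xenon signal carries no tissue contrast) → unweighted
least-squares fit of A·exp(−(x−μ)²/2σ²) to bin centers/frequencies,
initialized at the sample mean/SD/peak. The fitted μ is the
normalization value; ion counting statistics make the histogram
approximately Gaussian at the means involved (hundreds of counts), which
is why a Gaussian is the right fit family. With fewer than 5 occupied
bins, non-convergence, or a non-positive fitted mean, the sample mean/SD
are used and flagged (`fallback_used`).

**Factor.** factor(image) = μ(image) / μ(reference). The reference is
arbitrary (first image of the batch by default, overridable); its factor
is exactly 1, and all between-region or between-group *ratios* are
reference-independent. Means are *divided* by the factor, so
higher-sensitivity images scale down.

**Uncertainty.** The SD attached to the normalization value is
σ_fit/√n — the standard error of a mean estimated from n pixels, using
the fitted σ. (The curve-fit covariance of μ is an alternative; the
σ/√n form is used because it is what a pixel bootstrap of the
normalization value converges to, and the tests validate it against
exactly that bootstrap.) Normalized means carry three first-order
relative-variance terms — measured values, image Xe, reference Xe —
applied to both the pixel SD and the standard error of the mean.
Normalization happens strictly after segmentation, at the region-mean
level, never per pixel.

## Region classification

The original measurement used a commercial, pathologist-trained
rule-set platform for segmentation. This package deliberately replaces
that with a transparent, fully documented marker-score classifier — the
largest design deviation, made so that every threshold is inspectable
and reproducible:

1. Smooth each needed channel (Gaussian, σ = 1 px).
2. Rescale to [0, 1] (99th-percentile clip, then min-max), so scores
   are unit-free.
3. Stromal score = mean(Collagen I, αSMA); epithelial score =
   mean(Pan-Keratin, E-cadherin).
4. Tissue gate: Otsu on the smoothed TIC **in log space** — the TIC
   distribution is heavy-tailed (the drug-rich collagen compartment can
   dwarf everything else), which breaks Otsu's bimodality assumption on
   the raw scale.
5. Tissue pixels take argmax(score) when the winning score ≥ 0.1, else
   `unclassified`; stroma pixels with Collagen I above its own Otsu
   threshold are sub-labelled `stroma_collagen`.
6. Necrosis (configurable rule, on by default): tissue pixels with low
   nuclear signal and high γH2AX, restricted to pixels without a
   confident lineage score so that γH2AX halos around damaged nuclei in
   intact epithelium are not relabelled.

All thresholds default to Otsu on the relevant smoothed channel over
tissue pixels and accept absolute overrides in config.

Nucleus segmentation: Otsu on the smoothed mean of the nuclear channels
(Ir intercalator, Histone H3), connected components, removal of objects
below 4 px, optional watershed splitting (off by default — the simulated
nuclei are resolvable by construction, and watershed over-splits noisy
blobs).

Positive-nucleus fractions threshold per-nucleus channel means (Otsu by
default, absolute or gated variants available). The IdU (S-phase)
fraction is reported with EF5-positive nuclei gated out of the
denominator — hypoxic cells do not cycle, so the oxygenated-epithelium
fraction is the well-defined quantity; the gate uses a
4×median background-relative rule rather than Otsu because the gating
channel may have no positive population at all, in which case Otsu would
split noise.

"Viable tissue" = tissue minus necrosis. For the drug channel the
quantifier emits paired `viable_collagen` / `viable_noncollagen` records
(non-collagen = all viable tissue outside collagen-positive stroma;
the plain `epithelium` record provides the stricter epithelial-only
comparison, since either reading of "non-collagen" is defensible).

## Two-level error propagation and tests

Region means vary between areas (images) of one sample and between
samples (mice); both sources are propagated. Per mouse: mean of its
image values. Grand mean: unweighted mean of mouse means. Within
component: pooled variance of image values around their mouse means.
Between component: variance of mouse means minus the within
contribution (method-of-moments one-way random effects), floored at 0
and flagged when negative. Error bar SD = √(σ²_within + σ²_between).
With a single mouse, or one image per mouse, the inestimable component
is reported absent (NaN) with a warning — never silently zero.

Hypothesis tests run on per-mouse means (the mouse is the experimental
unit; images within a mouse are pseudo-replicates): classical one-way
ANOVA, and two-sided t-tests (Welch by default, classical Student
selectable). No multiple-testing correction is applied by default; a
Holm adjustment is available behind a flag.

## The simulator

The generator produces the study's conditions, not a tunable benchmark:

- **Morphology.** Tissue footprint 90% of the frame; epithelial glands
  as thresholded smoothed noise (30% of area); collagen fibers as
  dilated jittered random walks through stroma (12%); necrotic cores as
  eroded gland interiors (4%) with a 3 px hypoxic rim; nuclei as r = 2 px
  disks fully inside cellular tissue with enforced separation, covering
  12% of cellular area. Density thresholds are taken as exact quantiles,
  so realized fractions track targets; impossible targets raise after
  bounded retries. Fiber/blob shapes are aesthetic — only
  region-membership statistics matter to any test.
- **Emission.** Poisson per pixel per channel, λ = baseline ×
  marker-rule multiplier × drift. Baselines are ~0.5 counts (0.2 for
  Pt, 0.8 for the stromal markers), the on-target multiplier is 30 —
  giving the ~15–25 count signals over sub-count background typical of
  antibody channels. No detector dead-time model.
- **Platinum.** λ_Pt = baseline × drift × (1 + dose × 100 ×
  (1 + (E−1)·[collagen]) · [tissue]) with collagen enrichment E = 5 by
  default. The additive background term makes the untreated arm show
  pure background Pt (as observed at zero dose) while the treated-arm
  collagen/epithelium ratio approaches E (4.96 exactly, for these
  defaults). **E = 5 is an arbitrary simulator choice** — the source
  observations establish that collagen Pt greatly and significantly
  exceeds epithelial Pt, not a numeric ratio.
- **Functional markers.** IdU/Ki-67 on a 30% S-phase fraction of
  oxygenated epithelial nuclei, suppressed by dose as f/(1+4·dose);
  γH2AX on necrosis and, in treated animals, on 40% of epithelial
  nuclei; EF5 on the hypoxic rim. A nucleus counts as hypoxic/epithelial
  by majority overlap.
- **Instrument.** One drift factor per image, uniform in [0.5, 2],
  multiplying every channel including Xe (reference Xe mean
  400 counts); spot cross-contamination 1.5% (inside the instrument's
  stated <2% bound) spread over the 4-neighbours, edge shares returned
  to the source so counts are conserved.
- **Determinism.** Every stochastic operation takes an explicit seed;
  cohort generation derives per-image seeds from one root seed.

**What passing tests do not show.** The simulator has no plume/transport
physics, no spillover between mass channels, no within-scan drift, no
cell-shape realism, and its marker rules are noiseless indicator
functions scaled by Poisson statistics. Segmentation fidelity ≥ 90% and
exact fraction recovery on this material therefore validate the
*pipeline logic* (thresholding, bookkeeping, normalization algebra, error
propagation), not classifier performance on real histology, where
marker overlap and autofluorescence-like artifacts would dominate.

## Problem sizes

Simulated validation uses 256×256 px images (64×64 for format
round-trips): cohorts of 2 groups × 5 mice × 2 images for drift
cancellation and segmentation fidelity, 20 untreated images for
fraction recovery, 1000-draw bootstraps, 200-replicate variance-component
recovery, 2000 null replicates for test calibration and 500 for power.
These sizes put Monte-Carlo error well inside the asserted tolerances
while keeping the default suite fast.

## Known limitations

- The raw reader targets the tab-separated text dialect defined here;
  vendor binary acquisition formats are out of scope.
- No isotope-abundance/spillover compensation between mass channels.
- The between-mouse variance estimator is method-of-moments, not a
  likelihood fit; with very few mice it is noisy and the floor at zero
  biases it slightly upward on null data.
- Xe histograms default to all acquired pixels; if xenon were not
  uniform across a real image (e.g. strong matrix effects), the
  single-factor model would mis-correct — the reference-invariance and
  drift-cancellation tests only certify the uniform-drift regime.
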