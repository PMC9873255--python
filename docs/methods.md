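# Methods

This note documents the models, numerical choices, and limitations of
`myomorph`. It describes what the code computes; every number quoted
here is produced by the test suite or `scripts/acceptance.py`, not
asserted from outside.

## The cylinder decomposition

Muscle mass is modeled as fiber number × fiber cross-section × fiber
length × density. For tenotomy-to-sham ratios this gives

    Δm = ΔFN · (Σ_i AF_i · ΔCSA_i) · ΔFL,

with the density cancelling. Two points matter in practice:

* **AF_i are sham *area* fractions.** Writing the muscle mass as
  FN · FL · ρ · Σ_i f_i · CSA_i with number fractions f_i, the mass
  ratio is exactly ΔFN·ΔFL·Σ_i w_i·ΔCSA_i where
  w_i = f_i·CSA_i,sham / Σ_j f_j·CSA_j,sham — the fraction of sham
  cross-sectional *area* contributed by type i. Only under this reading
  is the decomposition an identity; the synthetic generator therefore
  aggregates fiber CSA as (sham mean CSA) × Σ_i AF_i·ΔCSA_i, and the
  packaged default AF = {1: 0.02, 2a: 0.28, 2x: 0.30, 2b: 0.40} is an
  area-fraction configuration. A fiber type missing a measured ΔCSA is
  treated as unchanged (ratio 1) and flagged in the result.
* **Contribution shares.** The log decomposition
  share_k = ln f_k / ln Δm is the default because it is the unique
  exact additive split of a multiplicative model (shares sum to 1
  whenever Δm ≠ 1). The one-at-a-time variant
  share_k = (1 − f_k)/(1 − Δm) is provided for comparison and reports
  its unallocated interaction remainder. Shares are undefined at
  Δm = 1 and are flagged, not fabricated. Per-animal shares are
  numerically unstable for animals whose realized ratio is close to 1
  (the ln Δm denominator vanishes), so group-level statements should
  use the `aggregate="group"` mode (shares of the group-mean deltas);
  both modes are exposed because it is genuinely ambiguous whether a
  figure-level share is "mean of per-animal shares" or "share of mean
  deltas".

Sham normalization is computed within matched (sex, genotype,
timepoint) cells: sham groups exist at every timepoint, and matching
all three factors is the least ambiguous reading of "normalized to the
average of the sham group of the same sex".

Validation regresses measured deficit (1 − TEN mass / matched sham mean
mass) on predicted deficit by ordinary least squares
(`scipy.stats.linregress`); slope, intercept, r², and the slope p-value
are reported. A zero-variance predictor is a degenerate input.

## Huang minimum-fuzziness thresholding

For a candidate threshold t, pixels split into background (g ≤ t) and
foreground (g > t) with class intensity means μ₀, μ₁. Each gray level's
membership to its class is μ(g) = 1/(1 + |g − μ_class|/C) with
C = g_max − g_min, and the partition's fuzziness is the
histogram-weighted Shannon fuzzy entropy Σ h(g)·S(μ(g)),
S(m) = −m ln m − (1−m) ln(1−m). The returned threshold minimizes this
fuzziness; ties break toward the lowest t. Candidates are restricted to
*occupied* gray levels below the maximum: an unoccupied candidate
induces the same partition as the occupied level below it, so this
restriction implements the tie-break exactly and avoids spurious
argmin changes from floating-point summation order. A histogram with
fewer than two occupied levels is degenerate. The implementation is
checked against an independently written exhaustive-search oracle.

For intensity images, the histogram uses 256 equal-width bins over the
image range and the threshold is returned in image units.

**Bimodality guard.** Thresholding a channel that contains no real
foreground (e.g. an MHC stain with zero fibers of that type, under
additive noise) splits the unimodal noise distribution down the middle
and would mark ~half the image positive. `foreground_threshold`
therefore rejects a split whose class-mean separation is below 0.25 of
the image range and reports "no foreground". This guard is applied to
MHC positivity scoring and to nucleus/puncta/marker blob detection; the
laminin segmentation channel, which always carries structure, uses the
plain threshold.

## Segmentation, typing, and counting rules

* Fibers are 4-connected components of the sub-threshold laminin phase
  (4-connectivity prevents diagonal leakage between fibers across a
  thin boundary); components touching the image border are excluded by
  default, and components outside [min_area = 100 µm², max_area = ∞]
  are dropped. Coordinates are pixel-center, row-major, 0-based; areas
  are always µm² (= pixel count × pixel_size²).
* Channel means per ROI are taken over the ROI eroded by 1 px to avoid
  boundary bleed. A fiber positive in exactly one MHC channel takes
  that type; positive in none is type 2x; positive in several is
  assigned to the channel with the largest min–max-normalized mean and
  flagged hybrid.
* A nucleus is a blob positive in both hematoxylin and DAPI (a blob
  counts as DAPI-positive when ≥ 50% of its pixels are); a basophilic
  punctum is hematoxylin-positive and DAPI-negative. Either is
  attributed to a fiber when its centroid lies inside the fiber ROI
  eroded by margin = 2 px, so structures straddling the laminin
  boundary are excluded. Outputs are percent of fibers containing at
  least one such structure.
* Marker-cell blobs are classified by centroid: *interstitial* = inside
  no fiber ROI (between laminin boundaries, FAP-like), *sublaminar* =
  inside a fiber but within margin = 2 px of its boundary
  (satellite-cell-like). Blobs deep inside a fiber belong to neither
  compartment. Outputs are cells per fiber.
* CSA statistics report the per-type arithmetic mean and a fixed-width
  histogram (default bin width 200 µm²) with bins starting at 0; an
  absent type is reported as missing, not zero. Stain area fractions
  are positive-pixel counts over tissue-mask pixels.

## The synthetic generators

**Cohort.** Animals occupy a fully crossed sex × genotype × treatment ×
timepoint design (default n = 7 per cell, the study-scale group size).
Sham animals realize sex-specific baselines (female baselines smaller);
tenotomized animals realize baseline × group effect factor × unit-mean
lognormal noise per morphological quantity (lognormal because masses
and lengths are positive and CV-parameterized; default noise_cv =
0.05), and muscle mass is then *constructed* through the cylinder
relation with its own lognormal factor. Records carry the realized
per-animal true factors, so decomposition recovery is testable. The
packaged default effect configuration is versioned,
labeled literature-inspired, and encodes the qualitative structure of the
study system: fiber-length loss dominates both sexes, males lose
additional mass through type-2b fiber atrophy (log CSA share ≈ 25% at
W8), females through fiber-number reduction (FN share ≈ 31–38%), and
the male W8 mass ratio (0.559) is below the female (0.590). These
defaults are generator choices, not measured ground truth, and were
fixed once at configuration time. Baseline morphology (e.g. male SS:
2800 fibers, area-weighted mean CSA ≈ 1900 µm², muscle length 1.2 cm,
fiber-length ratio 0.6) yields a ≈ 41 mg supraspinatus, a realistic
scale for an adult mouse.

**Sections.** The tissue is a disk (radius 0.46 × image side). Fiber
centroids are dart-throwing Poisson-disk samples with minimum distance
0.8·√(tissue area / n), which lower-bounds every Voronoi cell at ≈ half
the mean cell area; cells are nearest-centroid regions, and the laminin
ribbon is the label-change boundary dilated to ≈ the requested width.
Fiber interiors are defined as tissue minus ribbon, so the areas sum
exactly and the laminin channel is exactly the ribbon on noise-free
sections. The realized ribbon mask is recorded in the ground truth;
no exact-width contract is claimed. An infeasible packing (cell budget
below (2·ribbon + 6)² px, or dart throwing exhausting its tries)
raises a generation error. Types are drawn from the configured
fractions and rank-matched to cell sizes so larger target types occupy
larger cells; per-type CSA means therefore control relative, not
absolute, sizes (absolute scale is set by fiber density). Nuclei
(boundary and central), puncta, and marker cells are painted as small
disks at ground-truth-recorded centers, with placement rules mirroring
the counting rules (central structures ≥ margin+3 erosions deep;
sublaminar cells in the margin-wide rim; minimum center separations
prevent blob merging). The red-stain channel is painted in random
blobs and trimmed to the requested tissue fraction exactly to the
pixel. Gaussian blur, then additive Gaussian noise, are applied last;
ground truth records the pre-noise construction. Same seed gives
byte-identical output.

What the generator does **not** emulate: real laminin-intensity
variation and gaps, stain bleed-through between channels, uneven
illumination, out-of-plane fibers, touching/merged nuclei, necrotic
fibers, or non-convex fiber profiles. Passing recovery tests therefore
demonstrates correctness of the quantification rules, not robustness
to every real-histology artifact.

## Physiology

PCSA = m·cos(θ)/(ρ·Lf) in cm² (m in g, Lf in cm, ρ = 1.056 g/cm³ by
default); fiber length is predicted from measured muscle length by a
per-muscle ratio (default 0.6) — the architecture model that produces
such ratios is external, and the defaults are documented placeholders.
Angles are degrees in configuration, converted internally. The
generator uses θ = 0 (a parallel-fibered supraspinatus), which makes
the consistency identity PCSA = FN × (aggregated mean CSA in cm²)
exact on noise-free cohorts; any nonzero θ would scale both force and
PCSA consistently but break that identity by cos θ. Specific tension
is P0/PCSA and is invariant under uniform geometric scaling when force
scales with PCSA.

## Statistics

Factorial ANOVA fits the full-interaction linear model via
`statsmodels` OLS with type-II sums of squares — the standard choice
for the mildly unbalanced cell counts (n = 5–7) this design produces.
Pairwise contrasts compare levels of one factor within every
combination of the others by Welch t-tests, adjusted by Sidak (default
for ≤ 2 factors) or Benjamini–Hochberg FDR (default for 3). Cells that
are empty or singleton raise an explicit error listing the cells.
Normality is assessed by Shapiro–Wilk per cell and reported; failures
are never auto-switched to nonparametric tests. Missing animals are
handled by row-wise deletion before fitting. Calibration is verified
by simulation: the two-factor main-effect type-I error at α = 0.05
over 1000 null datasets lands inside the binomial 95% band.

## Problem sizes used in the checked runs

Acceptance-style checks use 512² px sections with 110 fibers (mean
fiber ≈ 1400 µm² at 1 µm/px, a realistic 20×-like sampling), 20 clean
plus 4–5 noisy sections, 50 cohort replicates at n = 7/group, 1000
ANOVA null simulations, and 1000 regression replicates — sizes chosen
to make the Monte-Carlo bands tight relative to the tested tolerances.

## Known limitations

* The fiber-length/pennation architecture model is abstracted to
  constants; no muscle-specific values ship with the package.
* Whole sections are quantified; the four-field 20× sampling scheme of
  bench protocols (superficial/deep regions) is not modeled.
* Necrotic-fiber identification (a blinded-rater judgment without a
  stated criterion) is not implemented.
* H&E/Oil-Red-O/Sirius-Red inputs are modeled as single pre-extracted
  intensity channels; no RGB stain deconvolution.
* No mixed-effects modeling and no a-priori power computation.
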