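# myomorph

Quantitative tooling for studies of skeletal-muscle atrophy after tendon
transection (tenotomy), built around three questions a rotator-cuff
atrophy experiment has to answer:

1. **Histology** — from multi-channel stained cross-sections (laminin
   outline, three myosin-heavy-chain isoform stains, DAPI, hematoxylin,
   red stains for fat/fibrosis, progenitor markers): how many fibers are
   there, how big are they, what type are they, and how much pathology
   (central nuclei, basophilic puncta, fibrosis, fatty infiltration,
   FAP-like and satellite-cell-like populations) is present?
2. **Geometry** — how much of the measured muscle-mass deficit is
   explained by each morphological route of atrophy: radial fiber
   atrophy (CSA), fiber loss (hypoplasia), and fiber shortening
   (sarcomere subtraction)?
3. **Physiology** — how should contractile output be normalized so that
   architectural change is accounted for (PCSA, specific tension)?

Every stage is driven by a synthetic-data module that generates cohorts
and stained sections with known ground truth, so the full pipeline is
testable without any external data.

## The model at the core

Treating each fiber as a cylinder, the tenotomy-to-sham muscle mass
ratio decomposes as

```
Δm = ΔFN · (ΔCSA₁·AF₁ + ΔCSA₂ₐ·AF₂ₐ + ΔCSA₂ₓ·AF₂ₓ + ΔCSA₂ᵦ·AF₂ᵦ) · ΔFL · ρ
```

where ΔFN, ΔCSA_i, ΔFL are dimensionless tenotomy-to-sham ratios of
fiber number, per-type fiber cross-sectional area, and fiber length;
AF_i are the fiber-type **area** fractions of the sham muscle (assumed
unchanged by tenotomy); and ρ is muscle density (1.056 g/cm³ by
default, cancelling when all quantities are ratios). The predicted
deficit is 1 − Δm. Because the model is multiplicative, the unique
exact additive split of the deficit over its three factors is the log
decomposition `share_k = ln(f_k) / ln(Δm)`; a one-at-a-time variant
with an explicit interaction remainder is also provided. Predictions
are validated by ordinary least squares of the measured deficit
(1 − TEN mass / sex-matched sham mean) on the predicted deficit.

On the imaging side, binarization uses the Huang–Wang minimum-fuzziness
threshold (Shannon fuzzy entropy of class memberships), fibers are the
connected components of the sub-threshold laminin phase filtered by
area and border contact, and fiber types are scored positive/negative
per MHC channel by mean ROI intensity against a bimodality-guarded
whole-image threshold (all-negative fibers are type 2x).

Physiological normalization uses
`PCSA = m·cos(θ) / (ρ·Lf)` with fiber length predicted from measured
muscle length via a per-muscle ratio, and specific tension `P0 / PCSA`.

## Worked example

Simulate a default two-sex wildtype cohort (7 animals per
sex × treatment × timepoint cell), decompose every tenotomized animal
against its matched sham group, and validate the prediction:

```sh
myomorph simulate-cohort --seed 42 --n-per-group 7 --out cohort.csv
myomorph decompose --table cohort.csv --out decomposition.csv
myomorph validate --table cohort.csv --out validation.json
```

which prints `wrote 84 animals to cohort.csv`,
`wrote 42 decompositions to decomposition.csv`, and

```
slope=0.984 r2=0.879 p=6.32e-20 n=42
```

— the regression of measured on predicted deficit has slope ≈ 1, i.e.
the three morphological routes account for essentially all simulated
mass loss. Averaging the per-animal contribution shares by group
(values in %):

```
               share_fiber_csa  share_fiber_number  share_fiber_length  measured_deficit
sex timepoint
F   W1                    -7.9                32.8                75.1              25.9
    W2                    -0.8                28.9                71.9              36.9
    W8                     1.4                38.8                59.9              45.4
M   W1                    25.3                27.5                47.2              16.6
    W2                    22.2                20.3                57.5              31.8
    W8                    28.3                14.7                57.0              45.7
```

Fiber shortening dominates the deficit in both sexes; males additionally
lose mass through type-2b fiber atrophy (CSA share ≈ 22–28%) while
females lose it through fiber-number reduction (≈ 29–39%) — the
sex-specific structure the default generator configuration emulates.

The same library quantifies sections:

```sh
myomorph simulate-sections --n 1 --seed 7 --out sections/
myomorph quantify --image sections/section_000.tif --out metrics.json
```

`metrics.json` then holds fiber number, per-type mean CSA and type
fractions, central-nuclei and puncta percentages, and the red-stain
area fraction for that section.

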