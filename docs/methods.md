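# Methods

## The assay being modeled

Cross-linking LFA-1 on T cells drives the transition from a round resting
cell to a polarized migratory one. An arrayed siRNA screen quantifies
this per gene: cells electroporated with one SMARTpool per well are
plated on stimulating antibody, fixed, stained for F-actin and the
nucleus, imaged (8 fields/well), and segmented into cell and nucleus
masks. The analysis then reduces each well to five shape parameters,
standardizes them against plate controls, and calls hits by a replicate
rule. This package implements everything downstream of segmentation,
plus a generator that emulates the screen design.

## Morphometry

Inputs are paired integer label images; each nucleus is matched to the
cell it overlaps most (ties broken by larger overlap, then lower label).
Per cell:

| parameter | definition | notes |
|---|---|---|
| 1/(Form factor) | P²/(4πA) | P via Crofton estimator, 4 directions |
| nuclear displacement | ‖c_nuc − c_cell‖ | length units; `normalize_displacement` divides by √(A/π) |
| area | pixel count · px² | |
| gyration radius | RMS pixel distance from centroid | disk → R/√2 |
| elongation factor | major/minor axis of moment-equivalent ellipse | floor of 1 px on the minor axis avoids ∞ on degenerate 1-px-wide regions |

Numerical choices: the Crofton perimeter is used because a raw
pixel-edge count overestimates P by up to ~27% and would put a circle's
roundness index near 1.6 instead of 1; with Crofton a rasterized disk of
radius 120 px measures 0.995. Border-touching cells are excluded (their
shape is truncated). Coordinates are pixel centers, origin top-left,
x = column. Rasterization keeps the roundness index within 5% of 1 for
small cells (radius ~10 px), so the per-cell invariant is enforced as
≥ 0.95 rather than ≥ 1. Foreground connectivity is 8-connected.

Wells aggregate cells pooled across all of the well's fields by the
arithmetic mean (median available); wells with fewer than `min_cells`
(default 20 at desk scale) fail QC and propagate as missing rather than
as zeros.

## Plate scoring

Raw well means are first divided by the mean of the plate's six
QC-passing non-targeting control wells, per parameter (`ratio_to_control`;
plates without usable controls are an error, never silently passed).
Z scores are computed per (plate, screen, parameter) over the plate's
**library** wells:

    Z = (x − mean) / SD        (classical; sample SD, n − 1)
    Z = (x − median) / (1.4826 · MAD)   (robust variant)

Controls are scored against the library distribution but never enter the
location/scale estimate — they anchor the normalization, and including
them would shrink the SD artificially. Both of these conventions
(SD with/without controls, n vs n−1) are exposed in `ScreenConfig`.
A zero SD or MAD raises an error instead of emitting zeros.

The hit rule: a parameter is significant when |Z| ≥ 1.5 in ≥ 2 of 3
screens; by default the exceedances must share a sign (mixed-sign
"replication" is biologically incoherent; the any-sign reading is a
config toggle, and the null-calibration analysis below uses it because
the binomial closed form describes that reading). A gene is a hit when
≥ 1 of 5 parameters is significant; the phenotype class is
`decreased_polarity` when all significant parameters are negative,
`increased_polarity` when all positive, else `mixed`. Genes with fewer
than 2 usable screens are reported `not_evaluable`, never "not hit". No
multiple-testing correction is applied beyond the replicate rule, which
matches screening practice for this assay family.

## Clustering

Profiles are the raw per-screen Z scores (not thresholded calls), 5
parameters × 3 screens per gene; the three control treatments are
averaged into one row each per screen so they act as phenotype anchors.
Distances are Euclidean (correlation optional); missing entries use
pairwise-complete columns rescaled by √(n_total/n_shared), and rows with
< 50% observed columns are excluded. Trees use average linkage; rows are
sorted lexicographically first so ties and the tree are independent of
input order.

Leaf ordering is computed by an exact dynamic program over the 2^(n−1)
tree-consistent orders: for every subtree and boundary-leaf pair (l, r)
the minimal internal cost is tabulated and combined by a min-plus
product at each merge (O(n³) in practice, ~30 ms at n = 200). The test
suite verifies optimality against exhaustive enumeration for n ≤ 8.
The two-cluster cut of planted all-negative vs all-positive profiles
separates the groups exactly. Dendrograms are exported as Newick with
branch lengths.

## Motility metrics

For a track {(tᵢ, xᵢ, yᵢ)}: velocity = ‖p_N − p_1‖/(t_N − t_1),
origin of distance = ‖p_N − p_1‖ (per-frame series available), speed =
Σᵢ‖p_{i+1} − pᵢ‖/(t_N − t_1). "Directionality" is read as the net
start→end displacement — the standard tracking-software convention;
with that reading speed ≥ velocity always (triangle inequality), and the
package asserts it. The live-cell frame interval this models is 50 s.
Tracks below a configurable minimum duration are dropped from population
summaries.

## Synthetic screens

The generator emulates the study design — 3 replicate screens, 96-well
plates with 6 non-targeting control wells, 2 talin-like positive-control
wells and 2 poly-L-lysine reference wells per plate (the control-well
counts beyond the six are this package's choice), one gene per library
well, 8 fields/well — at desk scale: 2 plates (172 genes) × 3 screens,
50 cells/well by default, far below the assay's ~6000–7500 seeded
cells/well but adequate for the statistics being tested.

Per-cell parameter draws are lognormal around a shifted target:

    value = baseline · effect · exp(ε_screen + ε_well + ε_cell − s²/2)

with ε_screen ~ N(0, 0.03) per (gene, screen, parameter) modeling
imperfect replicates, ε_well ~ N(0, 0.04), and ε_cell ~ N(0, 0.30)
cell-to-cell variability (mean-corrected). Elongation and roundness are
floored at their geometric minimum of 1. The polarized baseline
(1/FF 2.0, displacement 2.5 px, area 220 px², gyration 9 px, elongation
1.9) and the round/poly-L-lysine multipliers are chosen to mirror typical
resting-vs-migrating T-cell read-outs at 10× magnification; the talin
wells multiply all five parameters by 0.6, which lands them near Z ≈ −2.5
against the library distribution. Planted hits shift all five parameters
by ±35% (the all-parameter phenotypes); default hit fractions are 8%
decrease / 10% increase, the regime reported for kinome-scale screens of
this assay. With 50 cells/well the null well-to-well SD is ≈ 0.06 of the
baseline, so the planted effect is ≈ 6× the null noise scale and
recovery at the 2-of-3 rule is essentially complete; the
effect-magnitude ladder test confirms sensitivity is monotone in effect
size.

Null calibration: with all effects zero and ε_screen = 0 the screens are
independent and the per-(gene, parameter) rate of 2-of-3 exceedance under
the any-sign rule matches P(Bin(3, 2Φ(−1.5)) ≥ 2) ≈ 4.88%; the test
requires agreement within 3 Monte-Carlo SEs at 344 genes × 5 parameters.
The ε_screen term and the sign-consistency requirement both lower the
realized false-positive rate, which is why the calibration scenario
switches them off — the closed form is the model for that scenario, not
for the default screen.

Two tiers share the effect model. The feature tier draws the parameter
table directly. The image tier renders each cell as an ellipse body
(axis ratio from the drawn elongation, area-preserving) plus, for
polarized cells, a tapering triangular tail whose length tracks the
drawn roundness index, with the nucleus offset toward the leading edge;
cells are stamped on a 128-px grid inside 512-px fields, clear of the
border. The mapping from the five parameters to geometry is qualitative
— planted directions survive the render-and-remeasure round trip, which
is what the image-tier tests assert — and the rendered masks are clean
silhouettes: no fluorescence texture, no touching cells, no segmentation
errors beyond parameter jitter. Passing tests therefore demonstrate the
correctness of the measurement and scoring chain, not robustness to
segmentation artifacts in real images.

Determinism: every output is a pure function of (config, seed). Per-well
substreams are `default_rng([master_seed, screen_id, plate_index,
well_index])`; per-(gene, screen) replicate noise uses a tagged child
stream; image-tier field seeds derive from a CRC of the field's
identifiers. Re-running the pipeline with the same config and seed
reproduces byte-identical CSV outputs (checksummed in the manifest).

## Problem sizes

Defaults throughout are desk scale, chosen so the full test suite and
the acceptance script each run in well under a minute on one CPU:
2-plate default screens, a 4-plate (344-gene) null screen for
calibration, 20-row cluster benchmarks, n ≤ 8 exhaustive leaf-order
checks, and 1000 random tracks.

## Known limitations

- The aggregation order (per-cell pooling across fields before the well
  mean) and the unnormalized nuclear displacement are conventions the
  original acquisition software may or may not share; both alternatives
  are exposed.
- Classical Z is the default; screens with outlier-heavy plates should
  use the robust variant (the two agree at Jaccard ≥ 0.8 on clean
  synthetic screens).
- Hit fractions, effect sizes and noise scales in the generator are
  package choices describing a plausible screen of this design, not
  inferences about any particular dataset.
- The clustering input is hit genes plus averaged controls by default;
  `--all-genes` clusters the whole library.
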