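# Methods

`nichescreen` re-implements, as a tested library, the computational core of a
tumor-microenvironment high-content screen: a coculture of patient-derived
lung cancer cells and cancer-associated fibroblasts (CAFs) is imaged in three
fluorescence channels — Hoechst 33342 (nuclei), Nanog (stemness) and CD90
(fibroblasts) — scored into six phenotypic parameters per well, analysed at
screen level (percent change, rank-normal scores, hierarchical clustering,
rule-based hit calling), and complemented by single-hit limiting-dilution
frequency estimation for the cancer-stem-cell (CSC) readout.

## Image scoring model

Four fields per well are stitched into a 2×2 montage (field *i* at grid
position (*i*//2, *i*%2)); provenance keeps each field's pixel offset so
coordinates are recoverable.

**Pre-filtering (stemness channel only).** A white top-hat with a circular
element of size 30 px isolates nucleus-scale bright spots and removes the
background and any structure wider than the element; a morphological opening
with a 6 px circular element then deletes residual specks the element does
not fit into. Element "size" is the diameter; the radius is `size // 2`.
Both transforms are computed exactly: a flat disk is a union of centered
horizontal segments, so erosion/dilation reduce to per-row 1-D min/max
filters combined across rows. The border convention is
window-intersect-image (erosion pads +∞, dilation −∞), which is the direct
sliding-window definition and keeps the opening anti-extensive. The
implementation is verified pixel-exactly against an independent brute-force
sliding-window reference.

**Cell scoring.** Nuclei are connected components (8-connectivity) of
nuclear-channel pixels above a local background plus a per-channel offset.
"Local background" is the mean over a square window of 4× the maximum
nucleus width — a parameter-exposed reading of intensity-above-local-
threshold scoring. A component is a nucleus when its *equivalent width*
(diameter of the equal-area circle, a rotation-invariant reading of the
width gate) lies strictly inside the configured (min, max) range. A cell is
Nanog⁺ (resp. CD90⁺) when the mean filtered-stemness (resp. raw fibroblast)
intensity over its nucleus footprint exceeds that channel's local background
plus offset. Cells both CD90⁺ and Nanog⁺ are counted as CAFs (CD90 wins) and
logged; the collision is not defined by the assay.

**Colonies.** Non-CD90⁺ nuclei are dilated by a 5 px-radius disk ("grow
objects"), touching grown objects merge under 8-connectivity, holes are
filled per component, and each filled component must pass three filters to
count as a colony: area > 10,000 µm² (strict), elliptical form factor ≤ 2.5,
and stemness intensity SD ≥ a user-defined minimum. The form factor is the
major/minor axis ratio of the second-moment (inertia-equivalent) ellipse of
the filled mask. The minimum SD defaults to 2× the background SD of the
filtered stemness channel (background = pixels outside all grown objects),
so it is 0 for noise-free images; it is exposed because the original
screening software leaves it user-defined. Area is mask pixel count ×
`pixel_size_um²`; coordinates are 0-based, x rightward, y downward.

**Six parameters.** total cells = Hoechst⁺ nuclei; total CAFs = CD90⁺ cells;
total CSCs = Nanog⁺ cells inside colonies; colony count; total colony cells
= all member cells of colonies; colony density = total colony cells / total
colony area (cells/µm²). Nanog⁺ singletons outside colonies count only
toward total cells. A well with no colonies reports density 0 together with
an explicit `no_colonies` flag so screen matrices stay rectangular.

## Synthetic data

The generator emulates the assay conditions: 2,000 CAFs and 200 cancer cells
per 96-well, the cancer cells in 3 round colonies with 30% Nanog⁺ cells,
four 600×600 px fields per well at 1.75 µm/px, 16-bit-scale intensities
(signal 30,000 over backgrounds of 400–600 counts) with additive Gaussian
noise defaulting to 5% of the signal amplitude. Drug effects are
multiplicative factors on CSC fraction, colony count, cancer survival and
CAF survival, applied before synthesis so ground truth reflects them; well
counts are the rounded scaled values (an optional lognormal well-to-well CV,
default 0, adds biological variability). When a compound's colony count
rounds to 0 its colony-resident cancer cells are removed with it.

Deliberate idealisations, chosen so the noise-free well is *exactly*
recoverable and every scored quantity has a closed-form ground truth:

- **Hard-edged nuclei on the pixel grid.** Nuclei are rendered as hard
  digital disks (radius 4–6 px) at integer centers, not anti-aliased blobs:
  the noise-free thresholded mask then equals the rasterized disk for any
  sensible offset, making pixel-exact recovery of areas and colony density
  well defined rather than threshold-dependent.
- **Spaced, connected placement.** A minimum center spacing of 2·r_max + 3 px
  keeps nuclei 8-disconnected; colony cells sit on a jittered hexagonal
  lattice whose pitch lies between that spacing and the grow-merge distance,
  so each planted colony always emerges as exactly one grown component.
  CAFs scatter uniformly outside colonies by rejection sampling.
- **Stemness rendered over the nucleus footprint** (scoring colocalizes
  Nanog with Hoechst), not cytoplasmic.

What this does *not* emulate: anti-aliased or textured nuclei, overlapping
and touching cells, illumination gradients, PSF blur, debris, or 3-D
spheroids. Passing tests therefore demonstrate correctness of the scoring
*logic* under controlled conditions, not robustness to real microscopy
artifacts.

The truth-side oracle (`expected_phenotype`) recomputes colony geometry from
the ground-truth coordinates (rasterize member disks, grow, fill, measure) —
from the table, never from the image — and takes all counts from the table.
An all-Nanog⁻ colony is assumed to fail the SD filter unless the minimum SD
is 0; at the default 30% CSC fraction this case does not arise.

## Screen statistics

Per compound the six parameters are averaged over replicates (default 3) and
converted to percent change `(drug − control)/control` against the mean of
all control wells on the plate (the assay does not distinguish per-plate vs
global controls; per-plate is used). A zero control mean raises an explicit
degenerate-control error naming the parameter. Each parameter column is then
Blom-normalized, Φ⁻¹((r − 3/8)/(n + 1/4)) with average ranks for ties — the
standard constants for "Blom's method". Compounds are clustered
agglomeratively with Euclidean distance and centroid linkage
(`scipy.cluster.hierarchy`); merge heights are Euclidean centroid distances,
and centroid-linkage inversions are retained and flagged, never reordered.

**Flat cut.** The default cut lies below the largest *relative* jump between
consecutive merge heights. For screens whose replicate noise is small
against between-compound differences this isolates groups of near-identical
profiles; for a noise continuum it cuts low, which is conservative — hit
calling is rule-based per cluster, so over-segmentation costs nothing while
under-segmentation dilutes cluster means. An absolute height or a fixed
cluster count can be passed instead.

**Selection rules** (evaluated on cluster means of *raw* percent change,
since the published thresholds speak in percentages of control, not normal
scores):

- *excluded* (nonselective cytotoxicity): total CSCs, colony count and total
  colony cells each inhibited by more than 80%;
- *anti-CSC*: total CSCs inhibited by at least `min_effect` (default 20%),
  no colony parameter (count, colony cells, density) increased by
  `min_effect` or more, and |mean CAF change| < 15%;
- *anti-CAF*: total CAFs inhibited by at least `min_effect`, and not
  pan-cytotoxic;
- *neutral* otherwise.

The `min_effect` margin implements "inhibitory effects", which has no
printed magnitude: a literal "< 0" test would flip on the sign of replicate
noise and classify half of all inactive compounds as hits. Requiring strict
inhibition of *all four* colony parameters for anti-CSC calls would also
reject a compound that purely depletes the Nanog⁺ fraction (colony count and
density then sit at exactly 0% change), so the non-CSC colony parameters are
required not to *increase* rather than to strictly decrease. All thresholds
are exposed in `HitRules` and every decision is logged with its triggering
rule.

## Limiting-dilution frequency (single-hit model)

A well seeded with *d* cells responds with probability 1 − exp(−f·d) when
each of its cells initiates growth independently with probability *f*. This
is a binomial GLM with complementary log-log link and offset log *d*;
`fit_single_hit` takes the MLE of log *f* from `statsmodels` and a Wald 95%
CI on the log scale (the common choice for extreme limiting-dilution
analysis). Boundary designs are handled by one-sided profile likelihood: no
responding wells gives f̂ = 0 with upper bound 1.9207/Σnᵢdᵢ (the 95%
likelihood-ratio bound in closed form); all wells responding gives f̂
reported at the upper boundary 1 with a numerically profiled lower bound;
both are flagged. Goodness-of-fit to the single-hit assumption is the
deviance against the saturated per-dose model (reported, not enforced).
Frequencies are reported both as fractions and as "1 in N".

`compare_frequencies` is a likelihood-ratio test of one shared frequency
versus group-specific frequencies (df = 1), using the package's own
log-likelihood (binomial constants cancel) at the GLM/boundary MLEs; it is
undefined (explicit error) when both groups are degenerate.

Calibration, recomputed by `scripts/acceptance.py` and the test suite at the
assay's designs (doses {1, 10, 100, 500}, 24 wells/dose): single-dose MLE
equals the closed form −ln(1−p)/d to ~1e-15; 95% CI coverage ≈ 94–95% over
1,000 simulations at f = 1/100; LRT type-I error ≈ 5% over 2,000 null
replicates; power ≈ 100% for f = 1/50 vs 1/500 over 200 replicates (run at
200 so the whole script stays fast; the binomial SE at that size is ~1.5%).

## Problem sizes and numerical choices

- End-to-end recovery runs on a 6-well plate (2 controls + 2 compounds × 2
  replicates) at full per-well density, plus one noisy well at 5%-of-
  amplitude noise; each well takes ~1 s to score on one CPU.
- The planted screen uses 100 compounds × 3 replicates + 3 controls
  (303 wells, ground-truth phenotypes without rendering).
- Morphology equivalence uses 200 random rasters ≤ 64×64 (a third rounded
  to force ties); clustering equivalence uses 500 random instances, n ≤ 8.
- Thresholds are applied exactly as printed: area strictly > 10,000 µm²,
  form factor ≤ 2.5 inclusive, SD ≥ minimum. Clustering tie-breaks take the
  lowest-index pair; with exactly duplicated profiles merge order among
  duplicates is arbitrary but flat partitions are invariant.
- All randomness flows from a single integer seed through
  `numpy.random.default_rng` / `SeedSequence`; equal seeds give bit-identical
  images, tables and trees.

## Known limitations

- The width gates, intensity offsets and minimum Nanog SD are conventions
  (the original values are user-defined in the screening software and not
  printed); defaults suit the generator's 16-bit intensity scale and must be
  re-tuned for real images.
- The scorer assumes non-overlapping nuclei; clumped or dividing cells merge
  into one component and can be dropped by the width gate.
- Centroid linkage is quadratic in compounds via scipy; the 1,524-compound
  scale of a real screen is comfortable, but heights are Euclidean (not
  squared) distances — the tree is identical either way.
- Colony membership is assigned via the nucleus centroid's component label;
  a cell sitting inside another colony's filled hole keeps its own label
  (the generator never produces this configuration).
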