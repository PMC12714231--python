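# Methods

## Coordinate and labeling conventions

Pixel coordinates are 0-based `(row, col)` with pixel centers at integer
positions; protein coordinates are 1-based inclusive, the standard for
sequence annotation. Gut quarters are labeled 1–4 from proximal (the gut
start marker) to distal, matching the qrt1–qrt4 naming used for regional
counts. Groups in cohort tables are `control` and `ablated`.

## Detection

Z-stacks are reduced by per-pixel maximum-intensity projection. For
two-reporter images a composite is formed by rescaling each channel to
[0, 1] by its own maximum and taking the per-pixel max, so a single
threshold finds objects bright in either channel regardless of gain.
Binarization uses Otsu's method by default — the original analysis used an
automated ImageJ threshold whose exact variant is not recoverable, so a
fixed-value override exists for sensitivity analysis. Connected components
use 8-connectivity (ImageJ's particle-analysis default; diagonal-touching
pixels are one object), and components under 10 px² are discarded. Holes
are not filled; the blob-like cells this pipeline targets have none.
Per-object mean intensity is recorded for every channel supplied, because
classification needs both channels measured over the same mask.

## Weighted counting

Touching cells merge into single components. Rather than watershed
splitting, each object is weighted by its area relative to the median
object area: `weight = max(1, round(area / median))`. The median is the
mean of the middle two areas for an even count. Rounding is half-up —
the rule anchors integers ("twice the median → 2, three times → 3") without
specifying midpoints, and half-up is the natural reading; an object 2.5×
the median counts as 3. Weights are recomputed from areas only, so the
assignment is idempotent, and the weighted total equals the sum of weights.

Classification uses the ratio of mean intensities (mean rather than
integrated intensity, configurable) with thresholds 2 and 0.5; values
exactly at a threshold are double positive, since the defining conditions
for the single-positive classes are strict inequalities, leaving [0.5, 2]
closed. A zero denominator with a positive numerator maps to +∞ → A-only
(the rule's limiting behavior); an object with zero signal in both
channels cannot exist above threshold and is an error. A merged object
carries its whole weight into its single class — the overlap correction is
applied after classification, without splitting weights across classes.

## Gut-axis registration

Only two manual markers per image exist (gut start and end), so arc length
along the true midline is unavailable; the axial coordinate is the scalar
projection onto the start→end chord, clamped to [0, 1]. This is exact for
a straight gut and an ordering-preserving approximation for the gently
curved larval gut; the synthetic generator's curved guts quantify the
error, and an x-coordinate projection is available via `mode="x"`.
Quartile and percentile bins are half-open `[(k−1)/n, k/n)` with the last
bin closed at 1, 1-based. Density profiles over the 100 percentile bins
are smoothed with a Gaussian kernel (bandwidth 3 bins, reflected edges)
and rescaled to conserve the total; smoothing is a visualization default
only and never feeds the statistics. Quarter-4 exclusion supports analyses
that drop the distal quarter, where the ablation transgene is inefficient.

## Statistics

Totals are compared with Student's pooled-variance unpaired *t* test
(two-sided, n₁+n₂−2 df) — the common default for "unpaired t test" in
Prism-style analyses — with Welch available via `equal_var=False`. Zero
pooled variance with equal means reports t = 0, p = 1; with unequal means
it is an error rather than a silent infinity.

Regional counts use a two-way ANOVA (group × quarter with interaction) fit
by least squares. Type-II sums of squares are the default so unbalanced
fish numbers are handled; Type-III is available. For balanced designs the
decomposition SS_total = SS_group + SS_quarter + SS_interaction + SS_error
holds to numerical precision. A response with no variance reports every
F = 0 and p = 1 by convention. Tukey's multiple-comparisons test
studentizes pairwise marginal-mean differences with the ANOVA's MS_error
and error df (Tukey–Kramer for unequal sizes); for two groups its p value
coincides with the F test's (q = √(2F)). Stars follow the
0.05/0.01/0.001/0.0001 convention, with boundary p values assigned to the
less-significant label because the defining inequalities are strict on
both sides. No correction beyond Tukey is applied.

## Peptide atlas

Peptides are placed by exhaustive substring search on the precursor and on
every single-variant-substituted copy (a variant hit must cover the
variant position and not already match the reference); multi-variant
combinations are not attempted, matching how variant peptide databases are
typically built. Monoisotopic masses come from a bundled residue table
derived from elemental compositions (C 12 exact, H 1.0078250319,
N 14.0030740052, O 15.9949146221, S 31.97207069), plus one water and the
modification deltas; the supported set is carbamidomethyl (+57.0215),
oxidation (+15.9949), C-terminal amidation (−0.9840), N-terminal acetyl
(+42.0106), pyroglutamate from Gln (−17.0265) or Glu (−18.0106), and
octanoyl (+126.1045)/decanoyl (+154.1358) for acylated ghrelin; arbitrary
numeric deltas are accepted so the table is not a closed list.
Pyroglutamate is modeled as a delta on residue 1. Mass matching uses a
relative ppm window (10 ppm default, the MS1 accuracy of the underlying
searches). Dibasic sites are all adjacent K/R pairs, overlaps included.
The atlas records per-residue coverage depth, junction positions where one
peptide ends exactly where another begins (rendered as a shared boundary),
region overlaps per peptide, and the dibasic sites; raw hits are kept so a
deduplicated view can be derived downstream.

## Synthetic data

The image generator renders each cell as a Gaussian disc — amplitude ×
exp(−d²/2σ²) with σ = radius/3, truncated at 3σ — rather than a hard
disc, so the threshold/size-filter interplay is realistic; a final
isotropic Gaussian blur (`psf_sigma`, default 0.5 px) stands in for the
optics, then background and optional Gaussian noise (clipped at zero) are
added. Cells sit at an arc-length fraction along a polyline gut midline
(straight or sinusoidal), jittered perpendicular by at most one radius.
Cluster members share their anchor's jitter and chain along the local
tangent at 1.2 × radius center spacing, which merges them into one
component at any threshold capturing most of each blob while keeping the
merged area close enough to k × the singleton area that the weighting rule
recovers k exactly. Rendering is a pure function of the spec including its
seed, and the ground-truth table has one row per simulated cell. The
generator does not model 3-D volumes, non-Gaussian optics, or
autofluorescent gut background.

Count tables are negative-binomial (Var = μ + αμ², Poisson at α = 0) per
fish × subtype × quarter, with the ablated group's means multiplied by
(1 − effect). The default scenarios mirror the study's regimes: a 50%
total-EEC reduction and 30% subtype reductions, cohorts of ~15 fish per
group, per-fish totals of order 20–120 cells. Calibration checks run the
t test over many simulated cohorts: under the null the rejection rate is
the nominal 5%, and under a 50% reduction at n = 15/group power is ~1 and
the estimated reduction unbiased.

Peptide sets are sampled fragment-wise: maximal runs of ≥ 2 basic residues
act as convertase cleavage blocks; with probability 0.75 a peptide is an
exact cleavage-bounded fragment, otherwise its termini are uniform
(ragged degradation products). Modifications are drawn from the search
set with fixed carbamidomethyl on Cys. Since a precursor's own ends are
natural peptide boundaries, the dibasic preference is assessed over
internal termini, most of which sit adjacent to a cleavage block.

What passing tests on these synthetics do **not** show: performance on
real images with uneven illumination, autofluorescence, or densely
overlapping cells beyond the modeled clusters, nor on real spectra with
identification error — the generators validate the arithmetic of the
pipeline, not the microscopy or the search engine.

## Problem sizes

The bundled checks use 512 × 1024 px images with 60–100 cells, 10–20
seeds per imaging scenario, 200 cohort replicates for power / 2000 for
type-I error, 200 random peptides for the mass oracle, and 100 simulated
peptide sets for the atlas oracles — sizes at which every stochastic
estimate is stable to well inside its asserted band.
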