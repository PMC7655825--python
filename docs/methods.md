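# Methods

This note records the models, procedures, numerical choices and known
limitations behind `scopekit`, module by module.

## Barcode design

Candidates are uniform random 8-mers accepted when they pass four filters:
maximum homopolymer run ≤ 2 nt, GC content in [40%, 60%] (over 8 nt this
forces exactly 4 G/C bases), not equal to their own reverse complement, and
Levenshtein distance ≥ 3 to every previously accepted candidate (greedy
screening; the accepted set depends on draw order, which the seed fixes).
Distances are computed with edlib. An explicit iteration budget
(`max_trials`, default 2 × 10⁶ draws) turns infeasible requests into a clear
error rather than a hang.

**Self-complementarity score.** For a barcode *b*, every full-length capture
oligo containing *b* is considered: anchor (32 nt) + UMI part 1 + S slot +
UMI part 2 + Q slot + UMI part 3 + 30 dT, with *b* in the S slot against
every partner in the Q slot and vice versa, and the 8 UMI positions set to
N. The score of one oligo is the maximum weighted length of a contiguous
antiparallel Watson–Crick stretch the oligo can form with itself: position
pairs (i, j), (i+1, j−1), … accumulate 1 per C-G pair and 2/3 per A-T pair;
N pairs with any base at the weaker 2/3 weight (conservative), and a base
never pairs with itself. The definition covers both hairpins and self-dimers
and is evaluated by a vectorized run-length dynamic program along the
pairing anti-diagonals, batched over all partner oligos; the test suite
checks it against a brute-force enumeration of all substring pairs. The
barcode's score is the maximum over all its oligo contexts, and the
lower-scoring half of the candidate pool is retained (ties broken
lexicographically for determinism).

After the cut the retained sequences alternate, in (score, sequence) order,
between the S and Q roles so both roles receive a balanced score
distribution; the split rule is otherwise arbitrary.

**Binary codes.** Each role's 96 sequences receive distinct 8-bit codes
drawn (seeded) from the 254 codes that are neither all-zeros nor all-ones:
all-zeros is indistinguishable from a failed hybridization series, all-ones
from a stuck-bright bead, and the bead-by-bead decoder can only produce
splits with at least one 0 and one 1. The probe for a barcode is its
reverse complement; it joins the pool of cycle *k* iff bit *k* of the code
is 1 (S probes report in Cy5, Q probes in Cy3), so the union over all
cycles is exactly 192 distinct oligos and pool membership reconstructs every
code.

## Optical decoding

Both decoders consume the n-bead × (8 cycles × 2 channels) matrix of mean
bead fluorescence.

*Cycle-by-cycle* (population method): per cycle and channel, intensities are
natural-log transformed (inputs validated positive; no pseudocount) and
histogrammed into 50 bins. B₁ is the most-populated bin strictly below the
median, B₂ the most-populated bin strictly above it, and the threshold is
the center of the least-populated bin strictly between them. Two documented
fallbacks: when no bin lies between B₁ and B₂ the threshold is the midpoint
of their centers, and when a point-mass population leaves no bin center on
one side of the median the outermost populated bins stand in for the modes
(a single populated bin is an error and the beads are reported unmappable).
No retry is attempted for unmappable codes.

*Bead-by-bead*: per bead and channel, the eight values are floored at
ε = 1 a.u. (so the fold-change denominator is defined; ordering is
preserved), sorted ascending to y₁…y₈, and the relative fold changes
fₙ = (yₙ₊₁ − yₙ)/yₙ computed for n = 1…7. The largest fₙ (ties: smallest n,
deterministic) splits the values into 0s and 1s; if the code is not in the
table the split moves to the next largest fold change until a whitelisted
code appears or the seven splits are exhausted (unmappable). Channels are
decoded independently and a bead counts as decoded only when both channels
map. Because the split is chosen within the bead, the call is invariant to
per-bead intensity scaling and robust to per-bead additive background —
the regime where the population threshold degrades.

Decoding outcomes against a sequenced barcode set follow the three-way
taxonomy: (1) unmappable code, (2) mappable barcode absent from sequencing,
(3)/correct — mappable and sequenced. Outcomes 1 and 2 cost yield only.

## Image analysis

Pixel coordinates are 0-based, origin top-left, x rightward, y downward.
Wells (dark disks on a bright background) are found by a local-mean
threshold (window 51 px, offset 10 a.u. — both configurable; local
thresholding makes detection invariant to global offsets), 8-connectivity
labeling, and area/solidity gates. Occupancy comes from the bimodal
distribution of well-mean fluorescence via the Gaussian-mixture valley
threshold described under Downstream analysis; a unimodal distribution
yields all-unoccupied with a warning. Note the bimodal model assumes
multiplets are rare: at high doublet rates the well-mean distribution is
trimodal and the occupancy call degrades.

Cells are segmented per occupied-well crop (smallest bounding square) with
an Otsu auto-threshold, 8-connectivity, and a 20 px² minimum particle area;
wells with ≥ 2 particles are excluded. The 16 features use the Crofton
perimeter estimate (unbiased on digital disks, so a rasterized circle's
circularity ≈ 1, clamped at 1), moments-based ellipse axes, and Feret
diameters computed by exact rotating calipers over the convex hull of the
pixel corners (so 1-px-wide regions have nonzero width). Bead tracking maps
cycle B–H detections to the nearest cycle-A bead (unmatched detections
beyond the match radius are dropped); a bead missing from a cycle has its
intensities re-read from that cycle's images at the cycle-A position and is
flagged. Multiplet labels partition occupied wells: mixed (≥ 1 green and
≥ 1 magenta object), single-species multiplet (≥ 2 of one color), singlet.

## Sequence processing

Read 1 layout: positions 1–2, 11–12, 21–24 (1-based) concatenate to the
8-nt UMI; 3–10 are the S half and 13–20 the Q half. Reads shorter than
24 nt are dropped and counted. Barcode correction is exact match, else the
unique Hamming-1 neighbor (neighborhoods are provably disjoint at the
whitelists' minimum pairwise Hamming distance of 3; the index builder fails
loudly otherwise); N bases match nothing and count as mismatches. A read is
kept only when both halves resolve. Read 2 is trimmed at the first A-tract
of length ≥ 8 and discarded below 24 nt. Alignment is out of scope: a TSV
of (read_id, gene, species, chromosome[, region]) is the external aligner's
contract, restricted to reads uniquely mapped to exons on the annotated
strand. Reads sharing (cell barcode, gene) collapse UMIs by connected
components under Hamming-distance-1 edges (configurable to exact match);
molecule counts are independent of read order and duplication. Device
regions, when present, suffix the cell barcode so counting is per-region.
Species calls require a strict > 90% read fraction (default), otherwise
mixed; zero reads is unclassified.

## Linking

Decoding-round coordinates map onto the live-imaging frame by a similarity
transform (translation + isotropic scale + rotation) fit exactly to two
anchor wells — two point pairs cannot determine shear, so affine would be
underdetermined; the rotation comes for free in the complex-number form
z → az + b. Cells pair with the nearest mapped bead within one well radius;
a bead claims at most one cell (closest wins, ties by well id). A link
requires the decoded 16-nt barcode to appear exactly once among sequenced
profiles; beads in one region decoding to the same barcode are ambiguous
and both excluded, keeping the link table a partial injection.
Class-balanced accuracy is the unweighted mean of per-class agreement rates
with sequencing as the reference; multiplet sensitivity/specificity use
sequencing-based mixed-species calls as truth.

## Downstream analysis

**Valley threshold.** A two-component 1-D Gaussian mixture is fit by EM
(means initialized at the 25%/75% quantiles, tol 1e-6, ≤ 500 iterations),
and the threshold is the center of the least-populated histogram bin
(default 50 bins, matching the decoding histogram) strictly between the two
component means. The fit is rejected as degenerate when the means are
closer than one bin width or when Ashman's D = √2·|μ₂−μ₁|/√(σ₁²+σ₂²) < 2,
the standard condition for a two-Gaussian mixture to be bimodal — this is
what turns unimodal occupancy or score distributions into an explicit
failure instead of an arbitrary cut. On well-separated mixtures
(≥ 5σ) the threshold agrees with an exhaustive misclassification-minimizing
scan to within one bin width (tested).

**Dead-cell filter.** A single Gaussian is fit to live-stain intensities
(n ≥ 20) and cells below its 5th percentile (μ − 1.645σ) are dropped.

**Imputation and malignancy.** Expected expression is θβᵀ from a
nonnegative factor model; the imputed matrix is log₂(θβᵀ/10⁴ + 1)
(monotone in every θ and β entry). The malignancy score of a cell is its
mean imputed expression over Chr7 genes minus the mean over Chr10 genes;
the threshold comes from the valley threshold above and cells strictly
above it are labeled malignant. At realistic expected counts the transform
is nearly linear, so the score scales with cell depth; the separation
approaches log₂(1.5) − log₂(0.5) ≈ 1.585 only in the high-expression limit.

**Meta-features.** The 16 features are z-scored (constant features dropped
with a warning) and hierarchically clustered as variables with average
linkage and correlation distance; the dendrogram is cut at k = 3 (size,
shape, staining intensity) and each meta-feature is the mean of its
members' z-scores. Cells are then clustered on the meta-features the same
way and cut at k = 2; cluster ids are arbitrary.

**Differential expression.** Between two cell groups: (1) the larger group
is randomly subsampled to the smaller's size; (2) the deeper group's counts
are binomially thinned per cell at rate (target mean)/(group mean) so mean
molecules per cell match — the mechanism behind "random subsampling" is a
design choice, thinning being the exchangeable-molecule reading;
(3) normalization defaults to per-cell size factors scaling each cell to
the pooled mean depth (the published pooling normalization is an external
package's algorithm; externally computed size factors are accepted);
(4) per-gene two-sided Mann–Whitney U with normal approximation and tie
correction; (5) Benjamini–Hochberg adjustment. Genes with all-zero counts
in both groups are reported NA.

## Simulator

The simulator defines the study conditions; its defaults are fixed, not
tuning knobs.

*Bead intensities*: log-normal around on/off means (defaults 2000/100 a.u.,
a 20× contrast) with coefficient of variation 0.25; the per-bead
autofluorescence offset |N(0, σ)| is added to all eight Cy3 cycles only,
emulating bead autofluorescence at shorter wavelengths (Cy5 clean). σ = 100,
comparable to the off mean, is the regime used to contrast the decoders.

*Device images*: dark wells (radius 13 px, pitch 40 px) on a bright
background (200 vs 80 a.u., Gaussian read noise σ = 2); cells are
uniform-intensity disks (radius 5 px, 120 a.u. over a 10 a.u. fluorescence
background) in a green or magenta channel; two cells in a multiplet well
sit on opposite sides of the well so they never merge into one particle.

*Expression*: gamma-Poisson from K = 5 factors per species (cells express
only their species' genes). Per-cell loadings are normalized to unit sum
and multiplied by a lognormal library-size factor (CV 0.2), so depth varies
around a common mean (1000 cells × 200 genes, 2000 molecules/cell by
default) — without this, depth spread at realistic counts swamps the
aneuploidy signal near zero score, which is the denoising that a factor
model provides on real data. Malignant cells (40% by default) scale Chr7
gene rates ×1.5 and Chr10 ×0.5; the emitted θ/β carry the aneuploidy as a
duplicated gene-rescaled factor block, so θβᵀ equals the generative rate
exactly and imputation tests are well-posed.

*Reads*: read 1 follows the barcode/UMI layout with per-base substitution
errors; read 2 is a deterministic A-free 50-mer per gene, with a 10-A tail
appended at the poly(A) rate; 3 reads per molecule by default. Within one
(cell, gene) group, UMIs are drawn pairwise ≥ 3 substitutions apart, so the
truth molecule count is exact under Hamming-1 collapse (the collision bound
is zero by construction); the gene-tag table plays the perfect aligner.

Problem sizes throughout (hundreds to thousands of beads/cells, tens to
hundreds of genes) are chosen so every property is measurable with
comfortable statistical margins at desk scale.

## What the simulations do and do not show

Passing tests demonstrate the algorithms' correctness and the direction of
the bead-by-bead advantage, exact counting at zero error, and calibrated
thresholds **on the generative models above**. Real data add effects the
simulator omits: optical PSF blur and bead segmentation error, uneven
illumination, ambient RNA and barcode swapping, overdispersion beyond
gamma-Poisson, UMI collisions (real UMIs are not spaced), doublet
expression mixtures, and alignment ambiguity. Headline dataset metrics that
depend on deep sequencing of real libraries are correspondingly out of
reach at desk scale; the package reproduces the procedures and their
analytic/structural properties instead.
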