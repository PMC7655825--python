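# scopekit

Linking live-cell imaging to single-cell RNA-seq requires knowing which
sequencing barcode sits in the same microwell as each imaged cell. `scopekit`
implements the computational core of that workflow for optically decodable
mRNA capture beads: each bead carries a 16-nt cell barcode built from two
8-nt halves (roles **S** and **Q**, each drawn from a 96-member pool by
split-pool synthesis), and every 8-nt half maps to a unique 8-bit binary
code that is read out by eight cycles of two-color fluorescent probe
hybridization — presence of signal in cycle *k* means bit *k* = 1. The
package is aimed at people building or analyzing microwell-based
image+expression experiments, and at anyone who wants a fully simulated,
ground-truthed sandbox for the pipeline.

It covers, as a library with a thin CLI:

- **Barcode design** — candidate 8-mers filtered to pairwise Levenshtein
  distance ≥ 3, homopolymers ≤ 2 nt, GC ∈ [40%, 60%], no
  self-reverse-complements; each candidate scored by its worst-case
  self-complementarity over all full-length capture-oligo contexts
  (contiguous antiparallel Watson–Crick stretches, C-G pairs weighted 1 and
  A-T pairs 2/3) and the lower-scoring half retained; binary codes and
  per-cycle probe pools derived from the result.
- **Optical decoding** — two decoders for the n × (8 × 2) bead intensity
  matrix. *Cycle-by-cycle*: per cycle and channel, a valley threshold in the
  50-bin histogram of log intensities across all beads. *Bead-by-bead*: per
  bead and channel, sort the eight intensities y₁ ≤ … ≤ y₈, compute fold
  changes fₙ = (yₙ₊₁ − yₙ)/yₙ, split at argmax fₙ, and retry at the next
  largest gap while the code is absent from the code table.
- **Image analysis** — microwell detection by local thresholding, occupancy
  calls from the bimodal well-mean fluorescence, the 16 per-cell features
  (area, 5 intensity statistics, perimeter, width/height, ellipse axes,
  circularity = 4πA/P², Feret and minimum Feret diameters,
  roundness = 4A/(π·major²), solidity), bead tracking across cycles, and
  two-color multiplet labeling.
- **Sequence processing** — read-1 parsing (NN + S + NN + Q + NNNN, the N
  segments concatenating to the 8-nt UMI), single-substitution barcode
  correction against the whitelists, poly(A) trimming (tracts of > 7 A's;
  fragments < 24 nt discarded), Hamming-1 UMI collapse, and the
  cells × genes molecule count matrix (alignment is consumed as an external
  gene-tag table).
- **Linking** — two-anchor similarity registration, nearest-bead cell
  pairing within one well radius, exact-and-unique barcode joins with the
  three-outcome decoding-error taxonomy, class-balanced accuracy, and
  multiplet sensitivity/specificity.
- **Downstream analysis** — Gaussian-mixture valley thresholds, the
  5th-percentile dead-cell filter, factor-model imputation
  log₂(θβᵀ/10⁴ + 1), the malignancy score ⟨log₂ Chr7⟩ − ⟨log₂ Chr10⟩ with a
  double-Gaussian cut, imaging meta-features (k = 3 feature clusters) and
  k = 2 cell clustering, and subsampled Mann–Whitney differential expression
  with Benjamini–Hochberg correction.
- **Simulator** — every input above with ground truth: bimodal bead
  fluorescence with channel-asymmetric autofluorescence, microwell device
  images, barcoded reads with substitution errors and poly(A) tails, and
  gamma-Poisson expression with mixed species and Chr7-gain/Chr10-loss
  aneuploidy.

## Worked example

`examples/decode_beads.py` simulates 1,000 beads with per-bead Cy3
autofluorescence (offset σ = 100 at an off-state mean of 100) and decodes
them both ways:

```
bead-by-bead accuracy:  1.000
cycle-by-cycle accuracy: 0.996
```

The per-bead sorted-gap decoder is immune to per-bead additive background,
so it dominates the population threshold whenever autofluorescence blurs
the global on/off separation; at higher offsets the gap widens (across
seeds the population decoder drops to 0.86–0.99 while the per-bead decoder
stays at 1.00).

`examples/design_barcodes.py` prints the design's accounting:

```
S pool: 96 barcodes, Q pool: 96
combinatorial barcodes per region: 9216
min pairwise Levenshtein: 3   min pairwise Hamming: 3
max homopolymer run: 2 nt
distinct probes across all 8 cycles x 2 channels: 192
```

9216 of the 2¹⁶ = 65,536 possible 16-bit codes are in use, so most decoding
errors land on unmappable codes (yield loss, not wrong links). The other
examples cover image features, molecule counting, linking, and the
malignancy/differential-expression calls.

There is also a thin CLI: `scopekit design|decode|features|count|link|de|simulate`
(see `scopekit --help`).

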