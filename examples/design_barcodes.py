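"""Design the two 96-member barcode pools and their hybridization probe pools.

Generates candidate 8-mers under the sequence filters, scores each against
all full-length capture-oligo contexts, keeps the better (lower-scoring)
half, assigns 8-bit binary codes, and builds the per-cycle probe pools.
"""

import itertools

from scopekit import build_probe_pools, design_barcode_sets
from scopekit.barcode_design import hamming, levenshtein, max_homopolymer

design = design_barcode_sets(n_per_role=96, seed=0)
seqs = design.all_sequences

min_lev = min(levenshtein(a, b) for a, b in itertools.combinations(seqs, 2))
min_ham = min(hamming(a, b) for a, b in itertools.combinations(seqs, 2))
pools = build_probe_pools(design.s_set, design.q_set)
n_probes = len({p for c in pools.values() for pool in c.values() for p in pool.probes})

print(f"S pool: {len(design.s_set.sequences)} barcodes, Q pool: {len(design.q_set.sequences)}")
print(f"combinatorial barcodes per region: {len(design.s_set.sequences) * len(design.q_set.sequences)}")
print(f"min pairwise Levenshtein: {min_lev}   min pairwise Hamming: {min_ham}")
print(f"max homopolymer run: {max(max_homopolymer(s) for s in seqs)} nt")
print(f"distinct probes across all 8 cycles x 2 channels: {n_probes}")
print(f"example: barcode {seqs[0]} -> code {design.s_set.code_map[seqs[0]]}")
# The code's 1-bits say in which hybridization cycles this bead lights up;
# 192 probes cover both 96-member pools, one complement per barcode.
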