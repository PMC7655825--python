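"""Design of optically decodable split-pool bead barcodes.

Two pools of 96 8-nt barcodes (roles S and Q) are generated under sequence
constraints (pairwise Levenshtein distance >= 3, homopolymers <= 2 nt,
GC content in [40%, 60%], no self-reverse-complementary sequences), ranked
by a self-complementarity score computed over all full-length capture-oligo
contexts, and cut at the median score. Each retained barcode is assigned a
unique 8-bit binary code that drives the composition of the per-cycle
hybridization probe pools: the probe complementary to a barcode is present
in the pool for cycle k exactly when bit k of its code is 1.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import edlib
import numpy as np

__all__ = [
    "ANCHOR",
    "CYCLES",
    "BarcodeCandidate",
    "BarcodeSet",
    "OligoTemplate",
    "ProbePool",
    "DesignResult",
    "generate_candidates",
    "self_complementarity_score",
    "select_barcodes",
    "assign_binary_codes",
    "build_probe_pools",
    "build_full_length_oligo",
    "design_barcode_sets",
    "gc_percent",
    "max_homopolymer",
    "reverse_complement",
    "levenshtein",
    "hamming",
]

#: Universal PCR adapter + oligo(dT) priming anchor at the 5' end of every
#: capture oligo (32 nt).
ANCHOR = "TTTTTTTAAGCAGTGGTATCAACGCAGAGTAC"

#: Hybridization cycle labels; cycle k reads out bit k of the binary code.
CYCLES = "ABCDEFGH"

#: Reporter dye per barcode role.
ROLE_CHANNEL = {"S": "Cy5", "Q": "Cy3"}

_BASES = "ACGT"
_COMP = str.maketrans("ACGTN", "TGCAN")

# Alphabet indexing for vectorized pairing: A=0 C=1 G=2 T=3 N=4.
_IDX = {b: i for i, b in enumerate("ACGTN")}
_PAIRABLE = np.zeros((5, 5), dtype=bool)
for _a, _b in [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]:
    _PAIRABLE[_IDX[_a], _IDX[_b]] = True
_PAIRABLE[4, :] = True  # N treated as pairable with any base
_PAIRABLE[:, 4] = True
# Per-pair weights: C-G pairs count 1, A-T pairs 2/3; pairs involving N are
# taken at the weaker A-T affinity (conservative worst case).
_WEIGHT = np.full((5, 5), 2.0 / 3.0, dtype=np.float32)
_WEIGHT[_IDX["C"], _IDX["G"]] = 1.0
_WEIGHT[_IDX["G"], _IDX["C"]] = 1.0


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def gc_percent(seq: str) -> float:
    return 100.0 * (seq.count("G") + seq.count("C")) / len(seq)


def max_homopolymer(seq: str) -> int:
    """Length of the longest single-base run."""
    return max(len(list(g)) for _, g in itertools.groupby(seq))


def levenshtein(a: str, b: str) -> int:
    return edlib.align(a, b, task="distance")["editDistance"]


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class OligoTemplate:
    """Layout of the full-length mRNA capture oligo.

    anchor (32 nt) + UMI part 1 (2 nt) + S barcode (8 nt) + UMI part 2
    (2 nt) + Q barcode (8 nt) + UMI part 3 (4 nt) + oligo(dT) tail (30 nt),
    86 nt total. The 8-nt UMI is dispersed into three segments that double
    as spacers between the functional blocks.
    """

    anchor: str = ANCHOR
    umi_lengths: tuple[int, int, int] = (2, 2, 4)
    barcode_length: int = 8
    tail_length: int = 30

    @property
    def full_length(self) -> int:
        return (
            len(self.anchor)
            + sum(self.umi_lengths)
            + 2 * self.barcode_length
            + self.tail_length
        )

    def __post_init__(self) -> None:
        if sum(self.umi_lengths) != 8:
            raise ValueError("UMI segment lengths must sum to 8")


@dataclass(frozen=True)
class BarcodeCandidate:
    sequence: str
    selfcomp_score: float | None = None

    @property
    def gc_percent(self) -> float:
        return gc_percent(self.sequence)

    @property
    def max_homopolymer(self) -> int:
        return max_homopolymer(self.sequence)


@dataclass
class BarcodeSet:
    """One role's barcode whitelist with its binary code table."""

    role: str  # "S" or "Q"
    sequences: list[str]
    code_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.role not in ("S", "Q"):
            raise ValueError(f"role must be 'S' or 'Q', got {self.role!r}")

    @property
    def barcode_by_code(self) -> dict[str, str]:
        return {code: seq for seq, code in self.code_map.items()}


@dataclass(frozen=True)
class ProbePool:
    cycle: str  # one of A..H
    channel: str  # Cy5 (S role) or Cy3 (Q role)
    probes: tuple[str, ...]


@dataclass
class DesignResult:
    s_set: BarcodeSet
    q_set: BarcodeSet
    candidates: list[BarcodeCandidate]  # all scored candidates, pre-cut
    template: OligoTemplate

    @property
    def all_sequences(self) -> list[str]:
        return list(self.s_set.sequences) + list(self.q_set.sequences)


def _passes_filters(
    seq: str,
    max_homopolymer_run: int,
    gc_min: float,
    gc_max: float,
) -> bool:
    if max_homopolymer(seq) > max_homopolymer_run:
        return False
    if not (gc_min <= gc_percent(seq) <= gc_max):
        return False
    if seq == reverse_complement(seq):
        return False
    return True


def generate_candidates(
    n: int,
    seed: int,
    *,
    length: int = 8,
    min_distance: int = 3,
    max_homopolymer_run: int = 2,
    gc_min: float = 40.0,
    gc_max: float = 60.0,
    max_trials: int = 2_000_000,
) -> list[BarcodeCandidate]:
    """Rejection-sample barcode candidates under the design constraints.

    Uniform random k-mers are screened for homopolymer, GC and palindrome
    filters, then greedily accepted if their Levenshtein distance to every
    previously accepted candidate is at least ``min_distance``. Deterministic
    for a fixed seed.

    Raises
    ------
    RuntimeError
        If ``n`` candidates cannot be found within ``max_trials`` draws.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    accepted: list[str] = []
    seen: set[str] = set()
    trials = 0
    while len(accepted) < n:
        if trials >= max_trials:
            raise RuntimeError(
                f"could not find {n} candidates within the iteration budget "
                f"of {max_trials} draws ({len(accepted)} found)"
            )
        # draw in blocks to amortize RNG overhead
        block = rng.integers(0, 4, size=(256, length))
        for row in block:
            trials += 1
            seq = "".join(_BASES[i] for i in row)
            if seq in seen:
                continue
            seen.add(seq)
            if not _passes_filters(seq, max_homopolymer_run, gc_min, gc_max):
                continue
            if all(levenshtein(seq, other) >= min_distance for other in accepted):
                accepted.append(seq)
                if len(accepted) == n:
                    break
    return [BarcodeCandidate(s) for s in accepted]


def build_full_length_oligo(
    s: str,
    q: str,
    umi: str,
    template: OligoTemplate | None = None,
    *,
    allow_n: bool = False,
) -> str:
    """Assemble the full-length capture oligo for one (S, Q, UMI) triple."""
    template = template or OligoTemplate()
    k = template.barcode_length
    if len(s) != k or len(q) != k:
        raise ValueError(f"barcodes must be {k} nt")
    if len(umi) != sum(template.umi_lengths):
        raise ValueError(f"UMI must be {sum(template.umi_lengths)} nt")
    alphabet = set("ACGTN" if allow_n else "ACGT")
    for name, seq in (("S barcode", s), ("Q barcode", q), ("UMI", umi)):
        if not set(seq) <= alphabet:
            raise ValueError(f"{name} contains non-{''.join(sorted(alphabet))} characters: {seq}")
    l1, l2, l3 = template.umi_lengths
    return (
        template.anchor
        + umi[:l1]
        + s
        + umi[l1 : l1 + l2]
        + q
        + umi[l1 + l2 :]
        + "T" * template.tail_length
    )


def _encode(seqs: list[str]) -> np.ndarray:
    """Encode sequences (equal length) as an int matrix over ACGTN."""
    return np.array([[_IDX[b] for b in s] for s in seqs], dtype=np.int8)


def _max_pairing_runs(oligos: np.ndarray) -> np.ndarray:
    """Best contiguous antiparallel self-pairing score per oligo.

    For each oligo, positions i and j can pair when the bases are
    Watson-Crick complementary; a contiguous duplex stretch follows the
    anti-diagonal (i, j), (i+1, j-1), ... Scores accumulate per-pair weights
    (C-G = 1, A-T = 2/3) and the maximum over all stretches is returned.
    Vectorized dynamic program over a stack of oligos.
    """
    P, L = oligos.shape
    pair = _PAIRABLE[oligos[:, :, None], oligos[:, None, :]]
    w = _WEIGHT[oligos[:, :, None], oligos[:, None, :]]
    idx = np.arange(L)
    pair[:, idx, idx] = False  # a base cannot pair with itself
    best = np.zeros(P, dtype=np.float32)
    run = np.zeros((P, L), dtype=np.float32)  # run score ending at (i, j)
    for i in range(L):
        shifted = np.zeros_like(run)
        shifted[:, :-1] = run[:, 1:]  # run[i-1, j+1]
        run = np.where(pair[:, i, :], w[:, i, :] + shifted, 0.0)
        best = np.maximum(best, run.max(axis=1))
    return best


def self_complementarity_score(
    barcode: str,
    partner_set: list[str],
    template: OligoTemplate | None = None,
) -> float:
    """Worst-case self-hybridization score of a barcode in oligo context.

    The score of a single oligo is the weighted length of its longest
    contiguous self-complementary stretch (C-G pairs weight 1, A-T pairs
    2/3; undetermined N positions pair with anything at weight 2/3). The
    barcode's score is the maximum over all full-length oligos that contain
    it — in the S slot with every partner in the Q slot, and vice versa.
    """
    if not partner_set:
        raise ValueError("partner_set must be non-empty")
    template = template or OligoTemplate()
    umi = "N" * sum(template.umi_lengths)
    oligo_strs = [
        build_full_length_oligo(barcode, p, umi, template, allow_n=True)
        for p in partner_set
    ] + [
        build_full_length_oligo(p, barcode, umi, template, allow_n=True)
        for p in partner_set
    ]
    return float(_max_pairing_runs(_encode(oligo_strs)).max())


def score_candidates(
    candidates: list[BarcodeCandidate],
    template: OligoTemplate | None = None,
) -> list[BarcodeCandidate]:
    """Score every candidate against the full candidate pool."""
    seqs = [c.sequence for c in candidates]
    return [
        BarcodeCandidate(s, self_complementarity_score(s, seqs, template))
        for s in seqs
    ]


def select_barcodes(candidates: list[BarcodeCandidate]) -> list[BarcodeCandidate]:
    """Retain the floor(n/2) candidates with the lowest scores.

    Ties at the cutoff are broken lexicographically by sequence.
    """
    if len(candidates) < 2:
        raise ValueError("need at least 2 scored candidates")
    if any(c.selfcomp_score is None for c in candidates):
        raise ValueError("candidates must be scored before selection")
    ranked = sorted(candidates, key=lambda c: (c.selfcomp_score, c.sequence))
    return ranked[: len(candidates) // 2]


def assign_binary_codes(sequences: list[str], seed: int) -> dict[str, str]:
    """Assign each sequence a unique 8-bit code, excluding 0x00 and 0xFF.

    The all-zeros code is indistinguishable from total hybridization failure
    and all-ones from a stuck-bright bead, so both are excluded, leaving
    2^8 - 2 = 254 usable codes.
    """
    if len(set(sequences)) != len(sequences):
        raise ValueError("duplicate sequences in barcode set")
    usable = 2**8 - 2
    if len(sequences) > usable:
        raise ValueError(f"at most {usable} codes available")
    rng = np.random.default_rng(seed)
    codes = rng.permutation(np.arange(1, 255))[: len(sequences)]
    return {seq: format(int(c), "08b") for seq, c in zip(sequences, codes)}


def build_probe_pools(s_set: BarcodeSet, q_set: BarcodeSet) -> dict[str, dict[str, ProbePool]]:
    """Per-cycle two-channel probe pools.

    The probe for a barcode is its reverse complement; it enters the pool of
    cycle k exactly when bit k of the barcode's binary code is 1. S-role
    probes report in Cy5, Q-role probes in Cy3.
    """
    pools: dict[str, dict[str, ProbePool]] = {}
    for bc_set in (s_set, q_set):
        if not bc_set.code_map:
            raise ValueError(f"{bc_set.role} set has no code map")
    for k, cycle in enumerate(CYCLES):
        pools[cycle] = {}
        for bc_set in (s_set, q_set):
            probes = tuple(
                reverse_complement(seq)
                for seq in bc_set.sequences
                if bc_set.code_map[seq][k] == "1"
            )
            pools[cycle][bc_set.role] = ProbePool(
                cycle=cycle, channel=ROLE_CHANNEL[bc_set.role], probes=probes
            )
    return pools


def design_barcode_sets(
    n_per_role: int = 96,
    seed: int = 0,
    template: OligoTemplate | None = None,
    **candidate_kwargs,
) -> DesignResult:
    """Run the full design: candidates -> scores -> 50% cut -> roles -> codes.

    Twice the final number of barcodes is sampled so that the bottom-50%
    self-complementarity cut retains exactly ``2 * n_per_role`` sequences.
    Retained barcodes alternate between the S and Q roles in score order so
    both roles receive a balanced score distribution.
    """
    template = template or OligoTemplate()
    candidates = generate_candidates(4 * n_per_role, seed, **candidate_kwargs)
    scored = score_candidates(candidates, template)
    retained = select_barcodes(scored)
    s_seqs = [c.sequence for c in retained[0::2]]
    q_seqs = [c.sequence for c in retained[1::2]]
    s_set = BarcodeSet("S", s_seqs, assign_binary_codes(s_seqs, seed))
    q_set = BarcodeSet("Q", q_seqs, assign_binary_codes(q_seqs, seed + 1))
    return DesignResult(s_set=s_set, q_set=q_set, candidates=scored, template=template)
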