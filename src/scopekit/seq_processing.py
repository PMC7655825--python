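"""Read parsing, barcode/UMI error correction, and molecule counting.

Read 1 carries the cell-identifying barcode and UMI in the layout
NN (8-nt barcode S) NN (8-nt barcode Q) NNNN, where the N segments
concatenate to the 8-nt UMI. Read 2 carries the transcript fragment;
alignment is external and consumed as a gene-tag table of
(read_id, gene, species, chromosome) for reads uniquely mapped to exons on
the annotated strand. One substitution error is corrected in each barcode
half (the whitelists have minimum pairwise Hamming distance 3, so the
Hamming-1 neighborhoods of distinct barcodes are disjoint) and reads whose
two halves both resolve are kept. Reads sharing a corrected cell barcode,
gene, and UMI (up to one substitution) collapse to one molecule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "ReadRecord",
    "MoleculeCountMatrix",
    "parse_read1",
    "build_hamming1_index",
    "correct_barcode",
    "trim_polyA",
    "collapse_umis",
    "species_call",
    "count_pipeline",
]

_BASES = "ACGTN"


@dataclass
class ReadRecord:
    read_id: str
    s_obs: str
    q_obs: str
    umi_obs: str
    gene: str | None = None
    species: str | None = None
    chromosome: str | None = None
    region: str | None = None


@dataclass
class MoleculeCountMatrix:
    """Cells x genes unique-molecule counts with gene annotations.

    Cell barcodes are the 16-nt concatenation of the S and Q halves
    (suffixed with the device region when regions are used). ``gene_info``
    carries species and chromosome columns indexed by gene.
    """

    counts: sp.csr_matrix
    barcodes: list[str]
    gene_info: pd.DataFrame  # index: gene; columns: species, chromosome
    summary: dict = field(default_factory=dict)

    @property
    def genes(self) -> list[str]:
        return list(self.gene_info.index)

    def to_anndata(self):
        import anndata

        return anndata.AnnData(
            X=self.counts.astype(np.float32),
            obs=pd.DataFrame(index=self.barcodes),
            var=self.gene_info.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts.toarray(), index=self.barcodes, columns=self.genes
        )

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(str(outdir / "matrix.mtx"), sp.coo_matrix(self.counts))
        pd.Series(self.barcodes).to_csv(outdir / "barcodes.tsv", sep="\t", index=False, header=False)
        self.gene_info.to_csv(outdir / "genes.tsv", sep="\t", header=False)
        with open(outdir / "summary.json", "w") as fh:
            json.dump(self.summary, fh, indent=2)

    @classmethod
    def read(cls, indir: str | Path) -> "MoleculeCountMatrix":
        indir = Path(indir)
        counts = sp.csr_matrix(scipy.io.mmread(str(indir / "matrix.mtx")))
        barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0].tolist()
        gene_info = pd.read_csv(
            indir / "genes.tsv", sep="\t", header=None,
            names=["gene", "species", "chromosome"], index_col=0,
        )
        summary = {}
        summary_path = indir / "summary.json"
        if summary_path.exists():
            summary = json.loads(summary_path.read_text())
        return cls(counts=counts, barcodes=barcodes, gene_info=gene_info, summary=summary)


def parse_read1(seq: str) -> tuple[str, str, str] | None:
    """Extract (S, Q, UMI) from the read-1 layout NN S(8) NN Q(8) NNNN.

    Returns None for reads shorter than 24 nt (dropped upstream, counted).
    """
    if len(seq) < 24:
        return None
    s = seq[2:10]
    q = seq[12:20]
    umi = seq[0:2] + seq[10:12] + seq[20:24]
    return s, q, umi


def build_hamming1_index(whitelist: list[str]) -> dict[str, str]:
    """Map every sequence within Hamming distance 1 of a whitelist barcode
    to that barcode.

    With minimum pairwise Hamming distance 3 the neighborhoods are disjoint,
    so the mapping is well defined. Substituted positions include N so that
    an observed N (which matches nothing) still counts as one mismatch.
    """
    index: dict[str, str] = {}
    for bc in whitelist:
        index[bc] = bc
    for bc in whitelist:
        for i in range(len(bc)):
            for b in _BASES:
                if b == bc[i]:
                    continue
                neighbor = bc[:i] + b + bc[i + 1 :]
                prev = index.get(neighbor)
                if prev is not None and prev != bc:
                    raise ValueError(
                        f"whitelist violates minimum Hamming distance 3: "
                        f"{prev} and {bc} share neighbor {neighbor}"
                    )
                index[neighbor] = bc
    return index


def correct_barcode(obs: str, index: dict[str, str]) -> str | None:
    """Exact match, else the unique Hamming-1 neighbor, else None (reject)."""
    return index.get(obs)


def trim_polyA(read2: str, *, min_tract: int = 8, min_length: int = 24) -> str | None:
    """Remove the 3' poly(A) tail and length-filter the fragment.

    The suffix starting at the first A-tract of length >= ``min_tract``
    (i.e. more than 7 A's) is removed; fragments shorter than
    ``min_length`` nt afterwards are discarded (None).
    """
    run = 0
    cut = None
    for i, base in enumerate(read2):
        if base == "A":
            run += 1
            if run == min_tract:
                cut = i - min_tract + 1
                break
        else:
            run = 0
    trimmed = read2 if cut is None else read2[:cut]
    return trimmed if len(trimmed) >= min_length else None


def _umi_components(umis: list[str]) -> int:
    """Number of connected components under Hamming-distance-1 edges."""
    n = len(umis)
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    # index UMIs by their (position, base-masked) keys: two UMIs at Hamming 1
    # share a masked key at exactly the differing position
    buckets: dict[tuple[int, str], list[int]] = {}
    for i, u in enumerate(umis):
        for p in range(len(u)):
            buckets.setdefault((p, u[:p] + u[p + 1 :]), []).append(i)
    for members in buckets.values():
        for j in members[1:]:
            union(members[0], j)
    # exact duplicates also merge (same full key at any position)
    return len({find(i) for i in range(n)})


def collapse_umis(
    records: list[ReadRecord],
    *,
    method: str = "hamming1",
) -> MoleculeCountMatrix:
    """Collapse reads to molecules and build the count matrix.

    Reads with the same cell barcode and gene whose UMIs are connected by
    single-substitution edges are one molecule (``method="hamming1"``,
    connected components); ``method="exact"`` collapses identical UMIs only.
    """
    if method not in ("hamming1", "exact"):
        raise ValueError(f"unknown collapse method {method!r}")
    groups: dict[tuple[str, str], list[str]] = {}
    annot: dict[str, tuple[str | None, str | None]] = {}
    for r in records:
        if r.gene is None:
            continue
        cell = r.s_obs + r.q_obs
        if r.region is not None:
            cell = f"{cell}-{r.region}"
        groups.setdefault((cell, r.gene), []).append(r.umi_obs)
        annot[r.gene] = (r.species, r.chromosome)

    barcodes = sorted({cell for cell, _ in groups})
    genes = sorted({g for _, g in groups})
    bc_idx = {b: i for i, b in enumerate(barcodes)}
    g_idx = {g: j for j, g in enumerate(genes)}
    counts = sp.lil_matrix((len(barcodes), len(genes)), dtype=np.int64)
    for (cell, gene), umis in groups.items():
        if method == "exact":
            n_mol = len(set(umis))
        else:
            n_mol = _umi_components(sorted(set(umis)))
        counts[bc_idx[cell], g_idx[gene]] = n_mol
    gene_info = pd.DataFrame(
        {
            "species": [annot[g][0] for g in genes],
            "chromosome": [annot[g][1] for g in genes],
        },
        index=pd.Index(genes, name="gene"),
    )
    return MoleculeCountMatrix(
        counts=counts.tocsr(), barcodes=barcodes, gene_info=gene_info
    )


def species_call(
    species_counts: dict[str, int] | pd.Series,
    threshold: float = 0.90,
) -> str:
    """Call a cell's species from its species-split read counts.

    A species wins when its fraction of reads strictly exceeds
    ``threshold``; otherwise the cell is mixed. Zero total reads is
    unclassified.
    """
    counts = pd.Series(species_counts, dtype=float)
    total = counts.sum()
    if total == 0:
        return "unclassified"
    fractions = counts / total
    top = fractions.idxmax()
    return str(top) if fractions[top] > threshold else "mixed"


def _iter_fastq(path: str | Path):
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    import gzip

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for title, seq, _qual in FastqGeneralIterator(fh):
            yield title.split()[0], seq


def count_pipeline(
    r1_fastq: str | Path,
    r2_fastq: str | Path,
    tags: pd.DataFrame,
    s_whitelist: list[str],
    q_whitelist: list[str],
    *,
    collapse: str = "hamming1",
) -> MoleculeCountMatrix:
    """Full counting pipeline from FASTQ pairs and a gene-tag table.

    ``tags`` must have columns read_id, gene, species, chromosome (and an
    optional region column); it is the external aligner's contract and only
    lists reads uniquely mapped to exons on the annotated strand.
    """
    s_index = build_hamming1_index(s_whitelist)
    q_index = build_hamming1_index(q_whitelist)
    tag_map = tags.set_index("read_id")
    has_region = "region" in tags.columns

    stats = {
        "total_read_pairs": 0,
        "dropped_short_read1": 0,
        "dropped_barcode": 0,
        "dropped_short_read2": 0,
        "dropped_unaligned": 0,
        "kept": 0,
    }
    records: list[ReadRecord] = []
    for (rid1, seq1), (rid2, seq2) in zip(_iter_fastq(r1_fastq), _iter_fastq(r2_fastq)):
        if rid1 != rid2:
            raise ValueError(f"read id mismatch between mates: {rid1} vs {rid2}")
        stats["total_read_pairs"] += 1
        parsed = parse_read1(seq1)
        if parsed is None:
            stats["dropped_short_read1"] += 1
            continue
        s_obs, q_obs, umi = parsed
        s_bc = correct_barcode(s_obs, s_index)
        q_bc = correct_barcode(q_obs, q_index)
        if s_bc is None or q_bc is None:
            stats["dropped_barcode"] += 1
            continue
        if trim_polyA(seq2) is None:
            stats["dropped_short_read2"] += 1
            continue
        if rid1 not in tag_map.index:
            stats["dropped_unaligned"] += 1
            continue
        row = tag_map.loc[rid1]
        stats["kept"] += 1
        records.append(
            ReadRecord(
                read_id=rid1,
                s_obs=s_bc,
                q_obs=q_bc,
                umi_obs=umi,
                gene=row["gene"],
                species=row.get("species"),
                chromosome=row.get("chromosome"),
                region=row["region"] if has_region else None,
            )
        )
    matrix = collapse_umis(records, method=collapse)
    matrix.summary = stats
    return matrix
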