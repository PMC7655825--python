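"""Synthetic data generation for every pipeline input, with ground truth.

The simulator emulates the study conditions end to end: bimodal bead
fluorescence with channel-dependent separation (per-bead additive
autofluorescence in the shorter-wavelength Cy3 channel), microwell grids
with cells and beads, barcoded reads with substitution errors and poly(A)
tails, mixed-species count structure, and Chr7-gain/Chr10-loss aneuploidy.
Each generator returns its outputs together with the truth needed to score
any downstream accuracy metric, and is byte-reproducible for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .barcode_design import BarcodeSet
from .downstream_analysis import FactorModel
from .optical_decoding import BeadIntensityTable

__all__ = [
    "SimTruth",
    "simulate_bead_intensities",
    "simulate_device_images",
    "simulate_expression",
    "simulate_reads",
    "simulate_bead_cycle_detections",
    "write_fastq",
]

_BASES = np.array(list("ACGT"))


@dataclass
class SimTruth:
    """Ground-truth tables keyed by name, serializable alongside outputs."""

    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def __getitem__(self, key: str) -> pd.DataFrame:
        return self.tables[key]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, table in self.tables.items():
            table.to_csv(outdir / f"truth_{name}.csv", index=False)
        with open(outdir / "truth_params.json", "w") as fh:
            json.dump(self.params, fh, indent=2, default=str)


def _lognormal(rng: np.random.Generator, mean: np.ndarray, cv: float) -> np.ndarray:
    """Log-normal draws with the given arithmetic mean and coefficient of
    variation."""
    mean = np.asarray(mean, dtype=float)
    if cv <= 0:
        return mean.copy()
    sigma2 = np.log(1.0 + cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2))


def simulate_bead_intensities(
    n_beads: int,
    s_codes: dict[str, str],
    q_codes: dict[str, str],
    *,
    on_mean: float = 2000.0,
    off_mean: float = 100.0,
    cv: float = 0.25,
    autofluor_sd: float = 0.0,
    pitch: float = 40.0,
    seed: int = 0,
) -> tuple[BeadIntensityTable, SimTruth]:
    """Two-channel 8-cycle bead intensities with known barcodes.

    Each bead draws one S and one Q barcode; per cycle the intensity is
    log-normal around ``on_mean`` (bit 1) or ``off_mean`` (bit 0) with
    coefficient of variation ``cv``. A per-bead additive autofluorescence
    offset |N(0, autofluor_sd)| is drawn once and added to all eight Cy3
    cycles, emulating bead autofluorescence at shorter wavelengths; the Cy5
    channel carries no offset.
    """
    if not (on_mean > off_mean > 0):
        raise ValueError("need on_mean > off_mean > 0")
    if cv < 0 or autofluor_sd < 0:
        raise ValueError("cv and autofluor_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    s_seqs = list(s_codes)
    q_seqs = list(q_codes)
    s_pick = rng.integers(0, len(s_seqs), size=n_beads)
    q_pick = rng.integers(0, len(q_seqs), size=n_beads)
    s_bits = np.array(
        [[int(b) for b in s_codes[s_seqs[i]]] for i in s_pick], dtype=float
    ).reshape(n_beads, 8)
    q_bits = np.array(
        [[int(b) for b in q_codes[q_seqs[i]]] for i in q_pick], dtype=float
    ).reshape(n_beads, 8)
    cy5 = _lognormal(rng, np.where(s_bits == 1, on_mean, off_mean), cv)
    cy3 = _lognormal(rng, np.where(q_bits == 1, on_mean, off_mean), cv)
    offsets = np.abs(rng.normal(0.0, autofluor_sd, size=n_beads)) if autofluor_sd else np.zeros(n_beads)
    cy3 = cy3 + offsets[:, None]
    side = max(1, int(np.ceil(np.sqrt(max(n_beads, 1)))))
    idx = np.arange(n_beads)
    positions = np.column_stack([(idx % side) * pitch, (idx // side) * pitch]).astype(float)
    table = BeadIntensityTable(
        bead_ids=np.arange(n_beads), positions=positions, cy5=cy5, cy3=cy3
    )
    truth = SimTruth(
        tables={
            "beads": pd.DataFrame(
                {
                    "bead_id": np.arange(n_beads),
                    "s_barcode": [s_seqs[i] for i in s_pick],
                    "q_barcode": [q_seqs[i] for i in q_pick],
                    "s_code": [s_codes[s_seqs[i]] for i in s_pick],
                    "q_code": [q_codes[q_seqs[i]] for i in q_pick],
                    "autofluor_offset": offsets,
                }
            )
        },
        params={
            "n_beads": n_beads, "on_mean": on_mean, "off_mean": off_mean,
            "cv": cv, "autofluor_sd": autofluor_sd, "seed": seed,
        },
    )
    return table, truth


def simulate_bead_cycle_detections(
    table: BeadIntensityTable,
    *,
    jitter_sd: float = 0.0,
    dropout: float = 0.0,
    seed: int = 0,
) -> list[pd.DataFrame]:
    """Per-cycle bead detection lists (x, y, cy5, cy3) for tracking tests.

    Cycle A reports all beads at their reference positions; later cycles add
    Gaussian position jitter and drop each bead independently with
    probability ``dropout``.
    """
    rng = np.random.default_rng(seed)
    detections = []
    for k in range(8):
        keep = np.ones(len(table), dtype=bool)
        pos = table.positions.copy()
        if k > 0:
            if dropout > 0:
                keep = rng.random(len(table)) >= dropout
            if jitter_sd > 0:
                pos = pos + rng.normal(0, jitter_sd, size=pos.shape)
        df = pd.DataFrame(
            {
                "x": pos[keep, 0],
                "y": pos[keep, 1],
                "cy5": table.cy5[keep, k],
                "cy3": table.cy3[keep, k],
            }
        )
        if k > 0:  # cycle A keeps the reference bead order
            df = df.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)
        detections.append(df)
    return detections


def simulate_device_images(
    grid_shape: tuple[int, int] = (10, 10),
    *,
    occupancy: float = 0.3,
    multiplet_rate: float = 0.0,
    mixed_fraction: float = 0.5,
    pitch: int = 40,
    well_radius: int = 13,
    cell_radius: int = 5,
    background: float = 200.0,
    well_level: float = 80.0,
    cell_intensity: float = 120.0,
    fluor_background: float = 10.0,
    noise_sd: float = 2.0,
    seed: int = 0,
) -> tuple[dict[str, np.ndarray], SimTruth]:
    """Render a microwell device: bright-field plus two live-stain channels.

    The bright-field image shows dark well disks on a bright background.
    Occupied wells contain one cell (or two for multiplet wells) drawn as a
    fluorescent disk in the green channel (one species) or the magenta
    channel (the other); mixed multiplets get one of each color. Gaussian
    read noise is added everywhere. Returns the image dict
    (brightfield, green, magenta) and per-well truth.
    """
    rows, cols = grid_shape
    if 2 * well_radius >= pitch:
        raise ValueError("wells overlap: need pitch > 2 * well_radius")
    rng = np.random.default_rng(seed)
    h, w = rows * pitch + pitch, cols * pitch + pitch
    brightfield = np.full((h, w), background)
    green = np.full((h, w), fluor_background)
    magenta = np.full((h, w), fluor_background)
    yy, xx = np.ogrid[:h, :w]

    records = []
    well_id = 0
    for r in range(rows):
        for c in range(cols):
            cx = pitch // 2 + c * pitch + well_radius
            cy = pitch // 2 + r * pitch + well_radius
            well = (xx - cx) ** 2 + (yy - cy) ** 2 <= well_radius**2
            brightfield[well] = well_level
            occupied = rng.random() < occupancy
            n_green = n_magenta = 0
            if occupied:
                is_multiplet = rng.random() < multiplet_rate
                n_cells = 2 if is_multiplet else 1
                mixed = is_multiplet and rng.random() < mixed_fraction
                # two cells sit on opposite sides of the well so they never
                # merge into one particle
                angle = rng.uniform(0, 2 * np.pi)
                offsets = (
                    [np.zeros(2)]
                    if n_cells == 1
                    else [
                        0.5 * well_radius * np.array([np.cos(angle), np.sin(angle)]),
                        -0.5 * well_radius * np.array([np.cos(angle), np.sin(angle)]),
                    ]
                )
                for i in range(n_cells):
                    if mixed:
                        channel = green if i == 0 else magenta
                    else:
                        channel = green if rng.random() < 0.5 else magenta
                    px, py = cx + offsets[i][0], cy + offsets[i][1]
                    cell = (xx - px) ** 2 + (yy - py) ** 2 <= cell_radius**2
                    channel[cell] = cell_intensity
                    if channel is green:
                        n_green += 1
                    else:
                        n_magenta += 1
            if n_green >= 1 and n_magenta >= 1:
                label = "mixed_multiplet"
            elif n_green >= 2 or n_magenta >= 2:
                label = "multiplet"
            elif n_green + n_magenta == 1:
                label = "singlet"
            else:
                label = "empty"
            records.append(
                {
                    "well_id": well_id,
                    "x": cx, "y": cy,
                    "occupied": occupied,
                    "n_green": n_green,
                    "n_magenta": n_magenta,
                    "label": label,
                }
            )
            well_id += 1

    images = {
        "brightfield": brightfield + rng.normal(0, noise_sd, (h, w)),
        "green": green + rng.normal(0, noise_sd, (h, w)),
        "magenta": magenta + rng.normal(0, noise_sd, (h, w)),
    }
    truth = SimTruth(
        tables={"wells": pd.DataFrame(records)},
        params={
            "grid_shape": list(grid_shape), "occupancy": occupancy,
            "multiplet_rate": multiplet_rate, "pitch": pitch,
            "well_radius": well_radius, "seed": seed,
        },
    )
    return images, truth


def simulate_expression(
    n_cells: int = 1000,
    n_genes: int = 200,
    *,
    k: int = 5,
    species_mix: dict[str, float] | None = None,
    malignant_fraction: float = 0.4,
    chr7_scale: float = 1.5,
    chr10_scale: float = 0.5,
    chr7_fraction: float = 0.15,
    chr10_fraction: float = 0.15,
    mean_molecules: float = 2000.0,
    depth_cv: float = 0.2,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, FactorModel, SimTruth]:
    """Gamma-Poisson counts from a K-factor model, with optional aneuploidy
    and species structure.

    Genes are split across species per ``species_mix`` (default: one human
    pool) and each cell expresses only its own species' genes (factor blocks
    are species-specific). Within the human genes, ``chr7_fraction`` are
    annotated Chr7 and ``chr10_fraction`` Chr10; malignant cells (a
    ``malignant_fraction`` subset of human cells) scale Chr7 gene rates by
    ``chr7_scale`` and Chr10 by ``chr10_scale``, emulating the Chr7-gain /
    Chr10-loss aneuploidy of glioblastoma. Per-cell factor loadings are
    normalized to unit sum and multiplied by a lognormal library-size factor
    with coefficient of variation ``depth_cv``, so sequencing depth varies
    around a common mean instead of tracking raw gamma sums. The emitted
    factor model is
    exact: expected counts equal theta @ beta.T including the aneuploidy, so
    imputation from it reproduces the generative rates.

    Returns (counts cells x genes, gene annotation, FactorModel, truth).
    """
    if species_mix is None:
        species_mix = {"human": 1.0}
    rng = np.random.default_rng(seed)
    species = list(species_mix)
    probs = np.array([species_mix[s] for s in species], dtype=float)
    probs = probs / probs.sum()
    cell_species = rng.choice(len(species), size=n_cells, p=probs)

    # split genes across species; chromosomes annotated within human genes
    gene_species = rng.choice(len(species), size=n_genes, p=probs)
    chromosomes = np.array(["chr1"] * n_genes, dtype=object)
    if "human" in species:
        human_idx = np.flatnonzero(gene_species == species.index("human"))
    else:
        human_idx = np.array([], dtype=int)
    n7 = max(1, int(round(chr7_fraction * len(human_idx)))) if len(human_idx) else 0
    n10 = max(1, int(round(chr10_fraction * len(human_idx)))) if len(human_idx) else 0
    chr7_genes = human_idx[:n7]
    chr10_genes = human_idx[n7 : n7 + n10]
    chromosomes[chr7_genes] = "chr7"
    chromosomes[chr10_genes] = "chr10"

    malignant = np.zeros(n_cells, dtype=bool)
    if "human" in species and malignant_fraction > 0:
        human_cells = np.flatnonzero(cell_species == species.index("human"))
        n_mal = int(round(malignant_fraction * len(human_cells)))
        malignant[rng.choice(human_cells, size=n_mal, replace=False)] = True

    # species-block gamma factors; aneuploidy carried as a duplicated,
    # gene-rescaled factor block for malignant cells so theta @ beta.T is
    # exactly the generative rate
    theta_blocks, beta_blocks = [], []
    rate = np.zeros((n_cells, n_genes))
    scale_vec = np.ones(n_genes)
    scale_vec[chr7_genes] = chr7_scale
    scale_vec[chr10_genes] = chr10_scale
    for si in range(len(species)):
        cells_s = cell_species == si
        genes_s = gene_species == si
        th = np.zeros((n_cells, k))
        loadings = rng.gamma(2.0, 1.0, size=(cells_s.sum(), k))
        # normalize per-cell loadings to unit sum, then apply a lognormal
        # library-size factor: cell depth varies around a common mean rather
        # than tracking raw gamma sums
        loadings = loadings / loadings.sum(axis=1, keepdims=True)
        if depth_cv > 0:
            loadings = loadings * np.exp(
                rng.normal(0.0, depth_cv, size=cells_s.sum())
            )[:, None]
        th[cells_s] = loadings
        be = np.zeros((n_genes, k))
        be[genes_s] = rng.gamma(0.5, 1.0, size=(genes_s.sum(), k))
        base = th @ be.T
        mean_total = base[cells_s].sum(axis=1).mean() if cells_s.any() else 1.0
        be *= mean_molecules / max(mean_total, 1e-12)
        non_mal = ~malignant
        theta_blocks.append(th * non_mal[:, None])
        beta_blocks.append(be)
        theta_blocks.append(th * malignant[:, None])
        beta_blocks.append(be * scale_vec[:, None])
    theta = np.hstack(theta_blocks)
    beta = np.hstack(beta_blocks)
    rate = theta @ beta.T
    counts = rng.poisson(rate)

    genes = [f"{species[gene_species[j]]}_gene{j:04d}" for j in range(n_genes)]
    barcodes = [f"cell{i:05d}" for i in range(n_cells)]
    counts_df = pd.DataFrame(counts, index=barcodes, columns=genes)
    gene_info = pd.DataFrame(
        {
            "species": [species[s] for s in gene_species],
            "chromosome": chromosomes,
        },
        index=pd.Index(genes, name="gene"),
    )
    truth = SimTruth(
        tables={
            "cells": pd.DataFrame(
                {
                    "cell": barcodes,
                    "species": [species[s] for s in cell_species],
                    "malignant": malignant,
                }
            )
        },
        params={
            "n_cells": n_cells, "n_genes": n_genes, "k": k,
            "malignant_fraction": malignant_fraction,
            "chr7_scale": chr7_scale, "chr10_scale": chr10_scale,
            "mean_molecules": mean_molecules, "seed": seed,
        },
    )
    return counts_df, gene_info, FactorModel(theta=theta, beta=beta), truth


def _random_umis(rng: np.random.Generator, n: int, length: int = 8, min_dist: int = 3) -> list[str]:
    """UMIs pairwise >= ``min_dist`` substitutions apart within one group,
    so distinct molecules never merge under single-substitution collapse."""
    umis: list[str] = []
    while len(umis) < n:
        u = "".join(rng.choice(_BASES, size=length))
        if all(sum(a != b for a, b in zip(u, v)) >= min_dist for v in umis):
            umis.append(u)
    return umis


def _substitute(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    hits = np.flatnonzero(rng.random(len(chars)) < rate)
    for i in hits:
        alternatives = [b for b in "ACGT" if b != chars[i]]
        chars[i] = alternatives[rng.integers(3)]
    return "".join(chars)


def _gene_fragment(gene_index: int, length: int = 50) -> str:
    """Deterministic A-free pseudo-random fragment identifying one gene."""
    rng = np.random.default_rng(10_000_019 + gene_index)
    return "".join(rng.choice(np.array(list("CGT")), size=length))


def simulate_reads(
    cells: pd.DataFrame,
    expression: pd.DataFrame,
    gene_info: pd.DataFrame,
    *,
    error_rate: float = 0.005,
    polya_rate: float = 0.5,
    reads_per_molecule: int = 3,
    read1_length: int = 26,
    read2_length: int = 58,
    seed: int = 0,
) -> tuple[list[tuple[str, str, str]], pd.DataFrame, SimTruth]:
    """Paired reads and a gene-tag table from known molecules.

    ``cells`` needs columns cell, s_barcode, q_barcode (optional region);
    ``expression`` is the true molecule count matrix (cells x genes). Read 1
    follows the layout NN + S + NN + Q + NNNN with per-base substitution
    errors; read 2 carries the gene's synthetic fragment, optionally
    followed by a poly(A) tail. The tag table gives the true gene, species
    and chromosome for every read id (the external aligner's contract).
    Within one (cell, gene) group, UMIs are kept >= 3 substitutions apart so
    the truth count is exact under single-substitution UMI collapse.

    Returns (records, tags, truth) where records are
    (read_id, read1, read2) tuples.
    """
    rng = np.random.default_rng(seed)
    records: list[tuple[str, str, str]] = []
    tag_rows = []
    truth_rows = []
    read_no = 0
    genes = list(expression.columns)
    for ci, cell_row in cells.iterrows():
        cell = cell_row["cell"]
        s_bc, q_bc = cell_row["s_barcode"], cell_row["q_barcode"]
        counts = expression.loc[cell]
        for j, gene in enumerate(genes):
            n_mol = int(counts.iloc[j])
            if n_mol == 0:
                continue
            umis = _random_umis(rng, n_mol)
            truth_rows.append({"cell": cell, "gene": gene, "molecules": n_mol})
            for umi in umis:
                for _ in range(reads_per_molecule):
                    r1 = umi[0:2] + s_bc + umi[2:4] + q_bc + umi[4:8]
                    r1 = r1 + "T" * (read1_length - len(r1))
                    r1 = _substitute(r1, rng, error_rate)
                    frag = _gene_fragment(j)
                    if rng.random() < polya_rate:
                        frag = frag + "A" * 10
                    r2 = frag[:read2_length]
                    rid = f"read{read_no:08d}"
                    read_no += 1
                    records.append((rid, r1, r2))
                    row = {
                        "read_id": rid,
                        "gene": gene,
                        "species": gene_info.loc[gene, "species"],
                        "chromosome": gene_info.loc[gene, "chromosome"],
                    }
                    if "region" in cells.columns:
                        row["region"] = cell_row["region"]
                    tag_rows.append(row)
    tags = pd.DataFrame(tag_rows)
    truth = SimTruth(
        tables={"molecules": pd.DataFrame(truth_rows)},
        params={
            "error_rate": error_rate, "polya_rate": polya_rate,
            "reads_per_molecule": reads_per_molecule, "seed": seed,
        },
    )
    return records, tags, truth


def write_fastq(records: list[tuple[str, str, str]], r1_path: str | Path, r2_path: str | Path) -> None:
    """Write (read_id, read1, read2) records as a FASTQ pair."""
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for rid, r1, r2 in records:
            f1.write(f"@{rid}\n{r1}\n+\n{'I' * len(r1)}\n")
            f2.write(f"@{rid}\n{r2}\n+\n{'I' * len(r2)}\n")
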