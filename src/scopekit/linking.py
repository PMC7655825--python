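"""Linking microwell cell images to decoded beads and sequenced profiles.

Decoding-round images are registered onto the live-imaging frame with a
similarity transform anchored on two landmark wells (upper-left and
bottom-right). Cells pair with the nearest mapped bead within one microwell
radius, and a cell links to a sequenced expression profile when its bead's
decoded 16-nt barcode appears exactly once among the sequenced barcodes.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .optical_decoding import DecodeResult

__all__ = [
    "SimilarityTransform2D",
    "register_images",
    "assign_cells_to_beads",
    "link_profiles",
    "class_balanced_accuracy",
    "multiplet_metrics",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimilarityTransform2D:
    """Planar similarity: rotation + isotropic scale + translation.

    Represented as the complex map z -> a*z + b.
    """

    a: complex
    b: complex

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        z = pts[..., 0] + 1j * pts[..., 1]
        w = self.a * z + self.b
        return np.stack([w.real, w.imag], axis=-1)

    def inverse(self) -> "SimilarityTransform2D":
        return SimilarityTransform2D(a=1 / self.a, b=-self.b / self.a)

    @property
    def scale(self) -> float:
        return abs(self.a)

    @property
    def rotation(self) -> float:
        """Rotation angle in radians."""
        return float(np.angle(self.a))

    @property
    def translation(self) -> tuple[float, float]:
        return (self.b.real, self.b.imag)


def register_images(
    anchor_src: np.ndarray,
    anchor_dst: np.ndarray,
) -> SimilarityTransform2D:
    """Similarity transform mapping two source anchors onto two destination
    anchors exactly.

    Two point pairs determine translation, isotropic scale and rotation (but
    not shear, so the model is similarity rather than affine).
    """
    src = np.asarray(anchor_src, dtype=float)
    dst = np.asarray(anchor_dst, dtype=float)
    if src.shape != (2, 2) or dst.shape != (2, 2):
        raise ValueError("expected exactly two 2-D anchor points on each side")
    s1, s2 = src[0, 0] + 1j * src[0, 1], src[1, 0] + 1j * src[1, 1]
    d1, d2 = dst[0, 0] + 1j * dst[0, 1], dst[1, 0] + 1j * dst[1, 1]
    if s1 == s2:
        raise ValueError("source anchors are coincident")
    a = (d2 - d1) / (s2 - s1)
    b = d1 - a * s1
    return SimilarityTransform2D(a=a, b=b)


def assign_cells_to_beads(
    cells: pd.DataFrame,
    beads: pd.DataFrame,
    radius: float,
) -> pd.DataFrame:
    """Pair each cell with its nearest mapped bead within ``radius``.

    ``cells`` needs columns well_id, x, y; ``beads`` needs bead_id, x, y
    (bead positions already mapped into the live-imaging frame). A bead may
    claim at most one cell: the closest wins (ties broken by well_id) and
    the loser goes unpaired.
    """
    if radius <= 0:
        raise ValueError("pairing radius must be positive")
    if len(beads) == 0 or len(cells) == 0:
        return pd.DataFrame(columns=["well_id", "bead_id", "distance"])
    tree = cKDTree(beads[["x", "y"]].to_numpy(float))
    dists, idx = tree.query(cells[["x", "y"]].to_numpy(float))
    claims: dict[int, tuple[float, object]] = {}
    for row, (d, i) in enumerate(zip(dists, idx)):
        if d > radius:
            continue
        well = cells["well_id"].iloc[row]
        if i not in claims or (d, well) < claims[i][:2]:
            if i in claims:
                logger.debug("bead %s reassigned: cell %s outcompeted", i, claims[i][1])
            claims[i] = (d, well)
    rows = [
        {"well_id": well, "bead_id": beads["bead_id"].iloc[i], "distance": d}
        for i, (d, well) in claims.items()
    ]
    return pd.DataFrame(rows, columns=["well_id", "bead_id", "distance"])


def link_profiles(
    pairs: pd.DataFrame,
    decode_results: list[DecodeResult],
    sequenced_barcodes: set[str],
) -> pd.DataFrame:
    """Join cell-bead pairs to sequenced profiles through decoded barcodes.

    Only beads paired with an imaged cell are considered. A link requires
    the bead's decoded barcode to map exactly and uniquely: beads in the
    same region that decode to the same barcode are ambiguous and both
    excluded. Outcome labels: ``outcome1`` (unmappable code), ``outcome2``
    (mappable barcode absent from sequencing), ``ambiguous`` (duplicate
    decoded barcode), ``linked``.
    """
    by_bead = {r.bead_id: r for r in decode_results}
    paired = pairs[pairs["bead_id"].isin(by_bead)].copy()
    decoded_counts = Counter(
        by_bead[b].barcode
        for b in paired["bead_id"]
        if by_bead[b].status == "decoded"
    )
    rows = []
    for _, pair in paired.iterrows():
        res = by_bead[pair["bead_id"]]
        barcode = res.barcode
        if res.status != "decoded":
            outcome, profile = "outcome1", None
        elif decoded_counts[barcode] > 1:
            outcome, profile = "ambiguous", None
            logger.warning("duplicate decoded barcode %s; beads excluded", barcode)
        elif barcode not in sequenced_barcodes:
            outcome, profile = "outcome2", None
        else:
            outcome, profile = "linked", barcode
        rows.append(
            {
                "well_id": pair["well_id"],
                "bead_id": pair["bead_id"],
                "barcode": barcode,
                "profile_id": profile,
                "outcome": outcome,
            }
        )
    table = pd.DataFrame(
        rows, columns=["well_id", "bead_id", "barcode", "profile_id", "outcome"]
    )
    linked = table.loc[table["outcome"] == "linked", "profile_id"]
    assert linked.is_unique, "a profile may appear at most once in the link table"
    return table


def class_balanced_accuracy(
    reference: pd.Series | list,
    test: pd.Series | list,
) -> float:
    """Unweighted mean of per-class agreement rates, as a percentage.

    ``reference`` defines the classes (e.g. sequencing-based species calls);
    classes with zero members are excluded with a warning.
    """
    ref = pd.Series(list(reference))
    tst = pd.Series(list(test))
    if len(ref) != len(tst):
        raise ValueError("reference and test must have equal length")
    rates = []
    for cls in sorted(ref.unique()):
        mask = ref == cls
        if mask.sum() == 0:  # pragma: no cover - unique() excludes this
            logger.warning("class %s has zero members; excluded", cls)
            continue
        rates.append((tst[mask] == cls).mean())
    if not rates:
        raise ValueError("no classes with members")
    return float(100.0 * np.mean(rates))


def multiplet_metrics(
    image_multiplet: pd.Series | list,
    sequencing_multiplet: pd.Series | list,
) -> tuple[float, float]:
    """Multiplet-detection sensitivity and specificity (percentages).

    Sequencing-based mixed-species calls (> 10% minor species) are the
    reference: sensitivity = TP/(TP+FN), specificity = TN/(TN+FP).
    """
    img = np.asarray(list(image_multiplet), dtype=bool)
    seq = np.asarray(list(sequencing_multiplet), dtype=bool)
    if img.shape != seq.shape:
        raise ValueError("label vectors must have equal length")
    tp = int((img & seq).sum())
    fn = int((~img & seq).sum())
    tn = int((~img & ~seq).sum())
    fp = int((img & ~seq).sum())
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("a reference class is empty; metrics undefined")
    sensitivity = 100.0 * tp / (tp + fn)
    specificity = 100.0 * tn / (tn + fp)
    return sensitivity, specificity
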