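"""Calling bead barcodes from 8-cycle, two-channel hybridization intensities.

Each bead carries two 8-nt barcodes (roles S and Q) read out as 8-bit binary
codes over eight hybridization cycles: the S code in the Cy5 channel and the
Q code in Cy3. Two decoders are provided:

``decode_cycle_by_cycle``
    A population method: per cycle and channel, a global intensity threshold
    is placed in the valley of the bimodal log-intensity histogram across
    all beads, and each bead's bit is 1 if its intensity exceeds it.

``decode_bead_by_bead``
    A per-bead method: the eight intensities of one channel are sorted, the
    largest relative fold change between adjacent sorted values splits them
    into 0s and 1s, and unmappable codes retry at the next-largest fold
    change until a whitelisted code is found or the splits are exhausted.

The bead-by-bead method is robust to per-bead additive background (e.g.
autofluorescence in the shorter-wavelength channel) because the split is
chosen within each bead rather than across the population.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BeadIntensityTable",
    "DecodeResult",
    "decode_bead_by_bead",
    "decode_cycle_by_cycle",
    "map_code_to_barcode",
    "classify_outcomes",
    "intensity_table_from_frame",
]

logger = logging.getLogger(__name__)

UNMAPPABLE = "unmappable"

#: Intensity floor (arbitrary units) applied before fold-change computation
#: so the division by the smaller neighbor is defined; preserves ordering.
EPSILON = 1.0


@dataclass
class BeadIntensityTable:
    """Per-bead 8-cycle x 2-channel mean fluorescence with positions.

    ``cy5`` and ``cy3`` are (n_beads, 8) arrays in cycle order A..H; Cy5
    reports the S-role probes and Cy3 the Q-role probes.
    """

    bead_ids: np.ndarray  # (n,)
    positions: np.ndarray  # (n, 2) x, y in the cycle-A frame
    cy5: np.ndarray  # (n, 8)
    cy3: np.ndarray  # (n, 8)

    def __post_init__(self) -> None:
        self.bead_ids = np.asarray(self.bead_ids)
        self.positions = np.asarray(self.positions, dtype=float)
        self.cy5 = np.asarray(self.cy5, dtype=float)
        self.cy3 = np.asarray(self.cy3, dtype=float)
        n = len(self.bead_ids)
        for name, arr, ncol in (("cy5", self.cy5, 8), ("cy3", self.cy3, 8)):
            if arr.shape != (n, ncol):
                raise ValueError(f"{name} must have shape ({n}, {ncol}), got {arr.shape}")
        if (self.cy5 < 0).any() or (self.cy3 < 0).any():
            raise ValueError("intensities must be non-negative")

    def __len__(self) -> int:
        return len(self.bead_ids)

    def to_frame(self) -> pd.DataFrame:
        cols = {"bead_id": self.bead_ids, "x": self.positions[:, 0], "y": self.positions[:, 1]}
        for k, c in enumerate("ABCDEFGH"):
            cols[f"ch5_cycle{c}"] = self.cy5[:, k]
        for k, c in enumerate("ABCDEFGH"):
            cols[f"ch3_cycle{c}"] = self.cy3[:, k]
        return pd.DataFrame(cols)


def intensity_table_from_frame(df: pd.DataFrame) -> BeadIntensityTable:
    """Build a table from the CSV layout (bead_id, x, y, ch5_cycleA..)."""
    cy5 = df[[f"ch5_cycle{c}" for c in "ABCDEFGH"]].to_numpy(float)
    cy3 = df[[f"ch3_cycle{c}" for c in "ABCDEFGH"]].to_numpy(float)
    return BeadIntensityTable(
        bead_ids=df["bead_id"].to_numpy(),
        positions=df[["x", "y"]].to_numpy(float),
        cy5=cy5,
        cy3=cy3,
    )


@dataclass
class DecodeResult:
    bead_id: object
    s_code: str  # 8-bit string or "unmappable"
    q_code: str
    s_barcode: str | None
    q_barcode: str | None

    @property
    def status(self) -> str:
        return "decoded" if (self.s_barcode and self.q_barcode) else UNMAPPABLE

    @property
    def barcode(self) -> str | None:
        """Concatenated 16-nt cell barcode (S + Q) if fully decoded."""
        if self.status != "decoded":
            return None
        return self.s_barcode + self.q_barcode


def map_code_to_barcode(code: str, code_map: dict[str, str]) -> str | None:
    """Exact lookup of an 8-bit code in a barcode set's code table."""
    if len(code) != 8:
        raise ValueError(f"code must be 8 bits, got {code!r}")
    for seq, c in code_map.items():
        if c == code:
            return seq
    return None


def _inverse_code_map(code_map: dict[str, str]) -> dict[str, str]:
    return {code: seq for seq, code in code_map.items()}


def _bead_channel_call(values: np.ndarray, code_to_seq: dict[str, str]) -> tuple[str, str | None]:
    """Sorted-gap call of one bead in one channel with unmappable retry."""
    x = np.maximum(np.asarray(values, dtype=float), EPSILON)
    order = np.argsort(x, kind="stable")
    y = x[order]
    folds = (y[1:] - y[:-1]) / y[:-1]  # f_n, n = 1..7
    # try split points from largest fold change down; argmax ties -> smallest n
    candidates = sorted(range(7), key=lambda n: (-folds[n], n))
    first_code = None
    for n in candidates:
        bits = np.zeros(8, dtype=int)
        bits[order[n + 1 :]] = 1  # values above the split are 1
        code = "".join(map(str, bits))
        if first_code is None:
            first_code = code
        seq = code_to_seq.get(code)
        if seq is not None:
            return code, seq
    return first_code, None


def decode_bead_by_bead(
    table: BeadIntensityTable,
    s_codes: dict[str, str],
    q_codes: dict[str, str],
) -> list[DecodeResult]:
    """Per-bead sorted fold-change decoding of both channels.

    For each channel the eight intensities y1 <= ... <= y8 (floored at a
    small epsilon) define relative fold changes f_n = (y_{n+1} - y_n)/y_n;
    the largest f_n splits the values into 0s (below) and 1s (above). If the
    resulting code is not in the code table, the split is retried at the
    next-largest fold change until a whitelisted code is found or all seven
    splits are exhausted, in which case the channel is unmappable.
    """
    s_lookup = _inverse_code_map(s_codes)
    q_lookup = _inverse_code_map(q_codes)
    results = []
    for i in range(len(table)):
        s_code, s_bc = _bead_channel_call(table.cy5[i], s_lookup)
        q_code, q_bc = _bead_channel_call(table.cy3[i], q_lookup)
        results.append(
            DecodeResult(
                bead_id=table.bead_ids[i],
                s_code=s_code if s_bc else UNMAPPABLE,
                q_code=q_code if q_bc else UNMAPPABLE,
                s_barcode=s_bc,
                q_barcode=q_bc,
            )
        )
    return results


def _population_threshold(values: np.ndarray, bins: int = 50) -> float:
    """Valley threshold of a bimodal log-intensity population.

    Histogram the log intensities; B1 is the most-populated bin strictly
    below the median, B2 the most-populated bin strictly above it, and the
    threshold is the center of the least-populated bin strictly between B1
    and B2 (falling back to the midpoint of the B1/B2 bin centers when no
    bin lies between them).
    """
    counts, edges = np.histogram(values, bins=bins)
    centers = (edges[:-1] + edges[1:]) / 2
    m = np.median(values)
    below = np.flatnonzero(centers < m)
    above = np.flatnonzero(centers > m)
    if below.size and above.size:
        b1 = below[np.argmax(counts[below])]
        b2 = above[np.argmax(counts[above])]
    else:
        # point-mass populations can leave no bin center on one side of the
        # median; take the outermost populated bins as the two modes
        populated = np.flatnonzero(counts)
        b1, b2 = populated[0], populated[-1]
        if b1 == b2:
            raise ValueError(
                "degenerate intensity histogram: a single populated bin"
            )
        logger.warning(
            "no histogram bins strictly on both sides of the median; using "
            "outermost populated bins as modes"
        )
    between = np.arange(b1 + 1, b2)
    if between.size == 0:
        logger.warning(
            "no histogram bins between the two modes; falling back to their midpoint"
        )
        return float((centers[b1] + centers[b2]) / 2)
    b3 = between[np.argmin(counts[between])]
    return float(centers[b3])


def decode_cycle_by_cycle(
    table: BeadIntensityTable,
    s_codes: dict[str, str],
    q_codes: dict[str, str],
    bins: int = 50,
) -> list[DecodeResult]:
    """Population (global-threshold) decoding of both channels.

    Per cycle and channel, all bead intensities are log-transformed and a
    valley threshold is placed between the two modes of the 50-bin
    histogram; a bead's bit is 1 when its intensity exceeds the threshold.
    No retry is attempted for unmappable codes.
    """
    if len(table) < 100:
        raise ValueError("cycle-by-cycle decoding needs >= 100 beads")
    for name, arr in (("Cy5", table.cy5), ("Cy3", table.cy3)):
        if (arr <= 0).any():
            bad = table.bead_ids[np.argwhere(arr <= 0)[0][0]]
            raise ValueError(
                f"non-positive {name} intensity at bead {bad}: log transform undefined"
            )
    bits5 = np.zeros(table.cy5.shape, dtype=int)
    bits3 = np.zeros(table.cy3.shape, dtype=int)
    degenerate = False
    for arr, bits in ((table.cy5, bits5), (table.cy3, bits3)):
        for k in range(8):
            logv = np.log(arr[:, k])
            try:
                thr = _population_threshold(logv, bins=bins)
            except ValueError:
                logger.warning("degenerate histogram in cycle %d; all beads unmappable", k)
                degenerate = True
                break
            bits[:, k] = (logv > thr).astype(int)
        if degenerate:
            break

    s_lookup = _inverse_code_map(s_codes)
    q_lookup = _inverse_code_map(q_codes)
    results = []
    for i in range(len(table)):
        if degenerate:
            results.append(
                DecodeResult(table.bead_ids[i], UNMAPPABLE, UNMAPPABLE, None, None)
            )
            continue
        s_code = "".join(map(str, bits5[i]))
        q_code = "".join(map(str, bits3[i]))
        s_bc = s_lookup.get(s_code)
        q_bc = q_lookup.get(q_code)
        results.append(
            DecodeResult(
                bead_id=table.bead_ids[i],
                s_code=s_code if s_bc else UNMAPPABLE,
                q_code=q_code if q_bc else UNMAPPABLE,
                s_barcode=s_bc,
                q_barcode=q_bc,
            )
        )
    return results


def classify_outcomes(
    results: list[DecodeResult],
    sequenced_barcodes: set[str],
) -> dict[str, float]:
    """Tally decoding-outcome fractions over beads paired with cells.

    Outcome 1: the called code is unmappable (not in the barcode set).
    Outcome 2: the code maps to a barcode absent from the sequenced set.
    The remainder are linked — either correct or a silent mismatch
    (outcome 3), indistinguishable without ground truth.
    """
    if not sequenced_barcodes:
        raise ValueError("sequenced barcode set is empty")
    n = len(results)
    if n == 0:
        raise ValueError("no decode results")
    n1 = sum(1 for r in results if r.status != "decoded")
    n2 = sum(
        1 for r in results if r.status == "decoded" and r.barcode not in sequenced_barcodes
    )
    linked = n - n1 - n2
    return {
        "outcome1": n1 / n,
        "outcome2": n2 / n,
        "linked": linked / n,
    }


def results_to_frame(results: list[DecodeResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "bead_id": [r.bead_id for r in results],
            "s_code": [r.s_code for r in results],
            "q_code": [r.q_code for r in results],
            "s_barcode": [r.s_barcode or "" for r in results],
            "q_barcode": [r.q_barcode or "" for r in results],
            "status": [r.status for r in results],
        }
    )
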