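"""Microwell image analysis: well detection, cell features, bead tracking.

Coordinates are pixel coordinates with the origin at the top-left corner,
x rightward (columns), y downward (rows), 0-based.

The per-cell feature set mirrors ImageJ's particle measurements: area, five
intensity statistics, perimeter, bounding-box width/height, fitted-ellipse
major/minor axes, circularity, maximum and minimum Feret diameters,
roundness, and solidity — 16 features in total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, cKDTree
from skimage.filters import threshold_local, threshold_otsu
from skimage.measure import label, regionprops

__all__ = [
    "MicrowellGrid",
    "CellImageRecord",
    "ExcludedWell",
    "FEATURE_NAMES",
    "detect_microwells",
    "call_occupied_wells",
    "extract_cell_features",
    "extract_all_features",
    "track_beads_across_cycles",
    "identify_multiplets",
    "well_mean_intensities",
]

logger = logging.getLogger(__name__)

FEATURE_NAMES = [
    "area",
    "mean_intensity",
    "sd_intensity",
    "min_intensity",
    "max_intensity",
    "median_intensity",
    "perimeter",
    "width",
    "height",
    "major_axis",
    "minor_axis",
    "circularity",
    "feret_diameter",
    "min_feret_diameter",
    "roundness",
    "solidity",
]


@dataclass
class MicrowellGrid:
    centers: np.ndarray  # (n, 2) x, y
    radius: float
    occupancy: np.ndarray | None = None  # boolean flags, set by call_occupied_wells

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        if self.radius <= 0:
            raise ValueError("well radius must be positive")
        if len(np.unique(self.centers, axis=0)) != len(self.centers):
            raise ValueError("well centers must be unique")

    def __len__(self) -> int:
        return len(self.centers)


@dataclass
class CellImageRecord:
    well_id: int
    features: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(FEATURE_NAMES) - set(self.features)
        if missing:
            raise ValueError(f"missing features: {sorted(missing)}")


@dataclass
class ExcludedWell:
    well_id: int
    reason: str  # "no_particle" or "multiple_particles"


def detect_microwells(
    brightfield: np.ndarray,
    *,
    block_size: int = 51,
    offset: float = 10.0,
    min_area: int = 50,
    max_area: int | None = None,
    min_solidity: float = 0.8,
) -> MicrowellGrid:
    """Detect microwell outlines in a bright-field image.

    Wells appear as dark disks on a bright background. A local-mean
    threshold (window ``block_size``, darker than the local mean by more
    than ``offset``) makes detection invariant to global intensity offsets;
    connected components are gated on area and solidity.
    """
    img = np.asarray(brightfield, dtype=float)
    if img.ndim != 2:
        raise ValueError("bright-field image must be single-channel (2-D)")
    thr = threshold_local(img, block_size=block_size, method="mean", offset=offset)
    mask = img < thr
    labels = label(mask, connectivity=2)
    centers = []
    radii = []
    for region in regionprops(labels):
        if region.area < min_area:
            continue
        if max_area is not None and region.area > max_area:
            continue
        if region.solidity < min_solidity:
            continue
        cy, cx = region.centroid
        centers.append((cx, cy))
        radii.append(np.sqrt(region.area / np.pi))
    if not centers:
        raise ValueError("no microwells detected")
    return MicrowellGrid(centers=np.array(centers), radius=float(np.median(radii)))


def _disk_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    h, w = shape
    cx, cy = center
    yy, xx = np.ogrid[:h, :w]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2


def well_mean_intensities(grid: MicrowellGrid, image: np.ndarray) -> np.ndarray:
    """Mean fluorescence inside each well disk."""
    img = np.asarray(image, dtype=float)
    means = np.empty(len(grid))
    for i, (cx, cy) in enumerate(grid.centers):
        m = _disk_mask(img.shape, (cx, cy), grid.radius)
        means[i] = img[m].mean() if m.any() else 0.0
    return means


def call_occupied_wells(
    grid: MicrowellGrid,
    fluorescence: np.ndarray,
    bins: int = 50,
) -> np.ndarray:
    """Flag occupied wells from the bimodal distribution of well means.

    Per-well mean fluorescence follows a bimodal distribution when cells
    are present; the higher-intensity mode corresponds to occupied wells.
    A unimodal distribution yields all-unoccupied with a warning.
    """
    from .downstream_analysis import bimodal_threshold

    means = well_mean_intensities(grid, fluorescence)
    try:
        thr = bimodal_threshold(means, bins=bins)
    except ValueError as exc:
        logger.warning("well intensity distribution not bimodal (%s); no wells called occupied", exc)
        grid.occupancy = np.zeros(len(grid), dtype=bool)
        return grid.occupancy
    grid.occupancy = means > thr
    return grid.occupancy


def _feret_diameters(coords: np.ndarray) -> tuple[float, float]:
    """Maximum and minimum Feret diameters of a pixel region.

    Pixels are expanded to their four corners so single-pixel-wide regions
    have nonzero extent; the maximum Feret diameter is the largest distance
    between convex-hull vertices and the minimum is the smallest width over
    hull-edge-normal directions (rotating calipers).
    """
    corners = np.concatenate(
        [coords + d for d in ([-0.5, -0.5], [-0.5, 0.5], [0.5, -0.5], [0.5, 0.5])]
    )
    if len(np.unique(corners, axis=0)) < 3:
        return 1.0, 1.0
    hull = ConvexHull(corners)
    pts = corners[hull.vertices]
    diffs = pts[:, None, :] - pts[None, :, :]
    feret_max = float(np.sqrt((diffs**2).sum(-1)).max())
    edges = np.roll(pts, -1, axis=0) - pts
    norms = np.linalg.norm(edges, axis=1)
    normals = np.column_stack([-edges[:, 1], edges[:, 0]]) / norms[:, None]
    proj = pts @ normals.T  # vertices projected on each edge normal
    widths = proj.max(axis=0) - proj.min(axis=0)
    feret_min = float(widths.min())
    return feret_max, feret_min


def extract_cell_features(
    crop: np.ndarray,
    well_id: int,
    *,
    min_area: int = 20,
    threshold: float | None = None,
) -> CellImageRecord | ExcludedWell:
    """Measure the 16 features of the single cell in a well crop.

    The cell is segmented with an Otsu auto-threshold (8-connectivity,
    minimum particle area ``min_area`` px^2). Wells where more than one
    particle is detected are excluded, as are wells with none.

    circularity = 4*pi*area / perimeter^2 (clamped to <= 1),
    roundness = 4*area / (pi * major_axis^2),
    solidity = area / convex-hull area.
    """
    img = np.asarray(crop, dtype=float)
    thr = threshold_otsu(img) if threshold is None else threshold
    labels = label(img > thr, connectivity=2)
    regions = [r for r in regionprops(labels, intensity_image=img) if r.area >= min_area]
    if not regions:
        return ExcludedWell(well_id, "no_particle")
    if len(regions) > 1:
        return ExcludedWell(well_id, "multiple_particles")
    r = regions[0]
    pixels = img[labels == r.label]
    minr, minc, maxr, maxc = r.bbox
    # Crofton estimate: unbiased on digital disks, so circularity of a
    # rasterized circle comes out ~1 as it does in ImageJ
    perimeter = max(float(r.perimeter_crofton), 1.0)
    area = float(r.area)
    major = float(r.axis_major_length)
    minor = float(r.axis_minor_length)
    feret_max, feret_min = _feret_diameters(r.coords.astype(float))
    features = {
        "area": area,
        "mean_intensity": float(pixels.mean()),
        "sd_intensity": float(pixels.std()),
        "min_intensity": float(pixels.min()),
        "max_intensity": float(pixels.max()),
        "median_intensity": float(np.median(pixels)),
        "perimeter": perimeter,
        "width": float(maxc - minc),
        "height": float(maxr - minr),
        "major_axis": major,
        "minor_axis": minor,
        "circularity": min(1.0, 4.0 * np.pi * area / perimeter**2),
        "feret_diameter": feret_max,
        "min_feret_diameter": feret_min,
        "roundness": min(1.0, 4.0 * area / (np.pi * major**2)) if major > 0 else 1.0,
        "solidity": float(r.solidity),
    }
    return CellImageRecord(well_id=well_id, features=features)


def _well_crop(image: np.ndarray, center: tuple[float, float], radius: float) -> np.ndarray:
    """Smallest bounding square of a well, clipped to the image."""
    h, w = image.shape
    cx, cy = center
    r = int(np.ceil(radius))
    x0, x1 = max(0, int(round(cx)) - r), min(w, int(round(cx)) + r + 1)
    y0, y1 = max(0, int(round(cy)) - r), min(h, int(round(cy)) + r + 1)
    return image[y0:y1, x0:x1]


def extract_all_features(
    grid: MicrowellGrid,
    fluorescence: np.ndarray,
    *,
    min_area: int = 20,
) -> tuple[pd.DataFrame, list[ExcludedWell]]:
    """Feature extraction over all occupied wells; returns (table, excluded)."""
    if grid.occupancy is None:
        raise ValueError("call_occupied_wells must be run first")
    records, excluded = [], []
    for well_id in np.flatnonzero(grid.occupancy):
        crop = _well_crop(fluorescence, tuple(grid.centers[well_id]), grid.radius)
        result = extract_cell_features(crop, int(well_id), min_area=min_area)
        if isinstance(result, ExcludedWell):
            excluded.append(result)
        else:
            records.append({"well_id": result.well_id, **result.features})
    table = pd.DataFrame(records, columns=["well_id"] + FEATURE_NAMES)
    return table, excluded


def track_beads_across_cycles(
    detections: list[pd.DataFrame],
    match_radius: float,
    images: list[tuple[np.ndarray, np.ndarray]] | None = None,
    bead_radius: float | None = None,
):
    """Assemble the per-bead 8x2 intensity table across hybridization cycles.

    ``detections`` holds one DataFrame per cycle (A..H) with columns
    x, y, cy5, cy3. Beads detected in cycles B-H are mapped to the nearest
    cycle-A bead within ``match_radius``; unmatched detections are dropped.
    A bead missing from a later cycle has its intensities read from that
    cycle's images at the cycle-A position (fallback, flagged); without
    images the fallback value is NaN.

    Returns (BeadIntensityTable, fallback_flags) where fallback_flags is an
    (n_beads, 8) boolean array.
    """
    from .optical_decoding import BeadIntensityTable

    if len(detections) != 8:
        raise ValueError("expected 8 cycles of detections")
    ref = detections[0]
    if len(ref) == 0:
        raise ValueError("no beads detected in cycle A")
    n = len(ref)
    positions = ref[["x", "y"]].to_numpy(float)
    cy5 = np.full((n, 8), np.nan)
    cy3 = np.full((n, 8), np.nan)
    fallback = np.zeros((n, 8), dtype=bool)
    cy5[:, 0] = ref["cy5"].to_numpy(float)
    cy3[:, 0] = ref["cy3"].to_numpy(float)
    tree = cKDTree(positions)
    for k in range(1, 8):
        det = detections[k]
        claimed: dict[int, tuple[float, int]] = {}
        if len(det):
            pts = det[["x", "y"]].to_numpy(float)
            dists, idx = tree.query(pts)
            for j, (d, i) in enumerate(zip(dists, idx)):
                if d > match_radius:
                    logger.debug("cycle %d detection %d unmatched (%.1f px); dropped", k, j, d)
                    continue
                if i not in claimed or d < claimed[i][0]:
                    claimed[i] = (d, j)
        for i, (_, j) in claimed.items():
            cy5[i, k] = det["cy5"].iloc[j]
            cy3[i, k] = det["cy3"].iloc[j]
        missing = np.isnan(cy5[:, k])
        if missing.any():
            fallback[missing, k] = True
            if images is not None:
                img5, img3 = images[k]
                r = bead_radius if bead_radius is not None else match_radius
                for i in np.flatnonzero(missing):
                    m = _disk_mask(img5.shape, tuple(positions[i]), r)
                    cy5[i, k] = float(np.asarray(img5, float)[m].mean())
                    cy3[i, k] = float(np.asarray(img3, float)[m].mean())
    table = BeadIntensityTable(
        bead_ids=np.arange(n),
        positions=positions,
        cy5=np.nan_to_num(cy5),
        cy3=np.nan_to_num(cy3),
    )
    return table, fallback


def _count_particles(
    image: np.ndarray,
    center: tuple[float, float],
    radius: float,
    threshold: float,
    min_area: int,
) -> int:
    crop = _well_crop(np.asarray(image, dtype=float), center, radius)
    labels = label(crop > threshold, connectivity=2)
    return sum(1 for r in regionprops(labels) if r.area >= min_area)


def _channel_threshold(image: np.ndarray) -> float | None:
    """Otsu threshold, or None when the channel has no plausible objects."""
    img = np.asarray(image, dtype=float)
    if img.max() == img.min():
        return None
    thr = threshold_otsu(img)
    if (img > thr).mean() > 0.25:  # foreground should be sparse
        logger.warning("channel appears empty; no particles counted")
        return None
    return thr


def identify_multiplets(
    green: np.ndarray,
    magenta: np.ndarray,
    grid: MicrowellGrid,
    *,
    min_area: int = 20,
) -> pd.DataFrame:
    """Label each occupied well from two-channel live-stain images.

    mixed_multiplet: at least one green and one magenta object;
    multiplet: two or more objects of a single color;
    singlet: exactly one object in exactly one color.
    """
    if grid.occupancy is None:
        raise ValueError("call_occupied_wells must be run first")
    thr_g = _channel_threshold(green)
    thr_m = _channel_threshold(magenta)
    rows = []
    for well_id in np.flatnonzero(grid.occupancy):
        center = tuple(grid.centers[well_id])
        ng = (
            _count_particles(green, center, grid.radius, thr_g, min_area)
            if thr_g is not None
            else 0
        )
        nm = (
            _count_particles(magenta, center, grid.radius, thr_m, min_area)
            if thr_m is not None
            else 0
        )
        if ng >= 1 and nm >= 1:
            lab = "mixed_multiplet"
        elif ng >= 2 or nm >= 2:
            lab = "multiplet"
        elif ng + nm == 1:
            lab = "singlet"
        else:
            lab = "empty"
        rows.append({"well_id": int(well_id), "n_green": ng, "n_magenta": nm, "label": lab})
    return pd.DataFrame(rows)
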