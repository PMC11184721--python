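"""CFU-F plate-scan analysis: well location, stain unmixing, colony detection.

Crystal-violet stained colony-forming-unit (fibroblast) assays are scanned
as RGB images (1200 dpi flatbed convention).  The pipeline mirrors a
multi-well CellProfiler workflow stage by stage:

1. **Well location** — the blue channel is thresholded (wells have dark
   rims that absorb all colours, while crystal violet transmits blue);
   rim objects within a diameter range are detected, a regular 2x3 grid
   is fitted to their centroids and perfect circles placed at the nodes.
   The analysis circle is shrunk by 10 px in diameter (radius - 5) to
   stay off the well edge.
2. **Stain image** — per-channel optical density ``OD_c = -log10(I_c)``
   projected onto the unit-normalised crystal-violet absorbance vector
   (1, 1, 0)/sqrt(2) (red and green absorb, blue does not); pixels outside
   the analysis circles are zeroed; an illumination surface (20 px block
   medians, median-smoothed at the 80 px object scale, robustly capped)
   is subtracted.
3. **Detection** — Sobel edge magnitude (scaled to the stain range) is
   added to the stain image, a robust-background threshold (background
   mode + k * 1.4826 * MAD) binarises each well, a diamond closing of
   reach 10 merges dispersed-cell halos into their colony, and connected
   components are kept if their equivalent circular diameter lies in
   60-800 px.
4. **Measurement** — per-colony area (px^2 and mm^2 via dpi), equivalent
   diameter, eccentricity, integrated stain intensity and centroid;
   per-well counts and mean colony area.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import sobel
from skimage.measure import label as sk_label, regionprops
from skimage.morphology import closing as grey_closing, diamond

__all__ = [
    "PlateScan",
    "WellGeometry",
    "ColonyParams",
    "Colony",
    "WellReport",
    "locate_wells",
    "preprocess_plate",
    "detect_colonies",
    "measure_colonies",
    "analyse_plate",
]

MM_PER_INCH = 25.4


@dataclass
class PlateScan:
    """An RGB plate scan with resolution and layout metadata."""

    pixels: np.ndarray           # (h, w, 3) in [0, 1]
    dpi: float = 1200.0
    plate_layout: tuple[int, int] = (2, 3)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("plate scan must be an (h, w, 3) RGB array")
        if self.pixels.min() < -1e-9 or self.pixels.max() > 1 + 1e-9:
            raise ValueError("RGB values must lie in [0, 1]")


@dataclass
class WellGeometry:
    """One well's fitted circle; analysis restricted to radius - 5 px."""

    center: tuple[float, float]  # (row, col) px
    radius: float
    well_id: int = 0

    @property
    def analysis_radius(self) -> float:
        return self.radius - 5.0


@dataclass
class ColonyParams:
    """Stage parameters of the colony pipeline (CellProfiler-style defaults)."""

    well_threshold: float = 0.99
    well_diameter_range: tuple[float, float] = (1000.0, 2000.0)
    illum_block_size: int = 20
    illum_object_size: int = 80
    closing_reach: int = 10          # diamond closing, bridges gaps <= 2*reach
    colony_diameter_range: tuple[float, float] = (60.0, 800.0)
    background_k: float = 3.0        # robust-background threshold multiplier
    min_stain: float = 0.1           # OD floor so empty wells yield no colonies

    def __post_init__(self) -> None:
        for rng_ in (self.well_diameter_range, self.colony_diameter_range):
            if not 0 < rng_[0] < rng_[1]:
                raise ValueError("diameter ranges must be positive and ordered")
        for name in ("illum_block_size", "illum_object_size", "closing_reach"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class Colony:
    """One detected colony with size, shape and intensity measures."""

    well_id: int
    colony_id: int
    area_px: float
    area_mm2: float
    equivalent_diameter: float
    eccentricity: float
    integrated_intensity: float   # summed stain OD over the mask
    centroid: tuple[float, float]  # (row, col) px


@dataclass
class WellReport:
    """Per-well aggregate: colony count and mean colony area."""

    well_id: int
    n_colonies: int
    mean_area_px: float
    mean_area_mm2: float


def _fill_holes(mask: np.ndarray) -> np.ndarray:
    return ndi.binary_fill_holes(mask)


def locate_wells(scan: PlateScan, params: ColonyParams) -> list[WellGeometry]:
    """Detect well rims in the blue channel and fit a regular grid.

    Pixels darker than ``well_threshold`` in blue are rim candidates;
    hole-filled components with equivalent diameter inside
    ``well_diameter_range`` are wells.  A regular lattice (per-row mean
    row coordinate, per-column mean column coordinate) is fitted and
    perfect circles of the median fitted radius placed at every node.
    Raises if fewer rims than layout cells are found, naming the missing
    wells.
    """
    rows_n, cols_n = scan.plate_layout
    blue = scan.pixels[..., 2]
    rim_fg = blue < params.well_threshold
    fg = _fill_holes(rim_fg)
    lab = sk_label(fg)
    lo, hi = params.well_diameter_range
    cands = [
        p for p in regionprops(lab)
        if lo <= p.equivalent_diameter_area <= hi
    ]
    n_expected = rows_n * cols_n
    if len(cands) < min(4, n_expected):
        found = {(round(p.centroid[0]), round(p.centroid[1])) for p in cands}
        missing = n_expected - len(cands)
        raise ValueError(
            f"found only {len(cands)} well rims of {n_expected} expected "
            f"(missing {missing} wells); rim centroids found: {sorted(found)}"
        )
    cents = np.array([p.centroid for p in cands])
    # the open well area is the rim's interior hole; its equivalent radius
    # is the usable well radius (the filled disc includes the rim annulus)
    radii = []
    for p in cands:
        sl = p.slice
        hole = p.area - int(rim_fg[sl][p.image].sum())
        radii.append(math.sqrt(max(hole, p.area) / math.pi)
                     if hole <= 0 else math.sqrt(hole / math.pi))
    radius = float(np.median(radii))

    # assign candidates to lattice rows/cols by rank, then average
    row_order = np.argsort(cents[:, 0])
    row_groups = np.array_split(cents[row_order, 0], rows_n)
    row_pos = [float(np.mean(g)) for g in row_groups]
    col_order = np.argsort(cents[:, 1])
    col_groups = np.array_split(cents[col_order, 1], cols_n)
    col_pos = [float(np.mean(g)) for g in col_groups]

    wells = []
    wid = 0
    for r in row_pos:
        for c in col_pos:
            wells.append(WellGeometry(center=(r, c), radius=radius, well_id=wid))
            wid += 1
    return wells


def _analysis_mask(shape: tuple[int, int], wells: list[WellGeometry]) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    mask = np.zeros(shape, dtype=bool)
    for wg in wells:
        mask |= (yy - wg.center[0]) ** 2 + (xx - wg.center[1]) ** 2 <= wg.analysis_radius**2
    return mask


def _illumination_surface(stain: np.ndarray, inside: np.ndarray, params: ColonyParams) -> np.ndarray:
    """Background illumination estimate: block medians, median-smoothed, capped.

    Block size 20 px; median smoothing at the 80 px object scale.  The
    surface is capped at median + 3 * 1.4826 * MAD of the block medians so
    that colonies larger than the object scale do not subtract themselves.
    """
    b = params.illum_block_size
    h, w = stain.shape
    nh, nw = math.ceil(h / b), math.ceil(w / b)
    blocks = np.zeros((nh, nw))
    in_well = np.zeros((nh, nw), dtype=bool)
    for i in range(nh):
        for j in range(nw):
            tile = stain[i * b : (i + 1) * b, j * b : (j + 1) * b]
            msk = inside[i * b : (i + 1) * b, j * b : (j + 1) * b]
            vals = tile[msk]
            if vals.size:
                blocks[i, j] = np.median(vals)
                in_well[i, j] = True
    if not in_well.any():
        return np.zeros((h, w))
    well_vals = blocks[in_well]
    med = float(np.median(well_vals))
    mad = float(np.median(np.abs(well_vals - med)))
    cap = med + 3.0 * 1.4826 * mad
    blocks[~in_well] = med  # avoid edge blending against empty border blocks
    size = max(1, round(params.illum_object_size / b))
    if size % 2 == 0:
        size += 1
    smoothed = ndi.median_filter(blocks, size=size)
    smoothed = np.minimum(smoothed, cap)
    surface = ndi.zoom(smoothed, (h / nh, w / nw), order=1, grid_mode=True, mode="nearest")
    return surface[:h, :w]


def preprocess_plate(
    scan: PlateScan, wells: list[WellGeometry], params: ColonyParams
) -> np.ndarray:
    """Unmix the crystal-violet stain and flatten illumination.

    Per-pixel optical density ``OD_c = -log10(I_c)`` (zero intensities
    clipped to a small epsilon); stain = (OD_R + OD_G)/sqrt(2), the
    projection onto the unit absorbance vector (1, 1, 0).  Pixels outside
    the analysis circles are zeroed, then the illumination surface is
    subtracted and negatives clipped.
    """
    eps = 1e-4
    px = scan.pixels
    if np.any(px <= 0):
        import warnings

        warnings.warn("zero-intensity pixels clipped to epsilon before log", stacklevel=2)
    od = -np.log10(np.clip(px, eps, 1.0))
    stain = (od[..., 0] + od[..., 1]) / math.sqrt(2.0)
    inside = _analysis_mask(stain.shape, wells)
    stain = np.where(inside, stain, 0.0)
    surface = _illumination_surface(stain, inside, params)
    stain = np.where(inside, stain - surface, 0.0)
    return np.clip(stain, 0.0, None)


def _background_mode(values: np.ndarray, bins: int = 256) -> float:
    if values.size == 0:
        return 0.0
    lo, hi = float(values.min()), float(values.max())
    if hi <= lo:
        return lo
    hist, edges = np.histogram(values, bins=bins, range=(lo, hi))
    k = int(hist.argmax())
    return float(0.5 * (edges[k] + edges[k + 1]))


def detect_colonies(
    stain: np.ndarray, wells: list[WellGeometry], params: ColonyParams
) -> np.ndarray:
    """Segment colonies in the preprocessed stain image.

    Edge enhancement: Sobel gradient magnitude scaled to the stain
    image's dynamic range and added.  Threshold: per plate, background
    mode + k * 1.4826 * MAD of the analysis-circle pixels (robust
    background with mode averaging), floored at ``min_stain`` OD.  A
    diamond closing of reach 10 merges dispersed-cell halos (gaps up to
    2 * reach px) into their parent colony, holes are filled, and
    components outside the 60-800 px equivalent-diameter range are
    dropped.  Returns a labelled image; no label crosses an analysis
    circle boundary.
    """
    inside = _analysis_mask(stain.shape, wells)
    edges = sobel(stain)
    if edges.max() > 0:
        edges = edges * (stain.max() / edges.max())
    enhanced = np.where(inside, stain + edges, 0.0)

    bg_vals = enhanced[inside]
    mode = _background_mode(bg_vals)
    mad = float(np.median(np.abs(bg_vals - mode)))
    thr = max(mode + params.background_k * 1.4826 * mad, params.min_stain)

    mask = enhanced > thr
    mask = grey_closing(mask, diamond(params.closing_reach))
    mask = _fill_holes(mask) & inside

    lab = sk_label(mask)
    lo, hi = params.colony_diameter_range
    out = np.zeros_like(lab)
    nxt = 0
    for p in regionprops(lab):
        if lo <= p.equivalent_diameter_area <= hi:
            nxt += 1
            out[lab == p.label] = nxt
    return out


def measure_colonies(
    masks: np.ndarray,
    stain: np.ndarray,
    wells: list[WellGeometry],
    dpi: float = 1200.0,
) -> tuple[list[Colony], list[WellReport]]:
    """Measure detected colonies and aggregate per well.

    Pixel pitch is ``25.4 / dpi`` mm (21.17 um at 1200 dpi); colony areas
    are reported in px^2 and mm^2.  Each colony is assigned to the well
    whose center is nearest its centroid.
    """
    mm_per_px = MM_PER_INCH / dpi
    colonies: list[Colony] = []
    for p in regionprops(masks, intensity_image=stain):
        cy, cx = p.centroid
        dists = [math.hypot(cy - w.center[0], cx - w.center[1]) for w in wells]
        wid = wells[int(np.argmin(dists))].well_id
        colonies.append(
            Colony(
                well_id=wid,
                colony_id=int(p.label),
                area_px=float(p.area),
                area_mm2=float(p.area) * mm_per_px**2,
                equivalent_diameter=float(p.equivalent_diameter_area),
                eccentricity=float(p.eccentricity),
                integrated_intensity=float(p.image_intensity.sum()),
                centroid=(cy, cx),
            )
        )
    reports = []
    for wg in wells:
        mine = [c for c in colonies if c.well_id == wg.well_id]
        reports.append(
            WellReport(
                well_id=wg.well_id,
                n_colonies=len(mine),
                mean_area_px=float(np.mean([c.area_px for c in mine])) if mine else 0.0,
                mean_area_mm2=float(np.mean([c.area_mm2 for c in mine])) if mine else 0.0,
            )
        )
    return colonies, reports


def colonies_table(colonies: list[Colony]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "well_id": [c.well_id for c in colonies],
            "colony_id": [c.colony_id for c in colonies],
            "area_px2": [c.area_px for c in colonies],
            "area_mm2": [c.area_mm2 for c in colonies],
            "equivalent_diameter_px": [c.equivalent_diameter for c in colonies],
            "eccentricity": [c.eccentricity for c in colonies],
            "integrated_intensity_od_px": [c.integrated_intensity for c in colonies],
            "centroid_row_px": [c.centroid[0] for c in colonies],
            "centroid_col_px": [c.centroid[1] for c in colonies],
        }
    )


def analyse_plate(
    scan: PlateScan, params: ColonyParams | None = None
) -> tuple[list[Colony], list[WellReport], np.ndarray]:
    """Full pipeline: wells -> stain -> detection -> measurement."""
    if params is None:
        params = ColonyParams()
    wells = locate_wells(scan, params)
    stain = preprocess_plate(scan, wells, params)
    masks = detect_colonies(stain, wells, params)
    colonies, reports = measure_colonies(masks, stain, wells, dpi=scan.dpi)
    return colonies, reports, masks
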