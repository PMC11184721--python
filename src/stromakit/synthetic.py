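"""Synthetic data generators with exact ground truth.

Three families of inputs are emulated, matching the statistical structure
the downstream analyses assume:

* **Phase time-lapses** — two (or more) cell subpopulations that differ in
  aspect ratio, area, speed and dry mass, moving by a persistent random
  walk (Ornstein-Uhlenbeck velocity process), rendered as super-Gaussian
  elliptical phase blobs over a low-frequency background ramp plus
  Gaussian noise.  The integrated phase of each rendered cell encodes its
  dry mass through the standard QPI relation.
* **Scanned CFU-F plates** — 2x3 multi-well plates with dark well rims and
  crystal-violet colonies.  Colonies are rendered in optical-density
  space with absorbance in the red and green channels only (crystal
  violet transmits blue), converted to RGB by ``10**(-OD)``; this makes
  the downstream colour-unmixing step analytically checkable.  Dispersed
  cell halos and sub-threshold debris can be planted.
* **Abundance tables** — log-normal protein x sample tables, two groups x
  n replicates, with planted fold changes and matrisome membership flags.

Every generated object carries exactly one ground-truth record; all
randomness flows through a single seeded :class:`numpy.random.Generator`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .qpi import PhaseFrame, PhaseStack

__all__ = [
    "PopulationSpec",
    "TimelapseSpec",
    "PlateScanSpec",
    "AbundanceSpec",
    "GroundTruth",
    "GeneSetCollection",
    "generate_timelapse",
    "simulate_tracks",
    "generate_plate_scan",
    "generate_abundance_table",
    "generate_geneset_collection",
]


# --------------------------------------------------------------------------
# specs
# --------------------------------------------------------------------------

@dataclass
class PopulationSpec:
    """Morphometric and motility parameters of one cell subpopulation.

    Aspect ratios and areas are drawn per cell from normal distributions
    truncated to valid ranges; speed is the stationary mean speed of the
    persistent random walk in um/h.
    """

    n_cells: int
    mean_aspect_ratio: float
    sd_aspect_ratio: float = 0.0
    mean_area: float = 1500.0        # um^2
    sd_area: float = 150.0
    mean_speed: float = 20.0         # um/h
    persistence_time: float = 60.0   # min
    mean_dry_mass: float = 400.0     # pg
    sd_dry_mass: float = 40.0
    label: str = "pop"

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.mean_aspect_ratio < 1:
            raise ValueError("mean_aspect_ratio must be >= 1")
        for name in ("mean_area", "mean_speed", "persistence_time", "mean_dry_mass"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        for name in ("sd_aspect_ratio", "sd_area", "sd_dry_mass"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class TimelapseSpec:
    """Field geometry, timing and imaging noise of a synthetic time-lapse.

    Frame count = floor(duration_h * 60 / frame_interval_min) + 1.
    """

    populations: list[PopulationSpec] = field(default_factory=list)
    frame_interval: float = 24.0       # min; acquisition cadence 20-26 min
    duration: float = 96.0             # h
    field_size: tuple[int, int] = (512, 512)
    pixel_size: float = 1.0            # um/px
    background_ramp_amplitude: float = 0.2  # rad
    noise_sd: float = 0.02             # rad
    wavelength: float = 0.6            # um
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.frame_interval > 0 or not self.duration >= 0:
            raise ValueError("frame_interval must be > 0 and duration >= 0")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")

    @property
    def n_frames(self) -> int:
        return int(math.floor(self.duration * 60.0 / self.frame_interval)) + 1


@dataclass
class PlateScanSpec:
    """Layout and content of a synthetic scanned multi-well plate."""

    wells: int = 6
    well_diameter: float = 1000.0          # px; wells read out at 1000-2000 px
    colony_count_per_well: list[int] = field(default_factory=lambda: [2] * 6)
    colony_diameter_range: tuple[float, float] = (100.0, 300.0)
    dispersed_cell_fraction: float = 0.0
    debris_count: int = 0
    debris_diameter_range: tuple[float, float] = (20.0, 50.0)
    rim_darkness: float = 0.97             # rim OD (near-black rims)
    colony_od: float = 0.6                 # peak optical density of a colony
    dpi: float = 1200.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.wells != len(self.colony_count_per_well):
            raise ValueError("colony_count_per_well must have one entry per well")
        lo, hi = self.colony_diameter_range
        if not 0 < lo <= hi:
            raise ValueError("colony diameters must be positive and ordered")
        if hi >= self.well_diameter:
            raise ValueError("colony diameter exceeds well diameter")
        if self.wells % 3 != 0 and self.wells != 1:
            raise ValueError("wells are arranged on a 2x3-style grid")

    @property
    def layout(self) -> tuple[int, int]:
        if self.wells == 6:
            return (2, 3)
        if self.wells == 1:
            return (1, 1)
        return (self.wells // 3, 3)


@dataclass
class AbundanceSpec:
    """Two-group log-normal abundance table with planted fold changes.

    ``planted_effects`` entries are (protein_id, fold, direction) with
    direction ``"A"`` or ``"B"`` naming the elevated group; three
    biological replicates per group by default.
    """

    n_proteins: int = 861
    n_matrisome: int = 175
    replicates_per_group: int = 3
    cv: float = 0.1
    planted_effects: list[tuple[str, float, str]] = field(default_factory=list)
    base_abundance: float = 1e6
    planted_base_scale: float = 0.1  # planted proteins sit below the median
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_matrisome > self.n_proteins:
            raise ValueError("n_matrisome must be <= n_proteins")
        if self.replicates_per_group < 2:
            raise ValueError("replicates_per_group must be >= 2")
        ids = [p for p, _, _ in self.planted_effects]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate planted protein ids")
        for _, fold, direction in self.planted_effects:
            if not fold > 0:
                raise ValueError("planted folds must be > 0")
            if direction not in ("A", "B"):
                raise ValueError("direction must be 'A' or 'B'")


@dataclass
class GroundTruth:
    """Ground-truth record accompanying every generated object."""

    tracks: pd.DataFrame | None = None        # per cell x frame
    colony_masks: np.ndarray | None = None    # labelled image
    colony_table: pd.DataFrame | None = None  # per-colony truth
    effect_table: pd.DataFrame | None = None  # protein -> true fold


@dataclass
class GeneSetCollection:
    """Named gene sets, GMT-writable."""

    sets: dict[str, list[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def sizes(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.sets.items()}


# --------------------------------------------------------------------------
# time-lapse
# --------------------------------------------------------------------------

def _truncated_normal(rng, mean, sd, low, n):
    x = rng.normal(mean, sd, size=n)
    bad = x <= low
    while bad.any():
        x[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = x <= low
    return x


def simulate_tracks(spec: TimelapseSpec, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Simulate per-cell trajectories and morphometry without rendering.

    Motion is a persistent random walk: each cell's velocity follows a 2-D
    Ornstein-Uhlenbeck process with correlation time ``persistence_time``
    and stationary mean speed ``mean_speed``; positions advance by
    ``v * dt`` per frame and reflect off the field borders.  Per-cell
    aspect ratio, area and dry mass are drawn once and held constant.

    Returns a long-form DataFrame with one row per cell per frame:
    cell_id, population, frame, t_min, x_um, y_um, area_um2, aspect_ratio,
    length_um, width_um, dry_mass_pg.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    h, w = spec.field_size
    fw, fh = w * spec.pixel_size, h * spec.pixel_size
    dt_min = spec.frame_interval
    dt_h = dt_min / 60.0
    n_frames = spec.n_frames

    rows = []
    cell_id = 0
    placed: list[tuple[float, float, float]] = []  # (x, y, semi-major) across pops
    for pop in spec.populations:
        n = pop.n_cells
        if n == 0:
            continue
        aspect = _truncated_normal(rng, pop.mean_aspect_ratio, pop.sd_aspect_ratio, 1.0, n)
        area = _truncated_normal(rng, pop.mean_area, pop.sd_area, 0.0, n)
        mass = _truncated_normal(rng, pop.mean_dry_mass, pop.sd_dry_mass, 0.0, n)
        # semi-axes from area & aspect: area = pi a b, aspect = a/b
        b = np.sqrt(area / (np.pi * aspect))
        a = aspect * b

        margin = a.max() * 1.05
        if 2 * margin >= fw or 2 * margin >= fh:
            raise ValueError(
                f"field {fw:.0f}x{fh:.0f} um too small for cells with "
                f"semi-major axis up to {a.max():.0f} um"
            )
        # rejection-sample initial placements so cells start separated;
        # they may still overlap transiently while moving
        x = np.empty(n)
        y = np.empty(n)
        for i in range(n):
            for attempt in range(500):
                xi = rng.uniform(margin, fw - margin)
                yi = rng.uniform(margin, fh - margin)
                if all(
                    math.hypot(px_ - xi, py_ - yi) > 0.6 * (pa_ + a[i])
                    for px_, py_, pa_ in placed
                ):
                    x[i], y[i] = xi, yi
                    placed.append((xi, yi, a[i]))
                    break
            else:
                raise ValueError(
                    f"could not place {n} cells without overlap in a "
                    f"{fw:.0f}x{fh:.0f} um field"
                )
        # OU velocity: stationary |v| ~ Rayleigh, mean speed = sigma*sqrt(pi/2)
        sigma = pop.mean_speed * math.sqrt(2.0 / math.pi)
        decay = math.exp(-dt_min / pop.persistence_time)
        kick = sigma * math.sqrt(max(1.0 - decay**2, 0.0))
        v = rng.normal(0.0, sigma, size=(n, 2))
        theta = rng.uniform(0, 2 * np.pi, size=n)  # body orientation

        for f in range(n_frames):
            for i in range(n):
                rows.append(
                    (
                        cell_id + i, pop.label, f, f * dt_min,
                        x[i], y[i], area[i], aspect[i],
                        2 * a[i], 2 * b[i], mass[i], theta[i],
                    )
                )
            if f == n_frames - 1:
                break
            x = x + v[:, 0] * dt_h
            y = y + v[:, 1] * dt_h
            # reflecting boundaries
            x = np.where(x < 0, -x, x)
            x = np.where(x > fw, 2 * fw - x, x)
            y = np.where(y < 0, -y, y)
            y = np.where(y > fh, 2 * fh - y, y)
            v = decay * v + rng.normal(0.0, kick, size=(n, 2))
        cell_id += n

    return pd.DataFrame(
        rows,
        columns=[
            "cell_id", "population", "frame", "t_min", "x_um", "y_um",
            "area_um2", "aspect_ratio", "length_um", "width_um",
            "dry_mass_pg", "orientation_rad",
        ],
    )


def _render_cell(canvas, x_px, y_px, a_px, b_px, theta, peak_phase, power=4):
    """Add a super-Gaussian elliptical phase blob; returns added integral (px units)."""
    h, w = canvas.shape
    r_ext = max(a_px, b_px) * 1.6
    r0, r1 = int(max(0, y_px - r_ext)), int(min(h, y_px + r_ext + 1))
    c0, c1 = int(max(0, x_px - r_ext)), int(min(w, x_px + r_ext + 1))
    if r0 >= r1 or c0 >= c1:
        return 0.0
    yy, xx = np.mgrid[r0:r1, c0:c1]
    dx = xx - x_px
    dy = yy - y_px
    ct, st = math.cos(theta), math.sin(theta)
    u = (dx * ct + dy * st) / a_px
    v = (-dx * st + dy * ct) / b_px
    rho2 = u * u + v * v
    blob = peak_phase * np.exp(-math.log(2.0) * rho2**power)
    canvas[r0:r1, c0:c1] += blob
    return float(blob.sum())


def generate_timelapse(
    spec: TimelapseSpec, render: bool = True
) -> tuple[PhaseStack, GroundTruth]:
    """Generate a phase time-lapse with per-frame ground truth.

    Each cell is rendered as a super-Gaussian elliptical blob whose
    half-maximum contour is the nominal ellipse (so a half-max threshold
    recovers the nominal area) and whose integrated phase encodes the
    cell's dry mass: ``sum(phi) * px_area = 2 pi alpha m / lambda`` with
    alpha = 0.2 um^3/pg.  Background is a low-frequency ramp plus white
    Gaussian noise.

    With ``render=False`` only the ground truth is produced and the stack
    is empty (useful for large tracking ensembles).
    """
    rng = np.random.default_rng(spec.seed)
    truth = simulate_tracks(spec, rng)
    gt = GroundTruth(tracks=truth)
    if not render:
        return PhaseStack([]), gt

    h, w = spec.field_size
    p = spec.pixel_size
    alpha = 0.2
    yy, xx = np.mgrid[0:h, 0:w]
    ramp_dir = rng.uniform(0, 2 * np.pi)
    ramp = spec.background_ramp_amplitude * (
        (xx / max(w - 1, 1)) * math.cos(ramp_dir) + (yy / max(h - 1, 1)) * math.sin(ramp_dir)
    )

    frames = []
    by_frame = dict(tuple(truth.groupby("frame"))) if len(truth) else {}
    for f in range(spec.n_frames):
        canvas = np.zeros((h, w), dtype=float)
        sub = by_frame.get(f)
        if sub is not None:
            for row in sub.itertuples(index=False):
                a_px = (row.length_um / 2.0) / p
                b_px = (row.width_um / 2.0) / p
                target_integral = (
                    2.0 * math.pi * alpha * row.dry_mass_pg / spec.wavelength / (p * p)
                )
                # render at unit peak, then scale to hit the dry-mass integral
                tmp = np.zeros_like(canvas)
                got = _render_cell(
                    tmp, row.x_um / p - 0.5, row.y_um / p - 0.5,
                    a_px, b_px, row.orientation_rad, 1.0,
                )
                if got > 0:
                    canvas += tmp * (target_integral / got)
        noise = rng.normal(0.0, spec.noise_sd, size=(h, w)) if spec.noise_sd > 0 else 0.0
        frames.append(
            PhaseFrame(
                pixels=canvas + ramp + noise,
                pixel_size=p,
                timestamp=f * spec.frame_interval,
                wavelength=spec.wavelength,
            )
        )
    return PhaseStack(frames), gt


# --------------------------------------------------------------------------
# plate scan
# --------------------------------------------------------------------------

def _well_centers(spec: PlateScanSpec) -> tuple[np.ndarray, float, tuple[int, int]]:
    rows, cols = spec.layout
    pitch = spec.well_diameter * 1.15
    margin = spec.well_diameter * 0.65
    centers = []
    for r in range(rows):
        for c in range(cols):
            centers.append((margin + r * pitch, margin + c * pitch))
    height = int(round(2 * margin + (rows - 1) * pitch))
    width = int(round(2 * margin + (cols - 1) * pitch))
    return np.array(centers), spec.well_diameter / 2.0, (height, width)


def _irregular_blob_od(shape, cy, cx, radius, peak_od, rng, n_lobes=5, roughness=0.25):
    """Radially perturbed disc with smooth edges, in OD units."""
    h, w = shape
    r_ext = int(radius * 1.5) + 2
    r0, r1 = max(0, int(cy) - r_ext), min(h, int(cy) + r_ext + 1)
    c0, c1 = max(0, int(cx) - r_ext), min(w, int(cx) + r_ext + 1)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    dy, dx = yy - cy, xx - cx
    rr = np.hypot(dy, dx)
    ang = np.arctan2(dy, dx)
    amp = rng.uniform(-roughness, roughness, size=n_lobes)
    phase = rng.uniform(0, 2 * np.pi, size=n_lobes)
    wobble = sum(amp[k] * np.cos((k + 1) * ang + phase[k]) for k in range(n_lobes))
    local_r = radius * (1.0 + wobble)
    edge = 1.0 / (1.0 + np.exp((rr - local_r) / 0.5))  # sharp stained edge
    patch = peak_od * edge
    return (slice(r0, r1), slice(c0, c1)), patch


def generate_plate_scan(spec: PlateScanSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render an RGB plate scan and its colony ground truth.

    Well rims are dark annuli (absorbing in all channels, so they appear
    in the blue channel used for well detection); colonies absorb only in
    red and green, as crystal violet does, so they are invisible in blue.
    RGB = 10**(-OD) per channel.  Debris blobs smaller than the detection
    range are planted and marked ``is_colony=False`` in the truth table.
    """
    rng = np.random.default_rng(spec.seed)
    centers, radius, (h, w) = _well_centers(spec)
    od = np.zeros((h, w, 3), dtype=float)
    yy, xx = np.mgrid[0:h, 0:w]

    # rim = dark annulus just OUTSIDE the open well area (the well wall):
    # its inner edge marks the usable radius that well detection recovers
    rim_width = max(radius * 0.04, 8.0)
    rim_od = -math.log10(max(1.0 - spec.rim_darkness, 1e-6))
    for cy, cx in centers:
        rr = np.hypot(yy - cy, xx - cx)
        from scipy.special import expit

        rim = expit((rr - radius) / 0.3) - expit((rr - radius - rim_width) / 0.3)
        for ch in range(3):
            od[..., ch] += rim_od * rim

    masks = np.zeros((h, w), dtype=np.int32)
    truth_rows = []
    label = 0
    lo, hi = spec.colony_diameter_range
    # gap > 40 px between planted objects so diamond closing (reach 10,
    # bridging gaps <= 20 px) never merges distinct plantings
    placed: dict[int, list[tuple[float, float, float]]] = {i: [] for i in range(spec.wells)}

    def _place(widx, crad, clearance=40.0):
        cy, cx = centers[widx]
        rmax = radius - crad - 0.1 * radius
        if rmax <= 0:
            raise ValueError("colony diameter exceeds usable well area")
        for _ in range(300):
            rho = math.sqrt(rng.uniform(0, 1)) * rmax
            ang = rng.uniform(0, 2 * np.pi)
            by, bx = cy + rho * math.sin(ang), cx + rho * math.cos(ang)
            if all(
                math.hypot(py - by, px_ - bx) > pr + crad + clearance
                for py, px_, pr in placed[widx]
            ):
                placed[widx].append((by, bx, crad))
                return by, bx
        raise ValueError(f"could not place colony of radius {crad:.0f} px in well {widx}")

    for widx, (cy, cx) in enumerate(centers):
        for _ in range(spec.colony_count_per_well[widx]):
            label += 1
            diam = rng.uniform(lo, hi)
            crad = diam / 2.0
            by, bx = _place(widx, crad * 1.3)  # margin for edge wobble + halos
            sl, patch = _irregular_blob_od(
                (h, w), by, bx, crad, spec.colony_od, rng
            )
            od[sl][..., 0] += patch  # red absorbance
            od[sl][..., 1] += patch  # green absorbance
            core = patch >= spec.colony_od / 2.0
            region = masks[sl]
            region[core] = label
            masks[sl] = region
            area_px = int(core.sum())
            if spec.dispersed_cell_fraction > 0:
                n_disp = rng.poisson(spec.dispersed_cell_fraction * 20)
                for _ in range(n_disp):
                    dang = rng.uniform(0, 2 * np.pi)
                    drad = crad * rng.uniform(1.05, 1.3)
                    dy, dx = by + drad * math.sin(dang), bx + drad * math.cos(dang)
                    dsl, dpatch = _irregular_blob_od(
                        (h, w), dy, dx, rng.uniform(4, 8), spec.colony_od * 0.8, rng
                    )
                    od[dsl][..., 0] += dpatch
                    od[dsl][..., 1] += dpatch
            truth_rows.append(
                dict(
                    colony_id=label, well=widx, is_colony=True,
                    y_px=by, x_px=bx, diameter_px=diam, area_px=area_px,
                )
            )
    # debris: small blobs below the colony size range, spread over wells
    for _ in range(spec.debris_count):
        label += 1
        widx = int(rng.integers(0, spec.wells))
        dlo, dhi = spec.debris_diameter_range
        diam = rng.uniform(dlo, dhi)
        by, bx = _place(widx, diam / 2.0)
        sl, patch = _irregular_blob_od((h, w), by, bx, diam / 2.0, spec.colony_od, rng)
        od[sl][..., 0] += patch
        od[sl][..., 1] += patch
        truth_rows.append(
            dict(
                colony_id=label, well=widx, is_colony=False,
                y_px=by, x_px=bx, diameter_px=diam,
                area_px=int((patch >= spec.colony_od / 2).sum()),
            )
        )

    rgb = np.power(10.0, -od)
    gt = GroundTruth(
        colony_masks=masks,
        colony_table=pd.DataFrame(
            truth_rows,
            columns=["colony_id", "well", "is_colony", "y_px", "x_px",
                     "diameter_px", "area_px"],
        ),
    )
    return np.clip(rgb, 0.0, 1.0), gt


# --------------------------------------------------------------------------
# abundance table
# --------------------------------------------------------------------------

def generate_abundance_table(spec: AbundanceSpec) -> tuple[pd.DataFrame, GroundTruth]:
    """Log-normal protein x sample abundance table with planted effects.

    Columns are ``A_1..A_r, B_1..B_r``; the first ``n_matrisome`` proteins
    (ids ``MAT_*``) are flagged as matrisome members in the effect table.
    At ``cv = 0`` the table is noise-free and planted group-mean ratios
    are exact.  Planted protein ids may be any of the generated ids.

    Planted proteins are assigned a fixed base abundance of
    ``planted_base_scale * base_abundance`` (an order of magnitude below
    the median protein by default) instead of a random draw: differential
    proteins must remain minor contributors to the column totals, or
    total-intensity normalisation would genuinely attenuate every fold
    change and bias the null proteins — a real property of this
    normalisation, not an artefact.
    """
    rng = np.random.default_rng(spec.seed)
    ids = [f"MAT_{i:04d}" for i in range(spec.n_matrisome)] + [
        f"PRO_{i:04d}" for i in range(spec.n_proteins - spec.n_matrisome)
    ]
    known = set(ids)
    for pid, _, _ in spec.planted_effects:
        if pid not in known:
            raise ValueError(f"planted protein id {pid!r} not in generated table")

    base = spec.base_abundance * rng.lognormal(0.0, 1.0, size=spec.n_proteins)
    pid_index = {pid: i for i, pid in enumerate(ids)}
    for pid, _, _ in spec.planted_effects:
        base[pid_index[pid]] = spec.base_abundance * spec.planted_base_scale
    r = spec.replicates_per_group
    cols = [f"A_{j+1}" for j in range(r)] + [f"B_{j+1}" for j in range(r)]
    # multiplicative log-normal noise with the requested CV
    if spec.cv > 0:
        sigma = math.sqrt(math.log(1.0 + spec.cv**2))
        noise = rng.lognormal(-sigma**2 / 2.0, sigma, size=(spec.n_proteins, 2 * r))
    else:
        noise = np.ones((spec.n_proteins, 2 * r))
    values = base[:, None] * noise

    fold_a = np.ones(spec.n_proteins)  # true A/B mean ratio
    idx = pid_index
    for pid, fold, direction in spec.planted_effects:
        i = idx[pid]
        if direction == "A":
            values[i, :r] *= fold
            fold_a[i] *= fold
        else:
            values[i, r:] *= fold
            fold_a[i] /= fold

    table = pd.DataFrame(values, index=pd.Index(ids, name="protein"), columns=cols)
    effect = pd.DataFrame(
        {
            "protein": ids,
            "true_fold_a_over_b": fold_a,
            "is_matrisome": [pid.startswith("MAT_") for pid in ids],
        }
    ).set_index("protein")
    return table, GroundTruth(effect_table=effect)


# --------------------------------------------------------------------------
# gene sets
# --------------------------------------------------------------------------

def generate_geneset_collection(
    n_sets: int,
    size_range: tuple[int, int],
    universe: list[str],
    seed: int = 0,
) -> GeneSetCollection:
    """Sample named gene sets without replacement from a universe."""
    lo, hi = size_range
    if hi > len(universe):
        raise ValueError("set size exceeds universe size")
    if lo < 1 or lo > hi:
        raise ValueError("invalid size_range")
    rng = np.random.default_rng(seed)
    uni = np.asarray(universe, dtype=object)
    sets = {}
    for i in range(n_sets):
        k = int(rng.integers(lo, hi + 1))
        members = rng.choice(uni, size=k, replace=False)
        sets[f"SET_{i:03d}"] = sorted(members.tolist())
    return GeneSetCollection(sets=sets)
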