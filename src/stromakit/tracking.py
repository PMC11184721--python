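"""Cell tracking, exclusion gating and migration metrics.

Per-frame detections are linked into tracks by greedy mutual
nearest-neighbour matching under a distance cap.  Debris gates then
remove small objects (dry mass below 250 pg or area below 1000 um^2 by
default), large doublets (area above 25,000 um^2), and tracks observed
for fewer than 20 frames; every removal is recorded in an audit log.
Migration is summarised per track as mean speed (total path length over
elapsed time), net displacement from the tracking origin, and total path
length.  Rose-plot data are tracks translated to a common origin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .qpi import CellObject

__all__ = [
    "Track",
    "GateParams",
    "MigrationMetrics",
    "link_tracks",
    "apply_gates",
    "compute_migration_metrics",
    "export_rose_data",
    "metrics_table",
]


@dataclass
class Track:
    """Time-ordered chain of one cell's per-frame detections."""

    track_id: int
    cells: list[CellObject] = field(default_factory=list)
    times: list[float] = field(default_factory=list)  # min

    def __post_init__(self) -> None:
        if len(self.cells) != len(self.times):
            raise ValueError("cells and times must have equal length")
        if any(t2 <= t1 for t1, t2 in zip(self.times, self.times[1:])):
            raise ValueError("track times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.cells)

    @property
    def positions(self) -> np.ndarray:
        return np.array([c.centroid for c in self.cells], dtype=float)


@dataclass
class GateParams:
    """Exclusion-gate thresholds.

    Objects below ``min_dry_mass`` (pg) or below ``min_area`` (um^2) are
    debris; objects above ``max_area`` are doublets/large debris; tracks
    spanning fewer than ``min_frames`` frames are dropped.  The debris
    combinator is OR by default (an object failing either floor is
    removed); set ``debris_rule="and"`` to require both.
    """

    min_dry_mass: float = 250.0
    min_area: float = 1000.0
    max_area: float = 25000.0
    min_frames: int = 20
    max_link_distance: float = 50.0  # um
    debris_rule: str = "or"

    def __post_init__(self) -> None:
        if not self.min_area < self.max_area:
            raise ValueError("min_area must be < max_area")
        if self.min_frames < 1:
            raise ValueError("min_frames must be >= 1")
        if self.debris_rule not in ("or", "and"):
            raise ValueError("debris_rule must be 'or' or 'and'")


@dataclass
class MigrationMetrics:
    """Per-track migration summary (Fig-style speed and displacement)."""

    track_id: int
    mean_speed: float    # um/h: path_length / elapsed hours
    displacement: float  # um: |last - first|
    path_length: float   # um

    def __post_init__(self) -> None:
        if self.displacement > self.path_length + 1e-9:
            raise ValueError("displacement cannot exceed path length")
        if min(self.mean_speed, self.displacement, self.path_length) < 0:
            raise ValueError("metrics must be non-negative")


def _mutual_nearest(prev_xy: np.ndarray, cur_xy: np.ndarray, cap: float):
    """Greedy mutual nearest-neighbour pairs under the distance cap."""
    if len(prev_xy) == 0 or len(cur_xy) == 0:
        return []
    d = np.linalg.norm(prev_xy[:, None, :] - cur_xy[None, :, :], axis=2)
    pairs = []
    nn_of_prev = d.argmin(axis=1)
    nn_of_cur = d.argmin(axis=0)
    for i, j in enumerate(nn_of_prev):
        if nn_of_cur[j] == i and d[i, j] <= cap:
            pairs.append((i, int(j), d[i, j]))
    pairs.sort(key=lambda t: t[2])
    used_i, used_j, out = set(), set(), []
    for i, j, _ in pairs:
        if i not in used_i and j not in used_j:
            used_i.add(i)
            used_j.add(j)
            out.append((i, j))
    return out


def link_tracks(
    frames: list[list[CellObject]],
    gates: GateParams,
    times: list[float] | None = None,
) -> list[Track]:
    """Link per-frame detections into tracks.

    Frames must be time-ordered.  Matched detections extend their track;
    unmatched detections start new tracks; tracks with no match in the
    next frame end there (no gap closing).
    """
    if times is None:
        times = [float(i) for i in range(len(frames))]
    tracks: list[Track] = []
    open_tracks: list[Track] = []
    next_id = 0
    for f_idx, dets in enumerate(frames):
        t = times[f_idx]
        if open_tracks and dets:
            prev_xy = np.array([tr.cells[-1].centroid for tr in open_tracks])
            cur_xy = np.array([c.centroid for c in dets])
            pairs = _mutual_nearest(prev_xy, cur_xy, gates.max_link_distance)
        else:
            pairs = []
        matched_prev = {i for i, _ in pairs}
        matched_cur = {j for _, j in pairs}
        still_open = []
        for i, j in pairs:
            tr = open_tracks[i]
            tr.cells.append(dets[j])
            tr.times.append(t)
            still_open.append(tr)
        for i, tr in enumerate(open_tracks):
            if i not in matched_prev:
                tracks.append(tr)  # closed
        for j, det in enumerate(dets):
            if j not in matched_cur:
                tr = Track(track_id=next_id, cells=[det], times=[t])
                next_id += 1
                still_open.append(tr)
        open_tracks = still_open
    tracks.extend(open_tracks)
    tracks.sort(key=lambda tr: tr.track_id)
    return tracks


def _object_gate_reason(obj: CellObject, gates: GateParams) -> str | None:
    small_mass = obj.dry_mass < gates.min_dry_mass
    small_area = obj.area < gates.min_area
    if gates.debris_rule == "or":
        debris = small_mass or small_area
    else:
        debris = small_mass and small_area
    if debris:
        parts = []
        if small_mass:
            parts.append(f"dry_mass {obj.dry_mass:.1f} < {gates.min_dry_mass}")
        if small_area:
            parts.append(f"area {obj.area:.1f} < {gates.min_area}")
        return "debris: " + "; ".join(parts)
    if obj.area > gates.max_area:
        return f"doublet: area {obj.area:.1f} > {gates.max_area}"
    return None


def apply_gates(objects_or_tracks, gates: GateParams):
    """Apply exclusion gates; returns (kept, audit_log).

    Accepts a list of :class:`CellObject` (debris/doublet gates) or a list
    of :class:`Track` (object gates on member cells are NOT re-applied;
    only the minimum-span gate).  The audit log records one entry per
    removal with its reason; ``len(input) == len(kept) + len(audit)``.
    """
    kept, audit = [], []
    for item in objects_or_tracks:
        if isinstance(item, Track):
            if len(item) < gates.min_frames:
                audit.append(
                    {"id": item.track_id, "kind": "track",
                     "reason": f"span {len(item)} < min_frames {gates.min_frames}"}
                )
            else:
                kept.append(item)
        else:
            reason = _object_gate_reason(item, gates)
            if reason is None:
                kept.append(item)
            else:
                audit.append(
                    {"id": (item.frame_index, item.label), "kind": "object",
                     "reason": reason}
                )
    return kept, audit


def compute_migration_metrics(track: Track) -> MigrationMetrics:
    """Speed, displacement and path length of one track.

    mean speed   = total path length / elapsed time (um/h)
    displacement = Euclidean distance from first to last position (um)
    """
    if len(track) < 2:
        raise ValueError("track needs >= 2 points for migration metrics")
    xy = track.positions
    steps = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    path = float(steps.sum())
    elapsed_h = (track.times[-1] - track.times[0]) / 60.0
    disp = float(math.hypot(*(xy[-1] - xy[0])))
    return MigrationMetrics(
        track_id=track.track_id,
        mean_speed=path / elapsed_h,
        displacement=min(disp, path),  # guard float round-off on straight paths
        path_length=path,
    )


def metrics_table(tracks: list[Track]) -> pd.DataFrame:
    """Per-track metrics as a DataFrame (track_id, speed, displacement, path)."""
    rows = [compute_migration_metrics(t) for t in tracks if len(t) >= 2]
    return pd.DataFrame(
        {
            "track_id": [m.track_id for m in rows],
            "mean_speed_um_per_h": [m.mean_speed for m in rows],
            "displacement_um": [m.displacement for m in rows],
            "path_length_um": [m.path_length for m in rows],
        }
    )


def export_rose_data(tracks: list[Track]) -> pd.DataFrame:
    """Origin-centred long-form track table for rose plots.

    Each track is translated so its first point is (0, 0); columns are
    track_id, t_min, x_um, y_um.  Shifting all input coordinates by a
    constant leaves the export unchanged.
    """
    rows = []
    for tr in tracks:
        xy = tr.positions
        if len(xy) == 0:
            continue
        xy = xy - xy[0]
        for t, (x, y) in zip(tr.times, xy):
            rows.append((tr.track_id, t, x, y))
    return pd.DataFrame(rows, columns=["track_id", "t_min", "x_um", "y_um"])


def plot_rose(tracks: list[Track], ax=None):
    """Overlay origin-centred trajectories (matplotlib Axes returned)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    data = export_rose_data(tracks)
    for _, g in data.groupby("track_id"):
        ax.plot(g["x_um"], g["y_um"], lw=0.8, alpha=0.7)
    ax.axhline(0, color="k", lw=0.5)
    ax.axvline(0, color="k", lw=0.5)
    ax.set_aspect("equal")
    ax.set_xlabel("x (um)")
    ax.set_ylabel("y (um)")
    return ax
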