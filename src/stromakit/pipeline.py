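"""End-to-end composition of the pipeline stages on tables and synthetic runs."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .qpi import CellObject
from .tracking import (
    GateParams,
    Track,
    apply_gates,
    export_rose_data,
    link_tracks,
    metrics_table,
)

__all__ = ["cells_from_table", "track_cells_table", "run_all_synthetic"]


def cells_from_table(cells: pd.DataFrame) -> tuple[list[list[CellObject]], list[float]]:
    """Group a long-form cell table into per-frame CellObject lists."""
    frames: list[list[CellObject]] = []
    times: list[float] = []
    for f, sub in cells.groupby("frame", sort=True):
        dets = []
        for i, row in enumerate(sub.itertuples(index=False)):
            ar = max(float(getattr(row, "aspect_ratio", 1.0)), 1.0)
            area = float(getattr(row, "area_um2"))
            dets.append(
                CellObject(
                    frame_index=int(f),
                    label=int(getattr(row, "label", i + 1)),
                    centroid=(float(row.x_um), float(row.y_um)),
                    area=area,
                    length=float(getattr(row, "length_um", np.sqrt(area * ar))),
                    width=float(getattr(row, "width_um", np.sqrt(area / ar))),
                    aspect_ratio=ar,
                    dry_mass=float(getattr(row, "dry_mass_pg", 0.0)),
                    mean_phase=float(getattr(row, "mean_phase_rad", 0.0)),
                )
            )
        frames.append(dets)
        times.append(float(sub["t_min"].iloc[0]) if "t_min" in sub else float(f))
    return frames, times


def track_cells_table(
    cells: pd.DataFrame, gates: GateParams
) -> tuple[list[Track], pd.DataFrame, pd.DataFrame, list[dict]]:
    """Object gates -> linking -> track gates -> metrics + rose export."""
    frames, times = cells_from_table(cells)
    audit: list[dict] = []
    gated_frames = []
    for dets in frames:
        kept, removed = apply_gates(dets, gates)
        gated_frames.append(kept)
        audit.extend(removed)
    tracks = link_tracks(gated_frames, gates, times=times)
    tracks, removed = apply_gates(tracks, gates)
    audit.extend(removed)
    return tracks, metrics_table(tracks), export_rose_data(tracks), audit


def run_all_synthetic(cfg, seed: int = 0, out_dir: str | Path = "out") -> dict:
    """Small end-to-end run on freshly generated synthetic data.

    Exercises every stage (time-lapse -> segmentation -> tracking;
    plate -> colonies; abundance -> differential -> matrisome -> chi2 ->
    over-representation) and writes reports; returns the summary dict.
    """
    from .cfu import PlateScan, analyse_plate, colonies_table
    from .io import write_reports
    from .qpi import segment_frame
    from .secretome import (
        chisq_matrisome_enrichment,
        differential_abundance,
        normalize_abundance,
        overrepresentation,
    )
    from .synthetic import (
        AbundanceSpec,
        PlateScanSpec,
        PopulationSpec,
        TimelapseSpec,
        generate_abundance_table,
        generate_geneset_collection,
        generate_plate_scan,
        generate_timelapse,
    )

    rng = np.random.default_rng(seed)
    out = Path(out_dir)
    summary: dict = {"seed": seed}

    # --- imaging branch: short two-population time-lapse ------------------
    tl_spec = TimelapseSpec(
        populations=[
            PopulationSpec(n_cells=5, mean_aspect_ratio=3.59, sd_aspect_ratio=0.072,
                           mean_area=1400.0, label="Y201"),
            PopulationSpec(n_cells=5, mean_aspect_ratio=2.016, sd_aspect_ratio=0.051,
                           mean_area=1800.0, label="Y202"),
        ],
        duration=2.0, frame_interval=24.0, field_size=(384, 384),
        seed=int(rng.integers(2**31)),
    )
    stack, gt = generate_timelapse(tl_spec)
    params = cfg.segmentation
    rows = []
    for i, frame in enumerate(stack):
        for c in segment_frame(frame, params, frame_index=i):
            rows.append(dict(frame=i, label=c.label, t_min=frame.timestamp,
                             x_um=c.centroid[0], y_um=c.centroid[1],
                             area_um2=c.area, length_um=c.length,
                             width_um=c.width, aspect_ratio=c.aspect_ratio,
                             dry_mass_pg=c.dry_mass, mean_phase_rad=c.mean_phase))
    cells = pd.DataFrame(rows)
    gates = cfg.gates
    tracks, metrics, rose, audit = track_cells_table(cells, GateParams(
        min_dry_mass=gates.min_dry_mass, min_area=gates.min_area,
        max_area=gates.max_area, min_frames=min(gates.min_frames, len(stack)),
        max_link_distance=gates.max_link_distance,
    ))
    summary["n_cells_detected"] = len(cells)
    summary["n_tracks"] = len(tracks)

    # --- plate branch ----------------------------------------------------
    plate_spec = PlateScanSpec(
        colony_count_per_well=[2, 1, 2, 1, 2, 1],
        seed=int(rng.integers(2**31)),
    )
    rgb, plate_gt = generate_plate_scan(plate_spec)
    colonies, reports, _ = analyse_plate(PlateScan(pixels=rgb), cfg.colony)
    summary["n_colonies_detected"] = len(colonies)
    summary["n_colonies_planted"] = int(plate_gt.colony_table["is_colony"].sum())

    # --- secretome branch -------------------------------------------------
    ab_spec = AbundanceSpec(
        n_proteins=400, n_matrisome=80,
        planted_effects=[("MAT_0000", 71.0, "A"), ("MAT_0001", 104.0, "A"),
                         ("MAT_0002", 9.7, "B")],
        seed=int(rng.integers(2**31)),
    )
    table, ab_gt = generate_abundance_table(ab_spec)
    diff = differential_abundance(normalize_abundance(table),
                                  alpha=cfg["secretome"]["alpha"])
    sig = diff[diff["significant"] & (diff["fold_change"] > 1)]
    k_obs = int(sum(p.startswith("MAT_") for p in sig.index))
    chi2 = chisq_matrisome_enrichment(
        k_obs, len(sig), ab_spec.n_matrisome, ab_spec.n_proteins
    )
    universe = list(table.index)
    collection = generate_geneset_collection(
        10, (10, 60), universe, seed=int(rng.integers(2**31))
    )
    enr = overrepresentation(list(sig.index) or universe[:5], universe, collection,
                             q_max=cfg["secretome"]["q_max"],
                             K_max=cfg["secretome"]["K_max"])
    summary["n_significant"] = int(diff["significant"].sum())
    summary["chi2_matrisome"] = chi2.chi2
    summary["n_enriched_sets"] = int(enr["passed_filters"].sum())

    write_reports(
        {"cells": cells, "metrics": metrics, "rose": rose,
         "colonies": colonies_table(colonies), "differential": diff,
         "summary": summary},
        out, config=dict(cfg), seed=seed,
    )
    return summary
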