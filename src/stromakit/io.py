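"""Format readers/writers and run manifests.

Phase stacks travel as multi-page 32-bit float TIFF with calibration
stored in the image description; gene sets as GMT (tab-separated: name,
description, members); tabular outputs as CSV with unit-suffixed column
names (area_um2, speed_um_per_h) and a schema-version header comment.
Every report-writing run emits a JSON manifest (config snapshot, package
version, seed, input checksums, timestamp) sufficient to reproduce
deterministic stages bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .qpi import PhaseFrame, PhaseStack
from .synthetic import GeneSetCollection

__all__ = [
    "read_phase_stack",
    "write_phase_stack",
    "read_gmt",
    "write_gmt",
    "write_reports",
    "RunManifest",
]

SCHEMA_VERSION = "1"


def write_phase_stack(stack: PhaseStack, path: str | Path) -> Path:
    """Write a phase stack as multi-page float32 TIFF with calibration."""
    path = Path(path)
    meta = {
        "pixel_size_um": stack.pixel_size,
        "wavelength_um": stack.frames[0].wavelength,
        "timestamps_min": [f.timestamp for f in stack.frames],
    }
    tifffile.imwrite(
        path,
        stack.as_array().astype(np.float32),
        photometric="minisblack",
        description=json.dumps(meta),
    )
    return path


def read_phase_stack(
    path: str | Path,
    pixel_size: float | None = None,
    wavelength: float | None = None,
) -> PhaseStack:
    """Read a multi-page TIFF phase stack.

    Calibration is taken from the embedded description when present;
    otherwise ``pixel_size`` must be given explicitly (error if not).
    RGB input is rejected: phase stacks are single-channel.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        desc = tf.pages[0].description
    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    if arr.ndim == 2:
        arr = arr[None, ...]
    if arr.ndim != 3:
        raise ValueError("expected single-channel phase stack")
    if arr.shape[-1] in (3, 4) and arr.shape[-1] < min(arr.shape[:-1]):
        raise ValueError("expected single-channel phase stack, got RGB(A) TIFF")
    px = pixel_size if pixel_size is not None else meta.get("pixel_size_um")
    if px is None:
        raise ValueError(
            "pixel size not found in TIFF metadata; pass pixel_size explicitly"
        )
    lam = wavelength if wavelength is not None else meta.get("wavelength_um", 0.6)
    times = meta.get("timestamps_min", list(range(arr.shape[0])))
    frames = [
        PhaseFrame(pixels=arr[i].astype(float), pixel_size=float(px),
                   timestamp=float(times[i]), wavelength=float(lam))
        for i in range(arr.shape[0])
    ]
    return PhaseStack(frames)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT gene-set file (name TAB description TAB members...).

    Duplicate members within a set are deduplicated with a warning;
    a line with fewer than 3 fields raises with its line number; an
    empty file yields an empty collection with a warning.
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    lines = path.read_text().splitlines()
    if not any(line.strip() for line in lines):
        warnings.warn(f"empty GMT file: {path}", stacklevel=2)
        return GeneSetCollection(sets={})
    for ln, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{ln}: GMT line has {len(fields)} fields (< 3)")
        name, _desc, *members = fields
        members = [m for m in members if m]
        unique = list(dict.fromkeys(members))
        if len(unique) < len(members):
            warnings.warn(
                f"{path}:{ln}: set {name!r} has duplicate members; deduplicated",
                stacklevel=2,
            )
        sets[name] = unique
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        for name, members in collection.sets.items():
            fh.write("\t".join([name, "na", *members]) + "\n")
    return path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class RunManifest(dict):
    """JSON-serialisable record of a run (config, version, seed, checksums)."""

    @classmethod
    def create(cls, config: dict | None, seed: int | None,
               inputs: list[str | Path] = ()) -> "RunManifest":
        from . import __version__

        return cls(
            schema_version=SCHEMA_VERSION,
            software="stromakit",
            version=__version__,
            seed=seed,
            config=config or {},
            input_checksums={str(p): _sha256(Path(p)) for p in inputs},
            timestamp=datetime.now(timezone.utc).isoformat(),
        )


def _write_csv(df: pd.DataFrame, path: Path, index: bool) -> None:
    with path.open("w") as fh:
        fh.write(f"# stromakit schema v{SCHEMA_VERSION}\n")
        df.to_csv(fh, index=index, float_format="%.10g")


def read_report_csv(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", index_col=index_col)


def write_reports(
    results: dict[str, pd.DataFrame | dict],
    out_dir: str | Path,
    config: dict | None = None,
    seed: int | None = None,
    inputs: list[str | Path] = (),
    index: bool = False,
) -> RunManifest:
    """Write result tables (CSV) / dicts (JSON) plus a run manifest.

    Deterministic stages re-run with the same inputs and seed produce
    byte-identical CSVs (the manifest timestamp is the only varying
    output).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, obj in results.items():
        if isinstance(obj, pd.DataFrame):
            _write_csv(obj, out / f"{name}.csv", index=index)
        else:
            (out / f"{name}.json").write_text(
                json.dumps(obj, indent=2, default=float, sort_keys=True)
            )
    manifest = RunManifest.create(config, seed, inputs)
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
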