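"""Pipeline configuration: defaults, YAML loading, unknown-key rejection."""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import yaml

from .cfu import ColonyParams
from .qpi import SegmentationParams
from .tracking import GateParams

__all__ = ["default_config", "load_config", "PipelineConfig"]


def default_config() -> dict:
    """Full default configuration, one block per pipeline stage."""
    return {
        "seed": 0,
        "units": {"pixel_size_um": 1.0, "dpi": 1200.0, "frame_interval_min": 24.0},
        "segmentation": asdict(SegmentationParams()),
        "gates": asdict(GateParams()),
        "colony": asdict(ColonyParams()),
        "classifier": {"margin": 1.0, "d_max": 3.0},
        "secretome": {"alpha": 0.05, "q_max": 0.05, "K_max": 500},
    }


def _merge(defaults: dict, override: dict, path: str = "") -> dict:
    out = dict(defaults)
    for key, val in override.items():
        here = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ValueError(f"unknown configuration key: {here}")
        if isinstance(defaults[key], dict) and isinstance(val, dict):
            out[key] = _merge(defaults[key], val, here)
        else:
            out[key] = val
    return out


class PipelineConfig(dict):
    """Validated configuration; unknown keys rejected at load time."""

    @property
    def segmentation(self) -> SegmentationParams:
        return SegmentationParams(**self["segmentation"])

    @property
    def gates(self) -> GateParams:
        return GateParams(**self["gates"])

    @property
    def colony(self) -> ColonyParams:
        d = dict(self["colony"])
        for key in ("well_diameter_range", "colony_diameter_range"):
            d[key] = tuple(d[key])
        return ColonyParams(**d)


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> PipelineConfig:
    """Load configuration from YAML, merged over defaults.

    Every parameter has a default; any key not present in the defaults is
    rejected with its dotted path.
    """
    cfg = default_config()
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        cfg = _merge(cfg, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    return PipelineConfig(cfg)
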