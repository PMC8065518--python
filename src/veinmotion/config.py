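"""Run configuration: one serializable record for a whole pipeline run."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .errors import InputError

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    """Every knob of a detection run, fully serializable to YAML.

    Defaults follow the reference acquisition setup: 30 FPS input, grid
    spacing 4 px, 63 px subsets, a 15-points-per-side moving window, and a
    120-frame accumulation block.
    """

    # input
    input_path: str = ""
    fps: float = 30.0
    base_index: int = 0
    # grid
    grid_origin_x: int | None = None
    grid_origin_y: int | None = None
    grid_spacing: int = 4
    grid_n_cols: int | None = None
    grid_n_rows: int | None = None
    # subset / search / refinement
    subset_size: int = 63
    search_radius: int = 10
    nr_tol: float = 1e-4
    nr_max_iter: int = 50
    # filter
    filter_mode: str = "moving-row"
    filter_window_half: int = 15
    filter_ref_region: tuple[int, int, int, int] | None = None
    filter_include_center: bool = True
    # accumulation
    accumulate_start_frame: int = 1
    accumulate_n_frames: int = 120
    # rendering
    render_negative: bool = True
    render_alpha: float = 0.6
    # output
    output_dir: str = "veinmotion_out"
    log_level: str = "INFO"
    # synthetic-scene seeds (cmd_simulate)
    speckle_seed: int = 0
    tremor_seed: int = 1

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML config; unknown keys are rejected to catch typos."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise InputError(f"config {path} does not contain a mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise InputError(f"unknown config keys: {sorted(unknown)}")
    if "filter_ref_region" in data and data["filter_ref_region"] is not None:
        data["filter_ref_region"] = tuple(data["filter_ref_region"])
    return RunConfig(**data)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    """Write the effective configuration alongside the run's outputs."""
    data = cfg.to_dict()
    if data.get("filter_ref_region") is not None:
        data["filter_ref_region"] = list(data["filter_ref_region"])
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
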