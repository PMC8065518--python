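"""End-to-end detection pipeline: DIC -> motion filter -> cumulative map."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dic_core import (
    DEFAULT_MAX_ITER,
    DEFAULT_SEARCH_RADIUS,
    DEFAULT_TOL,
    DisplacementField,
    GridSpec,
    SubsetSpec,
    compute_field,
    prepare_reference,
)
from .errors import ConfigurationError, InputError
from .frameio import FrameSequence
from .pulsation_filter import FilterParams, PulsationMap, apply_filter
from .synthetic import GroundTruth, SceneParams, render_sequence
from .vein_mapper import CumulativeMap, accumulate

__all__ = [
    "DetectionResult",
    "auto_grid",
    "run_detection",
    "fields_to_cumulative",
    "band_contrast",
    "run_scene_detection",
]

DEFAULT_N_FRAMES = 120


@dataclass
class DetectionResult:
    """Products of one detection run."""

    cumulative: CumulativeMap
    fields: list[DisplacementField] = field(default_factory=list)
    maps: list[PulsationMap] = field(default_factory=list)
    invalid_counts: list[int] = field(default_factory=list)
    nonconverged_counts: list[int] = field(default_factory=list)
    low_quality_counts: list[int] = field(default_factory=list)


def auto_grid(
    height: int,
    width: int,
    subset: SubsetSpec,
    search_radius: int = DEFAULT_SEARCH_RADIUS,
    spacing: int = 4,
    max_cols: int | None = None,
    max_rows: int | None = None,
) -> GridSpec:
    """Largest centered grid that fits the frame with the required margin."""
    margin = subset.half + search_radius + 2
    avail_w = width - 1 - 2 * margin
    avail_h = height - 1 - 2 * margin
    if avail_w < 0 or avail_h < 0:
        raise ConfigurationError("frame too small for the subset and search radius")
    n_cols = avail_w // spacing + 1
    n_rows = avail_h // spacing + 1
    if max_cols is not None:
        n_cols = min(n_cols, max_cols)
    if max_rows is not None:
        n_rows = min(n_rows, max_rows)
    span_x = (n_cols - 1) * spacing
    span_y = (n_rows - 1) * spacing
    return GridSpec(
        origin_x=(width - span_x) // 2,
        origin_y=(height - span_y) // 2,
        spacing=spacing,
        n_cols=int(n_cols),
        n_rows=int(n_rows),
    )


def fields_to_cumulative(
    fields: list[DisplacementField], filt: FilterParams
) -> tuple[CumulativeMap, list[PulsationMap]]:
    """Filter each displacement field and accumulate the magnitudes."""
    maps = [apply_filter(f, filt) for f in fields]
    return accumulate(maps), maps


def run_detection(
    seq: FrameSequence,
    grid: GridSpec,
    subset: SubsetSpec,
    filt: FilterParams,
    start_frame: int = 1,
    n_frames: int = DEFAULT_N_FRAMES,
    search_radius: int = DEFAULT_SEARCH_RADIUS,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    quality_floor: float = 0.5,
    keep_fields: bool = True,
    progress: bool = False,
) -> DetectionResult:
    """Run the detection pipeline on a contiguous block of frames.

    Displacements are always computed against the sequence's base frame;
    ``start_frame`` .. ``start_frame + n_frames - 1`` are the current frames
    (the base frame itself is skipped if it falls inside the block).
    """
    last = start_frame + n_frames - 1
    if start_frame < 0 or last >= len(seq):
        raise InputError(
            f"frame block [{start_frame}, {last}] outside the {len(seq)}-frame sequence"
        )
    indices = [k for k in range(start_frame, last + 1) if k != seq.base_index]
    fields: list[DisplacementField] = []
    maps: list[PulsationMap] = []
    inv_counts: list[int] = []
    nc_counts: list[int] = []
    lq_counts: list[int] = []
    ref_cache = prepare_reference(seq.frames[seq.base_index], grid, subset)
    for k in indices:
        f = compute_field(
            seq, k, grid, subset, search_radius, tol=tol, max_iter=max_iter,
            quality_floor=quality_floor, ref_cache=ref_cache,
        )
        m = apply_filter(f, filt)
        inv_counts.append(int((~f.valid).sum()))
        nc_counts.append(int((f.valid & ~f.converged).sum()))
        with np.errstate(invalid="ignore"):
            lq_counts.append(int((f.valid & (f.quality < quality_floor)).sum()))
        if progress:
            print(
                f"frame {k}: {inv_counts[-1]} invalid, {nc_counts[-1]} "
                f"non-converged, {lq_counts[-1]} low-quality"
            )
        if keep_fields:
            fields.append(f)
        maps.append(m)
    return DetectionResult(
        cumulative=accumulate(maps),
        fields=fields,
        maps=maps,
        invalid_counts=inv_counts,
        nonconverged_counts=nc_counts,
        low_quality_counts=lq_counts,
    )


def band_contrast(
    cmap: CumulativeMap,
    gt: GroundTruth,
    grid: GridSpec | None = None,
    band_factor: float = 1.0,
    far_factor: float = 2.0,
) -> tuple[float, float, float]:
    """Mean cumulative magnitude inside the true vein band vs. far from it.

    Returns (ratio, inside_mean, outside_mean).  The band covers grid points
    within one vein width of the centerline (both flanks); the background is
    everything at least ``far_factor`` vein widths away.
    """
    grid = grid or cmap.grid
    inside = gt.vein_band_mask(grid, band_factor)
    outside = gt.far_mask(grid, far_factor)
    total = cmap.total
    finite = np.isfinite(total)
    inside &= finite
    outside &= finite
    if not inside.any() or not outside.any():
        raise InputError("vein band or background contains no grid points")
    inside_mean = float(total[inside].mean())
    outside_mean = float(total[outside].mean())
    ratio = inside_mean / outside_mean if outside_mean > 0 else np.inf
    return float(ratio), inside_mean, outside_mean


def run_scene_detection(
    scene: SceneParams | tuple[FrameSequence, GroundTruth],
    mode: str = "moving-row",
    subset: SubsetSpec | None = None,
    grid: GridSpec | None = None,
    search_radius: int = DEFAULT_SEARCH_RADIUS,
    window_half: int = 15,
    start_frame: int = 1,
    n_frames: int | None = None,
    spacing: int = 4,
    progress: bool = False,
) -> tuple[CumulativeMap, GroundTruth, GridSpec]:
    """Render (if needed) a synthetic scene and run the full pipeline on it."""
    if isinstance(scene, SceneParams):
        seq, gt = render_sequence(scene)
    else:
        seq, gt = scene
    subset = subset or SubsetSpec(21)
    search_radius = gt.required_search_radius(search_radius)
    if grid is None:
        grid = auto_grid(seq.height, seq.width, subset, search_radius, spacing)
    if n_frames is None:
        n_frames = min(DEFAULT_N_FRAMES, len(seq) - start_frame)
    filt = FilterParams(mode=mode, window_half=window_half)  # type: ignore[arg-type]
    result = run_detection(
        seq,
        grid,
        subset,
        filt,
        start_frame=start_frame,
        n_frames=n_frames,
        search_radius=search_radius,
        keep_fields=False,
        progress=progress,
    )
    return result.cumulative, gt, grid
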