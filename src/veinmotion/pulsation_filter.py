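"""Filters that strip gross limb motion from displacement fields.

The raw base-to-current displacement field is dominated by involuntary limb
motion, orders of magnitude larger than the sub-pixel skin pulsation above a
vein.  Two filters expose the pulsation residual:

* **fixed-region filter** — subtract the mean displacement vector of a
  vein-free reference rectangle from every point (removes a global rigid
  translation);
* **moving-average filter** — subtract from each point the local mean of its
  neighbors, either along the same grid row (``moving-row``, the default) or
  over a square neighborhood (``moving-square``).  The sliding window adapts
  to spatially non-uniform limb motion; its row-only variant is blind to
  veins running parallel to the x-axis, which the square variant fixes.

Both filters act on the (u, v) vector components; the pulsation magnitude
``sqrt(residual_u^2 + residual_v^2)`` is computed afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy import ndimage

from .dic_core import DisplacementField, GridSpec, _grid_from_points
from .errors import ConfigurationError, EmptyRegionError

__all__ = [
    "FilterParams",
    "PulsationMap",
    "grid_points_in_region",
    "subtract_region_mean",
    "subtract_moving_average",
    "apply_filter",
    "detectability_check",
    "DetectionVerdict",
]

FilterMode = Literal["fixed-region", "moving-row", "moving-square"]

DEFAULT_WINDOW_HALF = 15


@dataclass(frozen=True)
class FilterParams:
    """Configuration of the limb-motion filter.

    ``ref_region`` is an (x, y, width, height) rectangle in image pixels of
    an area without visible veins (used by the fixed-region mode);
    ``window_half`` is the number of neighboring grid points taken on each
    side for the moving average (default 15, i.e. 30 neighbors plus the
    center point).
    """

    mode: FilterMode = "moving-row"
    window_half: int = DEFAULT_WINDOW_HALF
    ref_region: tuple[int, int, int, int] | None = None
    include_center: bool = True

    def __post_init__(self) -> None:
        if self.window_half < 1:
            raise ConfigurationError("window_half must be >= 1")
        if self.mode == "fixed-region" and self.ref_region is None:
            raise ConfigurationError("fixed-region mode requires ref_region")


@dataclass
class PulsationMap:
    """Residual micro-shift field after limb-motion removal.

    ``magnitude`` is the elementwise Euclidean norm of the residual vector;
    NaN propagates at invalid points.
    """

    grid: GridSpec
    residual_u: np.ndarray
    residual_v: np.ndarray
    valid: np.ndarray
    ref_index: int = 0
    cur_index: int = 0

    def __post_init__(self) -> None:
        self.magnitude = np.hypot(self.residual_u, self.residual_v)
        self.magnitude[~self.valid] = np.nan

    def to_table(self) -> pd.DataFrame:
        X, Y = self.grid.meshgrid()
        return pd.DataFrame(
            {
                "point_x": X.ravel(),
                "point_y": Y.ravel(),
                "residual_u": self.residual_u.ravel(),
                "residual_v": self.residual_v.ravel(),
                "magnitude": self.magnitude.ravel(),
                "valid": self.valid.ravel(),
            }
        )

    def save_table(self, path: str | Path) -> None:
        self.to_table().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "PulsationMap":
        grid = _grid_from_points(table["point_x"].to_numpy(), table["point_y"].to_numpy())
        shape = (grid.n_rows, grid.n_cols)
        return cls(
            grid=grid,
            residual_u=table["residual_u"].to_numpy(np.float64).reshape(shape),
            residual_v=table["residual_v"].to_numpy(np.float64).reshape(shape),
            valid=table["valid"].to_numpy(bool).reshape(shape),
        )

    @classmethod
    def load_table(cls, path: str | Path) -> "PulsationMap":
        return cls.from_table(pd.read_csv(path, float_precision="round_trip"))


def grid_points_in_region(
    grid: GridSpec, region: tuple[float, float, float, float]
) -> np.ndarray:
    """Boolean (n_rows, n_cols) mask of grid points inside an (x, y, w, h) box."""
    x, y, w, h = region
    X, Y = grid.meshgrid()
    return (X >= x) & (X <= x + w - 1) & (Y >= y) & (Y <= y + h - 1)


def subtract_region_mean(
    field: DisplacementField, ref_region: tuple[float, float, float, float]
) -> PulsationMap:
    """Remove the mean displacement of a vein-free reference rectangle.

    The mean (u, v) over valid grid points inside ``ref_region`` is
    subtracted, as one vector, from every valid point of the field.

    Raises
    ------
    EmptyRegionError
        If the rectangle contains no valid grid point.
    """
    mask = grid_points_in_region(field.grid, ref_region) & field.valid
    if not mask.any():
        raise EmptyRegionError("reference region contains no valid grid points")
    mean_u = field.u[mask].mean()
    mean_v = field.v[mask].mean()
    res_u = field.u - mean_u
    res_v = field.v - mean_v
    res_u[~field.valid] = np.nan
    res_v[~field.valid] = np.nan
    return PulsationMap(
        grid=field.grid,
        residual_u=res_u,
        residual_v=res_v,
        valid=field.valid.copy(),
        ref_index=field.ref_index,
        cur_index=field.cur_index,
    )


def _window_mean(
    comp: np.ndarray,
    valid: np.ndarray,
    window_half: int,
    mode: str,
    include_center: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window mean of one component over valid neighbors.

    The window shrinks at grid boundaries (zero-padding of the *sums*, not of
    the data, so no values are fabricated).  Returns (mean, count_ok) where
    count_ok flags points whose window contains at least one usable value.
    """
    filled = np.where(valid, comp, 0.0)
    v = valid.astype(np.float64)
    size = 2 * window_half + 1
    if mode == "moving-row":
        sums = ndimage.correlate1d(filled, np.ones(size), axis=1, mode="constant", cval=0.0)
        counts = ndimage.correlate1d(v, np.ones(size), axis=1, mode="constant", cval=0.0)
    elif mode == "moving-square":
        sums = ndimage.correlate(filled, np.ones((size, size)), mode="constant", cval=0.0)
        counts = ndimage.correlate(v, np.ones((size, size)), mode="constant", cval=0.0)
    else:
        raise ConfigurationError(f"unknown moving-average mode {mode!r}")
    if not include_center:
        sums = sums - filled
        counts = counts - v
    counts = np.rint(counts)
    ok = counts > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(ok, sums / np.where(ok, counts, 1.0), np.nan)
    return mean, ok


def subtract_moving_average(
    field: DisplacementField,
    window_half: int = DEFAULT_WINDOW_HALF,
    mode: Literal["moving-row", "moving-square"] = "moving-row",
    include_center: bool = True,
) -> PulsationMap:
    """Remove the local mean displacement around each grid point.

    For each valid point the mean displacement vector of the grid points
    within ``window_half`` positions — along the same row (``moving-row``) or
    in the square neighborhood (``moving-square``) — is subtracted
    componentwise.  Invalid points are excluded from every mean; at row ends
    the window shrinks to the available neighbors.  With ``include_center``
    (the default) the point itself takes part in its own window mean.
    """
    if mode == "moving-row" and field.grid.n_cols < 2:
        raise ConfigurationError("moving-row filter needs at least 2 grid columns")
    if mode == "moving-square" and (field.grid.n_cols < 2 or field.grid.n_rows < 2):
        raise ConfigurationError("moving-square filter needs at least a 2x2 grid")
    mean_u, ok_u = _window_mean(field.u, field.valid, window_half, mode, include_center)
    mean_v, _ = _window_mean(field.v, field.valid, window_half, mode, include_center)
    valid = field.valid & ok_u
    res_u = np.where(valid, field.u - mean_u, np.nan)
    res_v = np.where(valid, field.v - mean_v, np.nan)
    return PulsationMap(
        grid=field.grid,
        residual_u=res_u,
        residual_v=res_v,
        valid=valid,
        ref_index=field.ref_index,
        cur_index=field.cur_index,
    )


def apply_filter(field: DisplacementField, params: FilterParams) -> PulsationMap:
    """Dispatch to the filter selected by ``params.mode``."""
    if params.mode == "fixed-region":
        assert params.ref_region is not None
        return subtract_region_mean(field, params.ref_region)
    return subtract_moving_average(
        field, params.window_half, params.mode, params.include_center
    )


@dataclass
class DetectionVerdict:
    """Outcome of a synthetic-scene detectability test."""

    detected: bool
    contrast_ratio: float
    inside_mean: float
    outside_mean: float
    mode: str


def detectability_check(
    scene,
    mode: Literal["moving-row", "moving-square"] = "moving-row",
    *,
    ratio_threshold: float = 2.0,
    **pipeline_kwargs,
) -> DetectionVerdict:
    """Whether the end-to-end pipeline reveals the scene's synthetic vein.

    Renders the scene, runs DIC + the selected moving-average filter +
    cumulative accumulation, and compares the mean cumulative magnitude in
    the band around the true vein against the mean far from it.  The vein
    counts as detected when the inside/outside ratio exceeds
    ``ratio_threshold`` (default 2).
    """
    from .pipeline import band_contrast, run_scene_detection

    cmap, gt, grid = run_scene_detection(scene, mode=mode, **pipeline_kwargs)
    ratio, inside, outside = band_contrast(cmap, gt, grid)
    return DetectionVerdict(
        detected=bool(ratio > ratio_threshold),
        contrast_ratio=float(ratio),
        inside_mean=float(inside),
        outside_mean=float(outside),
        mode=mode,
    )
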