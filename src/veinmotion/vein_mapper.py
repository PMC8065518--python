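"""Accumulation of pulsation maps over time and overlay rendering.

A single filtered map shows the skin pulsation at one instant; summing the
per-frame pulsation magnitudes over a block of frames (default 120, i.e. 4 s
at 30 FPS) makes the periodic vein signal persistent while incoherent noise
stays low.  Magnitudes — not signed vectors — are summed, because the
pulsation reverses sign across the cardiac cycle and signed sums would
cancel.

Because an out-of-plane bulge over a vein induces in-plane motion *away
from* the centerline, the accumulated magnitude is maximal at the vein
flanks and dips at the centerline: each vein renders as two parallel edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import matplotlib
import numpy as np
import pandas as pd
from scipy import ndimage

from .dic_core import GridSpec, _grid_from_points
from .errors import GridMismatchError, InputError
from .frameio import GrayFrame
from .pulsation_filter import PulsationMap

__all__ = [
    "CumulativeMap",
    "accumulate",
    "frames_to_seconds",
    "render_overlay",
    "save_figure",
    "two_edge_signature",
    "TwoEdgeResult",
]

DEFAULT_COLORMAP = "jet"  # blue (minimum shift) -> red (maximum shift)


@dataclass
class CumulativeMap:
    """Elementwise sum of pulsation magnitudes over ``n_frames`` frames."""

    grid: GridSpec
    total: np.ndarray
    n_frames: int

    def to_table(self) -> pd.DataFrame:
        X, Y = self.grid.meshgrid()
        return pd.DataFrame(
            {
                "point_x": X.ravel(),
                "point_y": Y.ravel(),
                "total": self.total.ravel(),
            }
        )

    def save_table(self, path: str | Path) -> None:
        self.to_table().to_csv(path, index=False, float_format="%.17g")

    def save_npz(self, path: str | Path) -> None:
        np.savez(
            path,
            total=self.total,
            n_frames=np.array([self.n_frames]),
            grid=np.array(
                [
                    self.grid.origin_x,
                    self.grid.origin_y,
                    self.grid.spacing,
                    self.grid.n_cols,
                    self.grid.n_rows,
                ]
            ),
        )

    @classmethod
    def load_npz(cls, path: str | Path) -> "CumulativeMap":
        with np.load(path) as data:
            g = data["grid"]
            grid = GridSpec(
                origin_x=int(g[0]),
                origin_y=int(g[1]),
                spacing=int(g[2]),
                n_cols=int(g[3]),
                n_rows=int(g[4]),
            )
            return cls(grid=grid, total=data["total"], n_frames=int(data["n_frames"][0]))

    @classmethod
    def from_table(cls, table: pd.DataFrame, n_frames: int = 1) -> "CumulativeMap":
        grid = _grid_from_points(table["point_x"].to_numpy(), table["point_y"].to_numpy())
        shape = (grid.n_rows, grid.n_cols)
        return cls(
            grid=grid,
            total=table["total"].to_numpy(np.float64).reshape(shape),
            n_frames=n_frames,
        )


def accumulate(maps: Sequence[PulsationMap]) -> CumulativeMap:
    """Sum pulsation magnitudes elementwise over an ordered list of maps.

    Invalid points contribute zero to the sum but the frame still counts.
    The operation is associative and permutation-invariant.
    """
    maps = list(maps)
    if not maps:
        raise InputError("cannot accumulate an empty list of maps")
    grid = maps[0].grid
    total = np.zeros((grid.n_rows, grid.n_cols))
    for m in maps:
        if m.grid != grid:
            raise GridMismatchError("pulsation maps use different grids")
        total += np.where(m.valid, m.magnitude, 0.0)
    return CumulativeMap(grid=grid, total=total, n_frames=len(maps))


def frames_to_seconds(n_frames: int, fps: float) -> float:
    """Duration in seconds of ``n_frames`` frames at ``fps`` frames/second."""
    if fps <= 0:
        raise InputError("fps must be positive")
    return n_frames / fps


def _normalize_map(total: np.ndarray) -> np.ndarray:
    finite = np.isfinite(total)
    if not finite.any():
        warnings.warn("cumulative map has no finite values; rendering mid-color")
        return np.full_like(total, 0.5)
    lo = total[finite].min()
    hi = total[finite].max()
    if hi - lo <= 0:
        warnings.warn("cumulative map is constant; rendering uniform mid-color")
        return np.full_like(total, 0.5)
    norm = (total - lo) / (hi - lo)
    return np.where(finite, norm, 0.0)


def render_overlay(
    base: GrayFrame,
    cmap: CumulativeMap,
    negative: bool = True,
    alpha: float = 0.6,
    upsample: Literal["nearest", "bilinear"] = "nearest",
    colormap: str = DEFAULT_COLORMAP,
) -> np.ndarray:
    """Blend the colored cumulative map over the (optionally negated) base.

    The map is normalized per call so its minimum maps to blue and its
    maximum to red, upsampled to image resolution (nearest-neighbor by
    default — no fabricated smoothness; bilinear optionally for display) and
    alpha-blended onto the grayscale base.  Returns an (H, W, 3) uint8 RGB
    array; the output is a pure function of its inputs.
    """
    grid = cmap.grid
    pix = base.pixels
    H, W = pix.shape
    if grid.xs[-1] > W - 1 or grid.ys[-1] > H - 1:
        raise GridMismatchError("cumulative-map grid extends beyond the base frame")
    gray = 255.0 - pix if negative else pix
    out = np.repeat(np.clip(gray, 0, 255)[:, :, None], 3, axis=2)

    norm = _normalize_map(cmap.total)
    s = grid.spacing
    if upsample == "bilinear" and min(norm.shape) > 1:
        up = ndimage.zoom(norm, s, order=1, grid_mode=False)
    else:
        up = np.repeat(np.repeat(norm, s, axis=0), s, axis=1)
    color = matplotlib.colormaps[colormap](np.clip(up, 0.0, 1.0))[:, :, :3] * 255.0

    # the block for grid point (x, y) covers [x - s//2, x + s - s//2)
    y0 = grid.origin_y - s // 2
    x0 = grid.origin_x - s // 2
    y1 = min(y0 + up.shape[0], H)
    x1 = min(x0 + up.shape[1], W)
    cy0, cx0 = max(y0, 0), max(x0, 0)
    block = color[cy0 - y0 : y1 - y0, cx0 - x0 : x1 - x0]
    region = out[cy0:y1, cx0:x1]
    out[cy0:y1, cx0:x1] = (1.0 - alpha) * region + alpha * block
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def save_figure(
    cmap: CumulativeMap,
    path: str | Path,
    base: GrayFrame | None = None,
    negative: bool = True,
    alpha: float = 0.6,
    colormap: str = DEFAULT_COLORMAP,
    title: str | None = None,
) -> None:
    """Write a colorbar-annotated figure of a cumulative map.

    With ``base`` given, the colored map is blended over the (optionally
    negated) frame as in :func:`render_overlay`; otherwise the map alone is
    shown at grid resolution.  The colorbar carries the map's physical
    units (summed shift magnitude, px).
    """
    import matplotlib.figure

    fig = matplotlib.figure.Figure(figsize=(6, 5), dpi=120)
    ax = fig.add_subplot(111)
    finite = cmap.total[np.isfinite(cmap.total)]
    vmin = float(finite.min()) if finite.size else 0.0
    vmax = float(finite.max()) if finite.size else 1.0
    if base is not None:
        ax.imshow(render_overlay(base, cmap, negative=negative, alpha=alpha,
                                 colormap=colormap))
    else:
        ax.imshow(cmap.total, cmap=colormap, vmin=vmin, vmax=vmax)
    sm = matplotlib.cm.ScalarMappable(
        norm=matplotlib.colors.Normalize(vmin=vmin, vmax=vmax),
        cmap=matplotlib.colormaps[colormap],
    )
    fig.colorbar(sm, ax=ax, label="cumulative shift magnitude (px)")
    ax.set_xlabel("x (px)")
    ax.set_ylabel("y (px)")
    if title:
        ax.set_title(title)
    fig.savefig(path, bbox_inches="tight")


@dataclass
class TwoEdgeResult:
    """Cross-vein profile analysis of a cumulative map."""

    positions: np.ndarray  # signed distance (px) of each profile sample
    profile: np.ndarray  # mean cumulative magnitude at each position
    left_peak: float
    right_peak: float
    center_value: float
    has_two_edges: bool


def two_edge_signature(
    cmap: CumulativeMap,
    centerline: float,
    axis: Literal["vertical", "horizontal"] = "vertical",
    max_distance: float | None = None,
    peak_ratio: float = 1.2,
) -> TwoEdgeResult:
    """Test for the two-edges-per-vein signature in a cumulative map.

    The map is averaged along the vein axis, giving a magnitude profile
    across the vein; the signature holds when both flanks carry a maximum
    exceeding ``peak_ratio`` times the value at the centerline (a relative
    minimum between two parallel ridges).  ``centerline`` is the image
    coordinate (x for a vertical vein, y for a horizontal one) of the true
    vein center; ``max_distance`` restricts the profile to that distance
    from the centerline.
    """
    grid = cmap.grid
    if axis == "vertical":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            profile = np.nanmean(cmap.total, axis=0)
        coords = grid.xs.astype(np.float64)
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            profile = np.nanmean(cmap.total, axis=1)
        coords = grid.ys.astype(np.float64)
    d = coords - centerline
    if max_distance is not None:
        keep = np.abs(d) <= max_distance
        d, profile = d[keep], profile[keep]
    if len(d) < 3:
        raise InputError("profile too short for a two-edge test")
    center_idx = int(np.argmin(np.abs(d)))
    center_value = float(profile[center_idx])
    left = profile[: center_idx]
    right = profile[center_idx + 1 :]
    left_peak = float(np.nanmax(left)) if left.size else np.nan
    right_peak = float(np.nanmax(right)) if right.size else np.nan
    floor = max(center_value, 1e-300)
    has = (
        np.isfinite(left_peak)
        and np.isfinite(right_peak)
        and left_peak > peak_ratio * floor
        and right_peak > peak_ratio * floor
    )
    return TwoEdgeResult(
        positions=d,
        profile=profile,
        left_peak=left_peak,
        right_peak=right_peak,
        center_value=center_value,
        has_two_edges=bool(has),
    )
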