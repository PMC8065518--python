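"""Subset-based digital image correlation (DIC).

For every point of a rectangular analysis grid, a square subset of the
reference (base) frame is located in the current frame in two stages:

1. *integer search* — exhaustive maximization of the normalized
   cross-correlation (NCC) coefficient

   .. math::

      C_{cc}(u, v) = \\frac{\\sum_S (f - f_m)(g - g_m)}
                          {\\sqrt{\\sum_S (f - f_m)^2 \\; \\sum_S (g - g_m)^2}}

   over integer shifts ``(u, v)`` inside a search window, where ``f`` and
   ``g`` are the reference and current subset intensities and ``f_m``,
   ``g_m`` their means;

2. *Newton-Raphson refinement* — Gauss-Newton minimization of the normalized
   least-squares criterion

   .. math::

      C_{LS}(u, v) = \\sum_S \\Big[\\frac{f - f_m}{\\|f - f_m\\|}
                     - \\frac{g(x+u, y+v) - g_m}{\\|g(x+u,y+v) - g_m\\|}\\Big]^2

   over continuous ``(u, v)``, with the current frame sampled by a bicubic
   B-spline interpolant whose coefficients are precomputed once per frame.
   At integer displacements the two criteria are algebraically linked by
   ``C_LS = 2 (1 - C_cc)``.

The subset shape function is zero-order (pure translation): only the
displacement components ``u`` (along x) and ``v`` (along y) are tracked.
Positive ``u`` means the subset content moved toward larger x in the current
frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage

from ._kernels import integer_search_points, refine_points
from .errors import (
    ConfigurationError,
    DegenerateSubsetError,
    GridMismatchError,
    OutOfBoundsError,
)
from .frameio import FrameSequence, GrayFrame

__all__ = [
    "GridSpec",
    "SubsetSpec",
    "Displacement",
    "DisplacementField",
    "Interpolator",
    "subset_mean",
    "extract_subset",
    "ncc",
    "least_squares_criterion",
    "integer_search",
    "refine_newton_raphson",
    "compute_field",
    "compute_fields",
    "ReferenceCache",
    "prepare_reference",
]

#: Relative (to the frame's dynamic range) intensity-std threshold below
#: which a subset is treated as textureless and its match as undefined.
DEGENERATE_REL_STD = 1e-8

#: Integer matches with peak NCC below this are flagged low-quality but
#: still refined.
DEFAULT_QUALITY_FLOOR = 0.5

DEFAULT_SEARCH_RADIUS = 10
DEFAULT_TOL = 1e-4
DEFAULT_MAX_ITER = 50


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSpec:
    """Rectangular lattice of analysis points.

    ``origin_x``/``origin_y`` locate the first grid point (top-left);
    adjacent points are ``spacing`` pixels apart along both axes.
    """

    origin_x: int
    origin_y: int
    spacing: int = 4
    n_cols: int = 130
    n_rows: int = 200

    def __post_init__(self) -> None:
        if self.spacing < 1:
            raise ConfigurationError("grid spacing must be >= 1")
        if self.n_cols < 1 or self.n_rows < 1:
            raise ConfigurationError("grid must have at least one row and column")

    @property
    def n_points(self) -> int:
        return self.n_cols * self.n_rows

    @property
    def xs(self) -> np.ndarray:
        """x (column) coordinates of the grid columns."""
        return self.origin_x + self.spacing * np.arange(self.n_cols)

    @property
    def ys(self) -> np.ndarray:
        """y (row) coordinates of the grid rows."""
        return self.origin_y + self.spacing * np.arange(self.n_rows)

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) coordinate arrays of shape (n_rows, n_cols)."""
        return np.meshgrid(self.xs, self.ys)

    def validate_for_frame(self, height: int, width: int, margin: int) -> None:
        """Raise if any grid point padded by ``margin`` leaves the frame."""
        if (
            self.origin_x - margin < 0
            or self.origin_y - margin < 0
            or self.xs[-1] + margin > width - 1
            or self.ys[-1] + margin > height - 1
        ):
            raise ConfigurationError(
                f"grid (+{margin} px margin) extends beyond the {width}x{height} frame"
            )


@dataclass(frozen=True)
class SubsetSpec:
    """Square correlation subset of odd side length ``size`` (pixels)."""

    size: int = 63

    def __post_init__(self) -> None:
        if self.size < 3 or self.size % 2 == 0:
            raise ConfigurationError("subset size must be odd and >= 3")

    @property
    def half(self) -> int:
        return (self.size - 1) // 2

    @property
    def n_points(self) -> int:
        """Number of data points in the subset (size squared)."""
        return self.size * self.size

    def offsets(self) -> tuple[np.ndarray, np.ndarray]:
        """Flattened (dx, dy) offsets of subset pixels from the center."""
        r = np.arange(-self.half, self.half + 1)
        dxx, dyy = np.meshgrid(r, r)
        return dxx.ravel().astype(np.float64), dyy.ravel().astype(np.float64)


@dataclass
class Displacement:
    """Displacement of one grid point, with match quality and flags."""

    u: float
    v: float
    quality: float = np.nan
    converged: bool = False
    valid: bool = True

    @classmethod
    def invalid(cls) -> "Displacement":
        return cls(u=np.nan, v=np.nan, quality=np.nan, converged=False, valid=False)


@dataclass
class DisplacementField:
    """Per-grid-point displacements between the base and one current frame.

    Arrays are shaped ``(n_rows, n_cols)``; ``u``/``v``/``quality`` hold NaN
    at invalid points.
    """

    grid: GridSpec
    u: np.ndarray
    v: np.ndarray
    quality: np.ndarray
    converged: np.ndarray
    valid: np.ndarray
    ref_index: int = 0
    cur_index: int = 0

    def __post_init__(self) -> None:
        shape = (self.grid.n_rows, self.grid.n_cols)
        for name in ("u", "v", "quality", "converged", "valid"):
            arr = getattr(self, name)
            if arr.shape != shape:
                raise GridMismatchError(
                    f"{name} has shape {arr.shape}, grid implies {shape}"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return (self.grid.n_rows, self.grid.n_cols)

    def to_table(self) -> pd.DataFrame:
        """Columnar representation (one row per grid point, row-major)."""
        X, Y = self.grid.meshgrid()
        return pd.DataFrame(
            {
                "point_x": X.ravel(),
                "point_y": Y.ravel(),
                "u": self.u.ravel(),
                "v": self.v.ravel(),
                "quality": self.quality.ravel(),
                "converged": self.converged.ravel(),
                "valid": self.valid.ravel(),
            }
        )

    def save_table(self, path: str | Path) -> None:
        self.to_table().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_table(
        cls, table: pd.DataFrame, ref_index: int = 0, cur_index: int = 0
    ) -> "DisplacementField":
        grid = _grid_from_points(table["point_x"].to_numpy(), table["point_y"].to_numpy())
        shape = (grid.n_rows, grid.n_cols)
        return cls(
            grid=grid,
            u=table["u"].to_numpy(dtype=np.float64).reshape(shape),
            v=table["v"].to_numpy(dtype=np.float64).reshape(shape),
            quality=table["quality"].to_numpy(dtype=np.float64).reshape(shape),
            converged=table["converged"].to_numpy(dtype=bool).reshape(shape),
            valid=table["valid"].to_numpy(dtype=bool).reshape(shape),
            ref_index=ref_index,
            cur_index=cur_index,
        )

    @classmethod
    def load_table(cls, path: str | Path) -> "DisplacementField":
        return cls.from_table(pd.read_csv(path, float_precision="round_trip"))

    def save_npz(self, path: str | Path) -> None:
        np.savez(
            path,
            u=self.u,
            v=self.v,
            quality=self.quality,
            converged=self.converged,
            valid=self.valid,
            grid=np.array(
                [
                    self.grid.origin_x,
                    self.grid.origin_y,
                    self.grid.spacing,
                    self.grid.n_cols,
                    self.grid.n_rows,
                ]
            ),
            indices=np.array([self.ref_index, self.cur_index]),
        )

    @classmethod
    def load_npz(cls, path: str | Path) -> "DisplacementField":
        with np.load(path) as data:
            g = data["grid"]
            grid = GridSpec(
                origin_x=int(g[0]),
                origin_y=int(g[1]),
                spacing=int(g[2]),
                n_cols=int(g[3]),
                n_rows=int(g[4]),
            )
            return cls(
                grid=grid,
                u=data["u"],
                v=data["v"],
                quality=data["quality"],
                converged=data["converged"].astype(bool),
                valid=data["valid"].astype(bool),
                ref_index=int(data["indices"][0]),
                cur_index=int(data["indices"][1]),
            )


def _grid_from_points(point_x: np.ndarray, point_y: np.ndarray) -> GridSpec:
    """Reconstruct a GridSpec from row-major point coordinate columns."""
    xs = np.unique(point_x)
    ys = np.unique(point_y)
    sx = int(np.diff(xs)[0]) if len(xs) > 1 else (int(np.diff(ys)[0]) if len(ys) > 1 else 1)
    return GridSpec(
        origin_x=int(xs[0]),
        origin_y=int(ys[0]),
        spacing=sx,
        n_cols=len(xs),
        n_rows=len(ys),
    )


# ---------------------------------------------------------------------------
# subset extraction and correlation coefficients
# ---------------------------------------------------------------------------

def _pixels(frame: GrayFrame | np.ndarray) -> np.ndarray:
    if isinstance(frame, GrayFrame):
        return frame.pixels
    return np.ascontiguousarray(frame, dtype=np.float64)


def extract_subset(
    frame: GrayFrame | np.ndarray, center: tuple[int, int], subset: SubsetSpec
) -> np.ndarray:
    """The ``size x size`` pixel block centered on ``center = (x, y)``."""
    pix = _pixels(frame)
    x, y = int(center[0]), int(center[1])
    h = subset.half
    if x - h < 0 or y - h < 0 or x + h >= pix.shape[1] or y + h >= pix.shape[0]:
        raise OutOfBoundsError(
            f"subset of size {subset.size} at ({x}, {y}) crosses the image border"
        )
    return pix[y - h : y + h + 1, x - h : x + h + 1]


def subset_mean(
    frame: GrayFrame | np.ndarray, center: tuple[int, int], subset: SubsetSpec
) -> float:
    """Arithmetic mean intensity of the subset centered on ``center``."""
    return float(extract_subset(frame, center, subset).mean())


def _dynamic_range(pix: np.ndarray) -> float:
    rng = float(pix.max() - pix.min())
    return rng if rng > 0 else 1.0


def _is_degenerate(block: np.ndarray, dyn_range: float) -> bool:
    return float(block.std()) < DEGENERATE_REL_STD * dyn_range


def ncc(
    ref: GrayFrame | np.ndarray,
    ref_center: tuple[int, int],
    cur: GrayFrame | np.ndarray,
    cur_center: tuple[int, int],
    subset: SubsetSpec,
) -> float:
    """Normalized cross-correlation coefficient between two subsets.

    Mean-subtracted and variance-normalized, hence bounded in [-1, 1] and
    invariant to affine intensity changes of either subset.

    Raises
    ------
    DegenerateSubsetError
        If either subset is (near-)flat, making the coefficient undefined.
    """
    f = extract_subset(ref, ref_center, subset)
    g = extract_subset(cur, cur_center, subset)
    if _is_degenerate(f, _dynamic_range(_pixels(ref))) or _is_degenerate(
        g, _dynamic_range(_pixels(cur))
    ):
        raise DegenerateSubsetError("flat subset: correlation undefined")
    f0 = f - f.mean()
    g0 = g - g.mean()
    denom = np.sqrt((f0 * f0).sum() * (g0 * g0).sum())
    return float((f0 * g0).sum() / denom)


# ---------------------------------------------------------------------------
# interpolation
# ---------------------------------------------------------------------------

class Interpolator:
    """Bicubic B-spline sampler for one frame, coefficients precomputed.

    The cubic spline reconstructs the frame exactly at integer coordinates;
    between pixels it provides the smooth intensity model that sub-pixel
    refinement optimizes over.
    """

    def __init__(self, frame: GrayFrame | np.ndarray):
        pix = _pixels(frame)
        self.shape = pix.shape
        self.coefficients = np.ascontiguousarray(
            ndimage.spline_filter(pix, order=3, mode="mirror")
        )

    def sample(self, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
        """Interpolated intensity at (xs, ys)."""
        out = ndimage.map_coordinates(
            self.coefficients,
            [np.ravel(ys), np.ravel(xs)],
            order=3,
            prefilter=False,
            mode="mirror",
        )
        return out.reshape(np.shape(xs))


# ---------------------------------------------------------------------------
# integer search
# ---------------------------------------------------------------------------

def _summed_area_tables(pix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(H+1, W+1) summed-area tables of the frame and its square."""
    H, W = pix.shape
    sat1 = np.zeros((H + 1, W + 1))
    sat2 = np.zeros((H + 1, W + 1))
    np.cumsum(np.cumsum(pix, axis=0), axis=1, out=sat1[1:, 1:])
    np.cumsum(np.cumsum(pix * pix, axis=0), axis=1, out=sat2[1:, 1:])
    return sat1, sat2


def _check_search_bounds(
    ref_pix: np.ndarray,
    cur_pix: np.ndarray,
    x: int,
    y: int,
    subset: SubsetSpec,
    search_radius: int,
) -> None:
    h = subset.half
    r = search_radius
    if x - h < 0 or y - h < 0 or x + h >= ref_pix.shape[1] or y + h >= ref_pix.shape[0]:
        raise OutOfBoundsError(f"reference subset at ({x}, {y}) crosses the border")
    if (
        x - h - r < 0
        or y - h - r < 0
        or x + h + r >= cur_pix.shape[1]
        or y + h + r >= cur_pix.shape[0]
    ):
        raise OutOfBoundsError(
            f"search window of radius {r} at ({x}, {y}) crosses the border"
        )


def integer_search(
    ref: GrayFrame | np.ndarray,
    cur: GrayFrame | np.ndarray,
    point: tuple[int, int],
    subset: SubsetSpec,
    search_radius: int = DEFAULT_SEARCH_RADIUS,
    quality_floor: float = DEFAULT_QUALITY_FLOOR,
) -> Displacement:
    """Pixel-accurate displacement of one grid point by exhaustive NCC search.

    The integer (u, v) maximizing the NCC over the (2r+1)^2-shift window is
    returned with the peak NCC as quality; ties break toward the smallest
    u^2+v^2, then smallest v, then smallest u (deterministic, favoring
    no-motion).  Matches below ``quality_floor`` are still returned —
    refinement may recover them — callers can use the quality to flag them.
    """
    ref_pix = _pixels(ref)
    cur_pix = _pixels(cur)
    x, y = int(point[0]), int(point[1])
    _check_search_bounds(ref_pix, cur_pix, x, y, subset, search_radius)
    sat1, sat2 = _summed_area_tables(cur_pix)
    u, v, q, valid = integer_search_points(
        ref_pix,
        cur_pix,
        sat1,
        sat2,
        np.array([x], np.int64),
        np.array([y], np.int64),
        subset.half,
        search_radius,
        DEGENERATE_REL_STD * _dynamic_range(ref_pix),
        DEGENERATE_REL_STD * _dynamic_range(cur_pix),
    )
    if not valid[0]:
        return Displacement.invalid()
    return Displacement(
        u=float(u[0]), v=float(v[0]), quality=float(q[0]), converged=False, valid=True
    )


# ---------------------------------------------------------------------------
# Newton-Raphson (Gauss-Newton) sub-pixel refinement
# ---------------------------------------------------------------------------

def _normalized_ref_subsets(
    ref_pix: np.ndarray, px: np.ndarray, py: np.ndarray, subset: SubsetSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Unit-normalized, mean-subtracted reference subsets, one row per point.

    Returns (f_hat, ok) where ok flags non-degenerate subsets.
    """
    h = subset.half
    windows = sliding_window_view(ref_pix, (subset.size, subset.size))
    iy = np.asarray(py, np.intp) - h
    ix = np.asarray(px, np.intp) - h
    f = windows[iy, ix].reshape(len(px), subset.n_points).astype(np.float64)
    f0 = f - f.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(f0, axis=1)
    dyn = _dynamic_range(ref_pix)
    ok = norms > DEGENERATE_REL_STD * dyn * subset.size
    norms = np.where(ok, norms, 1.0)
    return np.ascontiguousarray(f0 / norms[:, None]), ok


def least_squares_criterion(
    ref: GrayFrame | np.ndarray,
    cur: GrayFrame | np.ndarray,
    point: tuple[int, int],
    u: float,
    v: float,
    subset: SubsetSpec,
    interp: Interpolator | None = None,
) -> float:
    """Normalized least-squares matching criterion C_LS at displacement (u, v).

    The current subset is sampled at the interpolated positions
    ``(x + u, y + v)``.  At integer (u, v) this equals ``2 (1 - C_cc)`` up to
    interpolation round-off, which ties the refinement criterion back to the
    NCC coefficient.
    """
    ref_pix = _pixels(ref)
    cur_pix = _pixels(cur)
    if interp is None:
        interp = Interpolator(cur_pix)
    px = np.array([float(point[0])])
    py = np.array([float(point[1])])
    f_hat, ok = _normalized_ref_subsets(ref_pix, px, py, subset)
    if not ok[0]:
        raise DegenerateSubsetError("flat reference subset")
    dx, dy = subset.offsets()
    g = interp.sample(px[0] + dx + u, py[0] + dy + v)
    g0 = g - g.mean()
    g_norm = np.linalg.norm(g0)
    if g_norm < DEGENERATE_REL_STD * _dynamic_range(cur_pix) * subset.size:
        raise DegenerateSubsetError("flat current subset")
    d = f_hat[0] - g0 / g_norm
    return float((d * d).sum())


def refine_newton_raphson(
    ref: GrayFrame | np.ndarray,
    cur: GrayFrame | np.ndarray,
    point: tuple[int, int],
    init: Displacement,
    subset: SubsetSpec,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    search_radius: int = DEFAULT_SEARCH_RADIUS,
    interp: Interpolator | None = None,
) -> Displacement:
    """Sub-pixel refinement of one point starting from an integer estimate.

    Gauss-Newton iterations on C_LS with step damping; ``converged`` is set
    when the update norm drops below ``tol`` within ``max_iter`` iterations.
    On divergence outside the search window the last iterate is returned
    with ``converged=False``.
    """
    if not init.valid:
        return Displacement.invalid()
    ref_pix = _pixels(ref)
    cur_pix = _pixels(cur)
    if interp is None:
        interp = Interpolator(cur_pix)
    px = np.array([float(point[0])])
    py = np.array([float(point[1])])
    f_hat, ok = _normalized_ref_subsets(ref_pix, px, py, subset)
    if not ok[0]:
        return Displacement.invalid()
    u, v, q, conv, valid = refine_points(
        interp.coefficients,
        f_hat,
        px,
        py,
        np.array([float(init.u)]),
        np.array([float(init.v)]),
        subset.half,
        tol,
        max_iter,
        float(search_radius + 2),
        DEGENERATE_REL_STD * _dynamic_range(cur_pix) * subset.size,
    )
    if not valid[0]:
        return Displacement.invalid()
    return Displacement(
        u=float(u[0]), v=float(v[0]), quality=float(q[0]), converged=bool(conv[0])
    )


# ---------------------------------------------------------------------------
# full-field computation
# ---------------------------------------------------------------------------

@dataclass
class ReferenceCache:
    """Precomputed normalized reference subsets for one grid + subset.

    The reference frame never changes within a sequence, so these can be
    shared across all current frames.
    """

    grid: GridSpec
    subset: SubsetSpec
    px: np.ndarray
    py: np.ndarray
    f_hat: np.ndarray
    ok: np.ndarray
    ref_dyn: float


def prepare_reference(
    ref: GrayFrame | np.ndarray, grid: GridSpec, subset: SubsetSpec
) -> ReferenceCache:
    """Extract and normalize every grid point's reference subset once."""
    ref_pix = np.ascontiguousarray(_pixels(ref))
    X, Y = grid.meshgrid()
    px = X.ravel().astype(np.float64)
    py = Y.ravel().astype(np.float64)
    f_hat, ok = _normalized_ref_subsets(ref_pix, px, py, subset)
    return ReferenceCache(
        grid=grid,
        subset=subset,
        px=px,
        py=py,
        f_hat=f_hat,
        ok=ok,
        ref_dyn=_dynamic_range(ref_pix),
    )


def compute_field(
    seq: FrameSequence,
    cur_index: int,
    grid: GridSpec,
    subset: SubsetSpec = SubsetSpec(),
    search_radius: int = DEFAULT_SEARCH_RADIUS,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    quality_floor: float = DEFAULT_QUALITY_FLOOR,
    interp: Interpolator | None = None,
    ref_cache: ReferenceCache | None = None,
) -> DisplacementField:
    """Displacement field between the base frame and frame ``cur_index``.

    Every grid point goes through integer NCC search followed by
    Newton-Raphson refinement; degenerate points are flagged invalid and
    never interpolated.  Pass a precomputed ``interp`` for the current frame
    and/or a ``ref_cache`` (from :func:`prepare_reference`) to amortize the
    per-frame setup across calls.
    """
    if cur_index == seq.base_index:
        raise ConfigurationError("cur_index must differ from the base frame index")
    ref = seq.frames[seq.base_index]
    cur = seq.frames[cur_index]
    margin = subset.half + search_radius
    grid.validate_for_frame(seq.height, seq.width, margin)

    ref_pix = np.ascontiguousarray(ref.pixels)
    cur_pix = np.ascontiguousarray(cur.pixels)
    if ref_cache is None:
        ref_cache = prepare_reference(ref_pix, grid, subset)
    elif ref_cache.grid != grid or ref_cache.subset != subset:
        raise ConfigurationError("ref_cache was built for a different grid or subset")
    ref_dyn = ref_cache.ref_dyn
    cur_dyn = _dynamic_range(cur_pix)
    if interp is None:
        interp = Interpolator(cur_pix)

    px = ref_cache.px
    py = ref_cache.py
    n_pts = grid.n_points

    sat1, sat2 = _summed_area_tables(cur_pix)
    u0, v0, q0, ok0 = integer_search_points(
        ref_pix,
        cur_pix,
        sat1,
        sat2,
        px.astype(np.int64),
        py.astype(np.int64),
        subset.half,
        search_radius,
        DEGENERATE_REL_STD * ref_dyn,
        DEGENERATE_REL_STD * cur_dyn,
    )

    u = np.full(n_pts, np.nan)
    v = np.full(n_pts, np.nan)
    quality = np.full(n_pts, np.nan)
    converged = np.zeros(n_pts, dtype=bool)
    valid = ok0.astype(bool)

    valid &= ref_cache.ok
    idx = np.flatnonzero(valid)
    if idx.size:
        keep = idx
        if keep.size:
            ur, vr, qr, cr, vr_ok = refine_points(
                interp.coefficients,
                np.ascontiguousarray(ref_cache.f_hat[keep]),
                px[keep],
                py[keep],
                u0[keep].astype(np.float64),
                v0[keep].astype(np.float64),
                subset.half,
                tol,
                max_iter,
                float(search_radius + 2),
                DEGENERATE_REL_STD * cur_dyn * subset.size,
            )
            u[keep] = ur
            v[keep] = vr
            quality[keep] = qr
            converged[keep] = cr
            valid[keep] = vr_ok

    shape = (grid.n_rows, grid.n_cols)
    return DisplacementField(
        grid=grid,
        u=u.reshape(shape),
        v=v.reshape(shape),
        quality=quality.reshape(shape),
        converged=converged.reshape(shape),
        valid=valid.reshape(shape),
        ref_index=seq.base_index,
        cur_index=cur_index,
    )


def compute_fields(
    seq: FrameSequence,
    frame_indices: Iterable[int],
    grid: GridSpec,
    subset: SubsetSpec = SubsetSpec(),
    search_radius: int = DEFAULT_SEARCH_RADIUS,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    quality_floor: float = DEFAULT_QUALITY_FLOOR,
    progress: bool = False,
) -> list[DisplacementField]:
    """Displacement fields for several current frames against one base frame."""
    fields = []
    ref_cache = prepare_reference(seq.frames[seq.base_index], grid, subset)
    for k in frame_indices:
        fields.append(
            compute_field(
                seq,
                k,
                grid,
                subset,
                search_radius,
                tol=tol,
                max_iter=max_iter,
                quality_floor=quality_floor,
                ref_cache=ref_cache,
            )
        )
        if progress:
            f = fields[-1]
            n_bad = int((~f.valid).sum())
            n_nc = int((f.valid & ~f.converged).sum())
            print(f"frame {k}: {n_bad} invalid, {n_nc} non-converged points")
    return fields
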