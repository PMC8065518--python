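"""Synthetic speckle scenes with known tremor and vein pulsation.

The generator emulates the two motion components of a hand-held recording of
skin:

* **tremor** — a global rigid translation per frame, modeled as a smooth
  (low-pass filtered) random walk whose per-component standard deviation is
  ``tremor_amplitude``.  In the stressing regime this is orders of magnitude
  larger than the pulsation.
* **vein pulsation** — a localized, temporally periodic in-plane
  displacement directed away from the vein centerline.  An out-of-plane
  bulge of the skin over a pressurized vein tilts the surface, so a camera
  sees in-plane motion that vanishes at the bulge apex (the centerline) and
  peaks at the flanks.  The flank profile is a derivative-of-Gaussian in the
  signed distance ``d`` from the centerline,

  ``D(d) = (d/s) * exp((1 - (d/s)^2) / 2)``,  ``s = vein_width / 2``,

  normalized so ``|D| = 1`` exactly at the vein walls ``|d| = s``, and the
  temporal factor is ``sin(2 pi f t)``.

Only the induced in-plane displacement is simulated — no shading change —
which is precisely the quantity subset correlation measures.  Every frame's
exact displacement field is retained as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from scipy import ndimage

from .dic_core import GridSpec
from .errors import DomainError, MarginError
from .frameio import FrameSequence, GrayFrame

__all__ = [
    "SceneParams",
    "GroundTruth",
    "make_speckle",
    "pulsation_displacement",
    "tremor_trajectory",
    "render_sequence",
    "rotate_params",
]


@dataclass(frozen=True)
class SceneParams:
    """Full parametric description of a simulated sequence.

    Defaults describe the standard bench scene: 30 FPS, a tremor of 3 px
    standard deviation, a 0.3 px pulsation at 1.2 Hz (72 beats/min) over a
    24 px-wide vertical vein.
    """

    width: int = 300
    height: int = 380
    n_frames: int = 121
    fps: float = 30.0
    speckle_density: float = 0.05
    speckle_radius: float = 2.0
    speckle_seed: int = 0
    tremor_amplitude: float = 3.0
    tremor_seed: int = 1
    vein_axis: Literal["vertical", "horizontal"] | float = "vertical"
    vein_center: float = 0.0  # offset (px) of the centerline from frame center
    vein_width: float = 40.0
    pulse_amplitude: float = 0.3
    pulse_frequency: float = 1.2
    noise_std: float = 2.0  # sensor noise std, 0-255 intensity units
    noise_seed: int = 2
    margin: float = 24.0  # max |displacement| tolerated before a margin error

    def centerline(self) -> float:
        """Image coordinate of the vein centerline (x if vertical, y if horizontal)."""
        if self.vein_axis == "vertical":
            return self.width / 2.0 + self.vein_center
        if self.vein_axis == "horizontal":
            return self.height / 2.0 + self.vein_center
        raise DomainError("centerline() is defined only for axis-aligned veins")


def rotate_params(params: SceneParams) -> SceneParams:
    """The same scene rotated by 90 degrees (vertical vein <-> horizontal)."""
    if params.vein_axis == "vertical":
        new_axis: Literal["vertical", "horizontal"] = "horizontal"
    elif params.vein_axis == "horizontal":
        new_axis = "vertical"
    else:
        raise DomainError("rotate_params supports axis-aligned veins only")
    return replace(
        params, width=params.height, height=params.width, vein_axis=new_axis
    )


def make_speckle(
    width: int,
    height: int,
    density: float = 0.01,
    radius: float = 2.0,
    seed: int = 0,
) -> GrayFrame:
    """Seeded random speckle texture: smooth blobs on a mid-gray background.

    ``density`` is the expected number of blob centers per square pixel;
    ``radius`` the Gaussian blob scale in pixels.  The field is normalized to
    mean 128, standard deviation 40, clipped to [0, 255], which leaves every
    subset of practical size well above the degeneracy threshold.
    """
    if density <= 0:
        raise DomainError("speckle density must be positive")
    rng = np.random.default_rng(seed)
    n_spots = max(1, round(density * width * height))
    img = np.zeros((height, width))
    ys = rng.integers(0, height, n_spots)
    xs = rng.integers(0, width, n_spots)
    amps = rng.uniform(-1.0, 1.0, n_spots)
    np.add.at(img, (ys, xs), amps)
    img = ndimage.gaussian_filter(img, sigma=radius, mode="wrap")
    std = img.std()
    if std < 1e-12:
        import warnings

        warnings.warn("speckle parameters yield a flat texture")
        std = 1.0
    img = 128.0 + (img - img.mean()) * (40.0 / std)
    return GrayFrame(np.clip(img, 0.0, 255.0), index=0)


def _flank_profile(d: np.ndarray, s: float) -> np.ndarray:
    z = d / s
    return z * np.exp(0.5 * (1.0 - z * z))


def pulsation_displacement(
    x: np.ndarray | float,
    y: np.ndarray | float,
    t: float,
    params: SceneParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth pulsation displacement (u, v) at position(s) and time t (s).

    The displacement is normal to the vein axis, odd and compactly supported
    in the signed distance from the centerline, and sinusoidal in time; its
    extrema sit exactly at the vein walls (half a vein width from the
    centerline).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    s = params.vein_width / 2.0
    amp = params.pulse_amplitude * np.sin(2.0 * np.pi * params.pulse_frequency * t)
    if params.vein_axis == "vertical":
        d = x - params.centerline()
        u = amp * _flank_profile(d, s)
        v = np.zeros_like(u)
    elif params.vein_axis == "horizontal":
        d = y - params.centerline()
        v = amp * _flank_profile(d, s)
        u = np.zeros_like(v)
    else:
        theta = np.deg2rad(float(params.vein_axis))
        nx, ny = -np.sin(theta), np.cos(theta)
        cx = params.width / 2.0 + params.vein_center * nx
        cy = params.height / 2.0 + params.vein_center * ny
        d = (x - cx) * nx + (y - cy) * ny
        mag = amp * _flank_profile(d, s)
        u, v = mag * nx, mag * ny
    return u, v


def tremor_trajectory(params: SceneParams) -> np.ndarray:
    """Per-frame global tremor vectors, shape (n_frames, 2) as (u, v).

    Smooth random walk: white noise low-pass filtered along time (Gaussian,
    sigma = 4 frames) and rescaled so each component has standard deviation
    ``tremor_amplitude``.  Frame 0 (the base frame) is pinned at zero.
    """
    rng = np.random.default_rng(params.tremor_seed)
    raw = rng.standard_normal((params.n_frames, 2))
    smooth = ndimage.gaussian_filter1d(raw, sigma=4.0, axis=0, mode="nearest")
    if params.tremor_amplitude == 0:
        return np.zeros((params.n_frames, 2))
    smooth = smooth - smooth[0]  # base frame is displacement-free by definition
    std = smooth.std(axis=0)
    std = np.where(std > 1e-12, std, 1.0)
    return smooth * (params.tremor_amplitude / std)


@dataclass
class GroundTruth:
    """Exact displacement decomposition of a rendered scene.

    Total displacement at any pixel and frame is ``tremor[frame] +
    pulsation(x, y, t)`` by construction.
    """

    params: SceneParams
    tremor: np.ndarray  # (n_frames, 2), (u, v) per frame

    def required_search_radius(self, minimum: int = 10) -> int:
        """Smallest integer search radius covering the global motion.

        DIC's integer search must reach the largest base-to-frame shift;
        one extra pixel of slack absorbs the pulsation component.
        """
        return max(minimum, int(np.ceil(np.abs(self.tremor).max())) + 1)

    def displacement_at(
        self, x: np.ndarray | float, y: np.ndarray | float, frame_index: int
    ) -> tuple[np.ndarray, np.ndarray]:
        """Exact total (u, v) displacement of frame ``frame_index`` vs. base."""
        t = frame_index / self.params.fps
        pu, pv = pulsation_displacement(x, y, t, self.params)
        return pu + self.tremor[frame_index, 0], pv + self.tremor[frame_index, 1]

    def dense_field(self, frame_index: int) -> tuple[np.ndarray, np.ndarray]:
        """Dense per-pixel (u, v) arrays for one frame."""
        yy, xx = np.mgrid[0 : self.params.height, 0 : self.params.width]
        return self.displacement_at(xx, yy, frame_index)

    def signed_distance(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Signed distance (px) from the vein centerline."""
        p = self.params
        if p.vein_axis == "vertical":
            return np.asarray(x, np.float64) - p.centerline()
        if p.vein_axis == "horizontal":
            return np.asarray(y, np.float64) - p.centerline()
        theta = np.deg2rad(float(p.vein_axis))
        nx, ny = -np.sin(theta), np.cos(theta)
        cx = p.width / 2.0 + p.vein_center * nx
        cy = p.height / 2.0 + p.vein_center * ny
        return (np.asarray(x, np.float64) - cx) * nx + (np.asarray(y, np.float64) - cy) * ny

    def vein_band_mask(self, grid: GridSpec, band_factor: float = 1.0) -> np.ndarray:
        """Grid-point mask of the flank band: |d| <= band_factor * vein_width."""
        X, Y = grid.meshgrid()
        return np.abs(self.signed_distance(X, Y)) <= band_factor * self.params.vein_width

    def far_mask(self, grid: GridSpec, far_factor: float = 2.0) -> np.ndarray:
        """Grid-point mask of the vein-free background: |d| >= far_factor * width."""
        X, Y = grid.meshgrid()
        return np.abs(self.signed_distance(X, Y)) >= far_factor * self.params.vein_width


def render_sequence(params: SceneParams) -> tuple[FrameSequence, GroundTruth]:
    """Render a full scene and its exact ground truth.

    The base speckle frame is warped per frame by the total displacement
    using the inverse-mapping convention — the current frame samples the base
    at ``x - u(x)`` — with quintic-spline interpolation, so recovered DIC
    displacements carry the same sign as the ground truth.  Pure integer
    global shifts bypass interpolation entirely (a lossless array roll).

    Independent Gaussian sensor noise of standard deviation ``noise_std``
    is added to every frame (the base frame included), emulating the shot
    and read noise of a phone camera; set ``noise_std=0`` for a noiseless
    scene that isolates the warping itself.

    Raises
    ------
    MarginError
        If any frame's displacement magnitude exceeds ``params.margin``.
    """
    base = make_speckle(
        params.width,
        params.height,
        params.speckle_density,
        params.speckle_radius,
        params.speckle_seed,
    )
    tremor = tremor_trajectory(params)
    gt = GroundTruth(params=params, tremor=tremor)

    max_disp = np.abs(tremor).max() + abs(params.pulse_amplitude)
    if max_disp > params.margin:
        raise MarginError(
            f"peak displacement {max_disp:.2f} px exceeds the {params.margin:.2f} px margin"
        )

    coef = ndimage.spline_filter(base.pixels, order=5, mode="mirror")
    yy, xx = np.mgrid[0 : params.height, 0 : params.width].astype(np.float64)
    noise_rng = np.random.default_rng(params.noise_seed)
    frames = [GrayFrame(base.pixels.copy(), index=0)]
    for k in range(1, params.n_frames):
        t = k / params.fps
        pu, pv = pulsation_displacement(xx, yy, t, params)
        du = pu + tremor[k, 0]
        dv = pv + tremor[k, 1]
        pulse_free = params.pulse_amplitude == 0 or np.all(pu == 0) and np.all(pv == 0)
        tu, tv = tremor[k]
        if pulse_free and tu == round(tu) and tv == round(tv):
            pix = np.roll(base.pixels, (int(round(tv)), int(round(tu))), axis=(0, 1))
        else:
            pix = ndimage.map_coordinates(
                coef, [yy - dv, xx - du], order=5, prefilter=False, mode="mirror"
            )
            pix = np.clip(pix, 0.0, 255.0)
        frames.append(GrayFrame(pix, index=k))
    if params.noise_std > 0:
        for frame in frames:
            noisy = frame.pixels + noise_rng.normal(
                0.0, params.noise_std, frame.pixels.shape
            )
            frame.pixels = np.clip(noisy, 0.0, 255.0)
    seq = FrameSequence(frames=frames, fps=params.fps, base_index=0)
    return seq, gt
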