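# Methods

## Problem and approach

A vein under the skin pressurizes and relaxes with the cardiac cycle.  The
overlying skin bulges out of plane, and a camera looking at the skin sees the
*in-plane* component of that deformation: points on the bulge's flanks slide
away from the vein centerline as pressure peaks and return as it falls, while
the apex above the centerline barely moves in plane.  The displacements are
sub-pixel (tens of micrometres at a typical ~52 µm/px imaging scale), and
they ride on involuntary limb motion that is orders of magnitude larger.

`veinmotion` recovers this signature in three stages:

1. **Subset digital image correlation (DIC).**  The first frame of the video
   is the base frame.  For every point of a rectangular analysis grid, the
   square intensity subset around it is located in each subsequent frame —
   first to integer precision by exhaustive maximization of the normalized
   cross-correlation (NCC) coefficient over a search window, then to
   sub-pixel precision by Gauss-Newton ("Newton-Raphson") minimization of the
   normalized least-squares criterion with bicubic B-spline intensity
   interpolation.  The subset shape function is zero order: each subset is
   tracked as a pure translation (u, v).
2. **Motion filtering.**  The displacement field is dominated by limb
   motion.  Either the mean displacement of a designated vein-free rectangle
   is subtracted from every point (fixed-region filter), or each point's
   local mean over a sliding window of neighboring grid points — along its
   grid row, or over a square neighborhood — is subtracted (moving-average
   filter).  Filtering acts on the vector components; the residual magnitude
   is taken afterwards.
3. **Accumulation.**  Per-frame residual magnitudes are summed over a block
   of frames (default 120, i.e. 4 s at 30 FPS).  The pulsation reverses sign
   across the cycle, so signed sums would cancel; summed magnitudes make the
   periodic signal persistent.  Because the in-plane motion vanishes at the
   centerline and peaks at the flanks, each vein appears as **two parallel
   ridges** flanking a dip — the two-edge signature.

## Correlation criteria

With `f`, `g` the reference and current subset intensities and `f_m`, `g_m`
their means over the subset `S`:

```
C_cc(u, v) = Σ_S (f − f_m)(g − g_m) / sqrt( Σ_S (f − f_m)² · Σ_S (g − g_m)² )
```

maximized over integer (u, v), and

```
C_LS(u, v) = Σ_S [ (f − f_m)/‖f − f_m‖ − (g(x+u, y+v) − g_m)/‖g(x+u,y+v) − g_m‖ ]²
```

minimized over continuous (u, v).  The two are algebraically linked at
integer displacements by `C_LS = 2 (1 − C_cc)`, which the test suite verifies
numerically; both are invariant to affine intensity changes of either
subset.  The Gauss-Newton iteration uses the analytic gradient of the cubic
B-spline interpolant, a projection-corrected Jacobian of the normalized
residual, and step halving (up to four times) whenever a step would increase
`C_LS` or leave the frame.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| grid spacing | 4 px | distance between analysis points; the reference acquisition grid is 130 × 200 points (26,000 total) |
| subset size | 63 px | matching template side; must be odd so subsets are pixel-centered; large enough to contain several speckle features |
| search radius | 10 px | integer-search half-window; must exceed the largest base-to-frame global shift — on synthetic scenes it is sized from the known peak tremor |
| NR tolerance | 1e-4 px | convergence threshold on the Gauss-Newton update norm |
| NR max iterations | 50 | iteration cap; non-converged points are flagged, not discarded |
| quality floor | 0.5 NCC | integer matches below this are flagged low-quality but still refined |
| degenerate epsilon | 1e-8 × dynamic range | subset intensity std below this marks the point invalid (flat texture) |
| filter window half-width | 15 points | 15 neighbors per side; the 31-term mean includes the center point (configurable) |
| reference region | 100 × 300 px | vein-free rectangle for the fixed-region filter; taken from configuration, never auto-selected |
| accumulation block | 120 frames | 4 s at 30 FPS |

Tie-breaking in the integer search is deterministic: among peak-scoring
shifts (within 1e-9, absorbing float round-off between genuinely equal
candidates) the smallest u²+v² wins, then the smallest v, then the smallest
u — favoring no-motion.  Coordinates are 0-based with x along columns;
positive u means the subset content moved toward larger x.

## Synthetic scenes and what they do (not) show

No public dataset of skin-micromotion video exists, so the package ships a
generator whose scenes exercise exactly the mechanism the method measures:

* a seeded **speckle texture** (Gaussian blobs, normalized to mean 128 and
  std 40 on the 0–255 scale) standing in for skin texture.  The blob
  density must be matched to the subset size: scenes default to
  0.05 blobs/px² so that every 21 px subset of the bench carries texture
  (no chance blob-free holes, whose near-flat subsets would match at random
  under sensor noise); the generator's own default of 0.01 blobs/px²
  suffices for 63 px subsets;
* a **tremor** component: a global rigid translation per frame, modeled as
  Gaussian white noise low-pass filtered along time (σ = 4 frames), pinned
  to zero at the base frame and scaled so the per-component standard
  deviation of the base-to-frame displacement equals `tremor_amplitude`
  (default 3 px — orders of magnitude above the pulsation, the stressing
  regime);
* a **vein pulsation** component: displacement normal to the vein axis,
  `A · sin(2π f t) · D(d)` with `D(d) = (d/s)·exp((1−(d/s)²)/2)`,
  `s = vein_width/2`, an odd, compactly supported derivative-of-Gaussian
  flank profile whose extrema sit exactly at the vein walls.  Defaults:
  amplitude 0.3 px (≈16 µm at 52 µm/px — a declared fixture choice, not a
  physiological claim), frequency 1.2 Hz (72 beats/min), vein width 40 px
  (≈2 mm at 52 µm/px, a typical forearm vein);
* seeded Gaussian **sensor noise**, std 2.0 intensity levels, on every
  frame including the base — the shot/read noise floor of a phone camera.
  Without it the synthetic background is quieter than any real video by an
  order of magnitude, and residual subset-model error alone would register
  as "detection" in regimes where the method is in fact blind.

Frames are warped from the base by quintic-spline inverse mapping (current
frame samples the base at `x − u(x)`; exact for the global component, and
accurate to O(u·∂u/∂x) ≈ 1e-2 sub-pixel for the tiny spatially varying
component); pure integer shifts bypass interpolation via a lossless roll.
Out-of-plane geometry is *not* rendered photometrically (no shading change):
only its induced in-plane displacement is simulated, which is precisely the
quantity DIC measures.

What passing the synthetic suite shows: the pipeline recovers known global
and localized sub-pixel motion to the stated accuracy, reproduces the
two-edge signature, and reproduces the row-filter's directional blind spot.
What it does not show: performance on real skin (specularity, curvature,
non-rigid limb motion, lighting drift), vein depth sensitivity, or clinical
detection rates.

## Bench problem sizes

End-to-end scenes run at a reduced scale chosen as the package's standard
bench: 300 × 380 px frames, a 60 × 80-point grid at 4 px spacing, 21 px
subsets, 120 accumulated frames — the same structure as the full
1920 × 1080 / 130 × 200-grid / 63 px-subset reference setup at roughly a
fifth of the linear problem size.  Sub-pixel accuracy is benchmarked on
band-limited (Fourier) translations of a 160 × 160 speckle frame over the
full ±0.1 … ±0.9 px shift grid.

Detection is scored by **band contrast**: the mean cumulative magnitude over
grid points within one vein width of the true centerline divided by the mean
over points at least two vein widths away; a ratio above 2 counts as
detected.  The directional limitation is asserted by rotating the same scene
90°: the row-window filter subtracts a horizontal vein's own shift (every
point in a row sits at the same distance from the vein), so the contrast
collapses, while a square window restores detection.

## Numerical and design choices

* **Interpolation**: cubic B-spline with precomputed per-frame coefficients
  (`mirror` boundary), exact at integer coordinates; the scene generator
  uses quintic splines so fixture warping is more band-limited than the
  measurement model that analyses it.
* **Criterion form**: the NCC denominator uses the square root of the
  product of the two subset variances (the self-correlation-equals-one
  normalization), and the least-squares criterion samples the *current*
  frame at the displaced position — the form under which the criterion
  actually depends on (u, v).
* **Window-edge handling** in the moving-average filter: the window shrinks
  at grid boundaries (sums and counts zero-padded) — padding data would
  fabricate displacements.  Invalid points are excluded from every mean and
  never imputed.
* **Center point** of the moving window is included (a 31-term mean for
  window half-width 15); the invariance properties hold either way and the
  choice is configurable.
* **Accumulation** sums magnitudes, not vectors (sign reversal across the
  cardiac cycle), and map coloring is normalized per map (minimum → blue,
  maximum → red).
* **Grid-map upsampling** for overlays is nearest-neighbor by default; no
  smoothness is fabricated for display.
* **Degenerate inputs**: flat subsets raise (pairwise API) or are flagged
  invalid (field API); a constant cumulative map renders uniform mid-color
  with a warning rather than failing.

## Known limitations

* Zero-order subsets average any displacement gradient across the subset;
  veins much narrower than the subset are low-pass filtered and their
  flank profile is smoothed (first-order shape functions are out of scope).
* The fixed-region filter removes only a global translation; rotation and
  perspective components of limb motion are handled (approximately) by the
  moving-average filter, not modeled explicitly.
* The row-window filter cannot see veins parallel to the image x-axis; use
  the square window when vein orientation is unknown.
* Frame-to-frame (incremental) referencing, strain computation, vein
  tracing/vectorization, and flow-direction inference are out of scope.
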