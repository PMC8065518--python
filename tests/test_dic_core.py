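import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from veinmotion import (
    ConfigurationError,
    DegenerateSubsetError,
    Displacement,
    DisplacementField,
    FrameSequence,
    GrayFrame,
    GridSpec,
    Interpolator,
    OutOfBoundsError,
    SubsetSpec,
    compute_field,
    integer_search,
    least_squares_criterion,
    make_speckle,
    ncc,
    refine_newton_raphson,
    subset_mean,
)

from conftest import fourier_translate


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def ncc_oracle(f: np.ndarray, g: np.ndarray) -> float:
    """Direct elementwise evaluation of the correlation coefficient."""
    n = f.size
    fm = sum(f.ravel()) / n
    gm = sum(g.ravel()) / n
    num = den_f = den_g = 0.0
    for a, b in zip(f.ravel(), g.ravel()):
        num += (a - fm) * (b - gm)
        den_f += (a - fm) ** 2
        den_g += (b - gm) ** 2
    return num / np.sqrt(den_f * den_g)


def exhaustive_search_oracle(ref, cur, x, y, half, radius):
    """Double-loop exhaustive NCC maximization with the no-motion tie-break."""
    best = None
    for dv in range(-radius, radius + 1):
        for du in range(-radius, radius + 1):
            f = ref[y - half : y + half + 1, x - half : x + half + 1]
            g = cur[y + dv - half : y + dv + half + 1, x + du - half : x + du + half + 1]
            if g.std() < 1e-12:
                continue
            score = ncc_oracle(f, g)
            key = (-score, du * du + dv * dv, dv, du)
            if best is None or key < best[0]:
                best = (key, du, dv, score)
    assert best is not None
    return best[1], best[2], best[3]


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

class TestGeometry:
    def test_grid_point_count(self):
        grid = GridSpec(origin_x=50, origin_y=50, spacing=4, n_cols=130, n_rows=200)
        assert grid.n_points == 26_000

    def test_grid_margin_validation(self):
        grid = GridSpec(origin_x=10, origin_y=10, spacing=4, n_cols=10, n_rows=10)
        grid.validate_for_frame(100, 100, margin=10)
        with pytest.raises(ConfigurationError):
            grid.validate_for_frame(100, 100, margin=11)

    @pytest.mark.parametrize("size", [2, 4, 1, 0])
    def test_subset_size_must_be_odd_and_large_enough(self, size):
        with pytest.raises(ConfigurationError):
            SubsetSpec(size)

    def test_subset_counts(self):
        s = SubsetSpec(63)
        assert s.half == 31
        assert s.n_points == 3969


# ---------------------------------------------------------------------------
# subset mean
# ---------------------------------------------------------------------------

class TestSubsetMean:
    def test_constant_image(self):
        frame = GrayFrame(np.full((80, 80), 7.0))
        assert subset_mean(frame, (40, 40), SubsetSpec(63)) == pytest.approx(7.0)

    def test_three_by_three(self):
        pix = np.zeros((9, 9))
        pix[3:6, 3:6] = np.arange(1, 10).reshape(3, 3)
        assert subset_mean(pix, (4, 4), SubsetSpec(3)) == pytest.approx(5.0)

    def test_matches_double_loop_oracle(self, speckle_frame):
        sub = SubsetSpec(63)
        got = subset_mean(speckle_frame, (80, 79), sub)
        block = speckle_frame.pixels[79 - 31 : 79 + 32, 80 - 31 : 80 + 32]
        total = 0.0
        for row in block:
            for val in row:
                total += val
        assert got == pytest.approx(total / 63**2, rel=1e-12)

    def test_border_crossing_rejected(self, speckle_frame):
        with pytest.raises(OutOfBoundsError):
            subset_mean(speckle_frame, (10, 80), SubsetSpec(63))


# ---------------------------------------------------------------------------
# NCC
# ---------------------------------------------------------------------------

class TestNcc:
    def test_self_correlation_is_one(self, speckle_frame):
        val = ncc(speckle_frame, (80, 80), speckle_frame, (80, 80), SubsetSpec(21))
        assert val == pytest.approx(1.0, abs=1e-12)

    def test_negated_subset_gives_minus_one(self, speckle_frame):
        neg = GrayFrame(255.0 - speckle_frame.pixels)
        val = ncc(speckle_frame, (80, 80), neg, (80, 80), SubsetSpec(21))
        assert val == pytest.approx(-1.0, abs=1e-12)

    def test_affine_intensity_invariance(self, speckle_frame):
        affine = GrayFrame(1.7 * speckle_frame.pixels + 12.0)
        val = ncc(speckle_frame, (70, 90), affine, (70, 90), SubsetSpec(21))
        assert val == pytest.approx(1.0, abs=1e-12)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        sub = SubsetSpec(21)
        for _ in range(20):
            a = GrayFrame(rng.uniform(0, 255, (60, 60)))
            b = GrayFrame(rng.uniform(0, 255, (60, 60)))
            x, y = rng.integers(15, 45, 2)
            got = ncc(a, (x, y), b, (x, y), sub)
            f = a.pixels[y - 10 : y + 11, x - 10 : x + 11]
            g = b.pixels[y - 10 : y + 11, x - 10 : x + 11]
            assert got == pytest.approx(ncc_oracle(f, g), abs=1e-10)

    def test_flat_subset_rejected(self, speckle_frame):
        flat = GrayFrame(np.full((64, 64), 3.0))
        with pytest.raises(DegenerateSubsetError):
            ncc(speckle_frame, (80, 80), flat, (32, 32), SubsetSpec(21))

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_bounded_for_random_subsets(self, seed):
        rng = np.random.default_rng(seed)
        a = GrayFrame(rng.uniform(0, 255, (30, 30)))
        b = GrayFrame(rng.uniform(0, 255, (30, 30)))
        val = ncc(a, (15, 15), b, (15, 15), SubsetSpec(9))
        assert -1.0 - 1e-12 <= val <= 1.0 + 1e-12


# ---------------------------------------------------------------------------
# integer search
# ---------------------------------------------------------------------------

class TestIntegerSearch:
    def test_no_motion(self, speckle_frame):
        d = integer_search(speckle_frame, speckle_frame, (80, 80), SubsetSpec(21), 5)
        assert (d.u, d.v) == (0.0, 0.0)
        assert d.quality == pytest.approx(1.0, abs=1e-12)

    def test_recovers_integer_roll(self, speckle_frame):
        # roll by (dy, dx) moves content by (+dx, +dy)
        cur = GrayFrame(np.roll(speckle_frame.pixels, (-2, 3), axis=(0, 1)))
        d = integer_search(speckle_frame, cur, (80, 80), SubsetSpec(21), 5)
        assert (d.u, d.v) == (3.0, -2.0)
        assert d.quality == pytest.approx(1.0, abs=1e-12)

    def test_matches_exhaustive_oracle_on_random_instances(self, speckle_frame):
        rng = np.random.default_rng(21)
        sub = SubsetSpec(15)
        for _ in range(10):
            du, dv = rng.integers(-4, 5, 2)
            cur = GrayFrame(np.roll(speckle_frame.pixels, (dv, du), axis=(0, 1)))
            x, y = rng.integers(40, 120, 2)
            d = integer_search(speckle_frame, cur, (x, y), sub, 5)
            ou, ov, oscore = exhaustive_search_oracle(
                speckle_frame.pixels, cur.pixels, x, y, sub.half, 5
            )
            assert (d.u, d.v) == (ou, ov) == (du, dv)
            assert d.quality == pytest.approx(oscore, abs=1e-9)

    def test_out_of_window_shift_returns_in_window_argmax(self, speckle_frame):
        cur = GrayFrame(np.roll(speckle_frame.pixels, (0, 7), axis=(0, 1)))
        d = integer_search(speckle_frame, cur, (80, 80), SubsetSpec(21), 5)
        ou, ov, _ = exhaustive_search_oracle(
            speckle_frame.pixels, cur.pixels, 80, 80, 10, 5
        )
        assert (d.u, d.v) == (ou, ov)
        assert d.quality < 1.0

    def test_tie_break_favors_no_motion(self):
        # a 5-periodic pattern ties (0,0) with (+-5, 0), (0, +-5), ...
        xx, yy = np.meshgrid(np.arange(64), np.arange(64))
        pix = 128 + 60 * np.sin(2 * np.pi * xx / 5) * np.cos(2 * np.pi * yy / 5)
        frame = GrayFrame(pix)
        d = integer_search(frame, frame, (32, 32), SubsetSpec(11), 7)
        assert (d.u, d.v) == (0.0, 0.0)

    def test_flat_frame_gives_invalid(self):
        flat = GrayFrame(np.full((64, 64), 9.0))
        d = integer_search(flat, flat, (32, 32), SubsetSpec(11), 3)
        assert not d.valid
        assert np.isnan(d.u) and np.isnan(d.v)


# ---------------------------------------------------------------------------
# Newton-Raphson refinement
# ---------------------------------------------------------------------------

class TestRefinement:
    def test_no_motion_stays_at_zero(self, speckle_frame):
        init = Displacement(0.0, 0.0, 1.0)
        d = refine_newton_raphson(
            speckle_frame, speckle_frame, (80, 80), init, SubsetSpec(21)
        )
        assert d.converged
        assert abs(d.u) < 1e-6 and abs(d.v) < 1e-6
        assert d.quality == pytest.approx(1.0, abs=1e-9)

    def test_recovers_subpixel_translation(self, speckle_frame):
        cur = GrayFrame(fourier_translate(speckle_frame.pixels, 0.30, -0.60))
        init = integer_search(speckle_frame, cur, (80, 80), SubsetSpec(21), 3)
        d = refine_newton_raphson(speckle_frame, cur, (80, 80), init, SubsetSpec(21))
        assert d.converged
        assert d.u == pytest.approx(0.30, abs=0.05)
        assert d.v == pytest.approx(-0.60, abs=0.05)

    def test_invalid_init_propagates(self, speckle_frame):
        d = refine_newton_raphson(
            speckle_frame, speckle_frame, (80, 80), Displacement.invalid(), SubsetSpec(21)
        )
        assert not d.valid

    def test_criterion_identity_with_ncc(self, speckle_frame):
        # C_LS = 2 (1 - C_cc) at integer displacements
        rng = np.random.default_rng(5)
        cur = GrayFrame(np.roll(speckle_frame.pixels, (1, -2), axis=(0, 1)))
        itp = Interpolator(cur)
        sub = SubsetSpec(15)
        for _ in range(10):
            x, y = rng.integers(40, 120, 2)
            u, v = rng.integers(-3, 4, 2)
            c = ncc(speckle_frame, (x, y), cur, (x + u, y + v), sub)
            cls = least_squares_criterion(
                speckle_frame, cur, (x, y), float(u), float(v), sub, interp=itp
            )
            assert cls == pytest.approx(2.0 * (1.0 - c), abs=1e-9)

    def test_interpolator_exact_at_integer_coordinates(self, speckle_frame):
        itp = Interpolator(speckle_frame)
        xs = np.array([10.0, 80.0, 150.0])
        ys = np.array([12.0, 60.0, 140.0])
        got = itp.sample(xs, ys)
        expect = speckle_frame.pixels[ys.astype(int), xs.astype(int)]
        np.testing.assert_allclose(got, expect, atol=1e-9)


# ---------------------------------------------------------------------------
# full-field computation
# ---------------------------------------------------------------------------

class TestComputeField:
    GRID = GridSpec(origin_x=40, origin_y=40, spacing=8, n_cols=11, n_rows=11)
    SUB = SubsetSpec(21)

    def test_identical_frames_give_zero_field(self, identical_pair):
        field = compute_field(identical_pair, 1, self.GRID, self.SUB, 5)
        assert field.valid.all()
        assert field.converged.all()
        assert np.nanmax(np.abs(field.u)) < 1e-6
        assert np.nanmax(np.abs(field.v)) < 1e-6

    def test_base_frame_as_current_rejected(self, identical_pair):
        with pytest.raises(ConfigurationError):
            compute_field(identical_pair, 0, self.GRID, self.SUB, 5)

    def test_uniform_subpixel_shift_recovered(self, speckle_frame):
        shifted = GrayFrame(fourier_translate(speckle_frame.pixels, 2.4, 1.2), 1)
        seq = FrameSequence([speckle_frame, shifted], fps=30)
        field = compute_field(seq, 1, self.GRID, self.SUB, 5)
        assert abs(np.nanmedian(field.u) - 2.4) < 0.05
        assert abs(np.nanmedian(field.v) - 1.2) < 0.05

    def test_swapping_frames_negates_integer_translation(self, speckle_frame):
        cur = GrayFrame(np.roll(speckle_frame.pixels, (2, -3), axis=(0, 1)), 1)
        fwd = FrameSequence([speckle_frame, cur], fps=30)
        rev = FrameSequence([GrayFrame(cur.pixels, 0), GrayFrame(speckle_frame.pixels, 1)], fps=30)
        f1 = compute_field(fwd, 1, self.GRID, self.SUB, 5)
        f2 = compute_field(rev, 1, self.GRID, self.SUB, 5)
        np.testing.assert_allclose(f1.u, -f2.u, atol=1e-6)
        np.testing.assert_allclose(f1.v, -f2.v, atol=1e-6)

    def test_affine_intensity_change_leaves_displacements(self, speckle_frame):
        cur = GrayFrame(np.roll(speckle_frame.pixels, (1, 2), axis=(0, 1)), 1)
        bright = GrayFrame(0.6 * cur.pixels + 40.0, 1)
        f1 = compute_field(FrameSequence([speckle_frame, cur], fps=30), 1, self.GRID, self.SUB, 5)
        f2 = compute_field(FrameSequence([speckle_frame, bright], fps=30), 1, self.GRID, self.SUB, 5)
        np.testing.assert_allclose(f1.u, f2.u, atol=1e-6)
        np.testing.assert_allclose(f1.v, f2.v, atol=1e-6)
        assert np.all(f1.quality >= -1.0) and np.all(f1.quality <= 1.0 + 1e-12)

    def test_grid_beyond_margin_rejected(self, identical_pair):
        big = GridSpec(origin_x=5, origin_y=5, spacing=8, n_cols=20, n_rows=20)
        with pytest.raises(ConfigurationError):
            compute_field(identical_pair, 1, big, self.SUB, 5)


class TestFieldSerialization:
    def _field(self):
        rng = np.random.default_rng(9)
        grid = GridSpec(origin_x=30, origin_y=30, spacing=4, n_cols=6, n_rows=5)
        shape = (5, 6)
        valid = np.ones(shape, bool)
        valid[2, 3] = False
        u = rng.normal(size=shape)
        v = rng.normal(size=shape)
        u[~valid] = np.nan
        v[~valid] = np.nan
        q = rng.uniform(0.8, 1.0, shape)
        q[~valid] = np.nan
        return DisplacementField(
            grid=grid, u=u, v=v, quality=q, converged=valid.copy(), valid=valid,
            ref_index=0, cur_index=7,
        )

    def test_csv_round_trip_lossless(self, tmp_path):
        field = self._field()
        path = tmp_path / "field.csv"
        field.save_table(path)
        back = DisplacementField.load_table(path)
        assert back.grid == field.grid
        np.testing.assert_array_equal(back.u, field.u)
        np.testing.assert_array_equal(back.v, field.v)
        np.testing.assert_array_equal(back.valid, field.valid)

    def test_npz_round_trip_lossless(self, tmp_path):
        field = self._field()
        path = tmp_path / "field.npz"
        field.save_npz(path)
        back = DisplacementField.load_npz(path)
        assert back.grid == field.grid
        assert back.cur_index == 7
        np.testing.assert_array_equal(back.u, field.u)
        np.testing.assert_array_equal(back.quality, field.quality)
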