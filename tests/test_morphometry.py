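"""Morphometry: rotation, geometry, subregions, volume, ratio."""

import numpy as np
import pytest

from discload import morphometry as mo
from conftest import rasterize_ellipse, rasterize_rect

PX = 0.366  # mm per pixel


class TestPrincipalAngle:
    def test_axis_aligned_rectangle_is_zero(self):
        assert mo.principal_angle(rasterize_rect(0, 40, 16)) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("angle", [10, 20, 30, 45, -15, -30])
    def test_recovers_rasterization_angle(self, angle):
        est = mo.principal_angle(rasterize_rect(angle, 54, 22))
        assert est == pytest.approx(angle, abs=1.0)

    def test_circle_is_flagged_isotropic(self):
        _, iso = mo.principal_angle(rasterize_ellipse(0, 20, 20), return_isotropy=True)
        assert iso
        _, aniso = mo.principal_angle(rasterize_rect(0, 40, 16), return_isotropy=True)
        assert not aniso

    def test_single_pixel_raises(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2] = True
        with pytest.raises(ValueError, match="degenerate"):
            mo.principal_angle(mask)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="empty"):
            mo.principal_angle(np.zeros((5, 5), dtype=bool))


class TestRotateToHorizontal:
    def test_already_horizontal_is_identity(self):
        mask = rasterize_rect(0, 40, 16)
        assert np.array_equal(mo.rotate_to_horizontal(mask), mask)

    @pytest.mark.parametrize("angle", [10, 20, 30, 45])
    def test_restores_bounding_box_and_area(self, angle):
        """A 20x8 mm rectangle rasterized at an angle comes back to its
        axis-aligned footprint within 1 px, with area preserved to 2%."""
        n_len, n_ht = 20.0 / PX, 8.0 / PX
        tilted = rasterize_rect(angle, n_len, n_ht)
        rot = mo.rotate_to_horizontal(tilted)
        assert abs(int(rot.sum()) - int(tilted.sum())) / tilted.sum() < 0.02
        _, height, width = mo.disc_geometry(rot, PX)
        assert abs(width - 20.0) <= PX
        assert abs(height - 8.0) <= PX

    def test_double_application_is_idempotent(self):
        rot = mo.rotate_to_horizontal(rasterize_rect(30, 54, 22))
        assert abs(mo.principal_angle(rot)) < 1.0
        rot2 = mo.rotate_to_horizontal(rot)
        assert abs(mo.principal_angle(rot2)) < 1.0


class TestDiscGeometry:
    def test_rectangle_arithmetic(self):
        """20x8 px rectangle at 0.366 mm/px: width 7.32, height 2.928 mm."""
        mask = np.zeros((30, 30), dtype=bool)
        mask[10:18, 5:25] = True
        area, height, width = mo.disc_geometry(mask, PX)
        assert width == pytest.approx(20 * PX)       # 7.32 mm
        assert height == pytest.approx(8 * PX)       # 2.928 mm
        assert area == pytest.approx(160 * PX**2)    # 21.43 mm^2

    def test_ellipse_height_matches_column_scan_oracle(self):
        mask = rasterize_ellipse(0, 25, 8)
        _, height, _ = mo.disc_geometry(mask, 1.0)
        cols = np.nonzero(mask.any(axis=0))[0]
        oracle = np.mean(
            [np.nonzero(mask[:, c])[0][-1] - np.nonzero(mask[:, c])[0][0] + 1 for c in cols]
        )
        assert height == pytest.approx(oracle)

    def test_single_row_mask(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[4, 2:9] = True
        _, height, width = mo.disc_geometry(mask, 1.0)
        assert height == 1.0
        assert width == 7.0

    def test_translation_changes_nothing(self):
        base = rasterize_ellipse(0, 20, 6, shape=(100, 100), center=(40, 40))
        moved = np.roll(np.roll(base, 17, axis=0), 23, axis=1)
        assert mo.disc_geometry(base, PX) == mo.disc_geometry(moved, PX)


class TestSubregionProfile:
    def _disc_with_nucleus(self):
        disc = rasterize_ellipse(0, 26, 5, shape=(40, 80))
        nucleus = rasterize_ellipse(0, 13, 2.5, shape=(40, 80))
        t2 = np.full(disc.shape, np.nan)
        t2[disc] = 70.0
        t2[nucleus] = 120.0
        return disc, t2

    def test_uniform_disc_gives_five_equal_means(self):
        disc = rasterize_ellipse(0, 26, 5, shape=(40, 80))
        t2 = np.where(disc, 100.0, np.nan)
        sub, dense = mo.subregion_profile(disc, t2)
        assert np.allclose(sub, 100.0)
        assert dense.shape == (100,)
        assert np.allclose(dense, 100.0)

    def test_nucleus_raises_central_subregion(self):
        """Nucleus 120 / annulus 70 ms: central block above both ends, and
        each block mean matches direct per-block pixel averaging."""
        disc, t2 = self._disc_with_nucleus()
        sub, _ = mo.subregion_profile(disc, t2)
        assert sub[2] > sub[0] and sub[2] > sub[4]
        cols = np.nonzero(disc.any(axis=0))[0]
        blocks = mo._subregion_column_blocks(cols)
        for i, block_cols in enumerate(blocks):
            sel = np.zeros_like(disc)
            sel[:, block_cols] = disc[:, block_cols]
            assert sub[i] == pytest.approx(t2[sel].mean())

    def test_partition_preserves_whole_disc_mean(self):
        disc, t2 = self._disc_with_nucleus()
        sub, _ = mo.subregion_profile(disc, t2)
        cols = np.nonzero(disc.any(axis=0))[0]
        weights = [disc[:, b].sum() for b in mo._subregion_column_blocks(cols)]
        weighted = np.average(sub, weights=weights)
        assert weighted == pytest.approx(t2[disc].mean(), rel=1e-12)

    @pytest.mark.parametrize("width,expected", [
        (25, [5, 5, 5, 5, 5]),
        (26, [5, 5, 6, 5, 5]),
        (27, [5, 6, 5, 6, 5]),
        (28, [5, 6, 6, 6, 5]),
        (29, [5, 6, 7, 6, 5]),
    ])
    def test_remainder_columns_go_to_interior_blocks(self, width, expected):
        blocks = mo._subregion_column_blocks(np.arange(width))
        assert [b.size for b in blocks] == expected
        assert np.array_equal(np.concatenate(blocks), np.arange(width))

    def test_mostly_invalid_block_reported_missing(self):
        disc = np.zeros((10, 25), dtype=bool)
        disc[4:6, :] = True
        t2 = np.where(disc, 90.0, np.nan)
        t2[:, :5] = np.nan  # anterior block fully invalid
        sub, _ = mo.subregion_profile(disc, t2)
        assert np.isnan(sub[0])
        assert np.allclose(sub[1:], 90.0)

    def test_too_narrow_mask_raises(self):
        disc = np.zeros((6, 6), dtype=bool)
        disc[2, 1:4] = True
        with pytest.raises(ValueError, match="at least 5"):
            mo.subregion_profile(disc, np.where(disc, 1.0, np.nan))


class TestDiscVolume:
    def test_three_slice_closed_form(self):
        """Areas 200/250/300 mm^2 at 4.5 mm spacing integrate to 2.25 cm^3."""
        assert mo.disc_volume([200.0, 250.0, 300.0], 4.5) == pytest.approx(2.25)

    @pytest.mark.parametrize("k", [2, 5, 9])
    def test_constant_area_closed_form(self, k):
        assert mo.disc_volume([120.0] * k, 4.5) == pytest.approx(120.0 * 4.5 * (k - 1) / 1000)

    def test_linearity_in_area(self, rng):
        areas = rng.uniform(100, 400, 7)
        assert mo.disc_volume(2 * areas, 4.5) == pytest.approx(2 * mo.disc_volume(areas, 4.5))

    def test_matches_trapezoid_closed_form_on_random_areas(self, rng):
        areas = rng.uniform(50, 500, 9)
        closed = (areas[0] / 2 + areas[1:-1].sum() + areas[-1] / 2) * 4.5 / 1000
        assert mo.disc_volume(areas, 4.5) == pytest.approx(closed, rel=1e-12)

    def test_single_slice_raises(self):
        with pytest.raises(ValueError, match="2 slices"):
            mo.disc_volume([200.0], 4.5)


class TestHeightRatioAndPeriprocess:
    def test_ratio_arithmetic_and_units(self):
        assert mo.height_ratio(7.1, 28.4) == pytest.approx(0.25)
        assert mo.height_ratio(5.0, 5.0) == 1.0
        assert mo.height_ratio(0.71, 2.84) == pytest.approx(mo.height_ratio(7.1, 28.4))

    def test_nonpositive_raises(self):
        with pytest.raises(ValueError):
            mo.height_ratio(0.0, 28.4)

    def test_three_slice_average(self, rng):
        assert mo.periprocess_average([10.0, 12.0, 14.0], 1) == pytest.approx(12.0)
        vals = rng.uniform(0, 100, 9)
        i = 4
        assert mo.periprocess_average(vals, i) == pytest.approx(vals[3:6].mean())

    @pytest.mark.parametrize("idx", [0, 8])
    def test_boundary_slice_raises(self, idx):
        with pytest.raises(ValueError, match="neighbour"):
            mo.periprocess_average(np.arange(9.0), idx)


class TestRotationInvariance:
    @pytest.mark.parametrize("angle", [10, 20, 30, 45])
    def test_geometry_survives_rasterized_rotation(self, angle):
        """disc_geometry agrees between a shape and its rotated rasterization
        (after rotation-to-horizontal): 1 px on extents, 2% on area."""
        n_len, n_ht = 20.0 / PX, 8.0 / PX
        tilted = mo.rotate_to_horizontal(rasterize_rect(angle, n_len, n_ht))
        a1, h1, w1 = mo.disc_geometry(tilted, PX)
        # rotated presentations all come back to the true 20 x 8 mm footprint
        assert abs(w1 - 20.0) <= PX
        assert abs(h1 - 8.0) <= PX
        assert abs(a1 - 160.0) / 160.0 < 0.02
        # and agree with every other presentation angle
        other = mo.rotate_to_horizontal(rasterize_rect(17, n_len, n_ht))
        a2, h2, w2 = mo.disc_geometry(other, PX)
        assert abs(w1 - w2) <= PX and abs(h1 - h2) <= PX
        assert abs(a1 - a2) / a2 < 0.02

    @pytest.mark.parametrize("angle", [10, 30])
    def test_lens_shape_survives_rotation_within_tip_tolerance(self, angle):
        """Elliptical (lens-like) discs lose their sub-half-pixel tip columns
        when re-rasterized; extents agree within 3 px, area to 3%."""
        flat = rasterize_ellipse(0, 24, 8)
        tilted = mo.rotate_to_horizontal(rasterize_ellipse(angle, 24, 8))
        a0, h0, w0 = mo.disc_geometry(flat, PX)
        a1, h1, w1 = mo.disc_geometry(tilted, PX)
        assert abs(w1 - w0) <= 3 * PX
        assert abs(h1 - h0) <= PX
        assert abs(a1 - a0) / a0 < 0.03
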