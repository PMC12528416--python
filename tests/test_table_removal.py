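import warnings

import numpy as np
import pytest

from ctweigh import (
    InputError,
    TableRemovalConfig,
    detect_table_edges,
    extract_profiles,
    fit_table_curve,
    generate_phantom,
    remove_table,
    smooth_profile,
    weigh_volume,
)
from ctweigh.errors import TableRemovalWarning

from conftest import curved_table_spec


class TestExtractProfiles:
    def test_default_fraction_columns_512(self):
        image = np.zeros((16, 512))
        cols = [c for c, _ in extract_profiles(image)]
        assert cols == [128, 256, 383]  # round(f * 511)

    def test_uniform_slice_gives_constant_profiles(self):
        image = np.full((32, 64), -1000.0)
        for _, profile in extract_profiles(image):
            assert np.all(profile == -1000.0)

    def test_duplicate_columns_collapsed_on_narrow_slice(self):
        # 4 columns: base fractions round to 1, 2, 2 — a third distinct
        # column must be recruited from the expanded fraction set
        image = np.zeros((8, 4))
        cols = [c for c, _ in extract_profiles(image)]
        assert len(cols) == len(set(cols)) == 3

    def test_too_narrow_slice_rejected(self):
        with pytest.raises(InputError):
            extract_profiles(np.zeros((8, 3)))

    def test_profiles_run_down_the_column(self):
        image = np.tile(np.arange(10.0)[:, None], (1, 8))
        _, profile = extract_profiles(image)[0]
        assert np.array_equal(profile, np.arange(10.0))


class TestSmoothProfile:
    def test_constant_invariant(self):
        out = smooth_profile(np.full(50, 7.0), sigma_voxels=2.0)
        np.testing.assert_allclose(out, 7.0)

    def test_impulse_mass_preserved_and_symmetric(self):
        impulse = np.zeros(41)
        impulse[20] = 1.0
        out = smooth_profile(impulse, sigma_voxels=1.0)
        assert out.sum() == pytest.approx(1.0, abs=1e-6)
        np.testing.assert_allclose(out, out[::-1], atol=1e-12)
        assert out.argmax() == 20

    def test_tiny_sigma_is_identity(self):
        profile = np.random.default_rng(0).normal(size=30)
        out = smooth_profile(profile, sigma_voxels=1e-3)
        np.testing.assert_allclose(out, profile, atol=1e-6)

    def test_invalid_inputs(self):
        with pytest.raises(InputError):
            smooth_profile(np.zeros(2), 1.0)
        with pytest.raises(InputError):
            smooth_profile(np.zeros(10), 0.0)


def _profile(segments, length=200):
    """Build a profile from (start, stop_inclusive, value) segments over air."""
    p = np.full(length, -1000.0)
    for s, e, v in segments:
        p[s : e + 1] = v
    return p


class TestDetectTableEdges:
    def test_body_then_table_band_found(self):
        # air / body rows 100-140 / air gap / table rows 150-160 / air
        profile = _profile([(100, 140, 40.0), (150, 160, 250.0)])
        assert detect_table_edges(profile) == (150, 160)

    def test_all_air_profile_empty(self):
        assert detect_table_edges(_profile([])) is None

    def test_body_touching_table_declines(self):
        # merged body+table run is taller than max_band_mm -> no detection
        profile = _profile([(80, 160, 40.0)])
        profile[150:161] = 250.0
        assert detect_table_edges(profile) is None

    def test_insufficient_air_gap_declines(self):
        profile = _profile([(100, 148, 40.0), (150, 160, 250.0)])
        assert detect_table_edges(profile, min_gap_voxels=3) is None

    def test_band_height_limits(self):
        thin = _profile([(150, 152, 250.0)])  # 3 mm < 5 mm minimum
        assert detect_table_edges(thin) is None
        thick = _profile([(120, 190, 250.0)])  # 71 mm > 60 mm maximum
        assert detect_table_edges(thick) is None

    def test_spacing_scales_physical_height(self):
        # an 11-voxel band is 3.3 mm at 0.3 mm/voxel: below the minimum
        profile = _profile([(150, 160, 250.0)])
        assert detect_table_edges(profile, pixel_spacing_row=0.3) is None
        assert detect_table_edges(profile, pixel_spacing_row=1.0) == (150, 160)


class TestFitTableCurve:
    def test_three_points_interpolated_exactly(self):
        points = [(128, 300), (256, 290), (383, 301)]
        fit = fit_table_curve(points)
        assert fit.valid
        for col, row in points:
            assert fit.evaluate(col) == pytest.approx(row, abs=1e-6)

    def test_collinear_points_degenerate_to_line(self):
        fit = fit_table_curve([(0, 10), (50, 35), (100, 60)])
        a, b, c = fit.coefficients
        assert a == pytest.approx(0.0, abs=1e-9)
        assert b == pytest.approx(0.5, abs=1e-9)
        assert c == pytest.approx(10.0, abs=1e-6)

    def test_two_points_invalid_without_exception(self):
        fit = fit_table_curve([(10, 5), (20, 6)])
        assert not fit.valid
        assert fit.coefficients is None

    def test_duplicate_columns_invalid(self):
        fit = fit_table_curve([(10, 5), (10, 7), (20, 6)])
        assert not fit.valid

    def test_edge_points_sorted_by_column(self):
        fit = fit_table_curve([(30, 5), (10, 7), (20, 6)])
        assert [c for c, _ in fit.edge_points] == [10, 20, 30]


class TestRemoveTable:
    @pytest.mark.parametrize(
        "a,c0,band_height",
        [(0.0, 104.0, 8), (0.001, 100.0, 5), (-0.0008, 110.0, 25), (0.0012, 98.0, 40)],
    )
    def test_removal_recovers_table_free_weight_exactly(self, a, c0, band_height):
        spec = curved_table_spec(a, c0, band_height)
        volume, _ = generate_phantom(spec)
        cleaned, fits = remove_table(volume)
        assert all(f.valid for f in fits)
        spec.table = None
        table_free, truth = generate_phantom(spec)
        assert weigh_volume(cleaned).total_mass == truth.total_mass_kg
        # body voxels pass through untouched
        assert np.array_equal(cleaned.voxels, table_free.voxels)

    def test_table_voxels_filled_with_air(self, tabled_body):
        volume, _ = tabled_body
        cleaned, _ = remove_table(volume)
        changed = cleaned.voxels != volume.voxels
        assert changed.any()
        assert np.all(cleaned.voxels[changed] == -1000.0)

    def test_idempotent(self, tabled_body):
        volume, _ = tabled_body
        once, _ = remove_table(volume)
        twice, _ = remove_table(once)
        assert np.array_equal(once.voxels, twice.voxels)

    def test_input_not_mutated(self, tabled_body):
        volume, _ = tabled_body
        before = volume.voxels.copy()
        remove_table(volume)
        assert np.array_equal(volume.voxels, before)

    def test_table_free_volume_passes_through_bit_identical(self, simple_body):
        volume, _ = simple_body
        cleaned, fits = remove_table(volume)
        assert np.array_equal(cleaned.voxels, volume.voxels)
        assert not any(f.valid for f in fits)

    def test_without_removal_weight_exceeds_by_table_mass(self, tabled_body_spec):
        volume, _ = generate_phantom(tabled_body_spec)
        with_table = weigh_volume(volume).total_mass
        cleaned, _ = remove_table(volume)
        without_table = weigh_volume(cleaned).total_mass
        # table band voxels (HU 250 -> bone class) inflate the raw estimate
        table_voxels = int((volume.voxels == 250.0).sum())
        expected_excess = table_voxels * 1e-3 * 1.85 / 1000.0
        assert with_table - without_table == pytest.approx(expected_excess, abs=1e-12)

    def test_undetectable_slice_falls_back_to_median_curve(self, tabled_body_spec):
        volume, _ = generate_phantom(tabled_body_spec)
        # bridge the air gap on the last slice: body touches table there,
        # detection declines, but >=50% of slices still fit
        k = volume.slice_count - 1
        table_mask = volume.voxels[k] == 250.0
        table_top = int(np.argwhere(table_mask)[:, 0].min())
        volume.voxels[k, table_top - 12 : table_top, :] = 50.0
        cleaned, fits = remove_table(volume)
        assert not fits[k].valid
        assert sum(f.valid for f in fits) >= 0.5 * len(fits)
        # the median curve still removed the bridged slice's table
        assert np.all(cleaned.voxels[k][table_mask] == -1000.0)

    def test_minority_detection_warns_and_leaves_slices(self):
        spec = curved_table_spec(0.0, 120.0, 8, slices=4)
        volume, _ = generate_phantom(spec)
        # wipe the table on 3 of 4 slices -> <50% fitted
        for k in range(1, 4):
            volume.voxels[k][volume.voxels[k] == 250.0] = -1000.0
        reference = volume.voxels.copy()
        with pytest.warns(TableRemovalWarning):
            cleaned, fits = remove_table(volume)
        assert sum(f.valid for f in fits) == 1
        # unfitted slices are untouched
        assert np.array_equal(cleaned.voxels[1:], reference[1:])
        # the fitted slice lost its table
        assert not np.array_equal(cleaned.voxels[0], reference[0])
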