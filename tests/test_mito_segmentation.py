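"""Volume/spot detection, density, single-mitochondrion volumes, top-N."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from calmito.mito import (
    GanglionMask,
    Spot,
    density,
    detect_spots,
    detect_volume,
    select_top_spots,
    single_mito_volumes,
)
from calmito.simulate import MitoSimParams, simulate_mito_stack

VOX = (0.5, 0.25, 0.25)


def _full_mask(shape, vox=VOX):
    return GanglionMask(np.ones(shape, bool), vox)


class TestDetectVolume:
    def test_threshold_above_max_gives_zero(self):
        frame = np.random.default_rng(0).uniform(0, 10, (8, 16, 16))
        vol, ratio = detect_volume(frame, _full_mask(frame.shape), 100.0)
        assert vol == 0.0 and ratio == 0.0

    def test_counting_arithmetic(self):
        frame = np.zeros((10, 10, 10))
        frame.ravel()[:100] = 50.0  # 100 of 1000 voxels supra-threshold
        mask = _full_mask(frame.shape, (1.0, 1.0, 1.0))
        vol, ratio = detect_volume(frame, mask, 10.0)
        assert ratio == pytest.approx(0.1)
        assert vol == pytest.approx(100.0)

    def test_simulated_total_volume_within_20pct(self, small_mito):
        from calmito.mito import default_intensity_threshold

        params, stack, mask, truth = small_mito
        frame = stack.frame(0)
        spots = detect_spots(frame, mask, min_distance_um=1.0)
        thr = default_intensity_threshold(frame, mask, spots)
        vol, ratio = detect_volume(frame, mask, thr)
        true_vol = truth.mitochondria["voxel_volume_um3"].sum()
        assert vol == pytest.approx(true_vol, rel=0.20)
        assert 0.0 <= ratio <= 1.0

    def test_volume_ratio_invariant_under_intensity_scaling(self, small_mito):
        _params, stack, mask, _truth = small_mito
        frame = stack.frame(0)
        _, r1 = detect_volume(frame, mask, 100.0)
        _, r2 = detect_volume(frame * 3.0, mask, 300.0)
        assert r1 == r2


class TestDetectSpots:
    def test_uniform_image_has_no_spots(self):
        frame = np.full((8, 24, 24), 10.0)
        assert detect_spots(frame, _full_mask(frame.shape), intensity_floor=1.0) == []

    def test_two_point_sources_resolved(self):
        """Two rasterized sources 5 um apart -> exactly two spots within
        0.5 um of the true centres, with min_distance 2 um."""
        from scipy.ndimage import gaussian_filter

        frame = np.zeros((16, 40, 48))
        vsize = np.asarray(VOX)
        c1_um, c2_um = np.array([4.0, 5.0, 5.0]), np.array([4.0, 5.0, 10.0])
        for c in (c1_um, c2_um):
            z, y, x = np.round(c / vsize - 0.5).astype(int)
            frame[z, y, x] = 1000.0
        frame = gaussian_filter(frame, 0.4 / vsize)
        spots = detect_spots(
            frame, _full_mask(frame.shape), min_distance_um=2.0,
            intensity_floor=frame.max() / 10, log_sigma_um=0.4,
        )
        assert len(spots) == 2
        found = sorted((np.asarray(s.centroid_um) for s in spots), key=lambda p: p[2])
        assert np.linalg.norm(found[0] - c1_um) <= 0.5
        assert np.linalg.norm(found[1] - c2_um) <= 0.5

    def test_simulated_count_within_10pct(self, small_mito):
        params, stack, mask, _truth = small_mito
        spots = detect_spots(stack.frame(0), mask, min_distance_um=1.0)
        assert abs(len(spots) - params.n_mito) <= 0.10 * params.n_mito

    def test_centroids_inside_mask_bounding_box(self, small_mito):
        _params, stack, mask, _truth = small_mito
        spots = detect_spots(stack.frame(0), mask)
        lo = np.min(np.argwhere(mask.mask), axis=0) * np.asarray(VOX)
        hi = (np.max(np.argwhere(mask.mask), axis=0) + 1) * np.asarray(VOX)
        for s in spots:
            assert np.all(np.asarray(s.centroid_um) >= lo - 1e-9)
            assert np.all(np.asarray(s.centroid_um) <= hi + 1e-9)


class TestDensity:
    def test_arithmetic(self):
        mask = _full_mask((10, 10, 30), (1.0, 1.0, 1.0))  # 3000 um^3
        spots = [Spot(i, (0, 0, 0), 1.0) for i in range(12)]
        assert density(spots, mask) == pytest.approx(4.0)

    def test_empty(self):
        assert density([], _full_mask((4, 8, 8))) == 0.0

    def test_removing_a_spot_never_increases_density(self):
        mask = _full_mask((4, 8, 8))
        spots = [Spot(i, (0, 0, 0), 1.0) for i in range(5)]
        assert density(spots[:-1], mask) < density(spots, mask)

    def test_simulated_density_within_15pct(self, small_mito):
        params, stack, mask, _truth = small_mito
        spots = detect_spots(stack.frame(0), mask, min_distance_um=1.0)
        true_density = 1000.0 * params.n_mito / mask.volume_um3
        assert density(spots, mask) == pytest.approx(true_density, rel=0.15)


class TestSingleMitoVolumes:
    def test_single_cube_volume(self):
        frame = np.zeros((8, 8, 8))
        frame[2:4, 2:4, 2:4] = 100.0  # 8 voxels at 0.5^3 um^3
        mask = _full_mask(frame.shape, (0.5, 0.5, 0.5))
        mean, vols = single_mito_volumes(frame, mask, 50.0)
        assert mean == pytest.approx(1.0)
        assert len(vols) == 1

    def test_two_equal_cubes(self):
        frame = np.zeros((8, 16, 16))
        frame[2:4, 2:4, 2:4] = 100.0
        frame[2:4, 10:12, 10:12] = 100.0
        mask = _full_mask(frame.shape, (0.5, 0.5, 0.5))
        mean, vols = single_mito_volumes(frame, mask, 50.0)
        assert len(vols) == 2
        assert mean == pytest.approx(vols[0])

    def test_watershed_splits_touching_pair(self):
        """One 26-connected component holding two detected spot centres is
        split into two parts."""
        from scipy.ndimage import gaussian_filter

        frame = np.zeros((12, 24, 24))
        frame[5, 11, 8] = 2000.0
        frame[5, 11, 14] = 2000.0
        frame = gaussian_filter(frame, (1.0, 2.0, 2.0))
        mask = _full_mask(frame.shape, (0.5, 0.5, 0.5))
        thr = frame.max() * 0.3
        spots = [
            Spot(0, ((5 + 0.5) * 0.5, (11 + 0.5) * 0.5, (8 + 0.5) * 0.5), 1.0),
            Spot(1, ((5 + 0.5) * 0.5, (11 + 0.5) * 0.5, (14 + 0.5) * 0.5), 1.0),
        ]
        _, unsplit = single_mito_volumes(frame, mask, thr)
        assert len(unsplit) == 1
        _, split = single_mito_volumes(frame, mask, thr, spots)
        assert len(split) == 2

    def test_no_supra_threshold_voxels_rejected(self):
        with pytest.raises(ValueError, match="supra-threshold"):
            single_mito_volumes(np.zeros((4, 8, 8)), _full_mask((4, 8, 8)), 1.0)

    def test_simulated_mean_volume_within_25pct(self, small_mito):
        from calmito.mito import default_intensity_threshold

        params, stack, mask, truth = small_mito
        frame = stack.frame(0)
        spots = detect_spots(frame, mask, min_distance_um=1.0)
        thr = default_intensity_threshold(frame, mask, spots)
        mean, _ = single_mito_volumes(frame, mask, thr, spots)
        true_mean = truth.mitochondria["voxel_volume_um3"].mean()
        assert mean == pytest.approx(true_mean, rel=0.25)


class TestSelectTopSpots:
    def test_fewer_than_n_returns_all(self):
        spots = [Spot(i, (0, 0, float(i)), float(i)) for i in range(3)]
        assert len(select_top_spots(spots, 500)) == 3

    def test_brightest_two_of_three(self):
        spots = [
            Spot(0, (0, 0, 0), 5.0),
            Spot(1, (0, 0, 1), 9.0),
            Spot(2, (0, 0, 2), 7.0),
        ]
        top = select_top_spots(spots, 2)
        assert [s.centre_intensity for s in top] == [9.0, 7.0]

    def test_tie_break_by_centroid_order(self):
        spots = [
            Spot(0, (1.0, 0.0, 0.0), 5.0),
            Spot(1, (0.0, 2.0, 0.0), 5.0),
            Spot(2, (0.0, 1.0, 0.0), 5.0),
        ]
        top = select_top_spots(spots, 2)
        assert [s.centroid_um for s in top] == [(0.0, 1.0, 0.0), (0.0, 2.0, 0.0)]

    @settings(deadline=None, max_examples=30)
    @given(
        intensities=st.lists(st.floats(0, 100, allow_nan=False), min_size=1, max_size=40),
        n=st.integers(1, 50),
    )
    def test_matches_sort_oracle(self, intensities, n):
        """Output equals the full-sort-then-slice oracle (prefix property)."""
        spots = [Spot(i, (0.0, 0.0, float(i)), v) for i, v in enumerate(intensities)]
        oracle = sorted(spots, key=lambda s: (-s.centre_intensity, s.centroid_um))
        assert select_top_spots(spots, n) == oracle[: min(n, len(spots))]
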