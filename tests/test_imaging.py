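"""Unit and property tests for nanoparticle-cluster quantification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from retquant import imaging as im


class TestMomentsThreshold:
    def test_separates_two_equal_spikes(self):
        hist = np.zeros(256)
        hist[10] = 100
        hist[200] = 100
        t = im.moments_threshold(hist)
        assert 10 < t < 200

    def test_matches_brute_force_on_random_histograms(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            hist = _random_bimodal_hist(rng)
            assert im.moments_threshold(hist) == oracles.moments_threshold(hist)

    def test_shift_equivariance(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            hist = _random_bimodal_hist(rng, width=150)
            k = int(rng.integers(1, 80))
            shifted = np.zeros(256)
            shifted[k:k + 150] = hist[:150]
            assert im.moments_threshold(shifted) == im.moments_threshold(hist[:150].copy()) + k

    def test_degenerate_histogram_raises(self):
        hist = np.zeros(256)
        hist[37] = 1000
        with pytest.raises(im.DegenerateHistogramError):
            im.moments_threshold(hist)

    def test_rejects_invalid_input(self):
        with pytest.raises(ValueError):
            im.moments_threshold(np.zeros(256))


def _random_bimodal_hist(rng, width=256):
    hist = np.zeros(width)
    n1, n2 = rng.integers(100, 2000, size=2)
    lo = rng.normal(width * 0.2, width * 0.05, n1).astype(int)
    hi = rng.normal(width * 0.7, width * 0.08, n2).astype(int)
    for v in np.concatenate([lo, hi]):
        hist[np.clip(v, 0, width - 1)] += 1
    return hist


class TestBinarize:
    def test_extreme_thresholds(self):
        arr = np.arange(27).reshape(3, 3, 3)
        assert not im.binarize(arr, arr.max()).any()
        assert im.binarize(arr, arr.min() - 1).all()

    @settings(max_examples=20, derandomize=True)
    @given(st.integers(0, 1000))
    def test_mask_size_nonincreasing_in_threshold(self, seed):
        rng = np.random.default_rng(seed)
        arr = rng.integers(0, 255, size=(4, 8, 8))
        counts = [im.binarize(arr, t).sum() for t in range(0, 255, 16)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestConnectedComponents:
    def test_solid_cube_is_one_cluster(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[1:4, 1:4, 1:4] = True
        cs = im.connected_components(mask)
        assert len(cs) == 1
        assert cs.table["n_voxels"].iloc[0] == 27

    def test_corner_contact_depends_on_connectivity(self):
        mask = np.zeros((2, 2, 2), bool)
        mask[0, 0, 0] = mask[1, 1, 1] = True
        assert len(im.connected_components(mask, connectivity=26)) == 1
        assert len(im.connected_components(mask, connectivity=6)) == 2

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_partition_matches_flood_fill(self, connectivity):
        rng = np.random.default_rng(3)
        for _ in range(5):
            mask = rng.random((6, 10, 10)) < 0.25
            cs = im.connected_components(mask, connectivity=connectivity)
            ours = {frozenset(map(tuple, v)) for v in cs.voxels.values()}
            ref = set(oracles.flood_fill_components(mask, connectivity))
            assert ours == ref


class TestMajorDiameter:
    SPACING = (0.7, 0.25, 0.25)  # (z, y, x)

    def test_single_voxel_reports_voxel_pitch(self):
        d = im.major_diameter(np.array([[0, 0, 0]]), self.SPACING)
        assert d == pytest.approx(0.4)

    def test_collinear_voxels(self):
        vox = np.array([[0, 0, i] for i in range(5)])
        # 1 µm center span plus the quarter-pitch chord correction
        assert im.major_diameter(vox, self.SPACING) == pytest.approx(1.0 + 0.1)

    def test_matches_all_pairs_brute_force(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            n = rng.integers(2, 120)
            vox = np.unique(rng.integers(0, 12, size=(n, 3)), axis=0)
            assert im.major_diameter(vox, self.SPACING) == pytest.approx(
                oracles.major_diameter(vox, self.SPACING)
            )


class TestDiameterHistogram:
    def test_known_bin_frequencies(self):
        h = im.diameter_histogram([0.8, 0.9, 1.6])
        assert h.frequency[3] == pytest.approx(2 / 3)  # [0.75, 1.0)
        assert h.frequency[6] == pytest.approx(1 / 3)  # [1.5, 1.75)
        assert h.n_total == 3

    def test_frequencies_sum_to_one(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            d = rng.gamma(2.0, 0.4, size=rng.integers(1, 500))
            assert im.diameter_histogram(d).frequency.sum() == pytest.approx(1.0)

    def test_empty_input(self):
        h = im.diameter_histogram([])
        assert h.n_total == 0 and h.frequency.size == 0

    def test_generator_diameter_mode_falls_in_expected_bin(self):
        # 1e4 draws from the generator's log-normal (mode 0.85 µm)
        from retquant.synthetic import StackSpec

        spec = StackSpec()
        rng = np.random.default_rng(123)
        mu = np.log(spec.diameter_mode_um) + spec.diameter_sigma**2
        d = rng.lognormal(mu, spec.diameter_sigma, size=10_000)
        assert im.diameter_histogram(d).modal_bin_um == (0.75, 1.0)

    def test_fraction_below(self):
        h = im.diameter_histogram([0.1, 0.3, 3.0, 5.0])
        assert h.fraction_below(2.0) == pytest.approx(0.5)


class TestNearestNeighborDistances:
    def test_two_points(self):
        nnd, mean = im.nearest_neighbor_distances([[0, 0], [3, 0]])
        assert list(nnd) == [3, 3] and mean == 3

    def test_matches_all_pairs(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(0, 50, size=(40, 3))
        nnd, _ = im.nearest_neighbor_distances(pts)
        assert nnd == pytest.approx(oracles.nearest_neighbor_distances(pts))

    def test_requires_two_points(self):
        with pytest.raises(im.InsufficientPointsError):
            im.nearest_neighbor_distances([[1.0, 2.0]])


class TestCoverageFraction:
    ROI = [(0, 0), (100, 0), (100, 100), (0, 100)]

    def test_corner_points_cover_all(self):
        pts = np.array([[0.0, 0.0], [100, 0], [100, 100], [0, 100]])
        assert im.coverage_fraction(pts, self.ROI, shrink=0.0) == pytest.approx(100.0)

    def test_half_field(self):
        mask = np.zeros((100, 100), bool)
        mask[:, :50] = True
        cov = im.coverage_fraction(mask, self.ROI, spacing_yx=(1, 1), shrink=0.0)
        assert cov == pytest.approx(50.0, abs=3.0)

    def test_empty_projection(self):
        assert im.coverage_fraction(np.zeros((10, 10), bool), self.ROI) == 0.0

    def test_monotone_in_added_points(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(10, 90, size=(40, 2))
        cov = [
            im.coverage_fraction(pts[:n], self.ROI, shrink=0.0) for n in (5, 10, 20, 40)
        ]
        assert all(a <= b + 1e-9 for a, b in zip(cov, cov[1:]))

    def test_requires_positive_roi(self):
        with pytest.raises(ValueError):
            im.coverage_fraction(np.ones((4, 4), bool), [(0, 0), (1, 0), (2, 0)])


class TestInternalization:
    def _clusters(self, centroids, spacing=(1.0, 1.0, 1.0)):
        import pandas as pd

        table = pd.DataFrame(
            {
                "id": range(1, len(centroids) + 1),
                "centroid_z_um": [c[0] for c in centroids],
                "centroid_y_um": [c[1] for c in centroids],
                "centroid_x_um": [c[2] for c in centroids],
                "n_voxels": 1,
            }
        )
        return im.ClusterSet(table=table, voxels={}, spacing=spacing)

    def test_three_of_ten_inside(self):
        mask = np.zeros((10, 10, 10), bool)
        mask[:3] = True
        cents = [(z + 0.5, 5, 5) for z in range(10)]
        assert im.internalization_fraction(self._clusters(cents), mask) == pytest.approx(30.0)

    def test_empty_mask_gives_zero(self):
        cents = [(1.5, 1.5, 1.5), (2.5, 2.5, 2.5)]
        mask = np.zeros((5, 5, 5), bool)
        assert im.internalization_fraction(self._clusters(cents), mask) == 0.0

    def test_empty_cluster_set_raises(self):
        with pytest.raises(im.EmptyClusterSetError):
            im.internalization_fraction(self._clusters([]), np.ones((2, 2, 2), bool))


class TestManders:
    def test_identical_masks(self):
        m = np.zeros((5, 5), bool)
        m[1:3, 1:4] = True
        res = im.manders_coefficients(m, m)
        assert (res.m1, res.m2) == (1.0, 1.0)

    def test_disjoint_masks(self):
        a = np.zeros((5, 5), bool)
        b = np.zeros((5, 5), bool)
        a[0, 0] = b[4, 4] = True
        res = im.manders_coefficients(a, b)
        assert (res.m1, res.m2) == (0.0, 0.0)

    def test_partial_overlap_arithmetic(self):
        a = np.zeros(300, bool)
        b = np.zeros(300, bool)
        a[:100] = True
        b[50:250] = True
        res = im.manders_coefficients(a, b)
        assert res.m1 == pytest.approx(0.5)
        assert res.m2 == pytest.approx(0.25)

    def test_empty_side_flagged_undefined(self):
        a = np.zeros((3, 3), bool)
        b = np.ones((3, 3), bool)
        res = im.manders_coefficients(a, b)
        assert not res.m1_defined and np.isnan(res.m1)
        assert res.m2_defined and res.m2 == 0.0

    @settings(max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_coefficients_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random((6, 6)) < 0.4
        b = rng.random((6, 6)) < 0.4
        res = im.manders_coefficients(a, b)
        for v, defined in ((res.m1, res.m1_defined), (res.m2, res.m2_defined)):
            if defined:
                assert 0.0 <= v <= 1.0

    def test_intensity_mode(self):
        a = np.array([[True, True, False]])
        b = np.array([[False, True, True]])
        ia = np.array([[10.0, 30.0, 99.0]])
        ib = np.array([[99.0, 5.0, 15.0]])
        res = im.manders_coefficients(a, b, mode="intensity", intensities_a=ia, intensities_b=ib)
        assert res.m1 == pytest.approx(30.0 / 40.0)
        assert res.m2 == pytest.approx(5.0 / 20.0)


class TestIntegratedDensity:
    SQUARE = [(2.0, 2.0), (7.0, 2.0), (7.0, 7.0), (2.0, 7.0)]

    def test_uniform_intensity(self):
        img = np.full((10, 10), 3.0)
        values, mean = im.integrated_density(img, [self.SQUARE])
        assert values[0] == mean
        assert values[0] == pytest.approx(3.0 * 36)  # 6x6 lattice points inside

    def test_sum_projection_doubles_with_two_slices(self):
        stack = np.full((2, 10, 10), 3.0)
        values, _ = im.integrated_density(stack, [self.SQUARE])
        assert values[0] == pytest.approx(2 * 3.0 * 36)

    def test_matches_per_pixel_oracle(self):
        rng = np.random.default_rng(9)
        stack = rng.random((3, 20, 20))
        poly = [(2.3, 3.1), (17.2, 2.4), (15.8, 16.9), (4.1, 14.2)]
        values, _ = im.integrated_density(stack, [poly])
        assert values[0] == pytest.approx(oracles.integrated_density(stack, poly))

    def test_roi_outside_image_raises(self):
        with pytest.raises(ValueError):
            im.integrated_density(np.ones((5, 5)), [[(0, 0), (9, 0), (9, 9)]])


class TestQuantifyParticles:
    def test_per_slice_thresholding_handles_depth_dependent_offset(self):
        from retquant import synthetic as syn

        spec = syn.StackSpec(shape_xyz=(64, 64, 30), layer_band_z=(2, 28),
                             rpe_band_z=(18, 28), n_clusters=10,
                             noise_gaussian_sd=0.0, seed=2)
        stack, _, gt = syn.generate_np_stack(spec)
        arr = stack.channel("np")
        # depth-dependent background offset defeats a single global split
        offset = np.linspace(0, 400, arr.shape[0])[:, None, None]
        shifted = im.ImageStack({"np": arr + offset}, spacing=stack.spacing)
        rep = im.quantify_particles(shifted, "np", min_voxels=1,
                                    threshold_scope="per_slice")
        assert len(rep.clusters) == len(gt.clusters)

    def test_unknown_scope_rejected(self):
        from retquant import synthetic as syn

        spec = syn.StackSpec(shape_xyz=(32, 32, 20), layer_band_z=(2, 18),
                             rpe_band_z=(12, 18), n_clusters=2, seed=1)
        stack, _, _ = syn.generate_np_stack(spec)
        with pytest.raises(ValueError):
            im.quantify_particles(stack, "np", threshold_scope="per_column")
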