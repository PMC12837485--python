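import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pvla import (
    NoMeasurableAngleError,
    NoSharedSliceError,
    PhantomConfig,
    SlicePair,
    ValidationError,
    compute_pla,
    compute_pld,
    generate_phantom,
    major_axis_direction,
    min_slice_distance,
    quantile_subset,
    slice_angle,
    slice_centroid,
    slice_support,
)
from pvla.mask_io import LA, PV

from conftest import make_volume, random_blob


def brute_force_min_distance(pv, la):
    """Independent all-pairs oracle for the per-slice minimum distance."""
    best = np.inf
    for p in pv:
        for q in la:
            best = min(best, float(np.hypot(p[0] - q[0], p[1] - q[1])))
    return best


class TestSliceSupport:
    def test_cooccurring_band(self, two_structure_volume):
        pairs = slice_support(two_structure_volume)
        assert [p.k for p in pairs] == [3, 4, 5, 6, 7]

    def test_one_structure_missing(self):
        voxels = np.zeros((4, 5, 5), dtype=np.uint8)
        voxels[:, 1, 1] = PV
        assert slice_support(make_volume(voxels)) == []

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(0)
        voxels = rng.choice([0, 0, 0, 1, 2], size=(12, 10, 10)).astype(np.uint8)
        v = make_volume(voxels)
        expected = [
            k for k in range(12)
            if (voxels[k] == PV).any() and (voxels[k] == LA).any()
        ]
        assert [p.k for p in slice_support(v)] == expected


class TestMinSliceDistance:
    @pytest.mark.parametrize(
        "pv,la,expected",
        [
            ([(5, 5)], [(5, 6)], 1.0),  # edge-adjacent
            ([(0, 0)], [(3, 4)], 5.0),  # 3-4-5 triangle
            ([(2, 2)], [(3, 3)], np.sqrt(2)),
        ],
    )
    def test_examples(self, pv, la, expected):
        pair = SlicePair(k=0, pv_pixels=np.array(pv), la_pixels=np.array(la))
        assert min_slice_distance(pair) == pytest.approx(expected)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_on_random_blobs(self, seed):
        rng = np.random.default_rng(seed)
        pv = random_blob(rng, n_pixels=50)
        la = random_blob(rng, n_pixels=50) + np.array([0, 20])
        pair = SlicePair(k=0, pv_pixels=pv, la_pixels=la)
        assert min_slice_distance(pair) == pytest.approx(
            brute_force_min_distance(pv, la), abs=1e-12
        )

    def test_empty_side_rejected(self):
        pair = SlicePair(k=0, pv_pixels=np.empty((0, 2)), la_pixels=np.array([(1, 1)]))
        with pytest.raises(ValidationError):
            min_slice_distance(pair)


class TestQuantileSubset:
    def test_q100_returns_everything(self):
        assert quantile_subset([1, 2, 3, 4], 100) == [1, 2, 3, 4]

    @pytest.mark.parametrize("q", [1, 25, 50, 99, 100])
    def test_constant_set_survives_any_q(self, q):
        assert quantile_subset([3.5, 3.5, 3.5], q) == [3.5, 3.5, 3.5]

    def test_linear_interpolation_threshold(self):
        # t_75 of {1,1,1,3} under the linear rule is 1.5, keeping {1,1,1}
        subset, t_q = quantile_subset([1, 1, 1, 3], 75, return_threshold=True)
        assert t_q == pytest.approx(1.5)
        assert subset == [1, 1, 1]

    def test_errors(self):
        with pytest.raises(ValidationError):
            quantile_subset([], 50)
        for q in (0, -1, 101):
            with pytest.raises(ValidationError):
                quantile_subset([1.0], q)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(1, 100), min_size=1, max_size=30),
        st.floats(0.5, 100),
    )
    def test_shrinking_q_never_raises_the_mean(self, distances, q):
        full = quantile_subset(distances, 100)
        sub = quantile_subset(distances, q)
        assert sub  # never empty
        assert set(sub) <= set(distances)
        assert np.mean(sub) <= np.mean(full) + 1e-12


class TestComputePLD:
    def test_touching_phantom_is_exactly_one(self, touching_phantom):
        result = compute_pld(touching_phantom, q=100)
        assert result.pld == 1.0
        assert result.n_used == len(result.distances)

    def test_rigid_6px_separation_gives_seven(self, diverged_phantom):
        assert compute_pld(diverged_phantom, q=100).pld == 7.0

    def test_matches_brute_force_per_slice(self, two_structure_volume):
        result = compute_pld(two_structure_volume, q=100)
        expected = []
        for pair in slice_support(two_structure_volume):
            expected.append(brute_force_min_distance(pair.pv_pixels, pair.la_pixels))
        assert result.pld == pytest.approx(np.mean(expected), abs=1e-12)

    def test_pv_only_volume_raises_with_ranges(self):
        voxels = np.zeros((4, 5, 5), dtype=np.uint8)
        voxels[1:3, 1, 1] = PV
        with pytest.raises(NoSharedSliceError) as exc:
            compute_pld(make_volume(voxels))
        assert exc.value.pv_slices == (2, 3)  # 1-based
        assert exc.value.la_slices is None

    def test_lower_bound_and_translation_invariance(self):
        rng = np.random.default_rng(1)
        voxels = rng.choice([0, 0, 1, 2], size=(6, 20, 20)).astype(np.uint8)
        v = make_volume(voxels)
        base = compute_pld(v).pld
        assert base >= 1.0
        # embedding at an offset is a rigid in-plane translation of both masks
        voxels2 = np.zeros((6, 30, 30), dtype=np.uint8)
        voxels2[:, 4:24, 5:25] = voxels
        assert compute_pld(make_volume(voxels2)).pld == pytest.approx(base)
        assert compute_pld(make_volume(voxels[::-1])).pld == pytest.approx(base)

    def test_monotone_in_rigid_separation(self):
        plds = [
            compute_pld(generate_phantom(PhantomConfig(gap=g, angle=0.0))).pld
            for g in (0, 2, 4, 8)
        ]
        assert all(a <= b for a, b in zip(plds, plds[1:]))


class TestCentroidAndAxis:
    def test_centroid_examples(self):
        assert slice_centroid(np.array([(0, 0)])) == (0.0, 0.0)
        assert slice_centroid(np.array([(0, 0), (0, 2)])) == (0.0, 1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_centroid_matches_summation(self, seed):
        rng = np.random.default_rng(seed)
        blob = random_blob(rng, n_pixels=40)
        r, c = slice_centroid(blob)
        assert r == pytest.approx(sum(p[0] for p in blob) / len(blob))
        assert c == pytest.approx(sum(p[1] for p in blob) / len(blob))

    def test_horizontal_bar_axis_is_column_direction(self):
        bar = np.array([(5, c) for c in range(9)])
        axis = major_axis_direction(bar)
        assert abs(axis[1]) == pytest.approx(1.0)
        assert axis[0] == pytest.approx(0.0, abs=1e-12)

    def test_filled_square_is_degenerate(self):
        square = np.array([(r, c) for r in range(5) for c in range(5)])
        assert major_axis_direction(square) is None

    def test_single_pixel_is_degenerate(self):
        assert major_axis_direction(np.array([(3, 3)])) is None

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_eigendecomposition_oracle(self, seed):
        rng = np.random.default_rng(seed)
        # anisotropic cloud: stretch a random blob 3x along the columns
        blob = random_blob(rng, n_pixels=60)
        blob = np.column_stack([blob[:, 0], blob[:, 1] * 3])
        axis = major_axis_direction(blob)
        cov = np.cov(blob.astype(float).T, bias=True)
        eigvals, eigvecs = np.linalg.eigh(cov)
        expected = eigvecs[:, np.argmax(eigvals)]
        assert abs(float(np.dot(axis, expected))) == pytest.approx(1.0, abs=1e-9)

    def test_axis_symmetric_under_180_rotation(self):
        rng = np.random.default_rng(7)
        blob = random_blob(rng, n_pixels=60)
        blob = np.column_stack([blob[:, 0], blob[:, 1] * 2])
        axis = major_axis_direction(blob)
        center = blob.mean(axis=0)
        rotated = np.round(2 * center - blob).astype(int)
        axis_rot = major_axis_direction(rotated)
        assert abs(float(np.dot(axis, axis_rot))) == pytest.approx(1.0, abs=1e-9)


class TestSliceAngle:
    def _bar_pair(self, displacement):
        bar = np.array([(10, c) for c in range(5, 14)])  # centroid (10, 9)
        la = np.array([(10 + displacement[0], 9 + displacement[1])])
        return SlicePair(k=0, pv_pixels=bar, la_pixels=la)

    def test_row_displacement_is_90(self):
        theta, reason = slice_angle(self._bar_pair((7, 0)))
        assert reason is None and theta == 90.0

    def test_column_displacement_is_0(self):
        theta, reason = slice_angle(self._bar_pair((0, 7)))
        assert reason is None and theta == 0.0

    def test_raw_120_folds_to_60(self):
        # displacement at 120 deg from the column axis: (sin 120, cos 120)
        d = 20 * np.array([np.sin(np.radians(120)), np.cos(np.radians(120))])
        bar = np.array([(50.0, c) for c in np.arange(40, 61)])
        pair = SlicePair(
            k=0,
            pv_pixels=bar.astype(int),
            la_pixels=np.round(np.array([50, 50]) + d).astype(int)[None, :],
        )
        theta, _ = slice_angle(pair)
        assert theta == pytest.approx(60.0, abs=1.5)  # rounding of the LA pixel

    def test_isotropic_pv_flagged(self):
        square = np.array([(r, c) for r in range(5) for c in range(5)])
        pair = SlicePair(k=0, pv_pixels=square, la_pixels=np.array([(20, 20)]))
        theta, reason = slice_angle(pair)
        assert theta is None and reason == "isotropic-pv"

    def test_coincident_centroids_flagged(self):
        bar = np.array([(5, c) for c in range(3, 8)])
        pair = SlicePair(k=0, pv_pixels=bar, la_pixels=np.array([(5, 5)]))
        theta, reason = slice_angle(pair)
        assert theta is None and reason == "coincident-centroids"


class TestComputePLA:
    def test_constructed_30_degrees(self):
        v = generate_phantom(PhantomConfig(gap=2.0, angle=30.0))
        result = compute_pla(v)
        assert result.pla == pytest.approx(30.0, abs=2.0)
        # every used angle agrees with a per-slice arccos oracle
        for (k, theta), pair in zip(result.angles, slice_support(v)):
            axis = major_axis_direction(pair.pv_pixels)
            link = np.array(slice_centroid(pair.la_pixels)) - np.array(
                slice_centroid(pair.pv_pixels)
            )
            expected = np.degrees(
                np.arccos(abs(np.dot(link / np.linalg.norm(link), axis)))
            )
            assert theta == pytest.approx(expected, abs=1e-9)

    def test_mean_of_mixed_slices(self):
        lo = generate_phantom(PhantomConfig(gap=2.0, angle=10.0, shared_slices=4))
        hi = generate_phantom(PhantomConfig(gap=2.0, angle=50.0, shared_slices=4))
        voxels = np.concatenate([lo.voxels[4:8], hi.voxels[4:8]])
        result = compute_pla(make_volume(voxels))
        per_slice = [a for _, a in result.angles]
        assert result.pla == pytest.approx(np.mean(per_slice), abs=1e-12)
        assert result.pla == pytest.approx(30.0, abs=2.0)

    def test_isotropic_pv_everywhere_raises(self):
        voxels = np.zeros((4, 20, 20), dtype=np.uint8)
        voxels[:, 2:7, 2:7] = PV  # 5x5 squares: no major axis
        voxels[:, 10:14, 10:14] = LA
        with pytest.raises(NoMeasurableAngleError):
            compute_pla(make_volume(voxels))

    def test_range_and_exclusion_bookkeeping(self):
        rng = np.random.default_rng(3)
        voxels = rng.choice([0, 0, 0, 1, 2], size=(10, 15, 15)).astype(np.uint8)
        result = compute_pla(make_volume(voxels))
        assert all(0 <= a <= 90 for _, a in result.angles)
        assert result.n_used == len(result.angles)
        used_ks = {k for k, _ in result.angles} | {k for k, _ in result.excluded}
        assert used_ks == {p.k + 1 for p in slice_support(make_volume(voxels))}
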