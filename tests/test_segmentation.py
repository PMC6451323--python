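import numpy as np
import pytest
from skimage.filters import threshold_triangle

from zvasc.features import ChannelVolume, compute_feature_stack
from zvasc.segmentation import (
    BinaryMask,
    SegmentationConfig,
    SegmentationStageError,
    dice_coefficient,
    fit_feature_weights,
    luminal_proxy,
    morphological_cleanup,
    sample_training_points,
    score_volume,
    segment_volume,
    triangle_threshold,
)


class TestLuminalProxy:
    def test_empty_rbc_channel_gives_empty_mask(self):
        rbc = ChannelVolume(np.zeros((10, 10, 10)), channel="rbc")
        with pytest.warns(UserWarning, match="flat"):
            mask = luminal_proxy(rbc)
        assert mask.count() == 0

    def test_foreground_contained_in_true_lumen(self, small_phantom):
        mask = luminal_proxy(small_phantom.rbc)
        inside = (mask.voxels & small_phantom.truth_lumen).sum()
        assert inside / mask.count() >= 0.95

    def test_invariant_under_affine_intensity_rescaling(self, small_phantom):
        rbc = small_phantom.rbc
        rescaled = ChannelVolume(3.0 * rbc.intensities + 17.0,
                                 rbc.voxel_spacing, "rbc")
        a = luminal_proxy(rbc)
        b = luminal_proxy(rescaled)
        assert np.array_equal(a.voxels, b.voxels)

    def test_wrong_channel_tag_rejected(self, small_phantom):
        with pytest.raises(ValueError, match="rbc"):
            luminal_proxy(small_phantom.endothelial)


class TestTrainingSampling:
    def test_collects_exactly_n_per_class(self, small_phantom):
        lumen = luminal_proxy(small_phantom.rbc)
        ts = sample_training_points(small_phantom.endothelial, lumen, N=500, seed=0)
        assert ts.n_positive == 500 and ts.n_negative == 500
        assert not ts.shortfall
        # all coordinates distinct
        assert len(np.unique(ts.coordinates, axis=0)) == len(ts.coordinates)

    def test_empty_lumen_sets_shortfall_with_zero_positives(self, small_phantom):
        empty = BinaryMask(np.zeros(small_phantom.endothelial.shape, bool))
        ts = sample_training_points(small_phantom.endothelial, empty, N=100, seed=0)
        assert ts.shortfall and ts.n_positive == 0

    def test_same_seed_reproduces_coordinates(self, small_phantom):
        lumen = luminal_proxy(small_phantom.rbc)
        a = sample_training_points(small_phantom.endothelial, lumen, 200, seed=5)
        b = sample_training_points(small_phantom.endothelial, lumen, 200, seed=5)
        assert np.array_equal(a.coordinates, b.coordinates)

    def test_labels_match_lumen_membership(self, small_phantom):
        lumen = luminal_proxy(small_phantom.rbc)
        ts = sample_training_points(small_phantom.endothelial, lumen, 300, seed=1)
        membership = lumen.voxels[tuple(ts.coordinates.T)]
        assert np.array_equal(membership, ts.labels.astype(bool))


class TestWeightFit:
    def _training(self, phantom, n=400, seed=2):
        lumen = luminal_proxy(phantom.rbc)
        return sample_training_points(phantom.endothelial, lumen, n, seed=seed)

    def test_binary_raw_feature_target_fits_exactly(self):
        # labels equal the (binary) raw feature itself: the solve must
        # place all weight on that column (scaled by its standardization),
        # zero on the rest, with zero residual
        rng = np.random.default_rng(4)
        from zvasc.features import FeatureStack
        from zvasc.segmentation import TrainingSet

        raw = (rng.uniform(size=(12, 12, 12)) > 0.5).astype(float)
        others = [rng.normal(size=raw.shape) for _ in range(5)]
        fs = FeatureStack(raw, others[0], others[1], others[2],
                          np.abs(others[3]), np.abs(others[4]))
        coords = np.argwhere(np.ones_like(raw, dtype=bool))[
            rng.permutation(raw.size)[:400]]
        labels = raw[tuple(coords.T)].astype(np.int8)
        ts = TrainingSet(coords, labels, n_per_class=int(labels.sum()))
        model = fit_feature_weights(fs, ts)
        assert model.weights[0] == pytest.approx(fs.sds[0], rel=1e-8)
        assert np.allclose(model.weights[1:6], 0.0, atol=1e-8)
        assert model.training_summary["fit_residual"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_dense_pseudoinverse_oracle(self, small_phantom):
        ts = self._training(small_phantom)
        fs = compute_feature_stack(small_phantom.endothelial)
        model = fit_feature_weights(fs, ts)
        X = np.hstack([fs.standardized_at(ts.coordinates),
                       np.ones((len(ts.coordinates), 1))])
        oracle = np.linalg.pinv(X) @ ts.labels.astype(float)
        assert np.allclose(model.weights, oracle, rtol=1e-8, atol=1e-10)

    def test_rank_deficient_system_matches_oracle(self):
        # a volume whose x and y extents mirror each other makes grad_x and
        # grad_y identical up to transpose; duplicate features directly:
        rng = np.random.default_rng(0)
        X6 = rng.normal(size=(50, 6))
        X6[:, 3] = X6[:, 2]  # duplicated feature -> rank deficiency
        y = rng.integers(0, 2, 50).astype(float)
        X = np.hstack([X6, np.ones((50, 1))])
        lstsq = np.linalg.lstsq(X, y, rcond=None)[0]
        oracle = np.linalg.pinv(X) @ y
        assert np.allclose(lstsq, oracle, atol=1e-10)

    def test_label_swap_mirrors_predictions(self, small_phantom):
        ts = self._training(small_phantom)
        fs = compute_feature_stack(small_phantom.endothelial)
        model = fit_feature_weights(fs, ts)
        ts.labels = 1 - ts.labels
        swapped = fit_feature_weights(fs, ts)
        X = np.hstack([fs.standardized_at(ts.coordinates),
                       np.ones((len(ts.coordinates), 1))])
        assert np.allclose(X @ swapped.weights, 1.0 - X @ model.weights)

    def test_single_class_training_rejected(self, small_phantom):
        ts = self._training(small_phantom)
        ts.labels[:] = 1
        fs = compute_feature_stack(small_phantom.endothelial)
        with pytest.raises(ValueError, match="both classes"):
            fit_feature_weights(fs, ts)


class TestScoring:
    def test_zero_weights_give_constant_bias(self, small_phantom):
        fs = compute_feature_stack(small_phantom.endothelial)
        from zvasc.segmentation import SegmentationModel

        model = SegmentationModel(
            np.array([0, 0, 0, 0, 0, 0, 2.5]), fs.means, fs.sds
        )
        score = score_volume(fs, model)
        assert np.all(score == 2.5)

    def test_score_at_training_point_equals_fit_row_product(self, small_phantom):
        lumen = luminal_proxy(small_phantom.rbc)
        ts = sample_training_points(small_phantom.endothelial, lumen, 100, seed=3)
        fs = compute_feature_stack(small_phantom.endothelial)
        model = fit_feature_weights(fs, ts)
        score = score_volume(fs, model)
        X = np.hstack([fs.standardized_at(ts.coordinates),
                       np.ones((len(ts.coordinates), 1))])
        assert np.allclose(score[tuple(ts.coordinates.T)], X @ model.weights)

    def test_doubling_weights_doubles_scores(self, small_phantom):
        lumen = luminal_proxy(small_phantom.rbc)
        ts = sample_training_points(small_phantom.endothelial, lumen, 100, seed=3)
        fs = compute_feature_stack(small_phantom.endothelial)
        model = fit_feature_weights(fs, ts)
        doubled = type(model)(2 * model.weights, model.feature_means,
                              model.feature_sds)
        assert np.allclose(
            score_volume(fs, doubled), 2 * score_volume(fs, model)
        )


class TestTriangleThreshold:
    def test_spike_and_far_tail(self):
        # line from (0,100) to (4,10): distances at bins 1,2,3 are
        # 77.5, 55, 32.5 -> bin 1 maximizes
        assert triangle_threshold([100, 0, 0, 0, 10]) == (1, False)

    def test_reversed_histogram_gives_mirrored_threshold(self):
        h = [100, 0, 0, 0, 10]
        idx, _ = triangle_threshold(h)
        idx_m, _ = triangle_threshold(h[::-1])
        assert idx_m == len(h) - 1 - idx

    def test_symmetric_histogram_threshold_is_tail_symmetric(self):
        # both tails are equivalent by symmetry: the threshold must land
        # at one of the two mirror-image bins
        h = [10, 0, 100, 0, 10]
        idx, _ = triangle_threshold(h)
        assert idx in (1, 3)

    def test_single_spike_degenerate(self):
        assert triangle_threshold([0, 50, 0]) == (1, True)

    def test_agrees_with_reference_implementation(self):
        rng = np.random.default_rng(0)
        checked = 0
        for _ in range(50):
            n_bins = int(rng.integers(16, 128))
            counts = np.zeros(n_bins, dtype=int)
            # unimodal-ish histogram: background peak + signal tail
            peak = int(rng.integers(0, n_bins // 3))
            counts[peak] = int(rng.integers(500, 5000))
            tail = rng.integers(0, 40, size=n_bins)
            decay = np.exp(-np.arange(n_bins) / rng.uniform(3, 20))
            counts = counts + (tail * np.roll(decay, peak)).astype(int)
            data = np.repeat(np.arange(n_bins), counts)
            ours, _ = triangle_threshold(counts)
            ref = threshold_triangle(data, nbins=n_bins)
            assert ours == ref, (counts.tolist(), ours, ref)
            checked += 1
        assert checked == 50


class TestMorphologicalCleanup:
    def test_isolated_voxel_removed(self):
        m = np.zeros((9, 9, 9), bool)
        m[4, 4, 4] = True
        assert morphological_cleanup(BinaryMask(m)).count() == 0

    def test_solid_cube_preserved(self):
        m = np.zeros((14, 14, 14), bool)
        m[2:12, 2:12, 2:12] = True
        out = morphological_cleanup(BinaryMask(m))
        # opening of a large solid keeps its body intact and adds nothing
        assert out.voxels[3:11, 3:11, 3:11].all()
        assert not np.any(out.voxels & ~m)

    def test_empty_mask_unchanged(self):
        m = BinaryMask(np.zeros((5, 5, 5), bool))
        assert morphological_cleanup(m).count() == 0


class TestSegmentVolume:
    def test_phantom_mask_overlaps_truth(self, small_phantom):
        mask, model = segment_volume(
            small_phantom.endothelial, small_phantom.rbc,
            SegmentationConfig(n_samples=2000, seed=0),
        )
        assert dice_coefficient(mask.voxels, small_phantom.truth_vessel) >= 0.8
        cov = (mask.voxels & small_phantom.truth_lumen).sum()
        assert cov / small_phantom.truth_lumen.sum() >= 0.9
        assert model.score_threshold is not None

    def test_empty_rbc_channel_fails_at_training_stage(self, small_phantom):
        empty = ChannelVolume(np.zeros(small_phantom.rbc.shape),
                              small_phantom.rbc.voxel_spacing, "rbc")
        with pytest.raises(SegmentationStageError) as err:
            with pytest.warns(UserWarning, match="flat"):
                segment_volume(small_phantom.endothelial, empty)
        assert err.value.stage == "training"

    def test_fixed_seed_reproduces_mask(self, small_phantom):
        cfg = SegmentationConfig(n_samples=1000, seed=11)
        a, _ = segment_volume(small_phantom.endothelial, small_phantom.rbc, cfg)
        b, _ = segment_volume(small_phantom.endothelial, small_phantom.rbc, cfg)
        assert np.array_equal(a.voxels, b.voxels)
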