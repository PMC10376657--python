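"""CNN architecture family, data split, training and prediction."""

import numpy as np
import pytest

from dipmap.cnn import (
    SUPPORTED_DEPTHS,
    CnnClassifier,
    TrainConfig,
    build_architecture,
    predict,
    split_dataset,
    train,
)

from conftest import make_image_dataset, make_quadrant_dataset


class TestArchitecture:
    @pytest.mark.parametrize("depth,k_blocks", [(16, 3), (19, 4), (22, 5), (25, 6)])
    def test_layer_count_and_conv_blocks(self, depth, k_blocks):
        arch = build_architecture(depth)
        assert arch.depth == depth
        assert len(arch.layers) == depth
        assert arch.n_conv_blocks == k_blocks
        types = [l.type for l in arch.layers]
        assert types[0] == "input"
        assert types[-3:] == ["fully-connected", "softmax", "classification-output"]
        assert types.count("cross-channel-normalization") == 2
        assert types.count("dropout") == 1

    @pytest.mark.parametrize("depth", SUPPORTED_DEPTHS)
    def test_spatial_map_stays_at_least_one_pixel(self, depth):
        arch = build_architecture(depth, input_size=227)
        trace = arch.shape_trace()
        assert all(h >= 1 and w >= 1 for h, w, _ in trace)
        assert trace[-1][2] == 2  # two-way output

    def test_filter_widths_double_and_cap(self):
        arch = build_architecture(25, base_filters=8, max_filters=128)
        filters = [l.options["filters"] for l in arch.layers if l.type == "convolution"]
        assert filters == [8, 16, 32, 64, 128, 128]

    def test_unsupported_depth_rejected_with_message(self):
        with pytest.raises(ValueError, match=r"16.*19.*22.*25"):
            build_architecture(17)

    def test_too_small_input_rejected(self):
        with pytest.raises(ValueError, match="collapses"):
            build_architecture(25, input_size=48)

    def test_dict_roundtrip(self):
        arch = build_architecture(22)
        from dipmap.cnn import CnnArchitecture

        back = CnnArchitecture.from_dict(arch.to_dict())
        assert back == arch


class TestSplit:
    def test_full_design_split_counts(self):
        ds = make_image_dataset(528, size=4)
        train_ds, val_ds = split_dataset(ds, ratio=0.7, seed=0)
        for cls in ("RHTF", "RHLF"):
            assert (train_ds.labels == cls).sum() == 370
            assert (val_ds.labels == cls).sum() == 158

    def test_all_train_split(self):
        ds = make_image_dataset(10, size=4)
        train_ds, val_ds = split_dataset(ds, ratio=1.0, seed=0)
        assert len(train_ds) == 20 and len(val_ds) == 0

    def test_different_seeds_same_counts_different_members(self):
        ds = make_image_dataset(50, size=4)
        t1, v1 = split_dataset(ds, 0.7, seed=1)
        t2, v2 = split_dataset(ds, 0.7, seed=2)
        assert len(t1) == len(t2) and len(v1) == len(v2)
        assert not np.array_equal(t1.images, t2.images)

    def test_split_is_disjoint_and_exhaustive(self):
        ds = make_image_dataset(33, size=4, seed=3)
        tr, va = split_dataset(ds, 0.7, seed=5)
        key = lambda d: {d.images[i].tobytes() for i in range(len(d))}
        assert key(tr) | key(va) == key(ds)
        assert not key(tr) & key(va)

    def test_tiny_class_rejected(self):
        ds = make_image_dataset(1, size=4)
        with pytest.raises(ValueError):
            split_dataset(ds, 0.7, seed=0)

    def test_grouped_split_keeps_subjects_on_one_side(self):
        ds = make_image_dataset(30, size=4, n_subjects=5)
        tr, va = split_dataset(ds, 0.6, seed=0, group_by_subject=True)
        assert set(tr.meta["subject"]) & set(va.meta["subject"]) == set()


@pytest.fixture(scope="module")
def toy_training():
    """Depth-16 net trained on the separable quadrant set (shared)."""
    ds = make_quadrant_dataset(100, size=56)
    tr, va = split_dataset(ds, 0.7, seed=1)
    arch = build_architecture(16, input_size=56, base_filters=8, max_filters=64)
    cfg = TrainConfig(epochs=20, seed=0)
    model, history = train(arch, tr, cfg)
    return model, history, tr, va, arch, cfg


class TestTraining:
    def test_toy_set_reaches_perfect_validation(self, toy_training):
        model, _, _, va, _, _ = toy_training
        assert model.score(va) == 1.0

    def test_loss_non_increasing_over_epoch_windows(self, toy_training):
        _, history, *_ = toy_training
        loss = np.array(history.loss)
        means = loss.reshape(4, 5).mean(axis=1)  # 5-epoch averages
        assert np.all(np.diff(means) <= 1e-6)

    def test_training_is_deterministic_for_fixed_seed(self, toy_training):
        model, history, tr, _, arch, cfg = toy_training
        model2, history2 = train(arch, tr, cfg)
        np.testing.assert_allclose(history2.loss, history.loss, rtol=1e-6)
        np.testing.assert_allclose(history2.accuracy, history.accuracy, rtol=1e-6)

    def test_zero_epochs_returns_untrained_model_at_chance(self):
        # structureless images: label-independent, so an untrained net
        # cannot do better than coin-flipping
        ds = make_image_dataset(100, size=56, seed=2)
        arch = build_architecture(16, input_size=56, base_filters=4, max_filters=16)
        model, history = train(arch, ds, TrainConfig(epochs=0, seed=0))
        assert history.loss == [] and history.accuracy == []
        acc = model.score(ds)
        # binomial 99% interval around 0.5 at n = 200
        half_width = 2.576 * np.sqrt(0.25 / len(ds))
        assert abs(acc - 0.5) <= half_width

    def test_class_count_mismatch_rejected(self):
        ds = make_image_dataset(5, size=56)
        ds.labels[:] = "RHTF"
        ds.meta["label"] = "RHTF"
        arch = build_architecture(16, input_size=56, base_filters=4, max_filters=16)
        model = CnnClassifier(arch, seed=0)
        with pytest.raises(ValueError):
            model.fit(ds, TrainConfig(epochs=1))


class TestPrediction:
    def test_scores_sum_to_one_single_image(self, toy_training):
        model, *_ = toy_training
        ds = make_quadrant_dataset(1, size=56, seed=9)
        labels, scores = predict(model, ds.images[:1])
        assert labels.shape == (1,)
        assert scores.shape == (1, 2)
        assert scores.sum() == pytest.approx(1.0, abs=1e-6)

    def test_batch_invariance(self, toy_training):
        model, _, _, va, _, _ = toy_training
        batch_scores = model.predict_proba(va.images)
        single = np.concatenate([
            model.predict_proba(va.images[i : i + 1]) for i in range(len(va))
        ])
        np.testing.assert_allclose(single, batch_scores, atol=1e-6)

    def test_wrong_image_size_rejected(self, toy_training):
        model, *_ = toy_training
        with pytest.raises(ValueError):
            model.predict_proba(np.zeros((1, 28, 28, 3), dtype=np.float32))


class TestTrainConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(epochs=-1)
        with pytest.raises(ValueError):
            TrainConfig(learn_rate=0.0)
        with pytest.raises(ValueError):
            TrainConfig(momentum=1.0)
        with pytest.raises(ValueError):
            TrainConfig(solver="adam")
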