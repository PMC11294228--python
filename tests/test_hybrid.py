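"""Hybrid estimator: projection contract, split-arm network, training."""

import numpy as np
import pytest

from mfkit.dictionary import rotate_dictionary
from mfkit.hybrid import (
    HybridConfig,
    NNLSWeights,
    TrainedRegressor,
    compute_weight_features,
    hybrid_predict,
    hybrid_predict_batch,
    nnls_projection,
    train_hybrid,
)
from mfkit.synthdata import SynthConfig, generate_dataset


@pytest.fixture(scope="module")
def tiny_train(tiny_dictionary):
    return generate_dataset(120, tiny_dictionary, SynthConfig(K=2), seed=0).sorted_by_nu()


@pytest.fixture(scope="module")
def tiny_model(tiny_train, tiny_dictionary):
    cfg = HybridConfig(arm_width=16, hidden=(32, 16), epochs=60, batch_size=32)
    return train_hybrid(tiny_train, tiny_dictionary, cfg, seed=1)


class TestProjection:
    def test_zero_signal_zero_weights(self, tiny_dictionary):
        design = rotate_dictionary(
            tiny_dictionary, np.array([[0.0, 0.0, 1.0], [1.0, 0.0, 0.0]])
        )
        y = np.zeros(tiny_dictionary.scheme.M)
        y[tiny_dictionary.scheme.b0_mask] = 1.0  # keep normalization defined
        w = nnls_projection(y, design)
        assert w.w.shape == (2 * tiny_dictionary.N,)
        assert np.all(w.w >= 0)

    def test_single_atom_reconstruction(self, tiny_dictionary):
        design = rotate_dictionary(
            tiny_dictionary, np.array([[0.0, 0.0, 1.0], [1.0, 0.0, 0.0]])
        )
        y = design.blocks[0][:, 3].copy()
        w = nnls_projection(y, design)
        assert w.residual < 1e-8
        assert np.allclose(design.matrix @ w.w, y, atol=1e-8)

    def test_exactly_one_solve(self, tiny_dictionary):
        design = rotate_dictionary(
            tiny_dictionary, np.array([[0.0, 0.0, 1.0], [0.0, 1.0, 0.0]])
        )
        y = design.blocks[1][:, 0]
        assert nnls_projection(y, design).n_nnls_solves == 1

    def test_weight_layout_validation(self):
        with pytest.raises(ValueError):
            NNLSWeights(w=np.zeros(5), block_layout=(2, 3))
        with pytest.raises(ValueError):
            NNLSWeights(w=-np.ones(6), block_layout=(2, 3))


class TestPredict:
    def test_outputs_in_range_and_normalized(self, tiny_model, tiny_dictionary):
        rng = np.random.default_rng(0)
        w = rng.uniform(0, 0.5, size=(40, 2 * tiny_dictionary.N))
        pred = hybrid_predict_batch(tiny_model, w)
        assert np.allclose(pred["nu"].sum(axis=1), 1.0, atol=1e-9)
        p = tiny_dictionary.params
        assert np.all(pred["fvf"] >= p["fvf"].min()) and np.all(pred["fvf"] <= p["fvf"].max())
        assert np.all(pred["dex"] >= p["dex"].min()) and np.all(pred["dex"] <= p["dex"].max())

    def test_single_voxel_wrapper(self, tiny_model, tiny_dictionary):
        w = NNLSWeights(
            w=np.random.default_rng(1).uniform(0, 0.3, 2 * tiny_dictionary.N),
            block_layout=(2, tiny_dictionary.N),
        )
        est = hybrid_predict(tiny_model, w)
        assert est.K == 2
        assert abs(est.nu.sum() - 1.0) < 1e-9

    def test_shape_mismatch_is_error(self, tiny_model):
        with pytest.raises(ValueError):
            hybrid_predict_batch(tiny_model, np.zeros((3, 7)))

    def test_shared_arms_symmetric_representation(self, tiny_dictionary, tiny_train):
        # weight-sharing arms: identical weight blocks produce identical
        # per-arm representations (the trunk may still break the symmetry)
        cfg = HybridConfig(arm_width=8, hidden=(16,), epochs=2, shared_arms=True)
        model = train_hybrid(tiny_train, tiny_dictionary, cfg, seed=0)
        N = tiny_dictionary.N
        w_half = np.random.default_rng(2).uniform(0, 0.4, N)
        w = np.concatenate([w_half, w_half])[None, :]
        model.net.forward_cached(model.standardize(w), train=False)
        pre = model.net._pre[0]
        A = cfg.arm_width
        # standardization is per-feature, so feed the raw shared-arm path
        net = model.net
        x = np.concatenate([w_half, w_half])[None, :]
        h1 = x[:, :N] @ net.arms[0].W + net.arms[0].b
        h2 = x[:, N:] @ net.arms[1].W + net.arms[1].b
        assert np.allclose(h1, h2)
        assert net.arms[0] is net.arms[1]

    def test_scale_invariance_after_b0_normalization(self, tiny_model, tiny_dictionary, tiny_train):
        design = rotate_dictionary(tiny_dictionary, tiny_train.orientations[0])
        y = tiny_train.y[0]
        w1 = nnls_projection(y, design)
        w2 = nnls_projection(7.5 * y, design)
        assert np.allclose(w1.w, w2.w, atol=1e-8)
        e1 = hybrid_predict(tiny_model, w1)
        e2 = hybrid_predict(tiny_model, w2)
        assert np.allclose(e1.nu, e2.nu, atol=1e-9)


class TestTraining:
    def test_determinism(self, tiny_train, tiny_dictionary, tmp_path):
        cfg = HybridConfig(arm_width=8, hidden=(16,), epochs=3)
        a = train_hybrid(tiny_train, tiny_dictionary, cfg, seed=5)
        b = train_hybrid(tiny_train, tiny_dictionary, cfg, seed=5)
        a.save(tmp_path / "a.npz")
        b.save(tmp_path / "b.npz")
        assert (tmp_path / "a.npz").read_bytes() == (tmp_path / "b.npz").read_bytes()

    def test_loss_decreases(self, tiny_model):
        losses = tiny_model.training_meta["loss_per_epoch"]
        assert losses[4] < losses[0]

    def test_overfits_small_dataset(self, tiny_train, tiny_dictionary):
        cfg = HybridConfig(arm_width=32, hidden=(64, 32), epochs=600,
                           dropout_keep=1.0, lr=2e-3, lr_decay=1.0, batch_size=10)
        sub = tiny_train.subset(np.arange(40))
        model = train_hybrid(sub, tiny_dictionary, cfg, seed=2)
        assert model.training_meta["loss_per_epoch"][-1] < 1e-3

    def test_empty_dataset_is_error(self, tiny_train, tiny_dictionary):
        with pytest.raises(ValueError):
            train_hybrid(tiny_train.subset(np.arange(0)), tiny_dictionary)

    def test_save_load_round_trip(self, tiny_model, tiny_dictionary, tmp_path):
        tiny_model.save(tmp_path / "m.npz")
        back = TrainedRegressor.load(tmp_path / "m.npz")
        w = np.random.default_rng(3).uniform(0, 0.5, (7, 2 * tiny_dictionary.N))
        a = hybrid_predict_batch(tiny_model, w)
        b = hybrid_predict_batch(back, w)
        for key in a:
            assert np.array_equal(a[key], b[key])
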