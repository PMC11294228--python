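"""Fully-learned estimator: SH basis/fit, orientation head, training."""

import numpy as np
import pytest

from mfkit.fully_learned import (
    FLConfig,
    _FLNet,
    featurize_dataset,
    fit_sh_per_shell,
    fl_predict,
    fl_predict_batch,
    real_even_sh_basis,
    train_fl,
)
from mfkit.hybrid import TrainedRegressor
from mfkit.protocol import repulsion_directions
from mfkit.synthdata import SynthConfig, generate_dataset


class TestSHBasis:
    def test_91_coefficients_at_lmax12(self):
        dirs = repulsion_directions(20, seed=0)
        B = real_even_sh_basis(dirs, lmax=12)
        assert B.shape == (20, 91)

    def test_l0_column_constant(self):
        dirs = repulsion_directions(15, seed=1)
        B = real_even_sh_basis(dirs, lmax=4)
        assert np.allclose(B[:, 0], 1.0 / np.sqrt(4 * np.pi))

    def test_orthonormal_under_uniform_quadrature(self):
        rng = np.random.default_rng(0)
        dirs = rng.normal(size=(10000, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        B = real_even_sh_basis(dirs, lmax=6)
        gram = B.T @ B * (4 * np.pi / len(dirs))
        assert np.allclose(gram, np.eye(B.shape[1]), atol=1e-1)
        assert np.abs(gram - np.eye(B.shape[1])).mean() < 1e-2

    def test_odd_lmax_rejected(self):
        with pytest.raises(ValueError):
            real_even_sh_basis(np.array([[0.0, 0.0, 1.0]]), lmax=5)


class TestSHFit:
    def test_band_limited_round_trip(self, hcp_scheme):
        # synthesize a random l<=12 signal on the 256-direction shell and
        # recover its coefficients without regularization
        rng = np.random.default_rng(2)
        sid, b, idx = [s for s in hcp_scheme.shells()][-1]
        assert len(idx) == 256
        coeffs_true = rng.normal(size=91) * np.exp(-0.1 * np.arange(91))
        B = real_even_sh_basis(hcp_scheme.directions[idx], 12)
        y = np.zeros(hcp_scheme.M)
        y[idx] = B @ coeffs_true
        feats = fit_sh_per_shell(y, hcp_scheme, lmax=12, lambda_reg=0.0)
        got = feats.coefficients[-1]
        assert np.allclose(got, coeffs_true, atol=1e-8)

    def test_isotropic_signal_only_l0(self, hcp_scheme):
        # overdetermined fits (lmax=6 has 28 coeffs < 64 directions): a
        # constant shell signal loads only the l=0 coefficient
        y = np.full(hcp_scheme.M, 0.37)
        feats = fit_sh_per_shell(y, hcp_scheme, lmax=6, lambda_reg=0.0)
        for c in feats.coefficients:
            assert abs(c[0] - 0.37 * np.sqrt(4 * np.pi)) < 1e-8
            assert np.all(np.abs(c[1:]) < 1e-8)

    def test_robust_to_dropped_measurements(self, hcp_scheme):
        # removing 10% of the largest shell changes coefficients < 5% RMS
        from mfkit.protocol import subset

        rng = np.random.default_rng(3)
        from mfkit.dictionary import SubstrateConfig, analytic_fingerprint

        cfg = SubstrateConfig(fvf=0.5, d_ex=1.2)
        u = np.array([0.3, -0.5, 0.81])
        u /= np.linalg.norm(u)
        y = analytic_fingerprint(cfg, hcp_scheme, u)
        full = fit_sh_per_shell(y, hcp_scheme, 12, 1e-3).vector
        keep = np.ones(hcp_scheme.M, dtype=bool)
        _, _, idx = [s for s in hcp_scheme.shells()][-1]
        drop = rng.choice(idx, size=len(idx) // 10, replace=False)
        keep[drop] = False
        sub_scheme = subset(hcp_scheme, np.flatnonzero(keep))
        sub = fit_sh_per_shell(y[keep], sub_scheme, 12, 1e-3).vector
        rel = np.linalg.norm(sub - full) / np.linalg.norm(full)
        assert rel < 0.05

    def test_small_shell_is_error(self, tiny_scheme):
        import dataclasses

        from mfkit.protocol import AcquisitionScheme

        dirs = np.concatenate([np.zeros((1, 3)), repulsion_directions(4, seed=0)])
        bv = np.array([0.0, 1000, 1000, 1000, 1000.0])
        s = AcquisitionScheme(directions=dirs, bvalues=bv, delta_small=12.9,
                              delta_big=21.8)
        with pytest.raises(ValueError):
            fit_sh_per_shell(np.ones(5), s, lmax=4, lambda_reg=1e-3)

    def test_permutation_invariance_within_shell(self, tiny_scheme):
        # SH fitting is order-free: permuting a shell's measurements permutes
        # nothing in the coefficients
        rng = np.random.default_rng(4)
        y = rng.uniform(0.2, 1.0, tiny_scheme.M)
        feats = fit_sh_per_shell(y, tiny_scheme, lmax=4, lambda_reg=1e-3)
        perm = np.arange(tiny_scheme.M)
        _, _, idx = next(tiny_scheme.shells())
        perm[idx] = rng.permutation(idx)
        from mfkit.protocol import subset

        s2 = subset(tiny_scheme, perm)
        feats2 = fit_sh_per_shell(y[perm], s2, lmax=4, lambda_reg=1e-3)
        assert np.allclose(feats.vector, feats2.vector, atol=1e-10)


@pytest.fixture(scope="module")
def fl_setup(tiny_dictionary):
    train = generate_dataset(150, tiny_dictionary, SynthConfig(K=2), seed=0)
    cfg = FLConfig(hidden=(32, 16), epochs=40, batch_size=32, lmax=4)
    model = train_fl(train, tiny_dictionary, cfg, seed=1)
    return train, cfg, model


class TestFLPredict:
    def test_orientations_on_half_sphere_unit_norm(self, fl_setup, tiny_dictionary):
        train, cfg, model = fl_setup
        feats = featurize_dataset(train, cfg.lmax, cfg.lambda_reg)
        pred = fl_predict_batch(model, feats)
        u = pred["orientations"]
        assert np.all(u[..., 2] >= 0)
        assert np.allclose(np.linalg.norm(u, axis=-1), 1.0, atol=1e-9)

    def test_scalars_in_range(self, fl_setup, tiny_dictionary):
        train, cfg, model = fl_setup
        feats = featurize_dataset(train, cfg.lmax, cfg.lambda_reg)
        pred = fl_predict_batch(model, feats)
        assert np.allclose(pred["nu"].sum(axis=1), 1.0, atol=1e-9)
        p = tiny_dictionary.params
        assert pred["fvf"].min() >= p["fvf"].min() and pred["fvf"].max() <= p["fvf"].max()

    def test_no_nnls_and_no_dictionary_scan(self, fl_setup, tiny_dictionary):
        train, cfg, model = fl_setup
        from mfkit.fully_learned import fit_sh_per_shell as fit

        feats = fit(train.y[0], tiny_dictionary.scheme, cfg.lmax, cfg.lambda_reg)
        est = fl_predict(model, feats)
        assert est.n_nnls_solves == 0

    def test_feature_length_mismatch_is_error(self, fl_setup):
        _, _, model = fl_setup
        with pytest.raises(ValueError):
            fl_predict_batch(model, np.zeros((2, 13)))


class TestFLTraining:
    def test_determinism(self, tiny_dictionary, tmp_path):
        train = generate_dataset(60, tiny_dictionary, SynthConfig(K=2), seed=2)
        cfg = FLConfig(hidden=(16,), epochs=3, lmax=4)
        a = train_fl(train, tiny_dictionary, cfg, seed=3)
        b = train_fl(train, tiny_dictionary, cfg, seed=3)
        a.save(tmp_path / "a.npz")
        b.save(tmp_path / "b.npz")
        assert (tmp_path / "a.npz").read_bytes() == (tmp_path / "b.npz").read_bytes()

    def test_overfit_small_set(self, tiny_dictionary):
        train = generate_dataset(100, tiny_dictionary, SynthConfig(K=2), seed=4)
        cfg = FLConfig(hidden=(64, 32), epochs=800, dropout_keep=1.0,
                       lr=2e-3, lr_decay=1.0, batch_size=25, lmax=4)
        model = train_fl(train, tiny_dictionary, cfg, seed=5)
        assert model.training_meta["loss_per_epoch"][-1] < 1e-2

    def test_antipodal_orientation_loss(self):
        from mfkit.fully_learned import _orientation_loss_grad

        rng = np.random.default_rng(6)
        raw = rng.normal(size=(10, 2, 3))
        u = rng.normal(size=(10, 2, 3))
        u /= np.linalg.norm(u, axis=-1, keepdims=True)
        la, _ = _orientation_loss_grad(raw, u)
        lb, _ = _orientation_loss_grad(raw, -u)
        assert abs(la - lb) < 1e-12

    def test_save_load_round_trip(self, fl_setup, tiny_dictionary, tmp_path):
        train, cfg, model = fl_setup
        model.save(tmp_path / "m.npz")
        back = TrainedRegressor.load(tmp_path / "m.npz")
        feats = featurize_dataset(train, cfg.lmax, cfg.lambda_reg)[:5]
        a = fl_predict_batch(model, feats)
        b = fl_predict_batch(back, feats)
        for key in a:
            assert np.array_equal(a[key], b[key])
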