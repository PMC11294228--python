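"""Exhaustive reference matching: NNLS contract and combinatorial search."""

from itertools import product

import numpy as np
import pytest
import scipy.optimize

from mfkit.dictionary import rotate_dictionary
from mfkit.reference_mf import FascicleEstimate, mf_exhaustive, nnls
from mfkit.synthdata import SynthConfig, generate_dataset


class TestNNLS:
    def test_identity_design(self):
        w, res = nnls(np.eye(2), np.array([1.0, 2.0]))
        assert np.allclose(w, [1.0, 2.0]) and res < 1e-12

    def test_nonnegativity_binds(self):
        A = np.array([[1.0], [1.0]])
        w, res = nnls(A, np.array([-1.0, -1.0]))
        assert w[0] == 0.0
        assert abs(res - np.sqrt(2.0)) < 1e-12

    def test_matches_support_enumeration(self):
        # brute-force oracle: minimize over all 2^P sign-support patterns
        rng = np.random.default_rng(0)
        for _ in range(20):
            A = rng.normal(size=(6, 3))
            y = rng.normal(size=6)
            w, res = nnls(A, y)
            best = np.inf
            for mask in product([0, 1], repeat=3):
                idx = [i for i in range(3) if mask[i]]
                if idx:
                    sol, *_ = np.linalg.lstsq(A[:, idx], y, rcond=None)
                    if np.any(sol < 0):
                        continue
                    r = np.linalg.norm(A[:, idx] @ sol - y)
                else:
                    r = np.linalg.norm(y)
                best = min(best, r)
            assert res <= best + 1e-10

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            nnls(np.array([[np.nan]]), np.array([1.0]))


def _brute_force_mf(y, design):
    """Independent oracle: scipy NNLS on every atom pair."""
    N1 = design.blocks[0].shape[1]
    N2 = design.blocks[1].shape[1]
    best = (None, None, np.inf)
    for i in range(N1):
        for j in range(N2):
            A = np.column_stack([design.blocks[0][:, i], design.blocks[1][:, j]])
            w, res = scipy.optimize.nnls(A, y)
            if res < best[2] - 1e-15:
                best = ((i, j), w, res)
    return best


class TestExhaustive:
    def test_noiseless_two_fascicle_recovery(self, tiny_dictionary):
        rng = np.random.default_rng(1)
        u1 = np.array([0.0, 0.0, 1.0])
        u2 = np.array([np.sin(np.pi / 3), 0.0, np.cos(np.pi / 3)])  # 60 deg
        design = rotate_dictionary(tiny_dictionary, np.stack([u1, u2]))
        y = 0.6 * design.blocks[0][:, 2] + 0.4 * design.blocks[1][:, 4]
        est = mf_exhaustive(y, design)
        assert est.atom_indices.tolist() == [2, 4]
        assert np.allclose(est.nu, [0.6, 0.4], atol=1e-8)
        assert est.n_nnls_solves == tiny_dictionary.N**2

    def test_single_atom_membership(self, tiny_dictionary):
        u1 = np.array([0.0, 0.0, 1.0])
        u2 = np.array([1.0, 0.0, 0.0])
        design = rotate_dictionary(tiny_dictionary, np.stack([u1, u2]))
        y = design.blocks[0][:, 3].copy()
        est = mf_exhaustive(y, design)
        assert est.nu[0] > 1 - 1e-8 and est.nu[1] < 1e-8

    def test_matches_brute_force_oracle(self, tiny_dictionary):
        # oracle equivalence on random noisy voxels (same b0-normalized input)
        from mfkit.reference_mf import _normalize_b0

        ds = generate_dataset(25, tiny_dictionary, SynthConfig(K=2), seed=3)
        for i in range(25):
            design = rotate_dictionary(tiny_dictionary, ds.orientations[i])
            est = mf_exhaustive(ds.y[i], design)
            y = _normalize_b0(ds.y[i], tiny_dictionary.scheme)
            idx, w, res = _brute_force_mf(y, design)
            assert tuple(est.atom_indices) == idx
            assert abs(est.residual - res) < 1e-10

    def test_degenerate_n1_k2_equals_single_nnls(self, tiny_dictionary, tiny_scheme):
        import pandas as pd

        from mfkit.dictionary import FingerprintDictionary

        one = FingerprintDictionary(
            atoms=tiny_dictionary.atoms[:1],
            params=tiny_dictionary.params.iloc[:1].reset_index(drop=True),
            scheme=tiny_scheme,
            generator_tag="analytic",
            substrate=tiny_dictionary.substrate,
        )
        u = np.array([[0.0, 0.0, 1.0], [1.0, 0.0, 0.0]])
        design = rotate_dictionary(one, u)
        rng = np.random.default_rng(0)
        y = np.abs(design.matrix @ np.array([0.3, 0.7]) + 0.01 * rng.normal(size=tiny_scheme.M))
        est = mf_exhaustive(y, design)
        from mfkit.reference_mf import _normalize_b0

        w, res = scipy.optimize.nnls(design.matrix, _normalize_b0(y, tiny_scheme))
        assert abs(est.residual - res) < 1e-10
        assert np.allclose(est.nu, w / w.sum(), atol=1e-8)

    def test_three_fascicle_generic_path(self, tiny_dictionary):
        rng = np.random.default_rng(5)
        ds = generate_dataset(2, tiny_dictionary, SynthConfig(K=3), seed=4)
        design = rotate_dictionary(tiny_dictionary, ds.orientations[0])
        est = mf_exhaustive(ds.y_clean[0], design)
        assert est.n_nnls_solves == tiny_dictionary.N**3
        assert abs(est.nu.sum() - 1.0) < 1e-9

    def test_all_zero_signal_is_error(self, tiny_dictionary):
        design = rotate_dictionary(
            tiny_dictionary, np.array([[0.0, 0.0, 1.0], [1.0, 0.0, 0.0]])
        )
        with pytest.raises(ValueError):
            mf_exhaustive(np.zeros(tiny_dictionary.scheme.M), design)

    def test_estimate_invariants(self, tiny_dictionary):
        ds = generate_dataset(5, tiny_dictionary, SynthConfig(K=2), seed=9)
        for i in range(5):
            design = rotate_dictionary(tiny_dictionary, ds.orientations[i])
            est = mf_exhaustive(ds.y[i], design)
            assert np.all(est.nu >= 0) and abs(est.nu.sum() - 1) < 1e-9
            assert est.residual >= 0


class TestRelaxationBound:
    def test_projection_residual_never_exceeds_exhaustive(self, tiny_dictionary):
        from mfkit.hybrid import nnls_projection

        ds = generate_dataset(30, tiny_dictionary, SynthConfig(K=2), seed=11)
        for i in range(30):
            design = rotate_dictionary(tiny_dictionary, ds.orientations[i])
            r_relaxed = nnls_projection(ds.y[i], design).residual
            r_exhaustive = mf_exhaustive(ds.y[i], design).residual
            assert r_relaxed <= r_exhaustive + 1e-10

    def test_fascicle_estimate_rejects_bad_nu(self):
        with pytest.raises(ValueError):
            FascicleEstimate(nu=np.array([0.7, 0.7]), fvf=np.zeros(2),
                             dex=np.zeros(2), residual=0.0)
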