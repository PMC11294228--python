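"""Fingerprint dictionaries: grid, analytic model, packing, MC cross-check."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mfkit.dictionary import (
    CylinderPacking,
    SubstrateConfig,
    analytic_fingerprint,
    build_dictionary,
    build_parameter_grid,
    mc_fingerprint,
    pack_cylinders,
    rotate_atoms,
    rotate_dictionary,
)
from mfkit.protocol import AcquisitionScheme

Z = np.array([0.0, 0.0, 1.0])


class TestParameterGrid:
    def test_default_grid(self):
        g = build_parameter_grid()
        assert len(g) == 380
        fvf = np.unique(g["fvf"])
        dex = np.unique(g["dex"])
        assert len(fvf) == 38 and len(dex) == 10
        assert np.allclose(np.diff(fvf), 0.02)
        assert np.allclose(np.diff(dex), 0.2)
        assert fvf.min() == 0.06 and fvf.max() == 0.8
        assert dex.min() == 0.6 and dex.max() == 2.4

    @given(
        n_fvf=st.integers(1, 12),
        n_dex=st.integers(1, 8),
    )
    @settings(deadline=None, max_examples=20)
    def test_row_count_is_product(self, n_fvf, n_dex):
        g = build_parameter_grid(n_fvf=n_fvf, n_dex=n_dex)
        assert len(g) == n_fvf * n_dex

    def test_rejects_bad_bounds(self):
        with pytest.raises(ValueError):
            build_parameter_grid(fvf_lo=0.5, fvf_hi=0.2)


class TestAnalyticFingerprint:
    def test_b0_equals_one(self, tiny_scheme):
        cfg = SubstrateConfig(fvf=0.4, d_ex=1.2)
        s = analytic_fingerprint(cfg, tiny_scheme, Z)
        assert np.all(s[tiny_scheme.b0_mask] == 1.0)

    def test_parallel_closed_form(self):
        # gradient parallel to the axis: both compartments are free Gaussian
        sch = AcquisitionScheme(
            directions=np.array([[0.0, 0.0, 1.0]]),
            bvalues=np.array([1000.0]),
            delta_small=12.9,
            delta_big=21.8,
        )
        cfg = SubstrateConfig(fvf=0.5, d_ex=1.5, d_in=2.2)
        s = analytic_fingerprint(cfg, sch, Z)
        expected = 0.5 * np.exp(-2.2) + 0.5 * np.exp(-1.5)
        assert abs(s[0] - expected) < 1e-12

    def test_low_fvf_approaches_isotropic_tensor(self, tiny_scheme):
        cfg = SubstrateConfig(fvf=1e-9, d_ex=1.0)
        s = analytic_fingerprint(cfg, tiny_scheme, Z)
        expected = np.exp(-tiny_scheme.b_ms_um2 * 1.0)
        expected[tiny_scheme.b0_mask] = 1.0
        assert np.allclose(s, expected, atol=1e-6)

    def test_antipodal_symmetry(self, tiny_scheme):
        cfg = SubstrateConfig(fvf=0.5, d_ex=1.4)
        rng = np.random.default_rng(3)
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        assert np.allclose(
            analytic_fingerprint(cfg, tiny_scheme, u),
            analytic_fingerprint(cfg, tiny_scheme, -u),
        )

    def test_values_in_unit_interval(self, full_dictionary):
        assert np.all(full_dictionary.atoms > 0)
        assert np.all(full_dictionary.atoms <= 1.0)

    def test_rejects_nonpositive_diffusivity(self):
        with pytest.raises(ValueError):
            SubstrateConfig(fvf=0.5, d_ex=-1.0)


class TestBuildDictionary:
    def test_default_dictionary_shape(self, full_dictionary, hcp_scheme):
        assert full_dictionary.N == 380
        assert full_dictionary.atoms.shape == (380, hcp_scheme.M)
        assert np.all(full_dictionary.atoms[:, hcp_scheme.b0_mask] == 1.0)

    def test_params_aligned_with_grid(self, full_dictionary):
        g = build_parameter_grid()
        assert np.allclose(full_dictionary.params["fvf"], g["fvf"])
        assert np.allclose(full_dictionary.params["dex"], g["dex"])


class TestRotation:
    def test_identity_rotation(self, small_dictionary):
        block = rotate_atoms(small_dictionary, Z)
        assert np.allclose(block, small_dictionary.atoms.T, atol=1e-12)

    def test_analytic_rotation_matches_direct_eval(self, small_dictionary, hcp_scheme):
        u = np.array([1.0, -2.0, 0.5])
        u /= np.linalg.norm(u)
        block = rotate_atoms(small_dictionary, u)
        for j, (fvf, dex) in enumerate(
            small_dictionary.params[["fvf", "dex"]].to_numpy()
        ):
            cfg = SubstrateConfig(fvf=float(fvf), d_ex=float(dex))
            assert np.allclose(
                block[:, j], analytic_fingerprint(cfg, hcp_scheme, u), atol=1e-12
            )

    def test_rotation_about_axis_invariant(self, tiny_dictionary):
        # the substrate is axially symmetric: any u gives a block that only
        # depends on |g.u| per shell; rotate by 180deg about u -> same block
        u = np.array([0.6, 0.0, 0.8])
        assert np.allclose(
            rotate_atoms(tiny_dictionary, u), rotate_atoms(tiny_dictionary, -u)
        )

    def test_design_matrix_stacks_blocks(self, tiny_dictionary):
        us = np.array([[0.0, 0.0, 1.0], [1.0, 0.0, 0.0]])
        design = rotate_dictionary(tiny_dictionary, us)
        assert design.K == 2
        assert design.matrix.shape == (
            tiny_dictionary.scheme.M,
            2 * tiny_dictionary.N,
        )


class TestPacking:
    def test_achieved_fvf(self):
        cfg = SubstrateConfig(fvf=0.3, d_ex=1.0)
        p = pack_cylinders(cfg, n_cyl=50, seed=1)
        assert abs(p.achieved_fvf - 0.3) < 0.01

    def test_no_overlaps_under_periodic_wrap(self):
        cfg = SubstrateConfig(fvf=0.4, d_ex=1.0)
        p = pack_cylinders(cfg, n_cyl=60, seed=2)
        assert p.overlaps() == 0

    def test_gamma_radius_moments(self):
        rng = np.random.default_rng(0)
        cfg = SubstrateConfig(fvf=0.3, d_ex=1.0)
        r = rng.gamma(cfg.gamma_shape, cfg.gamma_scale, size=10000)
        assert abs(r.mean() - 0.5) < 0.01
        assert abs(r.std() - 0.3) < 0.006

    def test_too_dense_is_error(self):
        with pytest.raises(ValueError):
            SubstrateConfig(fvf=0.95, d_ex=1.0)


@pytest.fixture(scope="module")
def mc_scheme():
    """3-direction single-shell scheme for Monte Carlo tests."""
    dirs = np.array(
        [[0, 0, 0], [0.0, 0.0, 1.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]
    )
    bvals = np.array([0.0, 1000.0, 1000.0, 1000.0])
    return AcquisitionScheme(
        directions=dirs, bvalues=bvals, delta_small=12.9, delta_big=21.8
    )


class TestMonteCarlo:
    def test_b0_is_one(self, mc_scheme):
        cfg = SubstrateConfig(fvf=0.3, d_ex=1.0)
        p = pack_cylinders(cfg, n_cyl=20, seed=3)
        s = mc_fingerprint(p, cfg, mc_scheme, n_spins=500, dt=5e-3, seed=0)
        assert s[0] == 1.0

    def test_free_diffusion_closed_form(self, mc_scheme):
        # no membranes: signal must match exp(-b D) in every direction
        cfg = SubstrateConfig(fvf=0.5, d_ex=2.0)
        s = mc_fingerprint(None, cfg, mc_scheme, n_spins=20000, dt=0.02, seed=1)
        expected = np.exp(-1.0 * 2.0)  # b = 1 ms/um^2, D = 2 um^2/ms
        # 3 sigma of the phase-average estimator at this spin count
        assert np.all(np.abs(s[1:] - expected) < 0.012)

    def test_restriction_raises_perpendicular_signal(self, mc_scheme):
        # restricted intra-axonal diffusion attenuates less than free water
        cfg = SubstrateConfig(fvf=0.75, d_ex=2.2, d_in=2.2)
        p = pack_cylinders(cfg, n_cyl=25, seed=4)
        s = mc_fingerprint(p, cfg, mc_scheme, n_spins=3000, dt=2e-3, seed=2)
        free = np.exp(-1.0 * 2.2)
        assert s[2] > free and s[3] > free

    def test_variance_shrinks_with_spin_count(self, mc_scheme):
        cfg = SubstrateConfig(fvf=0.5, d_ex=1.5)
        reps_small = [
            mc_fingerprint(None, cfg, mc_scheme, n_spins=500, dt=0.05, seed=s)[1]
            for s in range(8)
        ]
        reps_big = [
            mc_fingerprint(None, cfg, mc_scheme, n_spins=8000, dt=0.05, seed=s)[1]
            for s in range(8)
        ]
        # 16x the spins -> ~4x smaller std; allow slack for 8 replicates
        assert np.std(reps_big) < np.std(reps_small) / 2.0

    def test_agrees_with_analytic_at_low_b(self, mc_scheme):
        # dilute packing: the tortuosity closure (1 - fvf) is accurate there
        cfg = SubstrateConfig(fvf=0.25, d_ex=1.5)
        p = pack_cylinders(cfg, n_cyl=30, seed=5)
        mc = mc_fingerprint(p, cfg, mc_scheme, n_spins=8000, dt=2e-3, seed=3)
        an = analytic_fingerprint(cfg, mc_scheme, Z)
        rms = np.sqrt(np.mean((mc[1:] - an[1:]) ** 2))
        assert rms < 0.02

    def test_mc_dictionary_rotation_round_trip(self, tiny_scheme):
        # rotate to u and back to z via shell interpolation ~ canonical atoms
        grid = build_parameter_grid(n_fvf=2, fvf_lo=0.2, fvf_hi=0.5, n_dex=1,
                                    dex_lo=1.0, dex_hi=2.0)
        d = build_dictionary(grid, tiny_scheme, generator="montecarlo",
                             seed=1, n_spins=2000, n_cyl=15, dt=5e-3)
        block_z = rotate_atoms(d, Z)
        assert np.allclose(block_z, d.atoms.T, atol=0.05)
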