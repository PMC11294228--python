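"""Synthetic crossing-fascicle voxels.

Voxels contain K = 2 or 3 fascicles.  Each fascicle is one dictionary atom
(an (fvf, Dex) grid point) rotated to a sampled orientation; the noiseless
voxel signal is the nu-weighted convex combination of the rotated atoms.
Sampling laws follow the training recipe used throughout the package:

* crossing angles uniform in [15, 90] degrees (all pairwise angles for K=3);
* relative fractions nu ~ U(0.05, 0.95) for K = 2, Dirichlet(alpha=1) for
  K = 3;
* (fvf, Dex) pairs drawn uniformly from the dictionary grid rows;
* SNR ~ U(10, 100), defining Gaussian noise of s.d. sigma = s(b=0)/SNR;
* magnitude noise applied as s = sqrt(s_clean^2 + eps^2) with a single
  Gaussian draw eps per measurement (an optional two-channel Rician mode is
  available for sensitivity checks).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dictionary import FingerprintDictionary, _cached_model, rotate_atoms
from .protocol import AcquisitionScheme

__all__ = [
    "SynthConfig",
    "VoxelSample",
    "VoxelDataset",
    "sample_orientations",
    "add_noise",
    "generate_dataset",
    "build_test_set_exp1",
]


@dataclass
class SynthConfig:
    """Sampling laws for synthetic voxels."""

    K: int = 2
    angle_lo: float = 15.0  # degrees
    angle_hi: float = 90.0
    alpha: float = 1.0  # Dirichlet concentration for K >= 3
    nu_lo: float = 0.05  # uniform law bounds for K = 2
    nu_hi: float = 0.95
    snr_lo: float = 10.0
    snr_hi: float = 100.0
    snr_set: tuple | None = None  # overrides the uniform SNR law when set
    noise_mode: str = "rician_sq"  # or "rician2"

    def __post_init__(self):
        if not self.angle_lo < self.angle_hi:
            raise ValueError("angle_lo must be < angle_hi")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.K not in (2, 3):
            raise ValueError("K must be 2 or 3")


@dataclass
class VoxelSample:
    """One synthetic voxel with its ground truth."""

    y: np.ndarray
    y_clean: np.ndarray
    orientations: np.ndarray  # (K, 3)
    nu: np.ndarray
    fvf: np.ndarray
    dex: np.ndarray
    snr: float

    @property
    def K(self) -> int:
        return self.nu.size


@dataclass
class VoxelDataset:
    """Column-oriented collection of voxels sharing a scheme and K."""

    y: np.ndarray  # (n, M)
    y_clean: np.ndarray  # (n, M)
    orientations: np.ndarray  # (n, K, 3)
    nu: np.ndarray  # (n, K)
    fvf: np.ndarray  # (n, K)
    dex: np.ndarray  # (n, K)
    snr: np.ndarray  # (n,)
    scheme: AcquisitionScheme
    seed: int = 0

    def __len__(self) -> int:
        return self.y.shape[0]

    @property
    def K(self) -> int:
        return self.nu.shape[1]

    def __getitem__(self, i: int) -> VoxelSample:
        return VoxelSample(
            y=self.y[i],
            y_clean=self.y_clean[i],
            orientations=self.orientations[i],
            nu=self.nu[i],
            fvf=self.fvf[i],
            dex=self.dex[i],
            snr=float(self.snr[i]),
        )

    def sorted_by_nu(self) -> "VoxelDataset":
        """Copy with fascicles reordered so nu is descending in every voxel.

        Training utilities adopt the convention that fascicle 1 is the
        largest; inputs and targets must share one fascicle order.
        """
        order = np.argsort(-self.nu, axis=1, kind="stable")
        rows = np.arange(len(self))[:, None]
        return VoxelDataset(
            y=self.y,
            y_clean=self.y_clean,
            orientations=self.orientations[rows, order],
            nu=self.nu[rows, order],
            fvf=self.fvf[rows, order],
            dex=self.dex[rows, order],
            snr=self.snr,
            scheme=self.scheme,
            seed=self.seed,
        )

    def subset(self, index) -> "VoxelDataset":
        index = np.asarray(index)
        return VoxelDataset(
            y=self.y[index],
            y_clean=self.y_clean[index],
            orientations=self.orientations[index],
            nu=self.nu[index],
            fvf=self.fvf[index],
            dex=self.dex[index],
            snr=self.snr[index],
            scheme=self.scheme,
            seed=self.seed,
        )


def _random_unit(rng, n=None):
    v = rng.normal(size=(n, 3) if n else 3)
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def _rotate_z_to(u):
    """A rotation matrix mapping the z axis onto the unit vector u."""
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, u)
    s = np.linalg.norm(v)
    c = float(z @ u)
    if s < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)


def sample_orientations(K: int, config: SynthConfig, rng) -> np.ndarray:
    """K unit orientations with pairwise crossing angles in the configured range.

    The first orientation is uniform on the sphere; the second is placed at
    an angle drawn U(angle_lo, angle_hi) with uniform azimuth.  For K = 3 the
    third vector is rejection-sampled until every pairwise angle (folded to
    [0, 90] degrees, since fascicles are antipodally symmetric) lies in
    range.
    """
    if K not in (2, 3):
        raise ValueError("K must be 2 or 3")
    lo, hi = np.deg2rad(config.angle_lo), np.deg2rad(config.angle_hi)
    u1 = _random_unit(rng)
    theta = rng.uniform(lo, hi)
    phi = rng.uniform(0, 2 * np.pi)
    local = np.array(
        [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
    )
    u2 = _rotate_z_to(u1) @ local
    if K == 2:
        return np.stack([u1, u2])
    for _ in range(1000):
        u3 = _random_unit(rng)
        angles = np.degrees(
            np.arccos(np.clip(np.abs([u3 @ u1, u3 @ u2]), 0.0, 1.0))
        )
        if np.all((angles >= config.angle_lo) & (angles <= config.angle_hi)):
            return np.stack([u1, u2, u3])
    raise RuntimeError(
        "could not place a third fascicle within the angle range after 1000 tries"
    )


def add_noise(y_clean, snr: float, b0_value: float, rng, mode: str = "rician_sq"):
    """Magnitude noise at the given SNR.

    sigma = b0_value / snr.  Default mode ``rician_sq`` applies
    s = sqrt(s_clean^2 + eps^2) with one i.i.d. Gaussian draw eps per
    measurement; mode ``rician2`` applies the two-channel magnitude form
    sqrt((s + eps1)^2 + eps2^2).
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    y_clean = np.asarray(y_clean, dtype=float)
    sigma = b0_value / snr
    if mode == "rician_sq":
        eps = rng.normal(scale=sigma, size=y_clean.shape)
        return np.sqrt(y_clean**2 + eps**2)
    if mode == "rician2":
        e1 = rng.normal(scale=sigma, size=y_clean.shape)
        e2 = rng.normal(scale=sigma, size=y_clean.shape)
        return np.sqrt((y_clean + e1) ** 2 + e2**2)
    raise ValueError(f"unknown noise mode {mode!r}")


def _clean_signals(dictionary: FingerprintDictionary, fvf, dex, orientations, nu):
    """Noiseless voxel signals, vectorized over voxels (chunked internally).

    fvf, dex, nu : (n, K); orientations : (n, K, 3).  Analytic dictionaries
    evaluate the atoms in closed form; Monte Carlo dictionaries go through
    shell interpolation per voxel.
    """
    n, K = fvf.shape
    M = dictionary.scheme.M
    out = np.empty((n, M))
    if dictionary.generator_tag == "analytic":
        model = _cached_model(dictionary)
        # chunk so the (c, K, M, n_radii) GPA intermediate stays ~100 MB
        chunk = max(1, int(8e6 // (M * K * 48)))
        for a in range(0, n, chunk):
            b = min(n, a + chunk)
            s = model.signals(fvf[a:b], dex[a:b], orientations[a:b])  # (c, K, M)
            out[a:b] = np.einsum("ck,ckm->cm", nu[a:b], s)
    else:
        for i in range(n):
            s = np.stack(
                [
                    rotate_atoms(dictionary, orientations[i, k])[
                        :, _atom_index(dictionary, fvf[i, k], dex[i, k])
                    ]
                    for k in range(K)
                ]
            )
            out[i] = nu[i] @ s
    return out


def _atom_index(dictionary, fvf, dex):
    p = dictionary.params
    d = (p["fvf"].to_numpy() - fvf) ** 2 + (p["dex"].to_numpy() - dex) ** 2
    return int(np.argmin(d))


def generate_dataset(
    n: int,
    dictionary: FingerprintDictionary,
    config: SynthConfig | None = None,
    scheme: AcquisitionScheme | None = None,
    seed: int = 0,
) -> VoxelDataset:
    """Draw ``n`` voxels from the training recipe, reproducibly from ``seed``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    config = config or SynthConfig()
    scheme = scheme or dictionary.scheme
    rng = np.random.default_rng(seed)
    K = config.K
    grid = dictionary.params[["fvf", "dex"]].to_numpy()

    orientations = np.stack(
        [sample_orientations(K, config, rng) for _ in range(n)]
    )
    if K == 2:
        nu1 = rng.uniform(config.nu_lo, config.nu_hi, size=n)
        nu = np.stack([nu1, 1.0 - nu1], axis=1)
    else:
        nu = rng.dirichlet(np.full(K, config.alpha), size=n)
    rows = rng.integers(0, len(grid), size=(n, K))
    fvf = grid[rows, 0]
    dex = grid[rows, 1]
    if config.snr_set is not None:
        snr = rng.choice(np.asarray(config.snr_set, dtype=float), size=n)
    else:
        snr = rng.uniform(config.snr_lo, config.snr_hi, size=n)

    y_clean = _clean_signals(dictionary, fvf, dex, orientations, nu)
    sigma = 1.0 / snr  # atoms are b0-normalized, so s(b=0) = 1
    if config.noise_mode == "rician_sq":
        eps = rng.normal(size=y_clean.shape) * sigma[:, None]
        y = np.sqrt(y_clean**2 + eps**2)
    else:
        e1 = rng.normal(size=y_clean.shape) * sigma[:, None]
        e2 = rng.normal(size=y_clean.shape) * sigma[:, None]
        y = np.sqrt((y_clean + e1) ** 2 + e2**2)
    return VoxelDataset(
        y=y,
        y_clean=y_clean,
        orientations=orientations,
        nu=nu,
        fvf=fvf,
        dex=dex,
        snr=snr,
        scheme=scheme,
        seed=seed,
    )


def build_test_set_exp1(
    dictionary: FingerprintDictionary,
    scheme: AcquisitionScheme | None = None,
    K: int = 2,
    seed: int = 0,
    n_total: int = 15000,
    nu1_set=(0.5, 0.6, 0.7, 0.8, 0.9),
    snr_set=(20.0, 30.0, 50.0),
    angle_lo: float = 15.0,
    angle_hi: float = 90.0,
) -> VoxelDataset:
    """Structured test set: fixed nu1 levels (K = 2) and fixed SNR levels.

    For K = 2, fascicle 1 is the larger one (nu1 >= 0.5 drawn from
    ``nu1_set``); for K = 3 fractions follow Dirichlet(alpha=1) sorted in
    descending order.  Crossing angles are uniform in [angle_lo, angle_hi];
    (fvf, Dex) pairs are drawn uniformly from the dictionary grid.
    """
    if K not in (2, 3):
        raise ValueError("K must be 2 or 3")
    scheme = scheme or dictionary.scheme
    config = SynthConfig(K=K, angle_lo=angle_lo, angle_hi=angle_hi)
    rng = np.random.default_rng(seed)
    grid = dictionary.params[["fvf", "dex"]].to_numpy()

    orientations = np.stack(
        [sample_orientations(K, config, rng) for _ in range(n_total)]
    )
    if K == 2:
        nu1 = rng.choice(np.asarray(nu1_set, dtype=float), size=n_total)
        nu = np.stack([nu1, 1.0 - nu1], axis=1)
    else:
        nu = np.sort(rng.dirichlet(np.full(K, 1.0), size=n_total), axis=1)[:, ::-1]
    rows = rng.integers(0, len(grid), size=(n_total, K))
    fvf = grid[rows, 0]
    dex = grid[rows, 1]
    snr = rng.choice(np.asarray(snr_set, dtype=float), size=n_total)

    y_clean = _clean_signals(dictionary, fvf, dex, orientations, nu)
    eps = rng.normal(size=y_clean.shape) / snr[:, None]
    y = np.sqrt(y_clean**2 + eps**2)
    return VoxelDataset(
        y=y,
        y_clean=y_clean,
        orientations=orientations,
        nu=nu,
        fvf=fvf,
        dex=dex,
        snr=snr,
        scheme=scheme,
        seed=seed,
    )
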