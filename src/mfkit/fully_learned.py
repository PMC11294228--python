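"""Fully-learned accelerated estimator: per-shell spherical harmonics + MLP.

The DW-MRI signal of each nonzero shell is least-squares fitted with real,
even-degree spherical harmonics up to degree 12 (91 coefficients per shell),
with a Laplace–Beltrami ridge penalty so that shells with fewer directions
than coefficients remain well-posed.  The concatenated per-shell coefficients
feed a feed-forward network with ReLU + dropout hidden layers that jointly
predicts, per fascicle, the scalar parameters (nu, fvf, Dex) through a
sigmoid head and an orientation through a head constrained to the unit
half-sphere (u_z >= 0).  No NNLS solve and no dictionary search occur at
inference: the per-voxel cost does not depend on the dictionary size N.

The orientation loss is 1 - (u_hat . u)^2, which is antipodally symmetric —
appropriate since a fascicle and its mirror image produce identical signals.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .hybrid import TrainedRegressor, _scalar_targets, _scaling_from_grid
from .reference_mf import FascicleEstimate, _normalize_b0
from .synthdata import VoxelDataset

__all__ = [
    "SHFeatures",
    "FLConfig",
    "real_even_sh_basis",
    "fit_sh_per_shell",
    "featurize_dataset",
    "train_fl",
    "fl_predict",
    "fl_predict_batch",
]


def n_even_sh_coeffs(lmax: int) -> int:
    return (lmax + 1) * (lmax + 2) // 2


def real_even_sh_basis(directions, lmax: int = 12) -> np.ndarray:
    """Real even-degree orthonormal SH basis sampled at unit directions.

    Column order: l ascending over even degrees, m from -l to l.  Real SH
    convention: for m < 0 the (normalized) imaginary part, for m > 0 the real
    part of the complex harmonic, both scaled by sqrt(2); m = 0 is the plain
    real harmonic.  For lmax = 12 there are 91 columns.
    """
    if lmax % 2 != 0 or lmax < 0:
        raise ValueError("lmax must be a nonnegative even integer")
    from scipy.special import sph_harm_y

    d = np.atleast_2d(np.asarray(directions, dtype=float))
    theta = np.arccos(np.clip(d[:, 2], -1.0, 1.0))  # polar
    phi = np.arctan2(d[:, 1], d[:, 0])  # azimuth
    cols = []
    for l in range(0, lmax + 1, 2):
        for m in range(-l, l + 1):
            y = sph_harm_y(l, abs(m), theta, phi)
            if m < 0:
                cols.append(np.sqrt(2.0) * (-1.0) ** m * y.imag)
            elif m == 0:
                cols.append(y.real)
            else:
                cols.append(np.sqrt(2.0) * (-1.0) ** m * y.real)
    return np.stack(cols, axis=1)


def _lb_penalty(lmax: int) -> np.ndarray:
    """Diagonal Laplace–Beltrami weights l^2 (l+1)^2 per coefficient."""
    diag = []
    for l in range(0, lmax + 1, 2):
        diag.extend([float(l**2 * (l + 1) ** 2)] * (2 * l + 1))
    return np.asarray(diag)


class SHFeatures:
    """Per-shell real even SH coefficients of one voxel (or a batch)."""

    def __init__(self, coefficients, lmax: int, shell_bvalues, regularization: float):
        self.coefficients = coefficients  # list of (..., n_coeffs) arrays
        self.lmax = lmax
        self.shell_bvalues = list(shell_bvalues)  # ascending b
        self.regularization = regularization

    @property
    def vector(self) -> np.ndarray:
        """Concatenated coefficients, shells in ascending-b order."""
        return np.concatenate(self.coefficients, axis=-1)


class _SHFitter:
    """Precomputed per-shell ridge fitting operators for one scheme."""

    def __init__(self, scheme, lmax: int = 12, lambda_reg: float = 1e-3):
        self.scheme = scheme
        self.lmax = lmax
        self.lambda_reg = lambda_reg
        self.shells = []
        pen = np.diag(_lb_penalty(lmax))
        for sid, bmean, idx in scheme.shells():
            if idx.size < 6:
                raise ValueError(
                    f"shell b={bmean:.0f} has {idx.size} directions; need >= 6"
                )
            B = real_even_sh_basis(scheme.directions[idx], lmax)
            if lambda_reg > 0:
                F = np.linalg.solve(B.T @ B + lambda_reg * pen, B.T)
            else:
                # unregularized: minimum-norm least squares (underdetermined
                # shells would make the normal equations singular)
                F = np.linalg.pinv(B, rcond=1e-10)
            self.shells.append((bmean, idx, F))
        if not self.shells:
            raise ValueError("scheme has no nonzero shell")
        self.shells.sort(key=lambda s: s[0])

    def fit(self, y) -> SHFeatures:
        """y : (..., M) b0-normalized signal(s); b=0 entries are ignored."""
        y = np.asarray(y, dtype=float)
        coeffs = [y[..., idx] @ F.T for _, idx, F in self.shells]
        return SHFeatures(
            coefficients=coeffs,
            lmax=self.lmax,
            shell_bvalues=[b for b, _, _ in self.shells],
            regularization=self.lambda_reg,
        )


def fit_sh_per_shell(y, scheme, lmax: int = 12, lambda_reg: float = 1e-3) -> SHFeatures:
    """Ridge-regularized per-shell SH fit of one b0-normalized signal."""
    return _SHFitter(scheme, lmax, lambda_reg).fit(y)


def featurize_dataset(
    dataset: VoxelDataset, lmax: int = 12, lambda_reg: float = 1e-3
) -> np.ndarray:
    """SH feature matrix (n, n_shells * n_coeffs) for a whole dataset."""
    fitter = _SHFitter(dataset.scheme, lmax, lambda_reg)
    return fitter.fit(dataset.y).vector


from dataclasses import dataclass  # noqa: E402


@dataclass
class FLConfig:
    """Architecture and optimization settings for the fully-learned regressor."""

    hidden: tuple = (384, 256, 128)
    dropout_keep: float = 0.9
    lmax: int = 12
    lambda_reg: float = 1e-3
    lr: float = 1e-3
    lr_decay: float = 0.97  # multiplicative, per epoch
    epochs: int = 40
    batch_size: int = 256
    orientation_weight: float = 1.0
    norm_weight: float = 0.01  # keeps |v| of the orientation head near 1


class _FLNet:
    """MLP with a sigmoid scalar head and a half-sphere orientation head."""

    def __init__(self, n_in: int, K: int, config: FLConfig, rng):
        self.n_in = n_in
        self.K = K
        self.config = config
        drop_rng = np.random.default_rng(rng.integers(2**31))
        layers = []
        width = n_in
        for h in config.hidden:
            layers += [
                nn.Dense(width, h, rng),
                nn.ReLU(),
                nn.Dropout(config.dropout_keep, drop_rng),
            ]
            width = h
        self.trunk = nn.Sequential(layers)
        # 3K sigmoid scalars + 3K raw orientation outputs
        self.head = nn.Dense(width, 6 * K, rng)

    def forward_raw(self, x, train: bool):
        h = self.trunk.forward(x, train)
        return self.head.forward(h, train)

    def backward_raw(self, g):
        g = self.head.backward(g)
        self.trunk.backward(g)

    def params(self):
        yield from self.trunk.params()
        yield from self.head.params()

    def state_arrays(self):
        return [p for p, _ in self.params()]

    # -- output parameterization ---------------------------------------------

    def split(self, raw):
        K = self.K
        scalars = nn.sigmoid(raw[:, : 3 * K])
        ori_raw = raw[:, 3 * K :].reshape(-1, K, 3)
        return scalars, ori_raw

    @staticmethod
    def orientation(ori_raw):
        """Normalize the raw 3-vector head to a unit orientation.

        The training loss is antipodally symmetric, so the raw vector is left
        unconstrained (a nonnegativity transform on the z component stalls
        learning for equatorial orientations); the half-sphere convention
        u_z >= 0 is applied by a sign fold at readout (:func:`fold_half_sphere`).
        """
        v = ori_raw
        norm = np.linalg.norm(v, axis=-1, keepdims=True)
        return v / np.maximum(norm, 1e-12), v, norm


def fold_half_sphere(u):
    """Flip orientations so that u_z >= 0 (fascicle axes are sign-free)."""
    u = np.asarray(u, dtype=float)
    sign = np.where(u[..., 2:3] < 0, -1.0, 1.0)
    return u * sign


def _orientation_loss_grad(ori_raw, u_true, norm_weight: float = 0.0):
    """Loss mean(1 - (u_hat . u)^2) and its gradient wrt the raw outputs.

    An optional penalty norm_weight * mean((|v| - 1)^2) keeps the
    pre-normalization vector v at unit scale: the directional gradient decays
    as 1/|v|, so unchecked norm growth stalls orientation learning.
    """
    uhat, v, norm = _FLNet.orientation(ori_raw)
    dot = np.sum(uhat * u_true, axis=-1, keepdims=True)  # (n, K, 1)
    n, K = ori_raw.shape[0], ori_raw.shape[1]
    safe_norm = np.maximum(norm, 1e-12)
    loss = float(np.mean(1.0 - dot**2))
    # d(dot)/dv = (u - dot * uhat)/|v|; dL/dv = -2 dot * d(dot)/dv / (n*K)
    dv = -2.0 * dot * (u_true - dot * uhat) / safe_norm / (n * K)
    if norm_weight > 0:
        loss += norm_weight * float(np.mean((norm - 1.0) ** 2))
        dv = dv + norm_weight * 2.0 * (norm - 1.0) * uhat / (n * K)
    return loss, dv


def _best_assignment(scalars, ori_raw, t_group, u_group, ow: float):
    """Per-sample fascicle-label assignment minimizing the combined loss.

    Fascicle labels in a voxel are arbitrary: near nu_1 = nu_2 a fixed
    (descending-nu) target order supervises the network with effectively
    random labels, which stalls learning.  For each sample the permutation
    of the K target fascicles with the lowest scalar-MSE + orientation loss
    is selected, making the loss permutation-invariant.

    scalars : (B, 3K) sigmoid outputs; ori_raw : (B, K, 3) raw head outputs;
    t_group : (B, K, 3) scaled scalar targets; u_group : (B, K, 3) true
    orientations.  Returns targets (B, 3K) and orientations (B, K, 3) in the
    selected order.
    """
    from itertools import permutations

    B, K = t_group.shape[0], t_group.shape[1]
    uhat, _, _ = _FLNet.orientation(ori_raw)
    s_group = scalars.reshape(B, K, 3)
    perms = list(permutations(range(K)))
    costs = np.empty((B, len(perms)))
    for p, perm in enumerate(perms):
        idx = np.asarray(perm)
        mse = np.mean((s_group - t_group[:, idx, :]) ** 2, axis=(1, 2))
        dot = np.sum(uhat * u_group[:, idx, :], axis=-1)
        costs[:, p] = mse + ow * np.mean(1.0 - dot**2, axis=1)
    choice = np.argmin(costs, axis=1)
    t_sel = np.empty_like(t_group)
    u_sel = np.empty_like(u_group)
    for p, perm in enumerate(perms):
        sel = choice == p
        idx = np.asarray(perm)
        t_sel[sel] = t_group[sel][:, idx, :]
        u_sel[sel] = u_group[sel][:, idx, :]
    return t_sel.reshape(B, 3 * K), u_sel


def train_fl(
    dataset: VoxelDataset,
    dictionary,
    config: FLConfig | None = None,
    seed: int = 0,
    features: np.ndarray | None = None,
    verbose: bool = False,
) -> TrainedRegressor:
    """Train the fully-learned regressor on SH features.

    Targets are the min-max-scaled scalars (fascicles ordered by descending
    nu) plus the true orientations; the combined loss is scalar MSE +
    ``orientation_weight`` times the antipodally symmetric orientation loss.
    Deterministic given ``seed``.
    """
    if len(dataset) == 0:
        raise ValueError("empty training dataset")
    config = config or FLConfig()
    if features is None:
        features = featurize_dataset(dataset, config.lmax, config.lambda_reg)
    K = dataset.K
    rng = np.random.default_rng(seed)
    net = _FLNet(features.shape[1], K, config, rng)

    lo, hi = _scaling_from_grid(dictionary.params, K)
    t_scaled = (_scalar_targets(dataset) - lo) / (hi - lo)
    order = np.argsort(-dataset.nu, axis=1, kind="stable")
    rows = np.arange(len(dataset))[:, None]
    u_true = dataset.orientations[rows, order]  # (n, K, 3), nu-descending

    mean = features.mean(axis=0)
    std = features.std(axis=0) + 1e-8
    x = (features - mean) / std

    opt = nn.Adam(net, lr=config.lr)
    n = x.shape[0]
    losses = []
    for epoch in range(config.epochs):
        opt.lr = config.lr * config.lr_decay**epoch
        perm = rng.permutation(n)
        total = 0.0
        for a in range(0, n, config.batch_size):
            idx = perm[a : a + config.batch_size]
            raw = net.forward_raw(x[idx], train=True)
            scalars, ori_raw = net.split(raw)
            t_sel, u_sel = _best_assignment(
                scalars,
                ori_raw,
                t_scaled[idx].reshape(idx.size, K, 3),
                u_true[idx],
                config.orientation_weight,
            )
            diff = scalars - t_sel
            mse = float(np.mean(diff**2))
            oloss, dori = _orientation_loss_grad(ori_raw, u_sel, config.norm_weight)
            loss = mse + config.orientation_weight * oloss
            total += loss * idx.size
            draw = np.empty_like(raw)
            draw[:, : 3 * K] = (2.0 * diff / diff.size) * scalars * (1 - scalars)
            draw[:, 3 * K :] = (
                config.orientation_weight * dori.reshape(idx.size, -1)
            )
            net.backward_raw(draw)
            opt.step()
        losses.append(total / n)
        if verbose:
            print(f"epoch {epoch + 1}: loss {losses[-1]:.5f}")
    return TrainedRegressor(
        kind="fully_learned",
        net=net,
        K=K,
        input_mean=mean,
        input_std=std,
        output_lo=lo,
        output_hi=hi,
        training_meta={
            "seed": seed,
            "epochs": config.epochs,
            "lr": config.lr,
            "n_train": n,
            "loss_per_epoch": [float(l) for l in losses],
            "dataset_seed": dataset.seed,
        },
    )


def fl_predict_batch(model: TrainedRegressor, features: np.ndarray) -> dict:
    """Vectorized prediction from an (n, n_features) SH feature array."""
    if model.kind != "fully_learned":
        raise ValueError("model is not a fully-learned regressor")
    features = np.atleast_2d(np.asarray(features, dtype=float))
    if features.shape[1] != model.input_mean.size:
        raise ValueError("feature length does not match the model")
    raw = model.net.forward_raw(model.standardize(features), train=False)
    scalars, ori_raw = model.net.split(raw)
    uhat, _, _ = _FLNet.orientation(ori_raw)
    uhat = fold_half_sphere(uhat)
    vals = model.unscale_outputs(scalars).reshape(features.shape[0], model.K, 3)
    nu = vals[:, :, 0]
    s = nu.sum(axis=1, keepdims=True)
    nu = np.where(s > 0, nu / np.maximum(s, 1e-12), 1.0 / model.K)
    return {"nu": nu, "fvf": vals[:, :, 1], "dex": vals[:, :, 2], "orientations": uhat}


def fl_predict(model: TrainedRegressor, features: SHFeatures) -> FascicleEstimate:
    """Map one voxel's SH features to a per-fascicle estimate (with u_hat)."""
    vec = np.atleast_2d(features.vector)
    res = fl_predict_batch(model, vec)
    return FascicleEstimate(
        nu=res["nu"][0],
        fvf=res["fvf"][0],
        dex=res["dex"][0],
        residual=float("nan"),
        orientations=res["orientations"][0],
        n_nnls_solves=0,
    )


def featurize_signal(y, scheme, lmax: int = 12, lambda_reg: float = 1e-3) -> SHFeatures:
    """b0-normalize a raw signal and fit its per-shell SH features."""
    y = _normalize_b0(np.asarray(y, dtype=float), scheme)
    return fit_sh_per_shell(y, scheme, lmax, lambda_reg)
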