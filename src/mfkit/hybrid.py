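"""Hybrid accelerated estimator: NNLS projection + split-arm MLP.

Stage 1 relaxes the exhaustive combinatorial matching of
:func:`mfkit.reference_mf.mf_exhaustive`: the measured signal y is projected
onto *all* K*N rotated atoms at once by a single NNLS solve, ignoring the
multi-compartment structure (NNLS itself enforces sparsity).  Stage 2 maps
the resulting weight vector w to tissue parameters with a feed-forward
network whose first layer is split into K arms — one per fascicle block of w
— merged through batch normalization into a common MLP with ReLU hidden
layers, dropout, and a sigmoid output head.  Outputs are affinely unscaled to
(nu_k, fvf_k, Dex_k) and nu is renormalized to sum to one.

Because w lives in fingerprint space rather than measurement space, a model
trained under one acquisition scheme can be applied unchanged to data from
another scheme: only the stage-1 design matrix changes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .dictionary import FingerprintDictionary, RotatedDesign, rotate_dictionary
from .reference_mf import FascicleEstimate, nnls, _normalize_b0
from .synthdata import VoxelDataset

__all__ = [
    "NNLSWeights",
    "HybridConfig",
    "TrainedRegressor",
    "nnls_projection",
    "compute_weight_features",
    "train_hybrid",
    "hybrid_predict",
    "hybrid_predict_batch",
]


@dataclass
class NNLSWeights:
    """Nonnegative projection weights of one voxel onto K*N rotated atoms."""

    w: np.ndarray
    block_layout: tuple  # (K, N)
    residual: float = 0.0
    n_nnls_solves: int = 1

    def __post_init__(self):
        K, N = self.block_layout
        if self.w.size != K * N:
            raise ValueError("weight length inconsistent with block layout")
        if np.any(self.w < 0):
            raise ValueError("NNLS weights must be nonnegative")


def nnls_projection(y, design: RotatedDesign) -> NNLSWeights:
    """Project y onto the stacked design [C^1 ... C^K] with one NNLS solve."""
    scheme = design.dictionary.scheme
    y = _normalize_b0(np.asarray(y, dtype=float), scheme)
    A = design.matrix
    w, res = nnls(A, y)
    return NNLSWeights(
        w=w,
        block_layout=(design.K, design.dictionary.N),
        residual=res,
        n_nnls_solves=1,
    )


def compute_weight_features(
    dataset: VoxelDataset,
    dictionary: FingerprintDictionary,
    orientations: np.ndarray | None = None,
) -> np.ndarray:
    """Stage-1 NNLS weights for every voxel of a dataset, as an (n, K*N) array.

    ``orientations`` defaults to the dataset's ground-truth orientations;
    pass perturbed orientations to emulate an external orientation routine.
    """
    if orientations is None:
        orientations = dataset.orientations
    n = len(dataset)
    K = dataset.K
    out = np.empty((n, K * dictionary.N))
    for i in range(n):
        design = rotate_dictionary(dictionary, orientations[i])
        out[i] = nnls_projection(dataset.y[i], design).w
    return out


@dataclass
class HybridConfig:
    """Architecture and optimization settings for the hybrid regressor."""

    arm_width: int = 64
    hidden: tuple = (256, 128)
    dropout_keep: float = 0.9
    shared_arms: bool = False
    lr: float = 1e-3
    lr_decay: float = 0.97  # multiplicative, per epoch
    epochs: int = 30
    batch_size: int = 256


class _HybridNet:
    """Split arms -> concat -> batch norm -> common MLP -> sigmoid head."""

    def __init__(self, K: int, N: int, config: HybridConfig, rng):
        self.K, self.N = K, N
        self.config = config
        drop_rng = np.random.default_rng(rng.integers(2**31))
        if config.shared_arms:
            shared = nn.Dense(N, config.arm_width, rng)
            self.arms = [shared] * K
        else:
            self.arms = [nn.Dense(N, config.arm_width, rng) for _ in range(K)]
        self.arm_act = nn.ReLU()
        self.bn = nn.BatchNorm(K * config.arm_width)
        layers = []
        width = K * config.arm_width
        for h in config.hidden:
            layers += [
                nn.Dense(width, h, rng),
                nn.ReLU(),
                nn.Dropout(config.dropout_keep, drop_rng),
            ]
            width = h
        layers.append(nn.Dense(width, 3 * K, rng))
        self.trunk = nn.Sequential(layers)

    def forward(self, x, train: bool):
        K, N, A = self.K, self.N, self.config.arm_width
        self._pre = np.empty((x.shape[0], K * A))
        for k in range(K):
            self._pre[:, k * A : (k + 1) * A] = self.arms[k].forward(
                x[:, k * N : (k + 1) * N], train
            )
        h = self.arm_act.forward(self._pre, train)
        h = self.bn.forward(h, train)
        logits = self.trunk.forward(h, train)
        return nn.sigmoid(logits)

    def backward(self, dout, out):
        # dout is dL/d(sigmoid output); chain through the sigmoid first
        g = dout * out * (1.0 - out)
        g = self.trunk.backward(g)
        g = self.bn.backward(g)
        g = self.arm_act.backward(g)
        K, N, A = self.K, self.N, self.config.arm_width
        gx = np.empty((g.shape[0], K * N))
        if self.config.shared_arms:
            # accumulate shared gradients across arms manually
            arm = self.arms[0]
            dW = np.zeros_like(arm.W)
            db = np.zeros_like(arm.b)
            for k in range(K):
                gk = g[:, k * A : (k + 1) * A]
                dW += arm._xs[k].T @ gk
                db += gk.sum(axis=0)
                gx[:, k * N : (k + 1) * N] = gk @ arm.W.T
            arm.dW, arm.db = dW, db
        else:
            for k in range(K):
                gx[:, k * N : (k + 1) * N] = self.arms[k].backward(
                    g[:, k * A : (k + 1) * A]
                )
        return gx

    def forward_cached(self, x, train: bool):
        """Forward pass that also caches per-arm inputs (shared-arm case)."""
        if self.config.shared_arms:
            K, N, A = self.K, self.N, self.config.arm_width
            arm = self.arms[0]
            arm._xs = [x[:, k * N : (k + 1) * N] for k in range(K)]
            pre = np.empty((x.shape[0], K * A))
            for k in range(K):
                pre[:, k * A : (k + 1) * A] = arm._xs[k] @ arm.W + arm.b
            self._pre = pre
            h = self.arm_act.forward(pre, train)
            h = self.bn.forward(h, train)
            return nn.sigmoid(self.trunk.forward(h, train))
        return self.forward(x, train)

    def params(self):
        arms = self.arms[:1] if self.config.shared_arms else self.arms
        for arm in arms:
            yield from arm.params()
        yield from self.bn.params()
        yield from self.trunk.params()

    def state_arrays(self):
        arrays = [p for p, _ in self.params()]
        arrays += [self.bn.running_mean, self.bn.running_var]
        return arrays


@dataclass
class TrainedRegressor:
    """A trained hybrid or fully-learned network with its scaling metadata."""

    kind: str  # "hybrid" | "fully_learned"
    net: object
    K: int
    input_mean: np.ndarray
    input_std: np.ndarray
    output_lo: np.ndarray  # per scalar target, length 3K (nu, fvf, dex) x K
    output_hi: np.ndarray
    training_meta: dict = field(default_factory=dict)

    def scale_targets(self, t):
        return (t - self.output_lo) / (self.output_hi - self.output_lo)

    def unscale_outputs(self, s):
        return self.output_lo + s * (self.output_hi - self.output_lo)

    def standardize(self, x):
        return (x - self.input_mean) / self.input_std

    # -- persistence ---------------------------------------------------------

    def save(self, path) -> None:
        arrays = {f"arr_{i}": a for i, a in enumerate(self.net.state_arrays())}
        meta = {
            "kind": self.kind,
            "K": self.K,
            "training_meta": self.training_meta,
            "config": self.net.config.__dict__ | _extra_net_meta(self.net),
        }
        np.savez(
            path,
            input_mean=self.input_mean,
            input_std=self.input_std,
            output_lo=self.output_lo,
            output_hi=self.output_hi,
            meta=np.frombuffer(json.dumps(meta, default=str).encode(), dtype=np.uint8),
            **arrays,
        )

    @classmethod
    def load(cls, path) -> "TrainedRegressor":
        from .fully_learned import FLConfig, _FLNet  # local import, no cycle at load

        data = np.load(path, allow_pickle=False)
        meta = json.loads(bytes(data["meta"]).decode())
        cfgd = dict(meta["config"])
        K = int(meta["K"])
        rng = np.random.default_rng(0)
        if meta["kind"] == "hybrid":
            N = int(cfgd.pop("N"))
            cfg = HybridConfig(**{k: _coerce(v) for k, v in cfgd.items()})
            net = _HybridNet(K, N, cfg, rng)
        else:
            n_in = int(cfgd.pop("n_in"))
            cfg = FLConfig(**{k: _coerce(v) for k, v in cfgd.items()})
            net = _FLNet(n_in, K, cfg, rng)
        for tgt, key in zip(net.state_arrays(), [f"arr_{i}" for i in range(len(net.state_arrays()))]):
            tgt[...] = data[key]
        return cls(
            kind=meta["kind"],
            net=net,
            K=K,
            input_mean=data["input_mean"],
            input_std=data["input_std"],
            output_lo=data["output_lo"],
            output_hi=data["output_hi"],
            training_meta=meta["training_meta"],
        )


def _coerce(v):
    if isinstance(v, list):
        return tuple(v)
    return v


def _extra_net_meta(net):
    if isinstance(net, _HybridNet):
        return {"N": net.N}
    return {"n_in": net.n_in}


def _scalar_targets(dataset: VoxelDataset) -> np.ndarray:
    """Per-voxel target vector (nu_1, fvf_1, dex_1, ..., nu_K, ...), fascicles
    ordered by descending nu."""
    order = np.argsort(-dataset.nu, axis=1, kind="stable")
    rows = np.arange(len(dataset))[:, None]
    nu = dataset.nu[rows, order]
    fvf = dataset.fvf[rows, order]
    dex = dataset.dex[rows, order]
    return np.stack([nu, fvf, dex], axis=2).reshape(len(dataset), -1)


def _scaling_from_grid(params, K: int):
    lo = np.tile([0.0, params["fvf"].min(), params["dex"].min()], K)
    hi = np.tile([1.0, params["fvf"].max(), params["dex"].max()], K)
    return np.asarray(lo, dtype=float), np.asarray(hi, dtype=float)


def train_hybrid(
    dataset: VoxelDataset,
    dictionary: FingerprintDictionary,
    config: HybridConfig | None = None,
    seed: int = 0,
    weights: np.ndarray | None = None,
    orientations: np.ndarray | None = None,
    verbose: bool = False,
) -> TrainedRegressor:
    """Train the split-arm regressor on stage-1 NNLS weights.

    ``weights`` may carry precomputed (n, K*N) stage-1 features; in that case
    both the weights and the dataset must already follow the descending-nu
    fascicle order (see :meth:`VoxelDataset.sorted_by_nu`).  Otherwise the
    dataset is reordered here and features computed from ``orientations``
    (ground truth by default).  Minimizes the MSE between sigmoid outputs
    and min-max-scaled targets with Adam; deterministic given ``seed``.
    """
    if len(dataset) == 0:
        raise ValueError("empty training dataset")
    config = config or HybridConfig()
    if weights is None:
        if orientations is None:
            dataset = dataset.sorted_by_nu()
        weights = compute_weight_features(dataset, dictionary, orientations)
    K = dataset.K
    rng = np.random.default_rng(seed)
    net = _HybridNet(K, dictionary.N, config, rng)

    lo, hi = _scaling_from_grid(dictionary.params, K)
    targets = _scalar_targets(dataset)
    t_scaled = (targets - lo) / (hi - lo)

    mean = weights.mean(axis=0)
    std = weights.std(axis=0) + 1e-8
    x = (weights - mean) / std

    losses = _fit(net, x, t_scaled, config, rng)
    return TrainedRegressor(
        kind="hybrid",
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
            "n_train": len(dataset),
            "loss_per_epoch": [float(l) for l in losses],
            "dataset_seed": dataset.seed,
        },
    )


def _fit(net, x, t, config, rng):
    """Minibatch Adam on mean squared error; returns per-epoch losses."""
    opt = nn.Adam(net, lr=config.lr)
    n = x.shape[0]
    losses = []
    for epoch in range(config.epochs):
        opt.lr = config.lr * config.lr_decay**epoch
        perm = rng.permutation(n)
        total = 0.0
        for a in range(0, n, config.batch_size):
            idx = perm[a : a + config.batch_size]
            xb, tb = x[idx], t[idx]
            out = net.forward_cached(xb, train=True)
            diff = out - tb
            loss = float(np.mean(diff**2))
            total += loss * idx.size
            dout = 2.0 * diff / diff.size
            net.backward(dout, out)
            opt.step()
        losses.append(total / n)
    return losses


def hybrid_predict_batch(model: TrainedRegressor, w: np.ndarray) -> dict:
    """Vectorized prediction from an (n, K*N) weight array.

    Returns arrays ``nu``, ``fvf``, ``dex`` of shape (n, K) with nu
    renormalized to sum to one per voxel.
    """
    if model.kind != "hybrid":
        raise ValueError("model is not a hybrid regressor")
    w = np.atleast_2d(np.asarray(w, dtype=float))
    if w.shape[1] != model.input_mean.size:
        raise ValueError("weight vector length does not match the model")
    out = model.net.forward_cached(model.standardize(w), train=False)
    vals = model.unscale_outputs(out).reshape(w.shape[0], model.K, 3)
    nu = vals[:, :, 0]
    s = nu.sum(axis=1, keepdims=True)
    nu = np.where(s > 0, nu / np.maximum(s, 1e-12), 1.0 / model.K)
    return {"nu": nu, "fvf": vals[:, :, 1], "dex": vals[:, :, 2]}


def hybrid_predict(model: TrainedRegressor, w: NNLSWeights) -> FascicleEstimate:
    """Map one stage-1 weight vector to a per-fascicle estimate."""
    if w.block_layout[0] != model.K:
        raise ValueError("fascicle count mismatch between weights and model")
    res = hybrid_predict_batch(model, w.w[None, :])
    return FascicleEstimate(
        nu=res["nu"][0],
        fvf=res["fvf"][0],
        dex=res["dex"][0],
        residual=w.residual,
        n_nnls_solves=w.n_nnls_solves,
    )
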