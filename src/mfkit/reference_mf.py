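"""Reference exhaustive fingerprint matching.

Given fascicle orientations u_1..u_K (from an external source such as
constrained spherical deconvolution, or the ground truth in simulations), the
reference estimator rotates the single-fascicle dictionary into K
sub-dictionaries C^1..C^K and searches all N^K atom combinations, solving a
K-variable non-negative least-squares (NNLS) problem per combination and
keeping the best fit.  The cost is therefore O(N^K * K) per voxel — the
bottleneck the accelerated estimators in :mod:`mfkit.hybrid` and
:mod:`mfkit.fully_learned` remove.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import scipy.optimize

from .dictionary import RotatedDesign

__all__ = ["FascicleEstimate", "nnls", "mf_exhaustive"]


@dataclass
class FascicleEstimate:
    """Per-fascicle parameter estimates for one voxel.

    ``nu`` are relative fascicle volume fractions (normalized to sum to 1),
    ``fvf`` fiber volume fractions, ``dex`` extra-axonal diffusivities in
    um^2/ms.  ``orientations`` is present only for estimators that infer
    orientations themselves.  ``n_nnls_solves`` exposes the number of NNLS
    problems solved to produce the estimate.
    """

    nu: np.ndarray
    fvf: np.ndarray
    dex: np.ndarray
    residual: float
    orientations: np.ndarray | None = None
    atom_indices: np.ndarray | None = None
    n_nnls_solves: int = 0

    def __post_init__(self):
        self.nu = np.asarray(self.nu, dtype=float)
        if np.any(self.nu < -1e-12):
            raise ValueError("nu must be nonnegative")
        s = self.nu.sum()
        if s > 0 and abs(s - 1.0) > 1e-9:
            raise ValueError("nu must be normalized")

    @property
    def K(self) -> int:
        return self.nu.size


def nnls(A, y):
    """Non-negative least squares min ||A w - y|| s.t. w >= 0.

    Thin validated wrapper around the Lawson–Hanson active-set solver;
    returns ``(w, residual_norm)``.
    """
    A = np.asarray(A, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.all(np.isfinite(A)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite input to nnls")
    w, res = scipy.optimize.nnls(A, y)
    return w, float(res)


def _normalize_b0(y, scheme):
    b0 = scheme.b0_mask
    if not np.any(b0):
        return np.asarray(y, dtype=float)
    s0 = float(np.mean(np.asarray(y, dtype=float)[b0]))
    if s0 <= 0:
        raise ValueError("mean b=0 signal must be positive for normalization")
    return np.asarray(y, dtype=float) / s0


def _pairwise_nnls_scan(y, C1, C2):
    """Closed-form 2-variable NNLS over every column pair of (C1, C2).

    Vectorized over all N1*N2 pairs.  For two columns a, b the optimum is
    either the unconstrained 2x2 solution (when nonnegative) or the better
    of the two single-column nonnegative fits — the exact active-set case
    analysis for K = 2.  Returns the winning (i, j), weights and residual.
    Ties in residual are broken by the lowest (i, j) in row-major order.
    """
    yy = float(y @ y)
    gaa = np.einsum("mi,mi->i", C1, C1)  # (N1,)
    gbb = np.einsum("mj,mj->j", C2, C2)  # (N2,)
    gab = C1.T @ C2  # (N1, N2)
    da = C1.T @ y  # (N1,)
    db = C2.T @ y  # (N2,)

    det = gaa[:, None] * gbb[None, :] - gab**2
    safe = det > 1e-12 * gaa[:, None] * gbb[None, :]
    det_s = np.where(safe, det, 1.0)
    w1 = (gbb[None, :] * da[:, None] - gab * db[None, :]) / det_s
    w2 = (gaa[:, None] * db[None, :] - gab * da[:, None]) / det_s
    both_ok = safe & (w1 >= 0) & (w2 >= 0)
    res2_both = yy - (w1 * da[:, None] + w2 * db[None, :])

    w1_only = np.maximum(da / gaa, 0.0)  # (N1,)
    res2_a = yy - w1_only * da  # optimal single-column fit on C1
    w2_only = np.maximum(db / gbb, 0.0)
    res2_b = yy - w2_only * db

    res2_single = np.minimum(res2_a[:, None], res2_b[None, :])
    res2 = np.where(both_ok, res2_both, res2_single)
    res2 = np.maximum(res2, 0.0)

    flat = np.argmin(res2)  # first minimum in row-major order
    i, j = np.unravel_index(flat, res2.shape)
    if both_ok[i, j]:
        w = np.array([w1[i, j], w2[i, j]])
    elif res2_a[i] <= res2_b[j]:
        w = np.array([w1_only[i], 0.0])
    else:
        w = np.array([0.0, w2_only[j]])
    return (int(i), int(j)), w, float(np.sqrt(res2[i, j]))


def mf_exhaustive(y, design: RotatedDesign) -> FascicleEstimate:
    """Best-fit atom combination over all N^K NNLS sub-problems.

    ``y`` is b0-normalized before matching (atoms are b0-normalized).  The
    returned estimate carries the per-fascicle (nu, fvf, Dex) of the winning
    combination and the Euclidean fit residual over all M measurements.
    """
    scheme = design.dictionary.scheme
    y = _normalize_b0(y, scheme)
    if np.all(y == 0):
        raise ValueError("all-zero signal: fractions undefined")
    K = design.K
    params = design.dictionary.params

    if K == 2:
        (i, j), w, res = _pairwise_nnls_scan(y, design.blocks[0], design.blocks[1])
        best_idx, best_w, best_res = (i, j), w, res
        n_solves = design.blocks[0].shape[1] * design.blocks[1].shape[1]
    else:
        sizes = [blk.shape[1] for blk in design.blocks]
        best_res = np.inf
        best_idx = best_w = None
        n_solves = 0
        for combo in product(*[range(s) for s in sizes]):
            A = np.column_stack(
                [design.blocks[k][:, combo[k]] for k in range(K)]
            )
            w, res = nnls(A, y)
            n_solves += 1
            if res < best_res - 1e-15:
                best_res, best_idx, best_w = res, combo, w
        best_res = float(best_res)

    wsum = best_w.sum()
    if wsum <= 0:
        import warnings

        warnings.warn("all NNLS weights zero at optimum; nu set uniform")
        nu = np.full(K, 1.0 / K)
    else:
        nu = best_w / wsum
    idx = np.asarray(best_idx)
    return FascicleEstimate(
        nu=nu,
        fvf=params["fvf"].to_numpy()[idx],
        dex=params["dex"].to_numpy()[idx],
        residual=best_res,
        atom_indices=idx,
        n_nnls_solves=n_solves,
    )
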