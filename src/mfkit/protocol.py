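"""PGSE acquisition schemes and their shell structure.

An acquisition scheme is the list of diffusion-weighted measurements of a
pulsed-gradient spin-echo (PGSE) protocol: one gradient direction and b-value
per measurement, plus the gradient timing (duration ``delta_small``,
separation ``delta_big``) shared by all measurements.  b-values are carried in
s/mm^2; diffusivities elsewhere in the package are in um^2/ms, and the
conversion factor (1 s/mm^2 = 1e-3 ms/um^2) is applied internally wherever
``b * D`` products are formed.

Two presets are provided: a research multi-shell protocol (four shells up to
b = 10,000 s/mm^2, 552 volumes) and a clinically feasible three-shell
protocol (260 measurements).  Gradient direction tables are generated by
seeded electrostatic repulsion on the half-sphere since the presets do not
prescribe specific tables; user-supplied FSL bval/bvec files can replace
them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "AcquisitionScheme",
    "GYROMAGNETIC_RATIO",
    "build_hcp_mgh_scheme",
    "build_clinical_scheme",
    "group_shells",
    "repulsion_directions",
    "read_scheme",
    "write_scheme",
]

#: Proton gyromagnetic ratio in rad / (ms * mT/m * um) units:
#: 2.6752e8 rad/s/T = 2.6752e-4 rad * um^-1 * ms^-1 per (mT/m) ... times um.
#: With G in mT/m, delta in ms and x in um, gamma*G*x*dt is a phase in rad.
GYROMAGNETIC_RATIO = 2.6752218744e-4

#: Default tolerance (s/mm^2) under which two b-values belong to one shell.
SHELL_TOL = 50.0


def group_shells(bvalues, tol: float = SHELL_TOL):
    """Assign a shell id to every measurement by clustering b-values.

    Measurements whose b-values differ by at most ``tol`` share an id; ids
    are numbered 0, 1, ... by ascending b so that b=0 measurements (when
    present) always receive id 0.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    b = np.asarray(bvalues, dtype=float)
    ids = np.empty(b.shape, dtype=int)
    order = np.argsort(b, kind="stable")
    current = -1
    ref = -np.inf
    for idx in order:
        if b[idx] - ref > tol:
            current += 1
            ref = b[idx]
        ids[idx] = current
    return ids


@dataclass
class AcquisitionScheme:
    """Gradient table plus timing for a PGSE protocol.

    Parameters
    ----------
    directions : (M, 3) array
        Unit gradient directions; b=0 entries may carry the zero vector.
    bvalues : (M,) array
        b-values in s/mm^2.
    delta_small : float
        Gradient pulse duration delta, ms.
    delta_big : float
        Diffusion time Delta (pulse separation), ms.
    gradient_strengths : (M,) array, optional
        Gradient amplitude per measurement in mT/m.  Derived from the
        b-values and timing when omitted.
    te, tr : float, optional
        Echo/repetition time in ms, carried as metadata only.
    """

    directions: np.ndarray
    bvalues: np.ndarray
    delta_small: float
    delta_big: float
    gradient_strengths: np.ndarray | None = None
    te: float | None = None
    tr: float | None = None
    shell_ids: np.ndarray = field(default=None)  # type: ignore[assignment]
    name: str = "custom"

    def __post_init__(self):
        self.directions = np.atleast_2d(np.asarray(self.directions, dtype=float))
        self.bvalues = np.asarray(self.bvalues, dtype=float)
        if self.directions.shape != (self.bvalues.size, 3):
            raise ValueError(
                f"directions shape {self.directions.shape} does not match "
                f"{self.bvalues.size} b-values"
            )
        if np.any(self.bvalues < 0):
            raise ValueError("b-values must be nonnegative")
        nrm = np.linalg.norm(self.directions, axis=1)
        dw = self.bvalues > 0
        bad = dw & (np.abs(nrm - 1.0) > 1e-9)
        if np.any(bad):
            raise ValueError("diffusion-weighted directions must be unit vectors")
        if self.gradient_strengths is None:
            self.gradient_strengths = gradient_strength_from_b(
                self.bvalues, self.delta_small, self.delta_big
            )
        else:
            self.gradient_strengths = np.asarray(self.gradient_strengths, dtype=float)
        if self.shell_ids is None:
            self.shell_ids = group_shells(self.bvalues)
        else:
            self.shell_ids = np.asarray(self.shell_ids, dtype=int)
            for sid in np.unique(self.shell_ids):
                bs = self.bvalues[self.shell_ids == sid]
                if bs.max() - bs.min() > SHELL_TOL:
                    raise ValueError(f"shell {sid} spans inconsistent b-values")

    @property
    def M(self) -> int:
        """Total number of measurements."""
        return self.bvalues.size

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvalues <= SHELL_TOL

    @property
    def b_ms_um2(self) -> np.ndarray:
        """b-values converted to ms/um^2 (the unit matching um^2/ms)."""
        return self.bvalues * 1e-3

    def shells(self):
        """Yield ``(shell_id, b_mean, index_array)`` for every nonzero shell."""
        for sid in np.unique(self.shell_ids):
            idx = np.flatnonzero(self.shell_ids == sid)
            bmean = float(self.bvalues[idx].mean())
            if bmean <= SHELL_TOL:
                continue
            yield sid, bmean, idx

    def __eq__(self, other):
        if not isinstance(other, AcquisitionScheme):
            return NotImplemented
        return (
            np.allclose(self.directions, other.directions)
            and np.allclose(self.bvalues, other.bvalues)
            and np.isclose(self.delta_small, other.delta_small)
            and np.isclose(self.delta_big, other.delta_big)
        )

    def fingerprint(self) -> str:
        """Short deterministic digest of the scheme contents (provenance)."""
        import hashlib

        h = hashlib.sha256()
        h.update(np.round(self.directions, 9).tobytes())
        h.update(np.round(self.bvalues, 6).tobytes())
        h.update(np.float64([self.delta_small, self.delta_big]).tobytes())
        return h.hexdigest()[:16]


def gradient_strength_from_b(bvalues, delta_small: float, delta_big: float):
    """Gradient amplitude (mT/m) realizing each b-value for the given timing.

    Uses the rectangular-pulse PGSE relation b = gamma^2 G^2 delta^2
    (Delta - delta/3) with b converted to ms/um^2.
    """
    b = np.asarray(bvalues, dtype=float) * 1e-3
    factor = GYROMAGNETIC_RATIO**2 * delta_small**2 * (delta_big - delta_small / 3.0)
    return np.sqrt(b / factor)


def repulsion_directions(n: int, seed: int, n_iter: int = 200, step: float = 0.05):
    """Generate ``n`` near-uniform unit directions by electrostatic repulsion.

    Points interact with both each other and their antipodes (as appropriate
    for diffusion gradient tables, which are sign-invariant), starting from a
    seeded random configuration.  Deterministic given ``(n, seed)``.
    """
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, 3))
    x /= np.linalg.norm(x, axis=1, keepdims=True)
    for _ in range(n_iter):
        force = np.zeros_like(x)
        for sign in (1.0, -1.0):
            d = x[:, None, :] - sign * x[None, :, :]
            dist2 = np.einsum("ijk,ijk->ij", d, d)
            np.fill_diagonal(dist2, np.inf)
            dist2[dist2 < 1e-12] = np.inf
            force += np.einsum("ij,ijk->ik", dist2**-1.5, d)
        x = x + step * force / n
        x /= np.linalg.norm(x, axis=1, keepdims=True)
    return x


def _interleave_b0(dw_dirs, dw_bvals, block: int = 13):
    """Insert one b=0 measurement before every block of ``block`` DWIs."""
    dirs, bvals = [], []
    n = dw_bvals.size
    for start in range(0, n, block):
        dirs.append(np.zeros((1, 3)))
        bvals.append([0.0])
        dirs.append(dw_dirs[start : start + block])
        bvals.append(dw_bvals[start : start + block])
    return np.concatenate(dirs, axis=0), np.concatenate(bvals)


def build_hcp_mgh_scheme(seed: int = 0) -> AcquisitionScheme:
    """Research-grade multi-shell PGSE protocol (552 volumes).

    Four shells of 64/64/128/256 directions at b = 1000/3000/5000/10000
    s/mm^2, delta = 12.9 ms, Delta = 21.8 ms, TE/TR = 57/8800 ms, with one
    b=0 volume leading every block of 13 diffusion-weighted volumes
    (512 DWIs -> 40 b=0 -> 552 volumes total).
    """
    shells = [(64, 1000.0), (64, 3000.0), (128, 5000.0), (256, 10000.0)]
    dirs = np.concatenate(
        [
            repulsion_directions(n, seed=(seed * 101 + i) % 2**31)
            for i, (n, _) in enumerate(shells)
        ]
    )
    bvals = np.concatenate([np.full(n, b) for n, b in shells])
    all_dirs, all_bvals = _interleave_b0(dirs, bvals, block=13)
    return AcquisitionScheme(
        directions=all_dirs,
        bvalues=all_bvals,
        delta_small=12.9,
        delta_big=21.8,
        te=57.0,
        tr=8800.0,
        name="hcp_mgh",
    )


def build_clinical_scheme(seed: int = 0) -> AcquisitionScheme:
    """Clinically feasible three-shell PGSE protocol (260 measurements).

    64 directions at b = 1000 and 2000 s/mm^2 and 128 at b = 5000 s/mm^2
    plus 4 b=0 acquisitions; delta = 22.9 ms, Delta = 35.7 ms,
    TE/TR = 77.4/4842 ms.  High-b (10,000) and b = 3000 shells of the
    research protocol are deliberately absent.
    """
    shells = [(64, 1000.0), (64, 2000.0), (128, 5000.0)]
    dirs, bvals = [np.zeros((1, 3))], [[0.0]]
    for i, (n, b) in enumerate(shells):
        dirs.append(np.zeros((1, 3)))
        bvals.append([0.0])
        dirs.append(repulsion_directions(n, seed=(seed * 211 + i) % 2**31))
        bvals.append(np.full(n, b))
    return AcquisitionScheme(
        directions=np.concatenate(dirs, axis=0),
        bvalues=np.concatenate(bvals),
        delta_small=22.9,
        delta_big=35.7,
        te=77.4,
        tr=4842.0,
        name="clinical",
    )


def write_scheme(scheme: AcquisitionScheme, path_bval, path_bvec) -> None:
    """Write FSL-dialect bval/bvec text files (one row of b, three of xyz)."""
    with open(path_bval, "w") as f:
        f.write(" ".join(f"{b:.6g}" for b in scheme.bvalues) + "\n")
    with open(path_bvec, "w") as f:
        for row in scheme.directions.T:
            f.write(" ".join(f"{v:.9f}" for v in row) + "\n")


def read_scheme(
    path_bval,
    path_bvec,
    delta_small: float,
    delta_big: float,
    te: float | None = None,
    tr: float | None = None,
) -> AcquisitionScheme:
    """Read an FSL-dialect bval/bvec pair into an :class:`AcquisitionScheme`.

    Off-unit diffusion directions (norm error > 1e-3) are renormalized with
    a warning; mismatched bval/bvec counts are a hard error.
    """
    bvals = np.loadtxt(path_bval, ndmin=1)
    bvecs = np.loadtxt(path_bvec, ndmin=2)
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    if bvecs.shape != (bvals.size, 3):
        raise ValueError(
            f"bval count {bvals.size} does not match bvec shape {bvecs.shape}"
        )
    nrm = np.linalg.norm(bvecs, axis=1)
    dw = bvals > SHELL_TOL
    off = dw & (np.abs(nrm - 1.0) > 1e-3)
    if np.any(off):
        warnings.warn(
            f"renormalizing {int(off.sum())} off-unit gradient directions",
            stacklevel=2,
        )
    fix = dw & (nrm > 0)
    bvecs[fix] /= nrm[fix, None]
    bvecs[~dw] = 0.0
    return AcquisitionScheme(
        directions=bvecs,
        bvalues=bvals,
        delta_small=delta_small,
        delta_big=delta_big,
        te=te,
        tr=tr,
    )


def subset(scheme: AcquisitionScheme, index) -> AcquisitionScheme:
    """Scheme restricted to a subset of measurements (same timing)."""
    index = np.asarray(index)
    return replace(
        scheme,
        directions=scheme.directions[index],
        bvalues=scheme.bvalues[index],
        gradient_strengths=scheme.gradient_strengths[index],
        shell_ids=None,
    )
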