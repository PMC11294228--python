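"""Single-fascicle fingerprint dictionaries.

A fingerprint is the noiseless, b0-normalized DW-MRI signal of one fascicle
microstructure under a fixed acquisition scheme.  The dictionary spans a grid
of (fvf, Dex) values — fiber volume fraction and extra-axonal diffusivity —
at a canonical fascicle orientation (the z axis), and is rotated on demand to
arbitrary orientations.

Two signal generators are available:

``analytic`` (default)
    Two-compartment closed form.  The intra-axonal signal is the
    Gaussian-phase-approximation (GPA) signal of impermeable parallel
    cylinders with radii gamma-distributed (volume-weighted average), free
    diffusion along the axis.  The extra-axonal signal is an axially
    symmetric tensor whose perpendicular diffusivity is reduced by the
    tortuosity factor (1 - fvf).

``montecarlo``
    A reduced-fidelity random-walk simulator in a periodic 2D packing of
    straight cylinders, solving the same physics numerically.  It serves as
    an independent cross-check of the analytic atoms at moderate b-values
    and is orders of magnitude slower.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .protocol import GYROMAGNETIC_RATIO, AcquisitionScheme

__all__ = [
    "SubstrateConfig",
    "CylinderPacking",
    "FingerprintDictionary",
    "RotatedDesign",
    "build_parameter_grid",
    "analytic_fingerprint",
    "pack_cylinders",
    "mc_fingerprint",
    "build_dictionary",
    "rotate_dictionary",
]

_N_GPA_ROOTS = 20
_N_RADIUS_QUAD = 48


@dataclass
class SubstrateConfig:
    """Microstructural configuration of a single fascicle.

    Radii of the (straight, parallel, impermeable) cylinders follow a gamma
    law; diffusivities are in um^2/ms, radii in um.
    """

    fvf: float
    d_ex: float
    radius_mean: float = 0.5
    radius_sd: float = 0.3
    d_in: float = 2.2

    def __post_init__(self):
        if not (0.0 < self.fvf <= 0.9):
            raise ValueError("fvf must lie in (0, 0.9]")
        if self.d_in <= 0 or self.d_ex <= 0:
            raise ValueError("diffusivities must be positive")
        if self.radius_mean <= 0 or self.radius_sd <= 0:
            raise ValueError("radius distribution parameters must be positive")

    @property
    def gamma_shape(self) -> float:
        return self.radius_mean**2 / self.radius_sd**2

    @property
    def gamma_scale(self) -> float:
        return self.radius_sd**2 / self.radius_mean


def build_parameter_grid(
    n_fvf: int = 38,
    fvf_lo: float = 0.06,
    fvf_hi: float = 0.8,
    n_dex: int = 10,
    dex_lo: float = 0.6,
    dex_hi: float = 2.4,
) -> pd.DataFrame:
    """Cartesian (fvf, Dex) grid, fvf-major, endpoints inclusive.

    Defaults give 38 x 10 = 380 rows: fvf in [0.06, 0.8] (spacing 0.02) and
    Dex in [0.6, 2.4] um^2/ms (spacing 0.2).
    """
    if n_fvf < 1 or n_dex < 1:
        raise ValueError("grid counts must be >= 1")
    if fvf_lo >= fvf_hi or dex_lo >= dex_hi:
        raise ValueError("grid bounds must satisfy lo < hi")
    fvf = np.linspace(fvf_lo, fvf_hi, n_fvf)
    dex = np.linspace(dex_lo, dex_hi, n_dex)
    rows = [(f, d) for f in fvf for d in dex]
    return pd.DataFrame(rows, columns=["fvf", "dex"])


# ---------------------------------------------------------------------------
# Analytic generator: GPA cylinders + tortuosity tensor
# ---------------------------------------------------------------------------


def _radius_quadrature(config: SubstrateConfig, n: int = _N_RADIUS_QUAD):
    """Volume-weighted radius quadrature.

    Signal fractions are volume fractions, so each radius r is weighted by
    r^2 times the gamma density; the r^2-tilted Gamma(k, theta) is
    Gamma(k+2, theta), and equal-probability midpoint quantiles of that law
    give an n-point rule with uniform weights.
    """
    k, theta = config.gamma_shape, config.gamma_scale
    q = (np.arange(n) + 0.5) / n
    radii = stats.gamma.ppf(q, a=k + 2, scale=theta)
    weights = np.full(n, 1.0 / n)
    return radii, weights


def _gpa_perp_factors(radii, d_in: float, delta: float, Delta: float):
    """GPA attenuation factor Q(r) for cylinders: ln S_perp = -g_perp^2 Q(r).

    Finite-pulse Gaussian phase approximation for diffusion restricted in a
    cylinder of radius r (gradient perpendicular to the axis), summed over
    the Bessel-derivative roots.  g_perp is in mT/m, output Q has units of
    (mT/m)^-2.
    """
    r = np.asarray(radii, dtype=float)[..., None]
    beta = special.jnp_zeros(1, _N_GPA_ROOTS)[None, :]
    am2 = (beta / r) ** 2  # alpha_m^2, um^-2
    dam2 = d_in * am2  # 1/ms
    num = (
        2.0 * dam2 * delta
        - 2.0
        + 2.0 * np.exp(-dam2 * delta)
        + 2.0 * np.exp(-dam2 * Delta)
        - np.exp(-dam2 * (Delta - delta))
        - np.exp(-dam2 * (Delta + delta))
    )
    den = d_in**2 * am2**3 * (am2 * r**2 - 1.0)
    q = 2.0 * GYROMAGNETIC_RATIO**2 * np.sum(num / den, axis=-1)
    return q


class _AnalyticModel:
    """Vectorized analytic fingerprint evaluator bound to one scheme.

    Precomputes the radius quadrature and the per-radius GPA factors so that
    evaluating many atoms and orientations reduces to broadcasting.
    """

    def __init__(self, scheme: AcquisitionScheme, config: SubstrateConfig):
        self.scheme = scheme
        self.config = config
        self.radii, self.rweights = _radius_quadrature(config)
        self.q_perp = _gpa_perp_factors(
            self.radii, config.d_in, scheme.delta_small, scheme.delta_big
        )  # (R,)

    def signals(self, fvf, dex, u):
        """Signals for parameter arrays at orientations u.

        fvf, dex : (...,) broadcastable parameter arrays
        u        : (..., 3) unit orientations, broadcastable with fvf

        Returns an array of shape broadcast(fvf, dex, u[..., 0]).shape + (M,).
        """
        fvf = np.asarray(fvf, dtype=float)
        dex = np.asarray(dex, dtype=float)
        u = np.asarray(u, dtype=float)
        scheme = self.scheme
        g = scheme.directions  # (M, 3)
        b = scheme.b_ms_um2  # (M,)
        G = scheme.gradient_strengths  # (M,)

        cos_t = u @ g.T  # (..., M)
        cos2 = np.clip(cos_t**2, 0.0, 1.0)
        sin2 = 1.0 - cos2
        gperp2 = (G**2) * sin2  # (..., M)

        # Intra-axonal: free along the axis, GPA-restricted across it,
        # volume-averaged over the radius distribution.
        s_perp = np.exp(-gperp2[..., None] * self.q_perp) @ self.rweights
        s_in = np.exp(-b * self.config.d_in * cos2) * s_perp  # (..., M)

        # Extra-axonal: axially symmetric tensor with tortuosity-reduced
        # perpendicular diffusivity Dex * (1 - fvf).
        d_par = dex[..., None] * cos2
        d_perp = (dex * (1.0 - fvf))[..., None] * sin2
        s_ex = np.exp(-b * (d_par + d_perp))

        out = fvf[..., None] * s_in + (1.0 - fvf)[..., None] * s_ex
        out[..., scheme.b0_mask] = 1.0
        return out

    def atoms_at(self, fvf, dex, u):
        """All-atom evaluation at a single orientation, as an (M, N) block.

        The restricted (GPA) term depends on the orientation but not on the
        (fvf, Dex) grid, so it is computed once per call and broadcast.
        """
        fvf = np.asarray(fvf, dtype=float)
        dex = np.asarray(dex, dtype=float)
        scheme = self.scheme
        g = scheme.directions
        b = scheme.b_ms_um2
        G = scheme.gradient_strengths
        cos2 = np.clip((g @ u) ** 2, 0.0, 1.0)  # (M,)
        sin2 = 1.0 - cos2
        s_perp = np.exp(-(G**2 * sin2)[:, None] * self.q_perp) @ self.rweights
        s_in = np.exp(-b * self.config.d_in * cos2) * s_perp  # (M,)
        expo = -b[:, None] * (
            cos2[:, None] * dex[None, :]
            + sin2[:, None] * (dex * (1.0 - fvf))[None, :]
        )
        s_ex = np.exp(expo)  # (M, N)
        out = fvf[None, :] * s_in[:, None] + (1.0 - fvf)[None, :] * s_ex
        out[scheme.b0_mask, :] = 1.0
        return out


def analytic_fingerprint(
    config: SubstrateConfig, scheme: AcquisitionScheme, u
) -> np.ndarray:
    """Closed-form fingerprint S = fvf*S_in + (1-fvf)*S_ex at orientation u."""
    u = np.asarray(u, dtype=float)
    if abs(np.linalg.norm(u) - 1.0) > 1e-9:
        raise ValueError("orientation must be a unit vector")
    model = _AnalyticModel(scheme, config)
    return model.signals(np.float64(config.fvf), np.float64(config.d_ex), u)


# ---------------------------------------------------------------------------
# Monte Carlo generator: random walk in a periodic cylinder packing
# ---------------------------------------------------------------------------


@dataclass
class CylinderPacking:
    """Periodic 2D random packing of parallel circular cylinders."""

    centers: np.ndarray  # (n, 2) um
    radii: np.ndarray  # (n,) um
    cell_size: float  # um

    @property
    def achieved_fvf(self) -> float:
        return float(np.sum(np.pi * self.radii**2) / self.cell_size**2)

    def min_image(self, points):
        """Wrap displacements of ``points`` to all centers (periodic)."""
        d = points[:, None, :] - self.centers[None, :, :]
        d -= self.cell_size * np.round(d / self.cell_size)
        return d

    def overlaps(self) -> int:
        if len(self.radii) < 2:
            return 0
        d = self.centers[:, None, :] - self.centers[None, :, :]
        d -= self.cell_size * np.round(d / self.cell_size)
        dist = np.sqrt(np.einsum("ijk,ijk->ij", d, d))
        rsum = self.radii[:, None] + self.radii[None, :]
        np.fill_diagonal(dist, np.inf)
        return int(np.sum(dist < rsum) // 2)


def pack_cylinders(
    config: SubstrateConfig, n_cyl: int, seed: int, max_attempts: int = 20000
) -> CylinderPacking:
    """Random-sequential-addition packing at the configured volume fraction.

    Radii are drawn from the gamma law; the periodic cell size is set from
    the drawn radii so that the achieved area fraction equals the requested
    fvf by construction.
    """
    if n_cyl < 1:
        raise ValueError("n_cyl must be >= 1")
    if config.fvf > 0.8:
        raise ValueError("requested fvf too dense for random sequential addition")
    rng = np.random.default_rng(seed)
    radii = rng.gamma(shape=config.gamma_shape, scale=config.gamma_scale, size=n_cyl)
    radii = np.sort(radii)[::-1]  # place large cylinders first
    cell = float(np.sqrt(np.sum(np.pi * radii**2) / config.fvf))
    centers = np.empty((n_cyl, 2))
    for i, r in enumerate(radii):
        for attempt in range(max_attempts):
            c = rng.uniform(0.0, cell, size=2)
            if i == 0:
                centers[0] = c
                break
            d = centers[:i] - c
            d -= cell * np.round(d / cell)
            if np.all(np.hypot(d[:, 0], d[:, 1]) >= radii[:i] + r):
                centers[i] = c
                break
        else:
            raise RuntimeError(
                f"could not place cylinder {i} after {max_attempts} attempts; "
                "try a lower fvf or fewer cylinders"
            )
    return CylinderPacking(centers=centers, radii=radii, cell_size=cell)


def _reflect_radial(pos, centers, radii):
    """Mirror positions at circular boundaries: radial distance d -> 2r - d."""
    d = pos - centers
    dist = np.linalg.norm(d, axis=-1, keepdims=True)
    dist = np.maximum(dist, 1e-12)
    new_dist = 2.0 * radii[..., None] - dist
    return centers + d * (new_dist / dist)


def mc_fingerprint(
    packing: CylinderPacking | None,
    config: SubstrateConfig,
    scheme: AcquisitionScheme,
    n_spins: int = 10000,
    dt: float = 5e-3,
    seed: int = 0,
) -> np.ndarray:
    """Monte Carlo PGSE signal of the two-compartment cylinder substrate.

    Spins are seeded uniformly (a fraction ``fvf`` inside cylinders, the rest
    outside), perform Gaussian random-walk steps with elastic (mirror)
    reflection at the impermeable membranes, and accrue phase under
    rectangular PGSE lobes of duration ``delta_small`` separated by
    ``delta_big``.  The per-measurement signal is |mean exp(i phi)|.

    ``packing=None`` simulates free diffusion at ``config.d_ex`` (no
    membranes), useful as a closed-form validation case.
    """
    rng = np.random.default_rng(seed)
    delta, Delta = scheme.delta_small, scheme.delta_big
    n_steps = int(np.ceil((Delta + delta) / dt))
    dt_eff = (Delta + delta) / n_steps

    if packing is None:
        n_in = 0
        pos = rng.uniform(0.0, 100.0, size=(n_spins, 2))
        cell = np.inf
        own_center = own_radius = None
    else:
        fvf = packing.achieved_fvf
        n_in = int(round(n_spins * fvf))
        cell = packing.cell_size
        # intra spins: cylinder chosen with probability ~ r^2, uniform in disk
        p = packing.radii**2 / np.sum(packing.radii**2)
        owner = rng.choice(len(packing.radii), size=n_in, p=p)
        rad = packing.radii[owner] * np.sqrt(rng.uniform(size=n_in))
        ang = rng.uniform(0, 2 * np.pi, size=n_in)
        pos_in = packing.centers[owner] + np.stack(
            [rad * np.cos(ang), rad * np.sin(ang)], axis=1
        )
        own_center = packing.centers[owner]
        own_radius = packing.radii[owner]
        # extra spins: rejection-sample outside all cylinders
        n_ex = n_spins - n_in
        pos_ex = np.empty((0, 2))
        while pos_ex.shape[0] < n_ex:
            cand = rng.uniform(0.0, cell, size=(2 * n_ex, 2))
            d = packing.min_image(cand)
            inside = np.any(
                np.einsum("ijk,ijk->ij", d, d) < packing.radii[None, :] ** 2, axis=1
            )
            pos_ex = np.concatenate([pos_ex, cand[~inside]])[:n_ex]
        pos = np.concatenate([pos_in, pos_ex], axis=0)

    n_total = pos.shape[0]
    z = np.zeros(n_total)
    d_intra = config.d_in
    d_extra = config.d_ex
    step_in = np.sqrt(2.0 * d_intra * dt_eff)
    step_ex = np.sqrt(2.0 * d_extra * dt_eff)
    sigma = np.full(n_total, step_ex)
    sigma[:n_in] = step_in

    # Gradient-weighted position integral J = sum c(t) x(t) dt; the phase of
    # measurement m is gamma * G_m * (g_m . J).  c(t) = +1 during the first
    # lobe, -1 during the second, 0 in between.
    J = np.zeros((n_total, 3))
    t = 0.0
    for _ in range(n_steps):
        step2d = rng.normal(scale=1.0, size=(n_total, 2)) * sigma[:, None]
        stepz = rng.normal(scale=1.0, size=n_total) * sigma
        new = pos + step2d
        if packing is not None:
            if n_in:
                d = new[:n_in] - own_center
                out = np.linalg.norm(d, axis=1) > own_radius
                if np.any(out):
                    new[:n_in][out] = _reflect_radial(
                        new[:n_in][out], own_center[out], own_radius[out]
                    )
                    # clamp any residual escape from the mirror approximation
                    d = new[:n_in] - own_center
                    dist = np.linalg.norm(d, axis=1)
                    bad = dist > own_radius
                    if np.any(bad):
                        new[:n_in][bad] = (
                            own_center[bad]
                            + d[bad]
                            / dist[bad, None]
                            * (own_radius[bad] * 0.999)[:, None]
                        )
            n_ex = n_total - n_in
            if n_ex:
                ext = new[n_in:]
                disp = ext[:, None, :] - packing.centers[None, :, :]
                disp -= cell * np.round(disp / cell)
                dist2 = np.einsum("ijk,ijk->ij", disp, disp)
                hit = dist2 < packing.radii[None, :] ** 2
                rows = np.any(hit, axis=1)
                if np.any(rows):
                    which = np.argmin(
                        np.where(hit[rows], dist2[rows], np.inf), axis=1
                    )
                    dvec = disp[rows, which]
                    dist = np.sqrt(np.maximum(dist2[rows, which], 1e-24))
                    r = packing.radii[which]
                    new_dist = np.minimum(2.0 * r - dist, cell / 2 * 0.999)
                    ext[rows] = ext[rows] + dvec / dist[:, None] * (
                        new_dist - dist
                    )[:, None]
                    new[n_in:] = ext
        pos = new
        z = z + stepz
        if not np.all(np.isfinite(pos)):
            raise FloatingPointError("spin escaped numerical bounds")
        tm = t + 0.5 * dt_eff  # midpoint weighting of the lobe integral
        if tm < delta:
            c = 1.0
        elif Delta <= tm < Delta + delta:
            c = -1.0
        else:
            c = 0.0
        if c != 0.0:
            J[:, 0] += c * pos[:, 0] * dt_eff
            J[:, 1] += c * pos[:, 1] * dt_eff
            J[:, 2] += c * z * dt_eff
        t += dt_eff

    G = scheme.gradient_strengths
    phases = GYROMAGNETIC_RATIO * (J @ scheme.directions.T) * G[None, :]
    signal = np.abs(np.exp(1j * phases).mean(axis=0))
    signal[scheme.b0_mask] = 1.0
    return signal


# ---------------------------------------------------------------------------
# Dictionary assembly and rotation
# ---------------------------------------------------------------------------


@dataclass
class FingerprintDictionary:
    """N single-fascicle atoms at the canonical orientation (z axis)."""

    atoms: np.ndarray  # (N, M), b0-normalized
    params: pd.DataFrame  # columns fvf, dex; N rows
    scheme: AcquisitionScheme
    generator_tag: str = "analytic"
    substrate: SubstrateConfig | None = None

    @property
    def N(self) -> int:
        return self.atoms.shape[0]

    def __post_init__(self):
        if self.atoms.shape != (len(self.params), self.scheme.M):
            raise ValueError("atoms shape inconsistent with params/scheme")


@dataclass
class RotatedDesign:
    """Fascicle-specific sub-dictionaries C^k for K fascicle orientations."""

    blocks: list  # K arrays of shape (M, N)
    orientations: np.ndarray  # (K, 3)
    dictionary: FingerprintDictionary

    @property
    def K(self) -> int:
        return len(self.blocks)

    @property
    def matrix(self) -> np.ndarray:
        """Stacked M x (K*N) design [C^1 ... C^K]."""
        return np.concatenate(self.blocks, axis=1)


_Z = np.array([0.0, 0.0, 1.0])


def build_dictionary(
    grid: pd.DataFrame | None = None,
    scheme: AcquisitionScheme | None = None,
    generator: str = "analytic",
    seed: int = 0,
    substrate: SubstrateConfig | None = None,
    n_spins: int = 10000,
    n_cyl: int = 40,
    dt: float = 5e-3,
) -> FingerprintDictionary:
    """One atom per (fvf, Dex) grid row at the canonical orientation z."""
    if scheme is None:
        raise ValueError("an acquisition scheme is required")
    if grid is None:
        grid = build_parameter_grid()
    base = substrate or SubstrateConfig(fvf=0.5, d_ex=1.0)
    if generator == "analytic":
        model = _AnalyticModel(
            scheme, SubstrateConfig(
                fvf=0.5, d_ex=1.0,
                radius_mean=base.radius_mean, radius_sd=base.radius_sd,
                d_in=base.d_in,
            )
        )
        atoms = model.signals(
            grid["fvf"].to_numpy(), grid["dex"].to_numpy(),
            np.broadcast_to(_Z, (len(grid), 3)),
        )
    elif generator == "montecarlo":
        atoms = np.empty((len(grid), scheme.M))
        for i, (fvf, dex) in enumerate(grid[["fvf", "dex"]].to_numpy()):
            cfg = SubstrateConfig(
                fvf=float(fvf), d_ex=float(dex),
                radius_mean=base.radius_mean, radius_sd=base.radius_sd,
                d_in=base.d_in,
            )
            packing = pack_cylinders(cfg, n_cyl=n_cyl, seed=seed + i)
            atoms[i] = mc_fingerprint(
                packing, cfg, scheme, n_spins=n_spins, dt=dt, seed=seed + 7919 * i
            )
    else:
        raise ValueError(f"unknown generator {generator!r}")
    return FingerprintDictionary(
        atoms=atoms,
        params=grid.reset_index(drop=True),
        scheme=scheme,
        generator_tag=generator,
        substrate=base,
    )


def _cached_model(dictionary: FingerprintDictionary) -> _AnalyticModel:
    """Per-dictionary cache of the analytic evaluator (quadrature reuse)."""
    model = getattr(dictionary, "_model_cache", None)
    if model is None:
        base = dictionary.substrate or SubstrateConfig(fvf=0.5, d_ex=1.0)
        model = _AnalyticModel(dictionary.scheme, base)
        dictionary._model_cache = model
    return model


def rotate_atoms(dictionary: FingerprintDictionary, u) -> np.ndarray:
    """All N atoms re-oriented to u, as an (M, N) sub-dictionary C(u).

    Analytic dictionaries are re-evaluated in closed form (exact).  Monte
    Carlo dictionaries exploit the axial symmetry of the substrate: within
    each shell the atom value depends on the direction only through
    |g . u|, so the canonical atom is interpolated over that scalar
    (monotone cubic, PCHIP).
    """
    u = np.asarray(u, dtype=float)
    if abs(np.linalg.norm(u) - 1.0) > 1e-9:
        raise ValueError("orientation must be a unit vector")
    scheme = dictionary.scheme
    if dictionary.generator_tag == "analytic":
        model = _cached_model(dictionary)
        return model.atoms_at(
            dictionary.params["fvf"].to_numpy(),
            dictionary.params["dex"].to_numpy(),
            u,
        )
    from scipy.interpolate import PchipInterpolator

    g = scheme.directions
    t_new = np.abs(g @ u)
    t_can = np.abs(g @ _Z)
    out = np.empty((scheme.M, dictionary.N))
    out[scheme.b0_mask] = 1.0
    for _, _, idx in scheme.shells():
        x = t_can[idx]
        order = np.argsort(x)
        x_sorted = x[order]
        distinct = np.concatenate([[True], np.diff(x_sorted) > 1e-9])
        keep = idx[order][distinct]
        if keep.size < 4:
            raise ValueError(
                "shell has fewer than 4 distinct |g.u| samples; cannot "
                "interpolate Monte Carlo atoms"
            )
        for j in range(dictionary.N):
            f = PchipInterpolator(t_can[keep], dictionary.atoms[j, keep])
            out[idx, j] = f(np.clip(t_new[idx], t_can[keep][0], t_can[keep][-1]))
    return out


def rotate_dictionary(
    dictionary: FingerprintDictionary, orientations
) -> RotatedDesign:
    """Fascicle-specific sub-dictionaries for one or more orientations."""
    orientations = np.atleast_2d(np.asarray(orientations, dtype=float))
    blocks = [rotate_atoms(dictionary, u) for u in orientations]
    return RotatedDesign(blocks=blocks, orientations=orientations, dictionary=dictionary)
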