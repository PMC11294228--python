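"""Persistence, NIfTI volume processing and the command-line interface.

Artifacts (dictionaries, voxel datasets, trained models, reports) are stored
as single self-describing files: numpy ``.npz`` archives embedding the
configuration and seed that produced them, CSV for metric tables, and NIfTI
for parameter maps.
"""

from __future__ import annotations

import json
import sys
import time
import warnings
from pathlib import Path

import numpy as np

from . import __version__
from .dictionary import FingerprintDictionary, SubstrateConfig, build_dictionary, build_parameter_grid
from .protocol import (
    AcquisitionScheme,
    build_clinical_scheme,
    build_hcp_mgh_scheme,
    read_scheme,
    write_scheme,
)
from .synthdata import SynthConfig, VoxelDataset, generate_dataset

__all__ = [
    "save_dictionary",
    "load_dictionary",
    "save_dataset",
    "load_dataset",
    "fit_volume",
    "main",
]


# ---------------------------------------------------------------------------
# Archives
# ---------------------------------------------------------------------------


def _scheme_to_arrays(scheme: AcquisitionScheme) -> dict:
    return {
        "scheme_directions": scheme.directions,
        "scheme_bvalues": scheme.bvalues,
        "scheme_timing": np.array(
            [
                scheme.delta_small,
                scheme.delta_big,
                scheme.te or np.nan,
                scheme.tr or np.nan,
            ]
        ),
    }


def _scheme_from_arrays(data) -> AcquisitionScheme:
    t = data["scheme_timing"]
    return AcquisitionScheme(
        directions=data["scheme_directions"],
        bvalues=data["scheme_bvalues"],
        delta_small=float(t[0]),
        delta_big=float(t[1]),
        te=None if np.isnan(t[2]) else float(t[2]),
        tr=None if np.isnan(t[3]) else float(t[3]),
    )


def _meta_array(meta: dict) -> np.ndarray:
    return np.frombuffer(json.dumps(meta, default=str).encode(), dtype=np.uint8)


def _meta_from(data) -> dict:
    return json.loads(bytes(data["meta"]).decode())


def save_dictionary(dictionary: FingerprintDictionary, path) -> None:
    sub = dictionary.substrate or SubstrateConfig(fvf=0.5, d_ex=1.0)
    np.savez(
        path,
        atoms=dictionary.atoms,
        fvf=dictionary.params["fvf"].to_numpy(),
        dex=dictionary.params["dex"].to_numpy(),
        meta=_meta_array(
            {
                "kind": "dictionary",
                "generator_tag": dictionary.generator_tag,
                "substrate": {
                    "radius_mean": sub.radius_mean,
                    "radius_sd": sub.radius_sd,
                    "d_in": sub.d_in,
                },
                "version": __version__,
            }
        ),
        **_scheme_to_arrays(dictionary.scheme),
    )


def load_dictionary(path) -> FingerprintDictionary:
    import pandas as pd

    data = np.load(path, allow_pickle=False)
    meta = _meta_from(data)
    sub = meta["substrate"]
    return FingerprintDictionary(
        atoms=data["atoms"],
        params=pd.DataFrame({"fvf": data["fvf"], "dex": data["dex"]}),
        scheme=_scheme_from_arrays(data),
        generator_tag=meta["generator_tag"],
        substrate=SubstrateConfig(
            fvf=0.5,
            d_ex=1.0,
            radius_mean=sub["radius_mean"],
            radius_sd=sub["radius_sd"],
            d_in=sub["d_in"],
        ),
    )


def save_dataset(dataset: VoxelDataset, path, config: dict | None = None) -> None:
    np.savez(
        path,
        y=dataset.y,
        y_clean=dataset.y_clean,
        orientations=dataset.orientations,
        nu=dataset.nu,
        fvf=dataset.fvf,
        dex=dataset.dex,
        snr=dataset.snr,
        meta=_meta_array(
            {
                "kind": "voxel_dataset",
                "seed": dataset.seed,
                "config": config or {},
                "version": __version__,
            }
        ),
        **_scheme_to_arrays(dataset.scheme),
    )


def load_dataset(path) -> VoxelDataset:
    data = np.load(path, allow_pickle=False)
    meta = _meta_from(data)
    return VoxelDataset(
        y=data["y"],
        y_clean=data["y_clean"],
        orientations=data["orientations"],
        nu=data["nu"],
        fvf=data["fvf"],
        dex=data["dex"],
        snr=data["snr"],
        scheme=_scheme_from_arrays(data),
        seed=int(meta["seed"]),
    )


# ---------------------------------------------------------------------------
# Volume processing
# ---------------------------------------------------------------------------


def fit_volume(image, mask, scheme, estimator, orientations_source=None) -> dict:
    """Apply a per-voxel estimator within a mask of a 4D volume.

    Parameters
    ----------
    image : (X, Y, Z, M) array
        DW volume whose 4th dimension matches ``scheme.M``.
    mask : (X, Y, Z) array
        Binary mask; voxels outside are zero-filled in the output maps.
    estimator : callable
        ``estimator(y, orientations) -> FascicleEstimate``.
    orientations_source : (X, Y, Z, K, 3) array or None
        Per-voxel fascicle orientations for estimators that need them.

    Returns a dict of 3D (or 4D for orientation components) maps per
    parameter per fascicle, keyed e.g. ``nu_1``, ``fvf_2``, ``dex_1``,
    ``orientation_1``.
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask).astype(bool)
    if image.ndim != 4 or image.shape[-1] != scheme.M:
        raise ValueError("image 4th dimension must equal the scheme size M")
    if mask.shape != image.shape[:3]:
        raise ValueError("mask shape must match the image grid")
    coords = np.argwhere(mask)
    if coords.size == 0:
        warnings.warn("empty mask: all maps are zero")
    maps: dict = {}
    K = None
    for x, y, z in coords:
        u = None if orientations_source is None else orientations_source[x, y, z]
        est = estimator(image[x, y, z], u)
        if K is None:
            K = est.K
            for k in range(1, K + 1):
                maps[f"nu_{k}"] = np.zeros(mask.shape)
                maps[f"fvf_{k}"] = np.zeros(mask.shape)
                maps[f"dex_{k}"] = np.zeros(mask.shape)
                if est.orientations is not None:
                    maps[f"orientation_{k}"] = np.zeros(mask.shape + (3,))
        for k in range(K):
            maps[f"nu_{k + 1}"][x, y, z] = est.nu[k]
            maps[f"fvf_{k + 1}"][x, y, z] = est.fvf[k]
            maps[f"dex_{k + 1}"][x, y, z] = est.dex[k]
            if est.orientations is not None:
                maps[f"orientation_{k + 1}"][x, y, z] = est.orientations[k]
    if K is None:
        maps = {"nu_1": np.zeros(mask.shape)}
    return maps


def make_mf_estimator(dictionary):
    """Per-voxel exhaustive-matching estimator (needs orientations)."""
    from .dictionary import rotate_dictionary
    from .reference_mf import mf_exhaustive

    def estimate(y, orientations):
        if orientations is None:
            raise ValueError("the reference estimator requires orientations")
        return mf_exhaustive(y, rotate_dictionary(dictionary, orientations))

    return estimate


def make_hybrid_estimator(model, dictionary):
    from .dictionary import rotate_dictionary
    from .hybrid import hybrid_predict, nnls_projection

    def estimate(y, orientations):
        if orientations is None:
            raise ValueError("the hybrid estimator requires orientations")
        w = nnls_projection(y, rotate_dictionary(dictionary, orientations))
        return hybrid_predict(model, w)

    return estimate


def make_fl_estimator(model, scheme, lmax: int = 12, lambda_reg: float = 1e-3):
    from .fully_learned import featurize_signal, fl_predict

    def estimate(y, orientations=None):
        return fl_predict(model, featurize_signal(y, scheme, lmax, lambda_reg))

    return estimate


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

import click  # noqa: E402


def _snapshot(out_dir, command, params, seed, t0):
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    snap = {
        "command": command,
        "version": __version__,
        "seed": seed,
        "params": params,
        "wall_time_s": round(time.time() - t0, 3),
    }
    with open(out / f"{command}.config.json", "w") as f:
        json.dump(snap, f, indent=2, default=str)


@click.group()
def main():
    """Microstructure fingerprinting of crossing white-matter fascicles."""


@main.command()
@click.option("--preset", type=click.Choice(["hcp-mgh", "clinical"]), required=True)
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--out", "out_dir", type=click.Path(), required=True)
def scheme(preset, seed, out_dir):
    """Write a preset acquisition scheme as bval/bvec files."""
    t0 = time.time()
    s = build_hcp_mgh_scheme(seed) if preset == "hcp-mgh" else build_clinical_scheme(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_scheme(s, out / f"{preset}.bval", out / f"{preset}.bvec")
    _snapshot(out, "scheme", {"preset": preset, "M": s.M}, seed, t0)
    click.echo(f"wrote {s.M}-measurement scheme to {out}")


def _load_scheme_opts(scheme_name, bval, bvec, delta_small, delta_big, seed):
    if scheme_name:
        return (
            build_hcp_mgh_scheme(seed)
            if scheme_name == "hcp-mgh"
            else build_clinical_scheme(seed)
        )
    if not (bval and bvec and delta_small and delta_big):
        raise click.UsageError("provide --scheme or (--bval --bvec --delta --Delta)")
    return read_scheme(bval, bvec, delta_small, delta_big)


@main.command("dict")
@click.option("--scheme", "scheme_name", type=click.Choice(["hcp-mgh", "clinical"]))
@click.option("--bval", type=click.Path(exists=True))
@click.option("--bvec", type=click.Path(exists=True))
@click.option("--delta", "delta_small", type=float)
@click.option("--Delta", "delta_big", type=float)
@click.option("--generator", type=click.Choice(["analytic", "montecarlo"]), default="analytic", show_default=True)
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--out", type=click.Path(), required=True)
def dict_cmd(scheme_name, bval, bvec, delta_small, delta_big, generator, seed, out):
    """Build the (fvf, Dex) fingerprint dictionary."""
    t0 = time.time()
    s = _load_scheme_opts(scheme_name, bval, bvec, delta_small, delta_big, seed)
    d = build_dictionary(build_parameter_grid(), s, generator=generator, seed=seed)
    save_dictionary(d, out)
    _snapshot(Path(out).parent, "dict", {"generator": generator, "N": d.N}, seed, t0)
    click.echo(f"built {d.N}-atom dictionary ({generator}) -> {out}")


@main.command()
@click.option("--dict", "dict_path", type=click.Path(exists=True), required=True)
@click.option("--n", type=int, required=True)
@click.option("--k", "k_fascicles", type=int, default=2, show_default=True)
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--out", type=click.Path(), required=True)
def simulate(dict_path, n, k_fascicles, seed, out):
    """Generate a synthetic voxel dataset."""
    t0 = time.time()
    d = load_dictionary(dict_path)
    cfg = SynthConfig(K=k_fascicles)
    ds = generate_dataset(n, d, cfg, seed=seed)
    save_dataset(ds, out, config=cfg.__dict__)
    _snapshot(Path(out).parent, "simulate", {"n": n, "K": k_fascicles}, seed, t0)
    click.echo(f"simulated {n} voxels -> {out}")


@main.command("fit-mf")
@click.option("--dict", "dict_path", type=click.Path(exists=True), required=True)
@click.option("--voxels", type=click.Path(exists=True), required=True)
@click.option("--orientations", type=click.Choice(["truth"]), default="truth", show_default=True)
@click.option("--out", type=click.Path(), required=True)
def fit_mf(dict_path, voxels, orientations, out):
    """Exhaustive reference matching on a voxel dataset."""
    t0 = time.time()
    from .evaluation import _mf_batch

    d = load_dictionary(dict_path)
    ds = load_dataset(voxels)
    res = _mf_batch(ds, d, ds.orientations)
    np.savez(out, nu=res["nu"], fvf=res["fvf"], dex=res["dex"])
    _snapshot(Path(out).parent, "fit-mf", {"n": len(ds)}, ds.seed, t0)
    click.echo(f"fitted {len(ds)} voxels -> {out}")


@main.command("train-hybrid")
@click.option("--dict", "dict_path", type=click.Path(exists=True), required=True)
@click.option("--voxels", type=click.Path(exists=True), required=True)
@click.option("--epochs", type=int, default=30, show_default=True)
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--out", type=click.Path(), required=True)
def train_hybrid_cmd(dict_path, voxels, epochs, seed, out):
    """Train the hybrid (NNLS + split-arm MLP) regressor."""
    t0 = time.time()
    from .hybrid import HybridConfig, train_hybrid

    d = load_dictionary(dict_path)
    ds = load_dataset(voxels)
    model = train_hybrid(ds, d, HybridConfig(epochs=epochs), seed=seed)
    model.save(out)
    _snapshot(Path(out).parent, "train-hybrid", {"epochs": epochs, "n": len(ds)}, seed, t0)
    click.echo(f"trained hybrid model -> {out}")


@main.command("train-fl")
@click.option("--dict", "dict_path", type=click.Path(exists=True), required=True)
@click.option("--voxels", type=click.Path(exists=True), required=True)
@click.option("--epochs", type=int, default=40, show_default=True)
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--out", type=click.Path(), required=True)
def train_fl_cmd(dict_path, voxels, epochs, seed, out):
    """Train the fully-learned (SH + MLP) regressor."""
    t0 = time.time()
    from .fully_learned import FLConfig, train_fl

    d = load_dictionary(dict_path)
    ds = load_dataset(voxels)
    model = train_fl(ds, d, FLConfig(epochs=epochs), seed=seed)
    model.save(out)
    _snapshot(Path(out).parent, "train-fl", {"epochs": epochs, "n": len(ds)}, seed, t0)
    click.echo(f"trained fully-learned model -> {out}")


@main.command("fit-hybrid")
@click.option("--model", "model_path", type=click.Path(exists=True), required=True)
@click.option("--dict", "dict_path", type=click.Path(exists=True), required=True)
@click.option("--voxels", type=click.Path(exists=True), required=True)
@click.option("--out", type=click.Path(), required=True)
def fit_hybrid(model_path, dict_path, voxels, out):
    """Apply a trained hybrid model to a voxel dataset (truth orientations)."""
    t0 = time.time()
    from .hybrid import TrainedRegressor, compute_weight_features, hybrid_predict_batch

    model = TrainedRegressor.load(model_path)
    d = load_dictionary(dict_path)
    ds = load_dataset(voxels)
    w = compute_weight_features(ds, d)
    res = hybrid_predict_batch(model, w)
    np.savez(out, **res)
    _snapshot(Path(out).parent, "fit-hybrid", {"n": len(ds)}, ds.seed, t0)
    click.echo(f"fitted {len(ds)} voxels -> {out}")


@main.command("fit-fl")
@click.option("--model", "model_path", type=click.Path(exists=True), required=True)
@click.option("--voxels", type=click.Path(exists=True), required=True)
@click.option("--out", type=click.Path(), required=True)
def fit_fl(model_path, voxels, out):
    """Apply a trained fully-learned model to a voxel dataset."""
    t0 = time.time()
    from .fully_learned import featurize_dataset, fl_predict_batch
    from .hybrid import TrainedRegressor

    model = TrainedRegressor.load(model_path)
    ds = load_dataset(voxels)
    res = fl_predict_batch(model, featurize_dataset(ds))
    np.savez(out, **res)
    _snapshot(Path(out).parent, "fit-fl", {"n": len(ds)}, ds.seed, t0)
    click.echo(f"fitted {len(ds)} voxels -> {out}")


@main.command()
@click.option("--exp", type=click.Choice(["1", "2"]), required=True)
@click.option("--dict", "dict_path", type=click.Path(exists=True))
@click.option("--model", "model_path", type=click.Path(exists=True))
@click.option("--n-train", type=int, default=100000, show_default=True)
@click.option("--n-test", type=int, default=15000, show_default=True)
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--out", "out_dir", type=click.Path(), required=True)
def evaluate(exp, dict_path, model_path, n_train, n_test, seed, out_dir):
    """Run an experiment harness and write its report tables."""
    t0 = time.time()
    from .evaluation import run_experiment_1, run_experiment_2

    if exp == "1":
        if not dict_path:
            raise click.UsageError("--dict is required for experiment 1")
        d = load_dictionary(dict_path)
        report = run_experiment_1(d, seed=seed, n_train=n_train, n_test=n_test)
    else:
        if not model_path:
            raise click.UsageError("--model is required for experiment 2")
        from .hybrid import TrainedRegressor

        model = TrainedRegressor.load(model_path)
        report = run_experiment_2(model, seed=seed, n_train=n_train, n_test=n_test)
    report.save(out_dir)
    _snapshot(out_dir, "evaluate", {"exp": exp, "n_train": n_train, "n_test": n_test}, seed, t0)
    click.echo(report.summary.to_string(index=False))


@main.command()
@click.option("--image", type=click.Path(exists=True), required=True)
@click.option("--mask", "mask_path", type=click.Path(exists=True), required=True)
@click.option("--model", "model_path", type=click.Path(exists=True), required=True)
@click.option("--bval", type=click.Path(exists=True), required=True)
@click.option("--bvec", type=click.Path(exists=True), required=True)
@click.option("--delta", "delta_small", type=float, required=True)
@click.option("--Delta", "delta_big", type=float, required=True)
@click.option("--out", "out_dir", type=click.Path(), required=True)
def maps(image, mask_path, model_path, bval, bvec, delta_small, delta_big, out_dir):
    """Voxel-wise parameter maps from a NIfTI volume (fully-learned model)."""
    t0 = time.time()
    import nibabel as nib

    from .hybrid import TrainedRegressor

    img = nib.load(image)
    msk = nib.load(mask_path)
    s = read_scheme(bval, bvec, delta_small, delta_big)
    model = TrainedRegressor.load(model_path)
    estimator = make_fl_estimator(model, s)
    out_maps = fit_volume(img.get_fdata(), msk.get_fdata(), s, estimator)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, arr in out_maps.items():
        nib.save(nib.Nifti1Image(arr.astype(np.float32), img.affine), out / f"{name}.nii.gz")
    _snapshot(out, "maps", {"image": str(image)}, 0, t0)
    click.echo(f"wrote {len(out_maps)} maps to {out}")


if __name__ == "__main__":
    sys.exit(main())
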