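"""Readers/writers and configuration parsing.

Formats: NIfTI (.nii/.nii.gz, real float, lossless), PNG/TIFF (magnitude;
PNG is stored as uint8 of the magnitude clipped to [0, 255] and rounded, so
round-trips are exact to half a gray level), and HDF5 for complex images,
k-space bundles and dictionary snapshots.  Solver configuration is YAML
mirroring :class:`~wtbmdu.reconstruction.SolverConfig`; unknown keys are
rejected.
"""

from __future__ import annotations

import dataclasses
import json
import os
from pathlib import Path

import h5py
import numpy as np
import yaml

from .operators import KSpaceData, SamplingMask
from .reconstruction import SolverConfig

__all__ = [
    "load_config",
    "save_config",
    "read_image",
    "write_image",
    "save_kspace",
    "load_kspace",
    "save_dictionary",
    "load_dictionary",
    "write_mask_png",
    "run_experiment",
]

IMAGE_FORMATS = (".nii", ".nii.gz", ".png", ".tif", ".tiff", ".h5", ".hdf5")


def _suffix(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".nii.gz"):
        return ".nii.gz"
    return path.suffix.lower()


def load_config(path: str | os.PathLike) -> SolverConfig:
    """Parse and validate a YAML solver config; an empty file yields the
    nominal defaults.  Unknown keys are rejected."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    known = {f.name for f in dataclasses.fields(SolverConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ValueError(f"unknown config keys: {', '.join(unknown)}")
    return SolverConfig(**raw).validate()


def save_config(config: SolverConfig, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh)


def read_image(path: str | os.PathLike) -> np.ndarray:
    """Read a 2D image: NIfTI / PNG / TIFF (real or magnitude) or HDF5
    (complex, datasets /image/real and /image/imag)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    kind = _suffix(path)
    if kind in (".nii", ".nii.gz"):
        import nibabel as nib

        data = np.asanyarray(nib.load(str(path)).dataobj).squeeze()
        return data.astype(float)
    if kind in (".png", ".tif", ".tiff"):
        import imageio.v3 as iio

        return np.asarray(iio.imread(path)).astype(float)
    if kind in (".h5", ".hdf5"):
        with h5py.File(path, "r") as fh:
            return fh["image/real"][()] + 1j * fh["image/imag"][()]
    raise ValueError(
        f"unsupported image format {kind!r}; supported: {', '.join(IMAGE_FORMATS)}"
    )


def write_image(img: np.ndarray, path: str | os.PathLike) -> None:
    """Write an image by extension.  PNG stores the magnitude clipped to
    [0, 255] as uint8; NIfTI stores real float data; HDF5 stores the full
    complex field."""
    path = Path(path)
    img = np.asarray(img)
    kind = _suffix(path)
    if kind in (".nii", ".nii.gz"):
        import nibabel as nib

        if np.iscomplexobj(img):
            raise ValueError("NIfTI export is real-valued; write HDF5 for complex")
        nib.save(nib.Nifti1Image(img.astype(np.float64), np.eye(4)), str(path))
    elif kind in (".png", ".tif", ".tiff"):
        import imageio.v3 as iio

        mag = np.round(np.clip(np.abs(img), 0.0, 255.0)).astype(np.uint8)
        iio.imwrite(path, mag)
    elif kind in (".h5", ".hdf5"):
        with h5py.File(path, "w") as fh:
            fh.create_dataset("image/real", data=np.real(img))
            fh.create_dataset("image/imag", data=np.imag(img))
    else:
        raise ValueError(
            f"unsupported image format {kind!r}; supported: {', '.join(IMAGE_FORMATS)}"
        )


def save_kspace(data: KSpaceData, path: str | os.PathLike) -> None:
    """Write a k-space bundle: /kspace/real, /kspace/imag, /mask (uint8),
    attrs {sigma, kind, fraction, seed}."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("kspace/real", data=data.samples.real)
        fh.create_dataset("kspace/imag", data=data.samples.imag)
        fh.create_dataset("mask", data=data.mask.indicator.astype(np.uint8))
        fh.attrs["sigma"] = data.noise_sigma
        fh.attrs["kind"] = data.mask.kind
        fh.attrs["fraction"] = data.mask.fraction
        fh.attrs["seed"] = -1 if data.mask.seed is None else data.mask.seed


def load_kspace(path: str | os.PathLike) -> KSpaceData:
    with h5py.File(path, "r") as fh:
        samples = fh["kspace/real"][()] + 1j * fh["kspace/imag"][()]
        mask = SamplingMask(
            indicator=fh["mask"][()].astype(bool),
            kind=str(fh.attrs["kind"]),
            seed=int(fh.attrs["seed"]),
        )
        return KSpaceData(samples=samples, mask=mask,
                          noise_sigma=float(fh.attrs["sigma"]))


def save_dictionary(D: np.ndarray, path: str | os.PathLike, *, side: int,
                    K: int, iteration: int = 0) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("dict/real", data=np.real(D))
        fh.create_dataset("dict/imag", data=np.imag(D))
        fh.attrs.update({"s": side, "K": K, "iter": iteration})


def load_dictionary(path: str | os.PathLike) -> np.ndarray:
    with h5py.File(path, "r") as fh:
        return fh["dict/real"][()] + 1j * fh["dict/imag"][()]


def write_mask_png(mask: SamplingMask, path: str | os.PathLike) -> None:
    import imageio.v3 as iio

    iio.imwrite(Path(path), (mask.indicator * np.uint8(255)))


# ---------------------------------------------------------------------------
# experiment runner
# ---------------------------------------------------------------------------

SUMMARY_COLUMNS = [
    "phantom", "size", "variant", "p", "mask_kind", "fraction_target",
    "fraction", "accel", "sigma", "seed", "n_outer", "converged",
    "psnr_zero_filled_db", "psnr_db", "hfen", "status",
]


def run_experiment(manifest: dict, out_dir: str | os.PathLike) -> list[dict]:
    """Run a simulate -> reconstruct -> evaluate grid and summarize.

    ``manifest`` keys: ``phantom`` ({shepp_logan, piecewise_texture}),
    ``size``, ``seed``, and the grid lists ``variants`` (each a {variant, p}
    mapping or plain name), ``mask_kinds``, ``fractions``, ``sigmas``;
    optional ``config`` mapping of SolverConfig overrides.  Writes one
    MetricReport JSON per cell plus ``summary.csv``; per-cell failures are
    recorded in the summary and the run continues.
    """
    from . import synthetic
    from .evaluation import evaluate_pair, psnr
    from .operators import make_mask
    from .reconstruction import reconstruct
    from .operators import fourier_adjoint

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    phantom_kind = manifest.get("phantom", "shepp_logan")
    size = int(manifest.get("size", 128))
    seed = int(manifest.get("seed", 0))
    overrides = dict(manifest.get("config", {}))

    if phantom_kind == "shepp_logan":
        ref = synthetic.shepp_logan(size)
    elif phantom_kind == "piecewise_texture":
        ref = synthetic.piecewise_texture_phantom(size, seed=seed)
    else:
        raise ValueError(f"unknown phantom {phantom_kind!r}")

    rows = []
    for spec in manifest.get("variants", ["tbmdu"]):
        if isinstance(spec, str):
            variant, p = spec, overrides.get("p", 0.5)
        else:
            variant, p = spec["variant"], spec.get("p", overrides.get("p", 0.5))
        for kind in manifest.get("mask_kinds", ["radial"]):
            for fraction in manifest.get("fractions", [0.3]):
                for sigma in manifest.get("sigmas", [0.0]):
                    row = {
                        "phantom": phantom_kind, "size": size, "variant": variant,
                        "p": p, "mask_kind": kind, "fraction_target": fraction,
                        "sigma": sigma, "seed": seed, "status": "ok",
                    }
                    try:
                        mask = make_mask(kind, (size, size), fraction=fraction,
                                         seed=seed)
                        data = synthetic.simulate_acquisition(ref, mask, sigma,
                                                              seed=seed)
                        cfg = SolverConfig(**{**overrides, "variant": variant,
                                              "p": p, "seed": seed}).validate()
                        recon, hist = reconstruct(data, cfg, reference=ref)
                        report = evaluate_pair(ref, recon)
                        row.update(report.to_dict())
                        row["fraction"] = mask.fraction
                        row["accel"] = 1.0 / mask.fraction
                        row["n_outer"] = hist["n_outer"]
                        row["converged"] = hist["converged"]
                        row["psnr_zero_filled_db"] = psnr(ref, fourier_adjoint(data))
                        cell = (f"{phantom_kind}_{variant}_p{p}_{kind}"
                                f"_f{fraction}_s{sigma}.json")
                        with open(out_dir / cell, "w") as fh:
                            json.dump(row, fh, indent=2, default=float)
                    except Exception as exc:  # keep sweeping on cell failure
                        row["status"] = f"error: {exc}"
                    rows.append(row)

    with open(out_dir / "summary.csv", "w") as fh:
        fh.write(",".join(SUMMARY_COLUMNS) + "\n")
        for row in rows:
            fh.write(",".join(str(row.get(c, "")) for c in SUMMARY_COLUMNS) + "\n")
    return rows
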