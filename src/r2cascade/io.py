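"""File formats and run configuration.

Multi-echo series travel as 4D NIfTI volumes (echo along the 4th axis) with a
JSON sidecar carrying the echo times in ms and acquisition/simulation
provenance; parameter maps as paired 3D->2D NIfTI volumes (S0, R2*) plus a
JSON provenance record; patch corpora as HDF5 archives with aligned groups
and an embedded JSON manifest; run configuration as YAML with strict
(unknown keys rejected) parsing.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import yaml

from .fitting import FitOptions
from .nn import DenoiserConfig, MapperConfig, TrainConfig
from .phantom import PatchSet, PhantomSpec, SimulatedDataset
from .signal_model import EchoTimes, MultiEchoSeries, NoiseSpec, ParameterMaps

__all__ = [
    "read_multiecho",
    "write_multiecho",
    "read_maps",
    "write_maps",
    "write_dataset",
    "read_dataset",
    "save_patchset",
    "load_patchset",
    "RunConfig",
]


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def _save_nifti(data: np.ndarray, path: Path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), np.eye(4)), str(path))


def write_multiecho(series: MultiEchoSeries, path, extra: dict | None = None) -> Path:
    """Write a series as 4D NIfTI (H, W, 1, echo) plus a JSON sidecar."""
    path = Path(path)
    _save_nifti(series.data[:, :, None, :], path)
    sidecar = {"te_ms": series.te.te_ms.tolist(), **(extra or {})}
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))
    return path


def read_multiecho(path, te_ms=None) -> MultiEchoSeries:
    """Read a 4D NIfTI series; echo times from the sidecar unless given.

    The echo count of the volume must equal the TE count.
    """
    path = Path(path)
    vol = np.asarray(nib.load(str(path)).dataobj, dtype=float)
    if vol.ndim == 4:
        if vol.shape[2] == 1:
            vol = vol[:, :, 0, :]
        else:
            raise ValueError("expected a single-slice 4D volume (H, W, 1, echoes)")
    if vol.ndim != 3:
        raise ValueError("expected a 4D NIfTI with echoes along the last axis")
    if te_ms is None:
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise ValueError(f"no echo times given and no sidecar at {sidecar}")
        te_ms = json.loads(sidecar.read_text())["te_ms"]
    te = EchoTimes(np.asarray(te_ms, dtype=float))
    if vol.shape[2] != len(te):
        raise ValueError(
            f"volume has {vol.shape[2]} echoes but {len(te)} echo times were given"
        )
    if np.any(vol < 0):
        raise ValueError("magnitude volume contains negative intensities")
    return MultiEchoSeries(vol, te)


def write_maps(maps: ParameterMaps, prefix, provenance: dict | None = None) -> dict:
    """Write S0/R2* maps as <prefix>_s0.nii.gz / <prefix>_r2star.nii.gz.

    A JSON file <prefix>_maps.json records the units and any provenance
    (method, sigma, seed, ...) plus a hash of that configuration.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "s0": prefix.parent / f"{prefix.name}_s0.nii.gz",
        "r2star": prefix.parent / f"{prefix.name}_r2star.nii.gz",
    }
    _save_nifti(maps.s0, paths["s0"])
    _save_nifti(maps.r2star, paths["r2star"])
    record = {
        "units": {"s0": "arbitrary", "r2star": "s^-1"},
        "provenance": provenance or {},
    }
    record["config_hash"] = hashlib.sha256(
        json.dumps(record["provenance"], sort_keys=True).encode()
    ).hexdigest()
    meta = prefix.parent / f"{prefix.name}_maps.json"
    meta.write_text(json.dumps(record, indent=2))
    return {**{k: str(v) for k, v in paths.items()}, "meta": str(meta)}


def read_maps(prefix) -> ParameterMaps:
    prefix = Path(prefix)
    s0 = np.asarray(
        nib.load(str(prefix.parent / f"{prefix.name}_s0.nii.gz")).dataobj, dtype=float
    )
    r2 = np.asarray(
        nib.load(str(prefix.parent / f"{prefix.name}_r2star.nii.gz")).dataobj,
        dtype=float,
    )
    return ParameterMaps(np.squeeze(s0), np.squeeze(r2))


def write_dataset(ds: SimulatedDataset, outdir) -> Path:
    """Write one simulated subject: noisy/clean series, truth maps, masks."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    extra = {
        "sigma_g": ds.noise.sigma_g,
        "seed": ds.noise.seed,
        "snr": ds.snr,
        "dataset_id": ds.dataset_id,
    }
    write_multiecho(ds.noisy, outdir / "noisy.nii.gz", extra)
    write_multiecho(ds.clean, outdir / "clean.nii.gz", extra)
    write_maps(ds.truth, outdir / "truth", provenance=extra)
    for name, mask in ds.masks.items():
        _save_nifti(mask.astype(np.uint8), outdir / f"mask_{name}.nii.gz")
    return outdir


def read_dataset(outdir) -> SimulatedDataset:
    outdir = Path(outdir)
    noisy = read_multiecho(outdir / "noisy.nii.gz")
    clean = read_multiecho(outdir / "clean.nii.gz")
    truth = read_maps(outdir / "truth")
    sidecar = json.loads((outdir / "noisy.json").read_text())
    masks = {}
    for p in sorted(outdir.glob("mask_*.nii.gz")):
        name = p.name[len("mask_"): -len(".nii.gz")]
        masks[name] = np.asarray(nib.load(str(p)).dataobj).astype(bool)
    return SimulatedDataset(
        truth,
        clean,
        noisy,
        masks,
        NoiseSpec(sidecar["sigma_g"], sidecar["seed"]),
        sidecar["snr"],
        sidecar["dataset_id"],
    )


def save_patchset(patches: PatchSet, manifest: dict, path) -> Path:
    """HDF5 archive with aligned noisy/clean/truth groups and the manifest."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("noisy", data=patches.noisy, compression="gzip")
        f.create_dataset("clean", data=patches.clean, compression="gzip")
        f.create_dataset("truth", data=patches.truth, compression="gzip")
        f.create_dataset("sigma", data=patches.sigma)
        f.attrs["manifest"] = json.dumps(manifest)
    return path


def load_patchset(path) -> tuple[PatchSet, dict]:
    with h5py.File(path, "r") as f:
        manifest = json.loads(f.attrs["manifest"])
        patches = PatchSet(
            f["noisy"][...],
            f["clean"][...],
            f["truth"][...],
            f["sigma"][...],
            [
                (rec["dataset"], tuple(rec["offset"]), rec["op"])
                for rec in manifest["patches"]
            ],
        )
    return patches, manifest


def _from_dict(cls, d: dict):
    allowed = {f.name for f in fields(cls)}
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    d = dict(d)
    for key in ("r2star_range", "vessel_radius_range", "r2_bounds"):
        if key in d and d[key] is not None:
            d[key] = tuple(d[key])
    return cls(**d)


_STAGE_TYPES = {
    "phantom": PhantomSpec,
    "fit": FitOptions,
    "denoiser": DenoiserConfig,
    "mapper": MapperConfig,
    "train": TrainConfig,
}


@dataclass(frozen=True)
class RunConfig:
    """Serializable configuration for a full simulate/train/evaluate run."""

    phantom: PhantomSpec = PhantomSpec()
    fit: FitOptions = FitOptions()
    denoiser: DenoiserConfig = DenoiserConfig()
    mapper: MapperConfig = MapperConfig()
    train: TrainConfig = TrainConfig()
    seed: int = 0
    log_level: str = "INFO"

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        allowed = {f.name for f in fields(RunConfig)}
        unknown = set(raw) - allowed
        if unknown:
            raise ValueError(f"unknown keys in run config: {sorted(unknown)}")
        kwargs = {}
        for key, cls in _STAGE_TYPES.items():
            if key in raw:
                kwargs[key] = _from_dict(cls, raw[key])
        for key in ("seed", "log_level"):
            if key in raw:
                kwargs[key] = raw[key]
        return RunConfig(**kwargs)

    def to_yaml(self, path) -> None:
        payload = {key: asdict(getattr(self, key)) for key in _STAGE_TYPES}
        payload["seed"] = self.seed
        payload["log_level"] = self.log_level
        # tuples -> lists for clean YAML round-trips
        payload = json.loads(json.dumps(payload))
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))
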