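"""File formats, geometry bookkeeping, configuration, and run manifests.

Complex arrays (k-space, sensitivities) are stored in HDF5 as paired
real/imaginary datasets — portable across languages, unlike compound
complex types. Magnitude volumes and masks go to NIfTI-1 with the
voxel size encoded in the affine. Axis order for k-space containers is
``(coil, x, y, z)`` with the DC index stored explicitly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
from numpy.typing import NDArray

from csmra.phantom import KSpaceData, SensitivityMaps
from csmra.recon import ReconConfig
from csmra.sampling import MaskParams, SamplingMask

logger = logging.getLogger(__name__)


class MalformedFileError(ValueError):
    """A container is missing a required dataset or attribute."""


# ---------------------------------------------------------------- geometry


def fov_from_matrix(matrix: int, voxel_mm: float) -> float:
    """Field of view in mm: matrix size times voxel size.

    The exact product is returned; display rounding (e.g. 156.86 mm
    shown as 157 mm) is left to the caller.
    """
    if matrix < 1:
        raise ValueError("matrix size must be >= 1")
    if voxel_mm <= 0:
        raise ValueError("voxel size must be positive")
    return matrix * voxel_mm


@dataclass(frozen=True)
class GeometryHeader:
    """Acquisition geometry: matrix size, voxel size, derived FOV."""

    matrix: tuple[int, int, int]
    voxel_mm: tuple[float, float, float]
    slab_overlap: float = 0.0

    @property
    def fov_mm(self) -> tuple[float, float, float]:
        return tuple(
            fov_from_matrix(m, v) for m, v in zip(self.matrix, self.voxel_mm)
        )  # type: ignore[return-value]


# ---------------------------------------------------------------- k-space


def save_kspace(
    path: str | Path, kspace: KSpaceData, sens: SensitivityMaps | None = None
) -> None:
    """Write a k-space container (paired real/imag datasets + metadata)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("kspace_real", data=kspace.data.real)
        f.create_dataset("kspace_imag", data=kspace.data.imag)
        if sens is not None:
            f.create_dataset("sens_real", data=sens.maps.real)
            f.create_dataset("sens_imag", data=sens.maps.imag)
        f.attrs["shape"] = kspace.data.shape
        f.attrs["dc_index"] = kspace.dc_index
        f.attrs["noise_sigma"] = kspace.noise_sigma
        f.attrs["seed"] = -1 if kspace.seed is None else kspace.seed
        f.attrs["axis_order"] = "coil,x,y,z"


def load_kspace(
    path: str | Path,
) -> tuple[KSpaceData, SensitivityMaps | None]:
    """Read a k-space container written by :func:`save_kspace`."""
    with h5py.File(path, "r") as f:
        for name in ("kspace_real", "kspace_imag"):
            if name not in f:
                raise MalformedFileError(f"{path}: missing dataset '{name}'")
        data = f["kspace_real"][:] + 1j * f["kspace_imag"][:]
        if data.ndim != 4:
            raise MalformedFileError(
                f"{path}: dataset 'kspace_real' must be 4D (coil,x,y,z)"
            )
        sens = None
        if "sens_real" in f:
            sens = SensitivityMaps(f["sens_real"][:] + 1j * f["sens_imag"][:])
        seed = int(f.attrs.get("seed", -1))
        ks = KSpaceData(
            data=data,
            noise_sigma=float(f.attrs.get("noise_sigma", 0.0)),
            seed=None if seed < 0 else seed,
        )
    return ks, sens


# ---------------------------------------------------------------- masks


def save_mask(path: str | Path, mask: SamplingMask) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("mask", data=mask.mask.astype(np.uint8))
        f.attrs["R"] = mask.params.R
        f.attrs["pp"] = mask.params.pp
        f.attrs["calib"] = mask.params.calib
        f.attrs["seed"] = mask.params.seed
        f.attrs["achieved_R"] = mask.achieved_R
        f.attrs["r0"] = mask.r0


def load_mask(path: str | Path) -> SamplingMask:
    with h5py.File(path, "r") as f:
        if "mask" not in f:
            raise MalformedFileError(f"{path}: missing dataset 'mask'")
        try:
            params = MaskParams(
                R=float(f.attrs["R"]),
                pp=float(f.attrs["pp"]),
                calib=int(f.attrs["calib"]),
                seed=int(f.attrs["seed"]),
            )
        except KeyError as exc:
            raise MalformedFileError(f"{path}: missing attribute {exc}") from exc
        return SamplingMask(
            mask=f["mask"][:].astype(bool),
            params=params,
            achieved_R=float(f.attrs["achieved_R"]),
            r0=float(f.attrs.get("r0", np.nan)),
        )


def save_mask_png(path: str | Path, mask: SamplingMask) -> None:
    """Binary PNG of the sampling pattern, for visual inspection."""
    from PIL import Image

    Image.fromarray((mask.mask * 255).astype(np.uint8)).save(path)


def check_mask_matches(mask: SamplingMask, kspace: KSpaceData) -> None:
    if mask.shape != kspace.data.shape[2:]:
        raise MalformedFileError(
            f"mask shape {mask.shape} does not match k-space phase-encode "
            f"dims {kspace.data.shape[2:]}"
        )


# ---------------------------------------------------------------- NIfTI


def save_nifti(
    path: str | Path, volume: NDArray, voxel_mm: tuple[float, float, float] = (1, 1, 1)
) -> None:
    """Magnitude volume to NIfTI-1 with voxel size in the affine."""
    affine = np.diag([*voxel_mm, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float64), affine), str(path))


def load_nifti(path: str | Path) -> tuple[NDArray, tuple[float, float, float]]:
    img = nib.load(str(path))
    voxels = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj), voxels  # type: ignore[return-value]


# ---------------------------------------------------------------- config


def load_sweep_config(path: str | Path) -> tuple["SweepConfig", dict[str, str]]:
    """Read a TOML sweep configuration.

    Returns the :class:`~csmra.sweep.SweepConfig` and a mapping of
    volume id to k-space container path from the ``[datasets]`` table.
    """
    from csmra.sweep import SweepConfig

    with open(path, "rb") as f:
        raw = tomllib.load(f)
    grid = raw.get("grid", {})
    recon_tbl = raw.get("recon", {})
    cfg = SweepConfig(
        R_list=tuple(grid.get("R_list", SweepConfig.R_list)),
        pp_list=tuple(grid.get("pp_list", SweepConfig.pp_list)),
        calib_list=tuple(grid.get("calib_list", SweepConfig.calib_list)),
        masks_per_setting=int(grid.get("masks_per_setting", 2)),
        seed_base=int(grid.get("seed_base", 0)),
        recon=ReconConfig(
            lam=float(recon_tbl.get("lam", 0.007)),
            n_iter=int(recon_tbl.get("n_iter", 20)),
        ),
        calib_ref=int(grid.get("calib_ref", 32)),
    )
    datasets = {str(k): str(v) for k, v in raw.get("datasets", {}).items()}
    return cfg, datasets


# ---------------------------------------------------------------- manifest


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record: config, seeds, and per-file content digests."""

    tool_version: str
    config: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    files: dict = field(default_factory=dict)
    created: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )

    def add_file(self, role: str, path: str | Path) -> None:
        self.files[role] = {"path": str(path), "sha256": sha256_of(path)}

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as f:
            json.dump(self.__dict__, f, indent=2, default=str)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunManifest":
        with open(path) as f:
            raw = json.load(f)
        return cls(**raw)
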