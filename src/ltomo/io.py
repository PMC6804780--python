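"""Persistence: HDF5 measurement containers, TIFF/HDF5 volumes, presets.

Measurement schema (HDF5)
-------------------------
``/fields_re``, ``/fields_im``  float32, (L, nx, ny) -- complex fields as
paired real/imag (portable across HDF5 dialects); ``/illum`` float64 (L, 4)
columns (kx, ky, kz, amplitude); grid attributes ``nx ny nz dx dz
wavelength n0`` plus ``schema_version``; ``/meta`` JSON string.

Volumes are stored as 32-bit TIFF stacks (one page per z slice) with the
grid metadata in a JSON sidecar, or as a single HDF5 file.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import h5py
import numpy as np
import tifffile
import yaml

from .core import MeasurementSet, OpticalGrid, PlaneWaveIllumination, RIVolume

SCHEMA_VERSION = "1.0"


class SchemaError(ValueError):
    """Raised when a stored file does not match the expected schema."""


def _grid_attrs(grid: OpticalGrid) -> dict:
    return {
        "nx": grid.nx,
        "ny": grid.ny,
        "nz": grid.nz,
        "dx": grid.dx,
        "dz": grid.dz,
        "wavelength": grid.wavelength,
        "n0": grid.n0,
    }


def _grid_from_attrs(attrs, path) -> OpticalGrid:
    required = ("nx", "ny", "nz", "dx", "dz", "wavelength", "n0")
    for key in required:
        if key not in attrs:
            raise SchemaError(f"{path}: missing grid attribute {key!r}")
    return OpticalGrid(
        nx=int(attrs["nx"]),
        ny=int(attrs["ny"]),
        nz=int(attrs["nz"]),
        dx=float(attrs["dx"]),
        dz=float(attrs["dz"]),
        wavelength=float(attrs["wavelength"]),
        n0=float(attrs["n0"]),
    )


def save_measurements(path, measurements: MeasurementSet) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs.update(_grid_attrs(measurements.grid))
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["K"] = measurements.k_index
        f.create_dataset(
            "fields_re", data=measurements.fields.real.astype(np.float32)
        )
        f.create_dataset(
            "fields_im", data=measurements.fields.imag.astype(np.float32)
        )
        illum = np.array(
            [[il.kx, il.ky, il.kz, il.amplitude] for il in measurements.illuminations]
        )
        f.create_dataset("illum", data=illum)
        f.create_dataset("meta", data=json.dumps(measurements.meta, default=str))


def load_measurements(path) -> MeasurementSet:
    path = Path(path)
    try:
        with h5py.File(path, "r") as f:
            version = f.attrs.get("schema_version")
            if version is None:
                raise SchemaError(f"{path}: missing attribute 'schema_version'")
            major = str(version).split(".")[0]
            if major != SCHEMA_VERSION.split(".")[0]:
                raise SchemaError(
                    f"{path}: incompatible schema version {version}"
                )
            if str(version) != SCHEMA_VERSION:
                warnings.warn(
                    f"{path}: schema version {version} is newer than "
                    f"{SCHEMA_VERSION}; loading best-effort"
                )
            grid = _grid_from_attrs(f.attrs, path)
            for name in ("fields_re", "fields_im", "illum"):
                if name not in f:
                    raise SchemaError(f"{path}: missing dataset {name!r}")
            fields = f["fields_re"][...].astype(np.float64) + 1j * f["fields_im"][
                ...
            ].astype(np.float64)
            illum_arr = f["illum"][...]
            meta = json.loads(f["meta"][()]) if "meta" in f else {}
    except OSError as exc:
        raise SchemaError(f"{path}: not a readable HDF5 container ({exc})") from exc
    illums = [
        PlaneWaveIllumination(
            kx=float(r[0]),
            ky=float(r[1]),
            kz=float(r[2]),
            k_med=grid.k_med,
            amplitude=float(r[3]),
        )
        for r in illum_arr
    ]
    return MeasurementSet(illuminations=illums, fields=fields, grid=grid, meta=meta)


def save_volume(path, volume: RIVolume) -> None:
    """TIFF z-stack + JSON sidecar, or a single HDF5 file for .h5/.hdf5."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.attrs.update(_grid_attrs(volume.grid))
            f.attrs["schema_version"] = SCHEMA_VERSION
            f.create_dataset("n", data=volume.n.astype(np.float32))
        return
    # (nz, nx, ny) pages for conventional z-stack viewers
    pages = np.moveaxis(volume.n.astype(np.float32), -1, 0)
    tifffile.imwrite(path, pages)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(_grid_attrs(volume.grid), indent=2))


def load_volume(path) -> RIVolume:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            grid = _grid_from_attrs(f.attrs, path)
            if "n" not in f:
                raise SchemaError(f"{path}: missing dataset 'n'")
            n = f["n"][...].astype(np.float64)
        return RIVolume(n=n, grid=grid)
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise SchemaError(f"missing metadata sidecar {sidecar}")
    attrs = json.loads(sidecar.read_text())
    grid = _grid_from_attrs(attrs, sidecar)
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    n = np.moveaxis(pages.astype(np.float64), 0, -1)
    if n.shape != grid.shape_volume:
        raise SchemaError(
            f"{path}: stack shape {n.shape} does not match sidecar grid "
            f"{grid.shape_volume}"
        )
    return RIVolume(n=n, grid=grid)


def load_presets() -> dict:
    """Named scene/reconstruction presets shipped with the package."""
    text = (Path(__file__).parent / "presets.yaml").read_text()
    return yaml.safe_load(text)


def write_provenance(path, params: dict) -> None:
    """Record every parameter of a run so artifacts can be regenerated."""
    Path(path).write_text(json.dumps(params, indent=2, default=str))


__all__ = [
    "SCHEMA_VERSION",
    "SchemaError",
    "save_measurements",
    "load_measurements",
    "save_volume",
    "load_volume",
    "load_presets",
    "write_provenance",
]
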