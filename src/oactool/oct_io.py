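"""Readers and writers for OCT volumes, boundary surfaces, and en face maps.

The canonical on-disk volume format is a multi-page grayscale TIFF (one
lateral frame per depth index) accompanied by a JSON sidecar::

    {"shape": [nz, nx, ny], "dtype": "float32", "scale": "linear",
     "dz_um": 2.6, "dx_um": 11.72, "dy_um": 11.72}

The pipeline operates on linear-scale intensity throughout: the
depth-resolved attenuation estimator is only valid on linear intensity, so
``read_volume`` converts dB-scale inputs (``scale: "dB"``) on ingest and
everything downstream may assume linearity.

Axis convention: axis 0 is depth ``z`` with index 0 the shallowest sample
(vitreous side); axes 1 and 2 are the lateral fast/slow scan directions
``x`` and ``y``. All physical pitches are carried in micrometres.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import tifffile

from .errors import ConfigurationError, DataError

#: Sentinel marking boundary columns where no surface was found
#: (max representable value of the 16-bit storage type).
BOUNDARY_SENTINEL = np.uint16(65535)

_REQUIRED_SIDECAR_FIELDS = ("dz_um", "dx_um", "dy_um")


@dataclass
class OCTVolume:
    """A linear-scale OCT intensity raster volume.

    Attributes
    ----------
    data : ndarray, shape (nz, nx, ny)
        Non-negative linear-scale intensity. Depth index 0 is the
        shallowest sample.
    dz, dx, dy : float
        Axial and lateral pixel pitches in micrometres.
    meta : dict
        Free-form acquisition record (device, date, scale history, ...).
    """

    data: np.ndarray
    dz: float
    dx: float
    dy: float
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise DataError(f"volume must be 3-D (z, x, y), got ndim={self.data.ndim}")
        if min(self.dz, self.dx, self.dy) <= 0:
            raise ConfigurationError("pixel pitches dz, dx, dy must be positive")
        if np.any(self.data < 0):
            raise DataError("OCT intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def nz(self) -> int:
        return self.data.shape[0]

    @property
    def lateral_shape(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]


@dataclass
class BoundarySurface:
    """Per-(x, y) depth index of a retinal surface (the EZ upper boundary).

    ``valid_mask`` is False where no boundary could be found; such columns
    carry an in-filled index so slab extraction stays defined everywhere.
    """

    z_index: np.ndarray
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        self.z_index = np.asarray(self.z_index)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.z_index.shape != self.valid_mask.shape:
            raise DataError("z_index and valid_mask shapes differ")


@dataclass
class EnFaceImage:
    """A 2-D lateral map produced by slab averaging.

    ``kind`` records which pipeline arm produced it: ``"attenuation"``
    (values in mm^-1) or ``"intensity"`` (arbitrary linear units).
    """

    data: np.ndarray
    kind: str = "intensity"
    units: str = "arbitrary"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise DataError("en face image must be 2-D")
        if self.kind not in ("attenuation", "intensity"):
            raise ConfigurationError(f"unknown en face kind {self.kind!r}")


def _load_sidecar(sidecar_path: str | Path) -> dict[str, Any]:
    sidecar_path = Path(sidecar_path)
    if not sidecar_path.exists():
        raise ConfigurationError(f"sidecar not found: {sidecar_path}")
    with open(sidecar_path) as fh:
        sidecar = json.load(fh)
    missing = [k for k in _REQUIRED_SIDECAR_FIELDS if k not in sidecar]
    if missing:
        raise ConfigurationError(f"sidecar missing required fields: {missing}")
    return sidecar


def read_volume(path: str | Path, sidecar_path: str | Path | None = None) -> OCTVolume:
    """Read an OCT volume from multi-page TIFF or raw binary plus JSON sidecar.

    If ``sidecar_path`` is omitted, ``<path>.json`` is used. A sidecar
    ``scale`` of ``"dB"`` triggers conversion to linear intensity
    (``I_lin = 10**(I_dB / 10)``); the returned volume is always linear.
    """
    path = Path(path)
    if sidecar_path is None:
        sidecar_path = path.with_suffix(path.suffix + ".json")
    sidecar = _load_sidecar(sidecar_path)

    if path.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(path)
        if data.ndim == 2:  # single-page stack
            data = data[None]
    else:
        if "shape" not in sidecar or "dtype" not in sidecar:
            raise ConfigurationError("raw binary volumes need 'shape' and 'dtype' in the sidecar")
        data = np.fromfile(path, dtype=np.dtype(sidecar["dtype"]))
        data = data.reshape(tuple(sidecar["shape"]))

    if "shape" in sidecar and tuple(sidecar["shape"]) != data.shape:
        raise ConfigurationError(
            f"sidecar shape {tuple(sidecar['shape'])} does not match file shape {data.shape}"
        )

    scale = sidecar.get("scale", "linear")
    if scale == "dB":
        data = np.asarray(10.0 ** (np.asarray(data, dtype=np.float64) / 10.0))
    elif scale != "linear":
        raise ConfigurationError(f"unknown intensity scale {scale!r}")
    if np.any(data < 0):
        raise DataError("negative intensities after scale conversion")

    meta = {k: v for k, v in sidecar.items() if k not in ("dz_um", "dx_um", "dy_um")}
    meta["scale"] = "linear"
    return OCTVolume(data, dz=float(sidecar["dz_um"]), dx=float(sidecar["dx_um"]),
                     dy=float(sidecar["dy_um"]), meta=meta)


def write_volume(volume: OCTVolume, path: str | Path,
                 sidecar_path: str | Path | None = None) -> None:
    """Write a volume as multi-page TIFF with JSON sidecar (linear scale)."""
    path = Path(path)
    if sidecar_path is None:
        sidecar_path = path.with_suffix(path.suffix + ".json")
    tifffile.imwrite(path, volume.data, photometric="minisblack")
    sidecar = {
        "shape": list(volume.data.shape),
        "dtype": volume.data.dtype.name,
        "scale": "linear",
        "dz_um": volume.dz,
        "dx_um": volume.dx,
        "dy_um": volume.dy,
    }
    with open(sidecar_path, "w") as fh:
        json.dump(sidecar, fh, indent=2)


def write_enface(image: EnFaceImage, path: str | Path, bit_depth: int | str = "float") -> None:
    """Write an en face map as TIFF; integer depths are min-max scaled.

    For ``bit_depth`` 8 or 16 the image is scaled to the full integer range
    and the scaling bounds are recorded in ``<path>.json`` so the original
    values can be restored. ``"float"`` preserves values exactly.
    """
    path = Path(path)
    data = np.asarray(image.data, dtype=np.float64)
    sidecar: dict[str, Any] = {"kind": image.kind, "units": image.units,
                               "bit_depth": bit_depth}
    if bit_depth == "float":
        tifffile.imwrite(path, image.data)
    elif bit_depth in (8, 16):
        vmin, vmax = float(data.min()), float(data.max())
        top = 255 if bit_depth == 8 else 65535
        dtype = np.uint8 if bit_depth == 8 else np.uint16
        if vmax == vmin:
            warnings.warn("constant en face image written as zeros at integer bit depth")
            scaled = np.zeros_like(data)
        else:
            scaled = np.round((data - vmin) / (vmax - vmin) * top)
        tifffile.imwrite(path, scaled.astype(dtype))
        sidecar.update({"vmin": vmin, "vmax": vmax})
    else:
        raise ConfigurationError(f"bit_depth must be 8, 16 or 'float', got {bit_depth!r}")
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2)


def read_enface(path: str | Path) -> EnFaceImage:
    """Read an en face map written by :func:`write_enface`, undoing any scaling."""
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    sidecar: dict[str, Any] = {}
    if sidecar_path.exists():
        with open(sidecar_path) as fh:
            sidecar = json.load(fh)
    data = tifffile.imread(path)
    if "vmin" in sidecar:
        top = 255 if sidecar.get("bit_depth") == 8 else 65535
        data = data.astype(np.float64) / top * (sidecar["vmax"] - sidecar["vmin"]) + sidecar["vmin"]
    return EnFaceImage(data, kind=sidecar.get("kind", "intensity"),
                       units=sidecar.get("units", "arbitrary"))


def read_boundary(path: str | Path) -> BoundarySurface:
    """Read a boundary surface from 16-bit TIFF or CSV of z indices.

    The maximum representable value (65535) is the sentinel for columns
    without a boundary; ``valid_mask`` is False exactly there. Range checks
    against a particular volume happen at slab-extraction time.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        z = tifffile.imread(path)
    else:
        z = np.loadtxt(path, delimiter=",", dtype=np.int64, ndmin=2)
    z = np.asarray(z)
    valid = z != int(BOUNDARY_SENTINEL)
    return BoundarySurface(z_index=z.astype(np.int64), valid_mask=valid)


def write_boundary(boundary: BoundarySurface, path: str | Path) -> None:
    """Write a boundary surface (16-bit TIFF or CSV), sentinel-filling invalid columns."""
    path = Path(path)
    z = boundary.z_index.astype(np.int64).copy()
    z[~boundary.valid_mask] = int(BOUNDARY_SENTINEL)
    if path.suffix.lower() in (".tif", ".tiff"):
        if z.max() > int(BOUNDARY_SENTINEL):
            raise DataError("z indices exceed 16-bit range")
        tifffile.imwrite(path, z.astype(np.uint16))
    else:
        np.savetxt(path, z, fmt="%d", delimiter=",")


def write_metrics(metrics: dict[str, Any], path: str | Path) -> None:
    """Write a metrics/provenance record as JSON (CSV for flat tables via pandas upstream)."""
    with open(path, "w") as fh:
        json.dump(metrics, fh, indent=2, sort_keys=True)
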