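"""Volumetric I/O and slicing for photoacoustic amplitude stacks.

A :class:`Volume` is a 3D grid of photoacoustic amplitudes indexed
``data[x, y, z]`` with the third axis being depth (the optical axis),
together with the physical voxel spacing ``(dx, dy, dz)`` in micrometres.
Two on-disk formats are supported:

* multi-page TIFF — one page per z-plane, spacing stored as a JSON
  image description;
* raw little-endian float32 binary with a JSON sidecar carrying shape,
  dtype and spacing (bit-exact interchange).

Amplitudes are never rescaled on load; any normalization is an explicit,
separate step chosen by the caller.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

#: Default voxel spacing in µm used when a file carries no metadata.
DEFAULT_SPACING = (2.0, 2.0, 3.0)

AXES = {"x": 0, "y": 1, "z": 2}


class VolumeError(ValueError):
    """Base class for volume I/O and validation failures."""


class FormatError(VolumeError):
    """File contents do not match the declared format."""


class ValidationError(VolumeError):
    """Data violates a Volume invariant."""


@dataclass(frozen=True)
class Volume:
    """3D photoacoustic amplitude grid with physical voxel spacing.

    Parameters
    ----------
    data
        Array of shape ``(Nx, Ny, Nz)``; all values must be finite and every
        dimension at least 3 (second differences need interior voxels).
    spacing
        Voxel pitch ``(dx, dy, dz)`` in µm, strictly positive.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = DEFAULT_SPACING

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValidationError(f"volume must be 3D, got ndim={arr.ndim}")
        if min(arr.shape) < 3:
            raise ValidationError(
                f"every dimension must be >= 3, got shape {arr.shape}"
            )
        if not np.issubdtype(arr.dtype, np.floating):
            arr = arr.astype(np.float64)
        if not np.all(np.isfinite(arr)):
            raise ValidationError("volume contains NaN or Inf voxels")
        sp = tuple(float(s) for s in self.spacing)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise ValidationError(f"spacing must be 3 positive floats, got {self.spacing}")
        object.__setattr__(self, "data", arr)
        object.__setattr__(self, "spacing", sp)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def nz(self) -> int:
        return self.data.shape[2]

    @property
    def dz(self) -> float:
        return self.spacing[2]

    def with_data(self, data: np.ndarray) -> "Volume":
        """New Volume with the same spacing and different voxel data."""
        return Volume(data=data, spacing=self.spacing)


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        return "tiff"
    if suffix in (".raw", ".bin"):
        return "raw"
    raise FormatError(f"cannot infer volume format from suffix of {path}")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_volume(v: Volume, path, format: str | None = None) -> None:
    """Write a volume to disk in ``tiff`` or ``raw`` format.

    TIFF stores one page per z-plane (page ``k`` is ``data[:, :, k]``) with
    spacing in a JSON image description.  Raw stores C-ordered little-endian
    float32 plus a ``<name>.json`` sidecar.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    try:
        if fmt == "tiff":
            pages = np.ascontiguousarray(np.moveaxis(v.data, 2, 0))
            desc = json.dumps({"spacing_um": list(v.spacing), "axes": "xyz"})
            tifffile.imwrite(path, pages, photometric="minisblack", description=desc)
        elif fmt == "raw":
            arr = np.ascontiguousarray(v.data, dtype="<f4")
            meta = {
                "shape": list(v.shape),
                "dtype": "<f4",
                "order": "C",
                "spacing_um": list(v.spacing),
                "description": "pamfuse raw volume, axes (x, y, z)",
            }
            path.write_bytes(arr.tobytes())
            _sidecar_path(path).write_text(json.dumps(meta, indent=2))
        else:
            raise FormatError(f"unknown format {fmt!r}")
    except OSError as exc:
        raise VolumeError(f"failed writing volume to {path}: {exc}") from exc


def read_volume(path, format: str | None = None) -> Volume:
    """Read a volume written by :func:`write_volume`.

    Spacing defaults to ``(2, 2, 3)`` µm when the file has no metadata.
    """
    path = Path(path)
    if not path.exists():
        raise VolumeError(f"no such volume file: {path}")
    fmt = format or _infer_format(path)
    if fmt == "tiff":
        with tifffile.TiffFile(path) as tif:
            shapes = {page.shape for page in tif.pages}
            if len(shapes) != 1:
                raise FormatError(f"{path}: TIFF pages have mismatched shapes {shapes}")
            pages = tif.asarray()
            spacing = DEFAULT_SPACING
            desc = tif.pages[0].description
            if desc:
                try:
                    meta = json.loads(desc)
                    spacing = tuple(meta["spacing_um"])
                except (json.JSONDecodeError, KeyError, TypeError):
                    pass
        if pages.ndim == 2:  # single page
            pages = pages[None]
        data = np.moveaxis(pages, 0, 2)
    elif fmt == "raw":
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise FormatError(f"raw volume {path} is missing sidecar {sidecar}")
        meta = json.loads(sidecar.read_text())
        shape = tuple(meta["shape"])
        dtype = np.dtype(meta.get("dtype", "<f4"))
        spacing = tuple(meta.get("spacing_um", DEFAULT_SPACING))
        raw = path.read_bytes()
        expected = int(np.prod(shape)) * dtype.itemsize
        if len(raw) != expected:
            raise ValidationError(
                f"{path}: byte count {len(raw)} does not match shape {shape} "
                f"({expected} bytes expected)"
            )
        data = np.frombuffer(raw, dtype=dtype).reshape(shape)
    else:
        raise FormatError(f"unknown format {fmt!r}")
    if not np.all(np.isfinite(data)):
        raise ValidationError(f"{path}: volume contains NaN or Inf voxels")
    return Volume(data=np.array(data), spacing=spacing)


def max_amplitude_projection(v: Volume, axis: str = "z") -> np.ndarray:
    """Maximum amplitude projection (MAP) along one axis.

    Each output pixel is the maximum amplitude along the chosen axis; the MAP
    along z is the standard en-face view of a photoacoustic stack.
    """
    if axis not in AXES:
        raise ValidationError(f"axis must be one of {sorted(AXES)}, got {axis!r}")
    return np.max(v.data, axis=AXES[axis])


def extract_bscan(v: Volume, axis: str, index: int) -> np.ndarray:
    """Extract a lateral–depth cross-section (B-scan).

    ``axis='x'`` returns ``data[index, :, :]`` (a y–z image);
    ``axis='y'`` returns ``data[:, index, :]`` (an x–z image).
    """
    if axis not in ("x", "y"):
        raise ValidationError(f"B-scan axis must be 'x' or 'y', got {axis!r}")
    n = v.shape[AXES[axis]]
    if not 0 <= index < n:
        raise ValidationError(f"index {index} out of range [0, {n}) along {axis}")
    if axis == "x":
        return v.data[index, :, :]
    return v.data[:, index, :]


def write_projection(img: np.ndarray, path) -> None:
    """Write a 2D projection or slice as a single-page TIFF or PNG."""
    path = Path(path)
    if path.suffix.lower() == ".png":
        from imageio.v3 import imwrite

        lo, hi = float(np.min(img)), float(np.max(img))
        scaled = np.zeros_like(img, dtype=np.uint8) if hi == lo else (
            (255 * (img - lo) / (hi - lo)).astype(np.uint8)
        )
        imwrite(path, scaled.T)
    else:
        tifffile.imwrite(path, np.asarray(img, dtype=np.float32))
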