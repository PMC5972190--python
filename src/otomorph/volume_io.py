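"""Reading, writing and normalising 3-D grayscale volumes and binary masks.

Micro-CT reconstructions arrive as stacks of 16-bit slices (multi-page TIFF
or a directory of per-slice TIFFs), as NRRD, or as NIfTI-1.  Everything in
this package operates on intensities normalised to [0, 1]; integer samples
are divided by their *type* maximum (65535 for 16-bit), never by the observed
maximum, so absolute thresholds keep one fixed physical meaning across
volumes.

Axis convention is ``(z, y, x)`` with ``z`` the slice/stack (acquisition)
axis: slice ``k`` of a TIFF stack is ``data[k, :, :]``.  Voxel spacing is
carried in micrometres and is descriptive only — all filters are defined in
voxel units.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import (
    DimensionalityError,
    VolumeDataError,
    VolumeFormatError,
)

__all__ = [
    "IntensityVolume",
    "BinaryMask",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_labels",
    "write_labels",
]

_TIFF_EXT = {".tif", ".tiff"}
_NRRD_EXT = {".nrrd", ".nhdr"}
_NIFTI_EXT = {".nii", ".nii.gz"}


@dataclass
class IntensityVolume:
    """A 3-D scalar field with normalised intensities in [0, 1].

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Normalised, finite intensities.
    spacing : tuple of float
        Voxel spacing ``(sz, sy, sx)`` in micrometres; strictly positive.
    source_dtype : numpy dtype
        Sample type of the on-disk source (e.g. ``uint16``).
    name : str
        Free-text provenance.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    source_dtype: np.dtype = field(default_factory=lambda: np.dtype(np.float32))
    name: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise DimensionalityError(
                f"expected a 3-D volume, got {self.data.ndim} axes"
            )
        if any(s < 1 for s in self.data.shape):
            raise DimensionalityError(f"degenerate shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise VolumeDataError("volume contains non-finite values")
        if self.data.min() < 0.0 or self.data.max() > 1.0:
            raise VolumeDataError("normalised intensities must lie in [0, 1]")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise VolumeDataError(f"spacing must be 3 positive values, got {self.spacing}")
        self.source_dtype = np.dtype(self.source_dtype)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray, name: str | None = None) -> "IntensityVolume":
        """New volume sharing this one's metadata."""
        return IntensityVolume(
            data, spacing=self.spacing, source_dtype=self.source_dtype,
            name=self.name if name is None else name,
        )


@dataclass
class BinaryMask:
    """A 3-D boolean field congruent with an :class:`IntensityVolume`."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise DimensionalityError(f"expected a 3-D mask, got {self.data.ndim} axes")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise VolumeDataError(f"spacing must be 3 positive values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray) -> "BinaryMask":
        return BinaryMask(data, spacing=self.spacing)

    def voxel_count(self) -> int:
        return int(self.data.sum())


# ---------------------------------------------------------------------------
# format detection and raw readers
# ---------------------------------------------------------------------------

def _detect_format(path: str | os.PathLike, fmt: str) -> str:
    if fmt != "auto":
        if fmt not in {"tiff_stack", "nrrd", "nifti"}:
            raise VolumeFormatError(f"unknown format '{fmt}'")
        return fmt
    p = Path(path)
    if p.is_dir():
        return "tiff_stack"
    name = p.name.lower()
    if name.endswith(".nii.gz") or p.suffix.lower() in _NIFTI_EXT:
        return "nifti"
    if p.suffix.lower() in _NRRD_EXT:
        return "nrrd"
    if p.suffix.lower() in _TIFF_EXT:
        return "tiff_stack"
    raise VolumeFormatError(f"cannot infer format of '{path}'")


def _read_tiff(path: Path):
    import tifffile

    if path.is_dir():
        pages = sorted(
            q for q in path.iterdir() if q.suffix.lower() in _TIFF_EXT
        )
        if not pages:
            raise VolumeFormatError(f"no TIFF pages in directory '{path}'")
        slices = [tifffile.imread(str(q)) for q in pages]
        shapes = {s.shape for s in slices}
        if len(shapes) != 1:
            raise VolumeFormatError(f"TIFF pages in '{path}' have differing shapes")
        arr = np.stack(slices, axis=0)
        return arr, None

    with tifffile.TiffFile(str(path)) as tif:
        arr = tif.asarray()
        spacing = None
        try:
            page = tif.pages[0]
            xres = page.tags.get("XResolution")
            yres = page.tags.get("YResolution")
            sz = None
            if tif.imagej_metadata and "spacing" in tif.imagej_metadata:
                sz = float(tif.imagej_metadata["spacing"])
            if xres is not None and yres is not None:
                xn, xd = xres.value
                yn, yd = yres.value
                # a default (1, 1) resolution with no slice spacing carries
                # no information; treat it as absent metadata
                informative = (xn, xd) != (1, 1) or (yn, yd) != (1, 1) or sz is not None
                if xn > 0 and yn > 0 and informative:
                    sx = xd / xn
                    sy = yd / yn
                    spacing = (sz if sz else 1.0, sy, sx)
        except Exception:  # malformed tags are treated as absent metadata
            spacing = None
    return arr, spacing


def _read_nrrd(path: Path):
    import SimpleITK as sitk

    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    sx, sy, sz = img.GetSpacing()[:3]
    return arr, (sz, sy, sx)


def _read_nifti(path: Path):
    import nibabel as nib

    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj)  # (x, y, z)
    if arr.ndim == 3:
        arr = arr.T  # -> (z, y, x)
    zooms = img.header.get_zooms()[:3]
    return arr, (float(zooms[2]), float(zooms[1]), float(zooms[0]))


def _read_raw(path, fmt):
    p = Path(path)
    if not p.exists():
        raise VolumeFormatError(f"no such file: '{path}'")
    fmt = _detect_format(p, fmt)
    try:
        if fmt == "tiff_stack":
            arr, spacing = _read_tiff(p)
        elif fmt == "nrrd":
            arr, spacing = _read_nrrd(p)
        else:
            arr, spacing = _read_nifti(p)
    except (VolumeFormatError, DimensionalityError):
        raise
    except Exception as e:
        raise VolumeFormatError(f"cannot decode '{path}': {e}") from e
    arr = np.asarray(arr)
    if arr.ndim != 3:
        raise DimensionalityError(
            f"'{path}' holds a {arr.ndim}-D payload; a 3-D scalar volume is required"
        )
    if spacing is None:
        warnings.warn(
            f"'{path}' carries no voxel-spacing metadata; defaulting to (1, 1, 1) um",
            stacklevel=3,
        )
        spacing = (1.0, 1.0, 1.0)
    return arr, spacing, fmt


def _normalize(arr: np.ndarray) -> np.ndarray:
    if arr.dtype.kind in "ui":
        return arr.astype(np.float64) / float(np.iinfo(arr.dtype).max)
    if arr.dtype.kind == "f":
        if not np.all(np.isfinite(arr)):
            raise VolumeDataError("volume contains non-finite values")
        return np.clip(arr.astype(np.float64), 0.0, 1.0)
    raise VolumeDataError(f"unsupported sample type {arr.dtype}")


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def read_volume(path, fmt: str = "auto") -> IntensityVolume:
    """Read a 3-D scalar volume and normalise it to [0, 1].

    Integer samples are divided by the dtype maximum (65535 for 16-bit);
    floating samples are clipped to [0, 1].  A directory is read as a TIFF
    stack ordered by lexicographic filename.
    """
    arr, spacing, _ = _read_raw(path, fmt)
    if arr.dtype.kind not in "uif":
        raise VolumeDataError(f"unsupported sample type {arr.dtype}")
    if arr.dtype.kind == "f" and not np.all(np.isfinite(arr)):
        raise VolumeDataError(f"'{path}' contains non-finite values")
    data = _normalize(arr)
    return IntensityVolume(
        data, spacing=spacing, source_dtype=arr.dtype, name=str(path)
    )


def read_mask(path, fmt: str = "auto") -> BinaryMask:
    """Read a binary mask: any sample > 0 maps to foreground."""
    arr, spacing, _ = _read_raw(path, fmt)
    if arr.dtype.kind == "f" and not np.all(np.isfinite(arr)):
        raise VolumeDataError(f"'{path}' contains non-finite values")
    return BinaryMask(arr > 0, spacing=spacing)


def read_labels(path, fmt: str = "auto") -> tuple[np.ndarray, tuple]:
    """Read an integer label volume verbatim (no normalisation)."""
    arr, spacing, _ = _read_raw(path, fmt)
    if arr.dtype.kind not in "ui":
        if arr.dtype.kind == "f" and np.allclose(arr, np.round(arr)):
            arr = np.round(arr).astype(np.int32)
        else:
            raise VolumeDataError(f"'{path}' is not an integer label volume")
    return arr.astype(np.int32), spacing


def _store_array(data: np.ndarray, dtype: str) -> np.ndarray:
    if dtype == "float32":
        return data.astype(np.float32)
    if dtype == "uint16":
        return np.round(np.clip(data, 0.0, 1.0) * 65535.0).astype(np.uint16)
    raise VolumeFormatError(f"unsupported output dtype '{dtype}'")


def _write_tiff(arr: np.ndarray, path: Path, spacing) -> None:
    import tifffile

    sz, sy, sx = spacing
    tifffile.imwrite(
        str(path),
        arr,
        imagej=True,
        resolution=(1.0 / sx, 1.0 / sy),
        metadata={"spacing": sz, "unit": "um", "axes": "ZYX"},
    )


def _write_nrrd(arr: np.ndarray, path: Path, spacing) -> None:
    import SimpleITK as sitk

    img = sitk.GetImageFromArray(arr)
    sz, sy, sx = spacing
    img.SetSpacing((sx, sy, sz))
    sitk.WriteImage(img, str(path))


def _write_nifti(arr: np.ndarray, path: Path, spacing) -> None:
    import nibabel as nib

    sz, sy, sx = spacing
    affine = np.diag([sx, sy, sz, 1.0])
    img = nib.Nifti1Image(np.ascontiguousarray(arr.T), affine)
    img.header.set_zooms((sx, sy, sz))
    nib.save(img, str(path))


def _write_raw(arr, path, fmt, spacing):
    p = Path(path)
    if not p.parent.exists():
        raise VolumeFormatError(f"parent directory does not exist: '{p.parent}'")
    fmt = _detect_format(p, fmt)
    try:
        if fmt == "tiff_stack":
            _write_tiff(arr, p, spacing)
        elif fmt == "nrrd":
            _write_nrrd(arr, p, spacing)
        else:
            _write_nifti(arr, p, spacing)
    except (VolumeFormatError, OSError):
        raise
    except Exception as e:
        raise VolumeFormatError(f"cannot write '{path}': {e}") from e


def write_volume(vol: IntensityVolume, path, fmt: str = "auto",
                 dtype: str = "float32") -> None:
    """Write a volume; round trips are lossless for float32, within 1/65535 for uint16."""
    _write_raw(_store_array(vol.data, dtype), path, fmt, vol.spacing)


def write_mask(mask: BinaryMask, path, fmt: str = "auto") -> None:
    """Write a binary mask as 8-bit {0, 255} samples."""
    _write_raw(mask.data.astype(np.uint8) * np.uint8(255), path, fmt, mask.spacing)


def write_labels(labels: np.ndarray, path, fmt: str = "auto",
                 spacing=(1.0, 1.0, 1.0)) -> None:
    """Write an integer label volume verbatim."""
    _write_raw(np.asarray(labels, dtype=np.int16), path, fmt, spacing)
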