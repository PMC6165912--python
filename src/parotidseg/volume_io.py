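"""Volume and mask I/O, geometry, resampling and couch removal.

Internal convention: arrays are indexed ``(x, y, z)`` with ``x`` the
patient left-right axis, ``y`` anterior-posterior and ``z`` the transverse
(head-foot) axis along which CT slices are stacked.  NIfTI files are
reoriented to the closest canonical (RAS-like) orientation on read so that
this convention holds regardless of how the file was stored.
"""

from __future__ import annotations

import os
import zlib
from dataclasses import dataclass
from typing import Literal

import nibabel as nib
import numpy as np

__all__ = [
    "GridGeometry",
    "VolumeGrid",
    "BinaryMask",
    "VolumeIOError",
    "VolumeFormatError",
    "read_volume",
    "read_mask",
    "write_volume",
    "write_mask",
    "resample_transverse",
    "resample_mask_to_grid",
    "remove_couch",
    "apply_body_mask",
    "mirror_sagittal",
    "mirror_pad",
]

AIR_HU = -1024.0

Laterality = Literal["left", "right", "unspecified"]


class VolumeIOError(IOError):
    """Unreadable or unwritable volume file."""


class VolumeFormatError(ValueError):
    """File exists but does not describe a valid 3-D scalar volume."""


@dataclass(frozen=True)
class GridGeometry:
    """Physical placement of a voxel grid: extents, spacing and origin (mm)."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) < 1 for n in self.shape):
            raise ValueError(f"grid extents must be three positive integers, got {self.shape}")
        if len(self.spacing) != 3 or any(float(s) <= 0 for s in self.spacing):
            raise ValueError(f"spacing components must be positive, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    def voxel_centers(self, axis: int) -> np.ndarray:
        """Physical coordinates (mm) of voxel centers along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])


@dataclass
class VolumeGrid:
    """A 3-D scalar image (Hounsfield units) on a physical grid."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise VolumeFormatError(f"volume must be 3-D, got {self.voxels.ndim}-D")
        # GridGeometry validates spacing/extents
        self.geometry  # noqa: B018

    @property
    def geometry(self) -> GridGeometry:
        return GridGeometry(self.voxels.shape, self.spacing, self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.voxels.shape)


@dataclass
class BinaryMask:
    """A binary segmentation living on a :class:`GridGeometry`."""

    voxels: np.ndarray
    grid: GridGeometry
    laterality: Laterality = "unspecified"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        if tuple(self.voxels.shape) != self.grid.shape:
            raise ValueError(
                f"mask extents {self.voxels.shape} differ from grid extents {self.grid.shape}"
            )

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.grid.spacing

    @property
    def count(self) -> int:
        return int(self.voxels.sum())


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

_NIFTI_SUFFIXES = (".nii", ".nii.gz")
_META_SUFFIXES = (".mha", ".mhd")

_MET_DTYPES = {
    "MET_CHAR": np.int8,
    "MET_UCHAR": np.uint8,
    "MET_SHORT": np.int16,
    "MET_USHORT": np.uint16,
    "MET_INT": np.int32,
    "MET_UINT": np.uint32,
    "MET_FLOAT": np.float32,
    "MET_DOUBLE": np.float64,
}


def _is_nifti(path: str) -> bool:
    return path.endswith(_NIFTI_SUFFIXES)


def _is_meta(path: str) -> bool:
    return path.endswith(_META_SUFFIXES)


def read_volume(path: str | os.PathLike) -> VolumeGrid:
    """Read a NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd) volume.

    Spacing and origin are taken from the file header; the array is
    reoriented to the internal (x, y, z) convention for NIfTI input.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise VolumeIOError(f"no such volume file: {path}")
    if _is_nifti(path):
        return _read_nifti(path)
    if _is_meta(path):
        return _read_meta(path)
    raise VolumeFormatError(
        f"unsupported volume format for {path!r}; expected .nii, .nii.gz, .mha or .mhd"
    )


def _read_nifti(path: str) -> VolumeGrid:
    try:
        img = nib.load(path)
    except Exception as exc:  # nibabel raises a zoo of types
        raise VolumeIOError(f"cannot read volume {path}: {exc}") from exc
    if len(img.shape) != 3:
        raise VolumeFormatError(f"{path}: expected a 3-D volume, got shape {img.shape}")
    img = nib.as_closest_canonical(img)
    data = np.asarray(img.dataobj, dtype=np.float32)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(z <= 0 for z in zooms):
        raise VolumeFormatError(f"{path}: header carries non-positive voxel spacing {zooms}")
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return VolumeGrid(data, zooms, origin)


def _read_meta(path: str) -> VolumeGrid:
    header: dict[str, str] = {}
    data_offset = None
    with open(path, "rb") as fh:
        while True:
            line = fh.readline()
            if not line:
                raise VolumeFormatError(f"{path}: truncated MetaImage header")
            try:
                key, value = line.decode("ascii").split("=", 1)
            except ValueError as exc:
                raise VolumeFormatError(f"{path}: malformed MetaImage header line {line!r}") from exc
            key, value = key.strip(), value.strip()
            header[key] = value
            if key == "ElementDataFile":
                data_offset = fh.tell()
                break
    ndims = int(header.get("NDims", "0"))
    if ndims != 3:
        raise VolumeFormatError(f"{path}: expected a 3-D volume, got NDims={ndims}")
    if "DimSize" not in header:
        raise VolumeFormatError(f"{path}: MetaImage header lacks DimSize")
    shape = tuple(int(v) for v in header["DimSize"].split())
    if "ElementSpacing" not in header:
        raise VolumeFormatError(f"{path}: MetaImage header lacks ElementSpacing")
    spacing = tuple(float(v) for v in header["ElementSpacing"].split())
    origin = tuple(
        float(v) for v in header.get("Offset", header.get("Position", "0 0 0")).split()
    )
    et = header.get("ElementType", "MET_FLOAT")
    if et not in _MET_DTYPES:
        raise VolumeFormatError(f"{path}: unsupported ElementType {et}")
    dtype = np.dtype(_MET_DTYPES[et])
    datafile = header["ElementDataFile"]
    if datafile == "LOCAL":
        with open(path, "rb") as fh:
            fh.seek(data_offset)
            raw = fh.read()
    else:
        raw_path = os.path.join(os.path.dirname(path), datafile)
        if not os.path.exists(raw_path):
            raise VolumeIOError(f"{path}: referenced data file {raw_path} is missing")
        with open(raw_path, "rb") as fh:
            raw = fh.read()
    if header.get("CompressedData", "False").lower() == "true":
        raw = zlib.decompress(raw)
    if header.get("BinaryDataByteOrderMSB", "False").lower() == "true":
        dtype = dtype.newbyteorder(">")
    n_expected = int(np.prod(shape))
    arr = np.frombuffer(raw, dtype=dtype, count=n_expected)
    if arr.size != n_expected:
        raise VolumeFormatError(f"{path}: data block shorter than DimSize implies")
    # MetaImage raw data varies x fastest
    data = arr.reshape(shape, order="F").astype(np.float32)
    return VolumeGrid(data, spacing, origin)


def write_volume(vol: VolumeGrid, path: str | os.PathLike) -> None:
    """Write a volume as NIfTI or MetaImage (inferred from the suffix)."""
    path = os.fspath(path)
    if _is_nifti(path):
        affine = np.diag(list(vol.spacing) + [1.0])
        affine[:3, 3] = vol.origin
        nib.save(nib.Nifti1Image(vol.voxels.astype(np.float32), affine), path)
    elif _is_meta(path):
        _write_meta(vol.voxels.astype(np.float32), "MET_FLOAT", vol.spacing, vol.origin, path)
    else:
        raise VolumeFormatError(f"unsupported output format for {path!r}")


def _write_meta(data: np.ndarray, met_type: str, spacing, origin, path: str) -> None:
    if not path.endswith(".mha"):
        raise VolumeFormatError("MetaImage writing supports only single-file .mha output")
    nx, ny, nz = data.shape
    header = (
        "ObjectType = Image\n"
        "NDims = 3\n"
        "BinaryData = True\n"
        "BinaryDataByteOrderMSB = False\n"
        "CompressedData = False\n"
        f"DimSize = {nx} {ny} {nz}\n"
        f"ElementSpacing = {spacing[0]} {spacing[1]} {spacing[2]}\n"
        f"Offset = {origin[0]} {origin[1]} {origin[2]}\n"
        f"ElementType = {met_type}\n"
        "ElementDataFile = LOCAL\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(np.asfortranarray(data).tobytes(order="F"))


def read_mask(path: str | os.PathLike, laterality: Laterality = "unspecified") -> BinaryMask:
    """Read a binary mask stored as a volume file (foreground where > 0.5)."""
    vol = read_volume(path)
    return BinaryMask(vol.voxels > 0.5, vol.geometry, laterality)


def write_mask(mask: BinaryMask, path: str | os.PathLike) -> None:
    path = os.fspath(path)
    data = mask.voxels.astype(np.uint8)
    if _is_nifti(path):
        affine = np.diag(list(mask.grid.spacing) + [1.0])
        affine[:3, 3] = mask.grid.origin
        nib.save(nib.Nifti1Image(data, affine), path)
    elif _is_meta(path):
        _write_meta(data, "MET_UCHAR", mask.grid.spacing, mask.grid.origin, path)
    else:
        raise VolumeFormatError(f"unsupported output format for {path!r}")


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------


def _lanczos3(t: np.ndarray) -> np.ndarray:
    out = np.sinc(t) * np.sinc(t / 3.0)
    out[np.abs(t) >= 3.0] = 0.0
    return out


def resample_transverse(vol: VolumeGrid, target_z_spacing: float) -> VolumeGrid:
    """Resample along the transverse (z) axis only, to ``target_z_spacing`` mm.

    Interpolation is 1-D Lanczos with support size 3 along z; in-plane
    extents and spacing are untouched.  The output grid is anchored at the
    first input slice and has ``floor(physical_extent / target) + 1``
    slices.  Kernel weights are renormalized to sum to one per output
    sample (constants are preserved exactly) and samples beyond the volume
    are clamped to the edge slices.
    """
    if target_z_spacing <= 0:
        raise ValueError("target_z_spacing must be positive")
    sz = vol.spacing[2]
    nz = vol.shape[2]
    if abs(sz - target_z_spacing) < 1e-9:
        return VolumeGrid(vol.voxels.copy(), vol.spacing, vol.origin)
    if nz < 2:
        raise ValueError("cannot interpolate a single-slice volume to a different slice spacing")
    extent = (nz - 1) * sz
    nz_out = int(np.floor(extent / target_z_spacing)) + 1
    # fractional source slice index for each output slice
    src = np.arange(nz_out) * (target_z_spacing / sz)
    lo = int(np.floor(src.min())) - 3
    hi = int(np.ceil(src.max())) + 4
    taps = np.arange(lo, hi)
    # weight matrix (nz_out, ntaps); clamp tap indices to the valid range
    w = _lanczos3(src[:, None] - taps[None, :])
    w /= w.sum(axis=1, keepdims=True)
    tap_idx = np.clip(taps, 0, nz - 1)
    resampled = np.tensordot(vol.voxels[:, :, tap_idx], w, axes=([2], [1]))
    spacing = (vol.spacing[0], vol.spacing[1], float(target_z_spacing))
    return VolumeGrid(resampled.astype(vol.voxels.dtype, copy=False), spacing, vol.origin)


def _nearest_indices(target: GridGeometry, source: GridGeometry, axis: int) -> np.ndarray:
    """Index of the physically nearest source voxel center for each target
    center along one axis; equidistant ties go to the lower index.  Out of
    range positions map to -1."""
    phys = target.voxel_centers(axis)
    frac = (phys - source.origin[axis]) / source.spacing[axis]
    idx = np.ceil(frac - 0.5).astype(np.int64)  # ties-to-lower
    idx[(idx < 0) | (idx >= source.shape[axis])] = -1
    return idx


def resample_mask_to_grid(mask: BinaryMask, target: GridGeometry) -> BinaryMask:
    """Nearest-neighbor resampling of a binary mask onto another grid.

    Both grids are assumed axis-aligned; each output voxel copies the value
    of the source voxel whose center is physically nearest (ties to the
    lower index).  Target voxels outside the source grid are background.
    """
    src = mask.grid
    per_axis = [_nearest_indices(target, src, ax) for ax in range(3)]
    valid = [ix >= 0 for ix in per_axis]
    clipped = [np.where(v, ix, 0) for ix, v in zip(per_axis, valid)]
    out = mask.voxels[np.ix_(*clipped)]
    out = out & valid[0][:, None, None] & valid[1][None, :, None] & valid[2][None, None, :]
    return BinaryMask(out, target, mask.laterality)


# ---------------------------------------------------------------------------
# Couch removal and mirroring
# ---------------------------------------------------------------------------


def remove_couch(vol: VolumeGrid, threshold: float = -300.0) -> BinaryMask:
    """Compute the patient body mask, excluding a non-touching couch slab.

    Thresholds at ``threshold`` HU, keeps the largest 6-connected 3-D
    component and fills in-plane (axial) holes.
    """
    from scipy import ndimage

    fg = vol.voxels > threshold
    if not fg.any():
        raise ValueError("no body found: no voxel above the body threshold")
    structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    labels, n = ndimage.label(fg, structure=structure)
    if n > 1:
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        body = labels == int(np.argmax(sizes))
    else:
        body = fg
    # fill holes slice-wise so tunnels along z do not leak
    filled = np.empty_like(body)
    for k in range(body.shape[2]):
        filled[:, :, k] = ndimage.binary_fill_holes(body[:, :, k])
    return BinaryMask(filled, vol.geometry)


def apply_body_mask(vol: VolumeGrid, body: BinaryMask, fill: float = AIR_HU) -> VolumeGrid:
    """Set every voxel outside the body mask to ``fill`` (air by default)."""
    if body.grid != vol.geometry:
        raise ValueError("body mask geometry differs from volume geometry")
    out = np.where(body.voxels, vol.voxels, np.asarray(fill, dtype=vol.voxels.dtype))
    return VolumeGrid(out, vol.spacing, vol.origin)


_MIRROR_LATERALITY = {"left": "right", "right": "left", "unspecified": "unspecified"}


def mirror_sagittal(vol: VolumeGrid, mask: BinaryMask) -> tuple[VolumeGrid, BinaryMask]:
    """Flip volume and mask along the left-right (x) axis.

    Used to turn right-side structures into additional left-side training
    examples; applying it twice restores the input.
    """
    mvol = VolumeGrid(vol.voxels[::-1].copy(), vol.spacing, vol.origin)
    mmask = BinaryMask(
        mask.voxels[::-1].copy(), mask.grid, _MIRROR_LATERALITY[mask.laterality]
    )
    return mvol, mmask


def mirror_pad(arr: np.ndarray, pad: tuple[tuple[int, int], ...]) -> np.ndarray:
    """Symmetric (mirror) padding that tolerates pads wider than the array.

    ``np.pad(mode="symmetric")`` caps the pad at the axis length; repeated
    application extends arbitrarily small arrays to any context size.
    """
    pad = tuple(tuple(p) for p in pad)
    while any(b > 0 or a > 0 for b, a in pad):
        step = tuple(
            (min(b, arr.shape[i]), min(a, arr.shape[i])) for i, (b, a) in enumerate(pad)
        )
        arr = np.pad(arr, step, mode="symmetric")
        pad = tuple((b - sb, a - sa) for (b, a), (sb, sa) in zip(pad, step))
    return arr


def crop_to_box(arr: np.ndarray, box: tuple[tuple[int, int], ...]) -> np.ndarray:
    """Crop an array to per-axis half-open index intervals."""
    return arr[tuple(slice(lo, hi) for lo, hi in box)]
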