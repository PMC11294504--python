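"""Volume data model and I/O.

A :class:`Volume3D` is a 3-D scalar activity grid with physical geometry.
The canonical in-memory axis order is ``(x, y, z)`` — x runs patient
left-right, y anterior-posterior, z caudal-cranial — regardless of how the
file stores its slices; readers permute on load.  Indexing is 0-based with
half-open ranges, and physical coordinates refer to voxel centers.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import nibabel as nib


@dataclass
class Volume3D:
    """3-D non-negative scalar grid with voxel spacing (mm) and origin (mm)."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3-D, got {self.data.ndim}-D")
        if any(s < 2 for s in self.data.shape):
            raise ValueError(f"each axis needs >= 2 voxels, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume intensities must be finite")
        if self.data.min() < 0:
            raise ValueError("volume intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def physical_extent(self) -> np.ndarray:
        """Physical size per axis in mm (shape x spacing)."""
        return np.asarray(self.shape) * np.asarray(self.spacing)

    def voxel_centers_mm(self, center_origin: bool = False) -> np.ndarray:
        """(N, 3) physical coordinates of all voxel centers.

        With ``center_origin`` the grid center (not the stored origin) is
        subtracted, which is the frame the fitting stage works in.
        """
        idx = np.indices(self.shape).reshape(3, -1).T.astype(np.float64)
        pts = idx * np.asarray(self.spacing)
        if center_origin:
            pts -= (np.asarray(self.shape) - 1) / 2.0 * np.asarray(self.spacing)
        else:
            pts += np.asarray(self.origin)
        return pts


@dataclass(frozen=True)
class BoundingBox:
    """Per-axis inclusive start / exclusive stop voxel indices (0-based)."""

    start: tuple[int, int, int]
    stop: tuple[int, int, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "start", tuple(int(v) for v in self.start))
        object.__setattr__(self, "stop", tuple(int(v) for v in self.stop))
        if any(a >= b for a, b in zip(self.start, self.stop)):
            raise ValueError(f"box start must be < stop on every axis: {self}")
        if any(a < 0 for a in self.start):
            raise ValueError(f"box start must be >= 0: {self}")

    @property
    def extents(self) -> tuple[int, int, int]:
        return tuple(b - a for a, b in zip(self.start, self.stop))

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(a, b) for a, b in zip(self.start, self.stop))

    def within(self, shape: tuple[int, int, int]) -> bool:
        return all(b <= s for b, s in zip(self.stop, shape))


def read_volume(path: str | os.PathLike, format: str | None = None) -> Volume3D:
    """Read a NIfTI file or a DICOM series directory into a :class:`Volume3D`.

    ``format`` is ``"nifti"`` or ``"dicom_dir"``; when omitted it is inferred
    from the path (directory -> DICOM series, otherwise NIfTI).  DICOM slices
    are reassembled in ascending slice-position order irrespective of file
    naming.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if format is None:
        format = "dicom_dir" if path.is_dir() else "nifti"
    if format == "nifti":
        return _read_nifti(path)
    if format == "dicom_dir":
        return _read_dicom_dir(path)
    raise ValueError(f"unknown format {format!r}")


def _read_nifti(path: Path) -> Volume3D:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D NIfTI, got {data.ndim}-D")
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return Volume3D(np.clip(np.asarray(data, dtype=np.float64), 0.0, None), tuple(zooms), origin)


def _read_dicom_dir(path: Path) -> Volume3D:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.is_file() and not p.name.startswith("."))
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue
        if hasattr(ds, "pixel_array"):
            slices.append(ds)
    if not slices:
        raise ValueError(f"no readable DICOM slices in {path}")
    rows = {int(ds.Rows) for ds in slices}
    cols = {int(ds.Columns) for ds in slices}
    spacings = {tuple(round(float(v), 6) for v in ds.PixelSpacing) for ds in slices}
    if len(rows) > 1 or len(cols) > 1 or len(spacings) > 1:
        raise ValueError("inconsistent DICOM slice geometry (rows/cols/spacing differ)")

    def zpos(ds) -> float:
        if hasattr(ds, "ImagePositionPatient"):
            return float(ds.ImagePositionPatient[2])
        return float(getattr(ds, "SliceLocation", getattr(ds, "InstanceNumber", 0)))

    slices.sort(key=zpos)
    arrs = []
    for ds in slices:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        arrs.append(arr * slope + intercept)
    # DICOM pixel_array is (row, col) = (y, x); stack over z then permute to (x, y, z)
    stack = np.stack(arrs, axis=0)  # (z, y, x)
    data = np.transpose(stack, (2, 1, 0))
    row_sp, col_sp = (float(v) for v in slices[0].PixelSpacing)
    if len(slices) > 1:
        zs = [zpos(ds) for ds in slices]
        dz = float(np.median(np.diff(zs)))
        if dz <= 0:
            dz = float(getattr(slices[0], "SliceThickness", 1.0))
    else:
        dz = float(getattr(slices[0], "SliceThickness", 1.0))
    origin = (0.0, 0.0, 0.0)
    if hasattr(slices[0], "ImagePositionPatient"):
        ipp = slices[0].ImagePositionPatient
        origin = (float(ipp[0]), float(ipp[1]), float(ipp[2]))
    return Volume3D(np.clip(data, 0.0, None), (col_sp, row_sp, dz), origin)


def write_volume(vol: Volume3D, path: str | os.PathLike) -> None:
    """Write a volume as NIfTI-1, carrying spacing and origin in the header."""
    affine = np.diag(list(vol.spacing) + [1.0])
    affine[:3, 3] = vol.origin
    img = nib.Nifti1Image(vol.data.astype(np.float32), affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def crop_volume(vol: Volume3D, box: BoundingBox) -> Volume3D:
    """Extract the subvolume inside ``box``; the origin shifts by start x spacing."""
    if not box.within(vol.shape):
        raise ValueError(f"box {box} outside grid of shape {vol.shape}")
    data = vol.data[box.slices()].copy()
    origin = tuple(o + a * s for o, a, s in zip(vol.origin, box.start, vol.spacing))
    return Volume3D(data, vol.spacing, origin)


def resample_volume(
    vol: Volume3D,
    target_shape: tuple[int, int, int],
    interp: str = "trilinear",
) -> Volume3D:
    """Resample to ``target_shape`` voxels, preserving the physical extent.

    Spacing rescales by old_shape/new_shape per axis, so shape x spacing is
    unchanged.  ``interp`` is ``"trilinear"`` or ``"nearest"``; trilinear
    output is clipped to the input range (interpolation cannot overshoot, but
    clipping guards rounding).
    """
    from scipy import ndimage

    target_shape = tuple(int(s) for s in target_shape)
    if len(target_shape) != 3 or any(s < 2 for s in target_shape):
        raise ValueError(f"target shape must be 3 integers >= 2, got {target_shape}")
    if interp not in ("trilinear", "nearest"):
        raise ValueError(f"unknown interpolation {interp!r}")
    in_shape = np.asarray(vol.shape, dtype=np.float64)
    out_shape = np.asarray(target_shape, dtype=np.float64)
    scale = in_shape / out_shape
    # map output voxel centers into input index space (voxel-center aligned)
    matrix = np.diag(scale)
    offset = (scale - 1.0) / 2.0
    order = 1 if interp == "trilinear" else 0
    data = ndimage.affine_transform(
        vol.data, matrix, offset=offset, output_shape=target_shape, order=order, mode="nearest"
    )
    if interp == "trilinear":
        data = np.clip(data, vol.data.min(), vol.data.max())
    spacing = tuple(float(sp * sc) for sp, sc in zip(vol.spacing, scale))
    return Volume3D(data, spacing, vol.origin)
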