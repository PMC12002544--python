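"""3D volume container, NIfTI I/O, resampling, and derived maps.

All quantitative parameter maps, weighted images, and masks are carried as
:class:`Volume` objects: a 3D scalar array plus a 4x4 voxel-to-world affine
(mm) and a unit label.  Missing data (voxels not covered by an acquisition,
or invalidated by a division guard) are encoded as NaN in floating-point
volumes; binary masks are stored as uint8 and have no missing values.

The analysis grid is the 1 mm isotropic anatomical (MPRAGE) grid on which
the lesion masks natively live; all other maps are brought onto it by
trilinear interpolation of already co-registered images (the affines encode
the co-registration -- no registration is estimated here).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "BIOMARKERS",
    "BIOMARKER_UNITS",
    "ReferenceGrid",
    "Volume",
    "common_imaging_volume",
    "read_volume",
    "resample_nearest",
    "resample_trilinear",
    "t1w_t2w_ratio",
    "write_volume",
]

#: The nine (semi-)quantitative MR biomarkers of the panel, with units.
BIOMARKER_UNITS: dict[str, str] = {
    "MWF": "%",
    "MTsat": "%",
    "ihMTR": "%",
    "qT1": "ms",
    "qT2": "ms",
    "qT2star": "ms",
    "PD": "%",
    "QSM": "ppb",
    "T1wT2w": "",  # dimensionless ratio
}

#: Canonical biomarker order (used for tables and reports).
BIOMARKERS: tuple[str, ...] = tuple(BIOMARKER_UNITS)


@dataclass(frozen=True)
class ReferenceGrid:
    """Target sampling grid: shape, voxel-to-world affine, voxel spacing."""

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        object.__setattr__(self, "shape", shape)
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError("grid shape must be 3D with all dimensions >= 1")
        if abs(np.linalg.det(affine)) < 1e-12:
            raise ValueError("grid affine is singular")
        object.__setattr__(self, "affine", affine)
        spacing = tuple(float(s) for s in np.sqrt((affine[:3, :3] ** 2).sum(axis=0)))
        if any(s <= 0 for s in spacing):
            raise ValueError("voxel spacing must be strictly positive")
        object.__setattr__(self, "spacing", spacing)

    spacing: tuple[float, float, float] = field(init=False)

    @classmethod
    def isotropic(cls, shape: tuple[int, int, int], spacing_mm: float = 1.0) -> "ReferenceGrid":
        """A simple axis-aligned grid with isotropic spacing (default 1 mm)."""
        affine = np.diag([spacing_mm, spacing_mm, spacing_mm, 1.0])
        return cls(shape=tuple(shape), affine=affine)


@dataclass
class Volume:
    """A 3D scalar field with voxel-to-world affine and unit label.

    Missing voxels are NaN (floating dtype only).  Binary masks use uint8
    data with values in {0, 1}.
    """

    data: np.ndarray
    affine: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or any(s < 1 for s in self.data.shape):
            raise ValueError("volume data must be 3D with all dimensions >= 1")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine is not invertible")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def missing(self) -> np.ndarray:
        """Boolean mask of voxels with no valid value."""
        if np.issubdtype(self.data.dtype, np.floating):
            return np.isnan(self.data)
        return np.zeros(self.data.shape, dtype=bool)

    @property
    def grid(self) -> ReferenceGrid:
        return ReferenceGrid(shape=self.shape, affine=self.affine)

    def is_binary(self) -> bool:
        vals = np.unique(self.data[~self.missing])
        return bool(np.isin(vals, (0, 1)).all())

    def as_bool(self) -> np.ndarray:
        if not self.is_binary():
            raise ValueError("volume is not a binary mask")
        return self.data.astype(bool)

    def same_grid(self, other: "Volume | ReferenceGrid") -> bool:
        return self.shape == tuple(other.shape) and np.allclose(
            self.affine, other.affine, atol=1e-9
        )


def read_volume(path: str | Path, units: str | None = None) -> Volume:
    """Read a 3D NIfTI-1 volume.

    ``units`` overrides the stored unit label (NIfTI carries spatial units
    only, so value units are normally supplied by the caller or a manifest).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected a 3D image, got shape {data.shape}")
    return Volume(data=data, affine=img.affine, units=units or "")


def write_volume(vol: Volume, path: str | Path, dtype: np.dtype | None = None) -> None:
    """Write a Volume as NIfTI-1; NaN encodes missing voxels in float images."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    data = vol.data if dtype is None else vol.data.astype(dtype)
    img = nib.Nifti1Image(data, vol.affine)
    img.header.set_data_dtype(data.dtype)
    nib.save(img, str(path))


def _voxel_map(src_affine: np.ndarray, grid: ReferenceGrid) -> np.ndarray:
    """Coordinates (3, *grid.shape) of grid voxel centers in source voxel space."""
    mat = np.linalg.inv(src_affine) @ grid.affine
    idx = np.indices(grid.shape, dtype=float)
    coords = np.tensordot(mat[:3, :3], idx, axes=(1, 0))
    coords += mat[:3, 3][:, None, None, None]
    return coords


def resample_trilinear(vol: Volume, grid: ReferenceGrid) -> Volume:
    """Resample a scalar map onto ``grid`` by trilinear interpolation.

    Output voxels whose world position falls outside the source extent, or
    whose interpolation stencil touches a missing source voxel, are missing
    (NaN) -- resampling never extrapolates or zero-fills.
    """
    coords = _voxel_map(vol.affine, grid)
    src = vol.data.astype(float)
    out = ndimage.map_coordinates(src, coords, order=1, mode="constant", cval=np.nan)
    # map_coordinates treats NaN cval arithmetic correctly for floats: any
    # stencil touching the outside or a missing voxel yields NaN.
    return Volume(data=out, affine=grid.affine.copy(), units=vol.units)


def resample_nearest(vol: Volume, grid: ReferenceGrid) -> Volume:
    """Nearest-neighbor resampling, used for masks and label images.

    Out-of-extent voxels become 0 (background) for integer data, NaN for
    floating data.
    """
    coords = _voxel_map(vol.affine, grid)
    if np.issubdtype(vol.data.dtype, np.floating):
        out = ndimage.map_coordinates(
            vol.data, coords, order=0, mode="constant", cval=np.nan
        )
    else:
        out = ndimage.map_coordinates(vol.data, coords, order=0, mode="constant", cval=0)
    return Volume(data=out, affine=grid.affine.copy(), units=vol.units)


def common_imaging_volume(vols: list[Volume]) -> Volume:
    """Subject-specific common imaging volume: voxels covered by every map.

    All inputs must already be on the same reference grid.  A modality that
    is absent for a subject is simply not passed in, so it does not restrict
    the common volume.
    """
    if not vols:
        raise ValueError("common_imaging_volume requires at least one volume")
    first = vols[0]
    mask = ~first.missing
    for v in vols[1:]:
        if v.shape != first.shape:
            raise ValueError("all volumes must share the same grid shape")
        mask &= ~v.missing
    return Volume(data=mask.astype(np.uint8), affine=first.affine.copy(), units="")


def t1w_t2w_ratio(t1w: Volume, t2w: Volume) -> Volume:
    """Voxelwise T1w/T2w ratio (dimensionless, myelin-related in WM).

    Voxels where the T2w signal is non-positive, or where either input is
    missing, are marked missing rather than raising.
    """
    if not t1w.same_grid(t2w):
        raise ValueError("T1w and T2w volumes must be on the same grid")
    a = t1w.data.astype(float)
    b = t2w.data.astype(float)
    valid = ~np.isnan(a) & ~np.isnan(b) & (b > 0)
    out = np.full(a.shape, np.nan)
    out[valid] = a[valid] / b[valid]
    return Volume(data=out, affine=t1w.affine.copy(), units="")
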