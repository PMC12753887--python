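"""Volume and mask data model, NIfTI I/O, per-slice morphology, in-plane resampling.

The package works in a fixed internal convention: the *last* array axis is
the superior-inferior (cord) axis, so an axial slice is ``data[:, :, k]``.
Images loaded from disk are reoriented to RAS+ (via the NIfTI affine) so this
holds regardless of how the file was stored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage


class GeometryError(ValueError):
    """Raised when two objects that must share a voxel grid do not."""


@dataclass
class Volume3D:
    """A 3-D scalar intensity grid with voxel spacing and orientation metadata.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Intensities in arbitrary units. Must be finite everywhere.
    spacing : tuple of float
        Voxel size in mm along each axis; strictly positive.
    affine : ndarray, shape (4, 4), optional
        Voxel-to-world affine (NIfTI convention). Defaults to a diagonal
        affine built from ``spacing``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D array, got {self.data.ndim}-D")
        n_bad = int(np.count_nonzero(~np.isfinite(self.data)))
        if n_bad:
            raise ValueError(f"volume contains {n_bad} non-finite voxel(s)")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 strictly positive values, got {self.spacing}")
        if self.affine is None:
            self.affine = np.diag([*self.spacing, 1.0])
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_slices(self) -> int:
        """Number of axial slices (extent along the superior-inferior axis)."""
        return self.data.shape[2]

    @property
    def pixel_area_mm2(self) -> float:
        """In-plane voxel area in mm^2."""
        return self.spacing[0] * self.spacing[1]

    def with_data(self, data: np.ndarray) -> "Volume3D":
        """Return a copy carrying ``data`` on the same grid."""
        return replace(self, data=data)

    def same_geometry(self, other: "Volume3D | CordMask") -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing)


@dataclass
class CordMask:
    """Binary or soft (fractional) cord mask on the grid of a parent volume.

    Values lie in [0, 1]; a binary mask contains only {0, 1}. Fractional
    values arise from interpolation (e.g. after in-plane rescaling) and are
    carried through area computations as partial-volume weights.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D mask, got {self.data.ndim}-D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("mask contains non-finite values")
        if self.data.min() < 0 or self.data.max() > 1:
            raise ValueError(
                f"mask values must lie in [0, 1], got range "
                f"[{self.data.min():g}, {self.data.max():g}]"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        if self.affine is None:
            self.affine = np.diag([*self.spacing, 1.0])
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def is_binary(self) -> bool:
        return bool(np.isin(self.data, (0.0, 1.0)).all())

    def binary(self) -> np.ndarray:
        """Boolean array view of a binary mask (raises if fractional)."""
        if not self.is_binary:
            raise ValueError("operation requires a binary mask")
        return self.data.astype(bool)

    def threshold(self, level: float = 0.5) -> "CordMask":
        """Binarize a soft mask at ``level`` (strictly greater than)."""
        return CordMask((self.data > level).astype(float), self.spacing, self.affine)

    def with_data(self, data: np.ndarray) -> "CordMask":
        return CordMask(data, self.spacing, self.affine)

    def same_geometry(self, other: "Volume3D | CordMask") -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing)


@dataclass(frozen=True)
class StructuringElement:
    """In-plane circular (lattice-disc) structuring element.

    The footprint is the set of integer offsets (dx, dy) with
    dx^2 + dy^2 <= radius_px^2; it is symmetric under 90-degree rotation
    and point reflection. radius_px = 1 gives the 4-connected cross whose
    dilate-minus-erode produces a 2-pixel boundary ring.
    """

    radius_px: int

    def __post_init__(self) -> None:
        if self.radius_px < 1:
            raise ValueError("structuring-element radius must be >= 1 pixel")

    def footprint2d(self) -> np.ndarray:
        r = self.radius_px
        y, x = np.mgrid[-r : r + 1, -r : r + 1]
        return (x * x + y * y) <= r * r


def _check_binary(mask: CordMask) -> np.ndarray:
    if not mask.is_binary:
        raise ValueError("morphological operations require a binary mask")
    return mask.data.astype(bool)


def dilate_mask(mask: CordMask, se: StructuringElement) -> CordMask:
    """Per-axial-slice morphological dilation; never crosses slices."""
    data = _check_binary(mask)
    foot = se.footprint2d()[:, :, None]  # in-plane footprint, depth 1
    out = ndimage.binary_dilation(data, structure=foot)
    return mask.with_data(out.astype(float))


def erode_mask(mask: CordMask, se: StructuringElement) -> CordMask:
    """Per-axial-slice morphological erosion (dual of :func:`dilate_mask`)."""
    data = _check_binary(mask)
    foot = se.footprint2d()[:, :, None]
    out = ndimage.binary_erosion(data, structure=foot, border_value=0)
    return mask.with_data(out.astype(float))


def boundary_ring(mask: CordMask, se: StructuringElement | None = None) -> CordMask:
    """Dilate-minus-erode ring at the mask boundary.

    With the default radius-1 element this is the 2-pixel-wide annulus
    straddling the CSF/cord transition zone in each axial plane.
    """
    se = se or StructuringElement(1)
    d = dilate_mask(mask, se).data.astype(bool)
    e = erode_mask(mask, se).data.astype(bool)
    return mask.with_data((d & ~e).astype(float))


def rescale_inplane(
    vol: Volume3D,
    scale: float,
    center: np.ndarray | tuple[float, float] | None = None,
) -> Volume3D:
    """Shrink every axial slice about a fixed point by a linear factor.

    Uses inverse mapping (output -> input voxel coordinates) with bilinear
    interpolation per slice, which coincides with trilinear interpolation for
    a purely in-plane transform. Values are convex combinations of the input,
    so no intensity overshoot occurs; the through-plane axis is untouched.

    Parameters
    ----------
    scale : float in (0, 1]
        Linear shrink factor. 1.0 is the identity.
    center : (2,) point, (n_slices, 2) array, or None
        In-plane fixed point of the transform, per slice or shared. Defaults
        to the geometric slice center.
    """
    if not (0.0 < scale <= 1.0):
        raise ValueError(f"scale must be in (0, 1], got {scale}")
    nx, ny, nz = vol.shape
    if center is None:
        centers = np.tile([(nx - 1) / 2.0, (ny - 1) / 2.0], (nz, 1))
    else:
        centers = np.asarray(center, dtype=float)
        if centers.ndim == 1:
            centers = np.tile(centers, (nz, 1))
        if centers.shape != (nz, 2):
            raise ValueError("center must be a single (x, y) point or one per slice")
    if scale == 1.0:
        return vol.with_data(vol.data.copy())

    xi, yi = np.mgrid[0:nx, 0:ny].astype(float)
    out = np.empty_like(vol.data, dtype=float)
    for k in range(nz):
        cx, cy = centers[k]
        # inverse map: where in the input does output pixel (x, y) come from
        src_x = cx + (xi - cx) / scale
        src_y = cy + (yi - cy) / scale
        out[:, :, k] = ndimage.map_coordinates(
            vol.data[:, :, k].astype(float),
            [src_x, src_y],
            order=1,
            mode="nearest",
        )
    return vol.with_data(out)


# ---------------------------------------------------------------------------
# NIfTI I/O


def read_nifti(path: str | Path) -> Volume3D:
    """Load a NIfTI-1/2 image as a :class:`Volume3D`.

    The image is reoriented to RAS+ so the last axis is superior-inferior.
    Raises on missing files, non-3-D images, and non-finite voxels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.as_closest_canonical(nib.load(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D image, got {data.ndim}-D")
    n_bad = int(np.count_nonzero(~np.isfinite(data)))
    if n_bad:
        raise ValueError(f"{path}: image contains {n_bad} non-finite voxel(s)")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume3D(np.asarray(data, dtype=np.float64), spacing, np.asarray(img.affine))


def read_mask(path: str | Path) -> CordMask:
    """Load a NIfTI mask; data must already lie in [0, 1]."""
    vol = read_nifti(path)
    return CordMask(vol.data, vol.spacing, vol.affine)


def write_nifti(obj: Volume3D | CordMask, path: str | Path) -> None:
    """Write a volume (float64) or mask (uint8 if binary, float32 if soft)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(obj, CordMask):
        dtype = np.uint8 if obj.is_binary else np.float32
    else:
        dtype = np.float64
    img = nib.Nifti1Image(obj.data.astype(dtype), obj.affine)
    img.header.set_zooms(obj.spacing)
    nib.save(img, path)
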