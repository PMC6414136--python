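"""CT volume and binary-mask grid model plus I/O.

Conventions
-----------
* The patient coordinate frame is DICOM LPS (+x left, +y posterior,
  +z superior); every millimetre quantity downstream (meshes, air gaps, wall
  thickness) is expressed in it.
* Voxel arrays are indexed ``[k, j, i]`` = (slice, row, column); ``spacing``
  follows the same axis order.  ``origin`` is the LPS position of the *center*
  of voxel ``(0, 0, 0)``; voxel indices address voxel centers throughout, and
  masks live on the same lattice as the CT they were derived from.
* ``axes`` holds the unit direction (in LPS, as an (x, y, z) vector) along
  which each array axis increases.  For a standard axial acquisition this is
  ``[[0,0,1], [0,1,0], [1,0,0]]``.

Supported containers: DICOM CT series (read-only) and a small self-describing
NPZ container for fixtures and intermediate masks.
"""

from __future__ import annotations

import dataclasses
import os
from pathlib import Path

import numpy as np
import pydicom
from scipy import ndimage

from .errors import GridError, SeriesReadError

HU_MIN = -1024.0
HU_MAX = 3071.0

#: default array-axis directions for an axial LPS acquisition
AXIAL_AXES = np.array([[0.0, 0.0, 1.0], [0.0, 1.0, 0.0], [1.0, 0.0, 0.0]])


def _as_vec3(x, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float)
    if v.shape != (3,):
        raise GridError(f"{name} must be a 3-vector, got shape {v.shape}")
    return v


def _check_axes(axes: np.ndarray) -> np.ndarray:
    axes = np.asarray(axes, dtype=float)
    if axes.shape != (3, 3):
        raise GridError(f"axes must be 3x3, got {axes.shape}")
    if not np.allclose(axes @ axes.T, np.eye(3), atol=1e-6):
        raise GridError("grid axes are not orthonormal")
    return axes


@dataclasses.dataclass
class _Grid:
    """Shared geometry behaviour of :class:`CTVolume` and :class:`BinaryMask`."""

    voxels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    axes: np.ndarray = dataclasses.field(default_factory=lambda: AXIAL_AXES.copy())

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise GridError(f"expected a 3D voxel grid, got ndim={self.voxels.ndim}")
        self.spacing = _as_vec3(self.spacing, "spacing")
        if np.any(self.spacing <= 0):
            raise GridError(f"spacing must be positive, got {self.spacing}")
        self.origin = _as_vec3(self.origin, "origin")
        self.axes = _check_axes(self.axes)

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def same_geometry(self, other: "_Grid", atol: float = 1e-3) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
            and np.allclose(self.axes, other.axes, atol=1e-6)
        )

    def require_same_geometry(self, other: "_Grid", what: str = "grids") -> None:
        if not self.same_geometry(other):
            raise GridError(f"{what} do not share a common grid geometry")

    def world_coordinates(self, indices: np.ndarray) -> np.ndarray:
        """Map fractional voxel indices (N, 3) in (k, j, i) order to LPS mm."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return (idx * self.spacing) @ self.axes + self.origin

    def axis_world_coords(self, axis: int) -> np.ndarray:
        """World positions of voxel centers along one array axis (projected)."""
        n = self.shape[axis]
        return np.arange(n) * self.spacing[axis]

    def world_z(self) -> np.ndarray:
        """Patient-z (superior) coordinate of every voxel, shaped like voxels."""
        kk, jj, ii = np.meshgrid(
            np.arange(self.shape[0]),
            np.arange(self.shape[1]),
            np.arange(self.shape[2]),
            indexing="ij",
            sparse=True,
        )
        z = self.origin[2]
        z = (
            z
            + kk * self.spacing[0] * self.axes[0, 2]
            + jj * self.spacing[1] * self.axes[1, 2]
            + ii * self.spacing[2] * self.axes[2, 2]
        )
        return np.broadcast_to(z, self.shape)


@dataclasses.dataclass
class CTVolume(_Grid):
    """Regular 3D grid of Hounsfield units with LPS geometry."""

    def __post_init__(self) -> None:
        super().__post_init__()
        self.voxels = self.voxels.astype(np.float32, copy=False)
        if self.voxels.size:
            lo, hi = float(self.voxels.min()), float(self.voxels.max())
            if lo < HU_MIN - 0.5 or hi > HU_MAX + 0.5:
                raise GridError(
                    f"HU values outside [{HU_MIN:g}, {HU_MAX:g}]: range [{lo:g}, {hi:g}]"
                )


@dataclasses.dataclass
class BinaryMask(_Grid):
    """Boolean grid sharing the geometry of the CT it was derived from."""

    def __post_init__(self) -> None:
        super().__post_init__()
        self.voxels = self.voxels.astype(bool, copy=False)

    @property
    def count(self) -> int:
        return int(self.voxels.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def volume_mm3(self) -> float:
        return self.count * self.voxel_volume_mm3

    @classmethod
    def like(cls, other: _Grid, voxels: np.ndarray) -> "BinaryMask":
        return cls(
            voxels=voxels,
            spacing=other.spacing.copy(),
            origin=other.origin.copy(),
            axes=other.axes.copy(),
        )


# ---------------------------------------------------------------------------
# DICOM CT series reading
# ---------------------------------------------------------------------------

def read_ct_series(directory_path: str | os.PathLike) -> CTVolume:
    """Read a single axial CT series from a directory of DICOM files.

    Slices are sorted by position along the slice normal; Hounsfield units are
    computed from the stored values via each slice's rescale slope/intercept.

    Raises
    ------
    SeriesReadError
        If the directory holds no readable slices, mixes series identifiers,
        or has duplicate/non-uniform slice positions (the message names the
        offending position).
    """
    directory = Path(directory_path)
    slices = []
    for path in sorted(directory.iterdir()):
        if not path.is_file():
            continue
        try:
            ds = pydicom.dcmread(path)
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            slices.append(ds)
    if not slices:
        raise SeriesReadError(f"no readable DICOM image slices in {directory}")

    uids = {str(getattr(ds, "SeriesInstanceUID", "")) for ds in slices}
    if len(uids) > 1:
        raise SeriesReadError(
            f"directory mixes {len(uids)} series identifiers: {sorted(uids)}"
        )

    first = slices[0]
    orient = np.asarray(first.ImageOrientationPatient, dtype=float)
    row_dir, col_dir = orient[:3], orient[3:]  # direction of increasing column / row
    normal = np.cross(row_dir, col_dir)

    def slice_pos(ds) -> float:
        return float(np.dot(np.asarray(ds.ImagePositionPatient, dtype=float), normal))

    slices.sort(key=slice_pos)
    positions = np.array([slice_pos(ds) for ds in slices])
    if len(slices) > 1:
        steps = np.diff(positions)
        if np.any(np.abs(steps) < 1e-3):
            at = positions[np.argmin(np.abs(steps))]
            raise SeriesReadError(f"duplicate slice position near {at:.3f} mm")
        if np.ptp(steps) > 1e-3:
            k = int(np.argmax(np.abs(steps - np.median(steps))))
            raise SeriesReadError(
                "non-uniform slice spacing: step of "
                f"{steps[k]:.3f} mm between positions {positions[k]:.3f} and "
                f"{positions[k + 1]:.3f} mm (median step {np.median(steps):.3f} mm)"
            )
        slice_step = float(np.median(steps))
    else:
        slice_step = float(getattr(first, "SliceThickness", 1.0))

    hu = np.empty((len(slices),) + slices[0].pixel_array.shape, dtype=np.float32)
    for k, ds in enumerate(slices):
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        hu[k] = ds.pixel_array.astype(np.float32) * slope + intercept
    np.clip(hu, HU_MIN, HU_MAX, out=hu)

    pixel_spacing = np.asarray(first.PixelSpacing, dtype=float)  # (row, col)
    spacing = np.array([slice_step, pixel_spacing[0], pixel_spacing[1]])
    axes = np.vstack([normal, col_dir, row_dir])
    origin = np.asarray(slices[0].ImagePositionPatient, dtype=float)
    return CTVolume(voxels=hu, spacing=spacing, origin=origin, axes=axes)


# ---------------------------------------------------------------------------
# Fixture volume container (self-describing NPZ)
# ---------------------------------------------------------------------------

def save_volume(obj: CTVolume | BinaryMask, path: str | os.PathLike) -> None:
    """Write a volume or mask to the internal NPZ container."""
    kind = "mask" if isinstance(obj, BinaryMask) else "ct"
    np.savez_compressed(
        path,
        voxels=obj.voxels,
        spacing=obj.spacing,
        origin=obj.origin,
        axes=obj.axes,
        kind=np.array(kind),
    )


def load_volume(path: str | os.PathLike) -> CTVolume | BinaryMask:
    """Read a volume or mask previously written by :func:`save_volume`."""
    with np.load(path) as data:
        kind = str(data["kind"])
        cls = BinaryMask if kind == "mask" else CTVolume
        return cls(
            voxels=data["voxels"],
            spacing=data["spacing"],
            origin=data["origin"],
            axes=data["axes"],
        )


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def resample_isotropic(obj: CTVolume | BinaryMask, target_spacing_mm: float):
    """Resample to isotropic spacing, preserving the physical (edge-to-edge)
    extent to within one voxel.

    Scalar volumes are interpolated linearly, masks by nearest neighbour, so
    each kind maps to itself.
    """
    target = float(target_spacing_mm)
    if target <= 0:
        raise GridError(f"target spacing must be positive, got {target}")
    if np.allclose(obj.spacing, target):
        return dataclasses.replace(obj, voxels=obj.voxels.copy())

    zoom = obj.spacing / target
    is_mask = isinstance(obj, BinaryMask)
    if is_mask:
        out = ndimage.zoom(
            obj.voxels.astype(np.uint8), zoom, order=0,
            mode="nearest", grid_mode=True,
        ).astype(bool)
    else:
        out = ndimage.zoom(
            obj.voxels.astype(np.float32), zoom, order=1,
            mode="nearest", grid_mode=True,
        )
        np.clip(out, HU_MIN, HU_MAX, out=out)

    # voxel (0,0,0) center moves so that the outer grid edges stay fixed
    shift = (target - obj.spacing) / 2.0
    origin = obj.origin + shift @ obj.axes
    spacing = np.full(3, target)
    cls = BinaryMask if is_mask else CTVolume
    return cls(voxels=out, spacing=spacing, origin=origin, axes=obj.axes.copy())
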