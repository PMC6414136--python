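"""Conformality and wall-thickness QA for a built (or fitted) bolus.

Air gap: for every body-surface voxel inside the cap extent, the Euclidean
distance to the nearest bolus voxel, less half a voxel diagonal (the
center-to-center offset of two touching voxels), floored at zero.  A shell
grown directly on the skin therefore reports a gap of zero to within voxel
tolerance; a displaced or badly fitting bolus reports the physical gap.  The
metric is volumetric (3D distances), independent of slice orientation, and is
evaluated only inside the cap extent because the rim necessarily diverges
from the scalp.

Wall thickness: at every inner-surface bolus voxel (a bolus voxel touching
the body) inside the extent, the distance through the solid (body ∪ bolus)
to the outside air — a double distance transform.  For a uniform shell of
thickness t this recovers t.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .errors import QaError
from .grid import BinaryMask

_CONN6 = ndimage.generate_binary_structure(3, 1)


@dataclasses.dataclass(frozen=True)
class GapMap:
    """Skin-to-bolus air-gap samples (mm) and their summary."""

    distances_mm: np.ndarray
    max_mm: float
    mean_mm: float
    p95_mm: float

    @classmethod
    def from_distances(cls, d: np.ndarray) -> "GapMap":
        d = np.asarray(d, dtype=float)
        return cls(
            distances_mm=d,
            max_mm=float(d.max()),
            mean_mm=float(d.mean()),
            p95_mm=float(np.percentile(d, 95)),
        )


@dataclasses.dataclass(frozen=True)
class ThicknessMap:
    """Bolus wall-thickness samples (mm) and their summary."""

    thickness_mm: np.ndarray
    median_mm: float
    min_mm: float
    max_mm: float

    @classmethod
    def from_samples(cls, t: np.ndarray) -> "ThicknessMap":
        t = np.asarray(t, dtype=float)
        return cls(
            thickness_mm=t,
            median_mm=float(np.median(t)),
            min_mm=float(t.min()),
            max_mm=float(t.max()),
        )


def _surface(voxels: np.ndarray) -> np.ndarray:
    """Voxels of a mask with at least one 6-neighbour outside it."""
    return voxels & ~ndimage.binary_erosion(voxels, structure=_CONN6, border_value=0)


def air_gap_map(body: BinaryMask, bolus: BinaryMask, extent: BinaryMask) -> GapMap:
    """Air gap from each body-surface voxel inside the extent to the bolus."""
    body.require_same_geometry(bolus, "body and bolus masks")
    body.require_same_geometry(extent, "body and extent masks")
    if not (bolus.voxels & extent.voxels).any():
        raise QaError("bolus mask is empty inside the cap extent")
    samples = _surface(body.voxels) & extent.voxels
    if not samples.any():
        raise QaError("no body-surface voxels inside the cap extent")

    dist_to_bolus = ndimage.distance_transform_edt(~bolus.voxels, sampling=body.spacing)
    half_diag = float(np.linalg.norm(body.spacing)) / 2.0
    gaps = np.maximum(dist_to_bolus[samples] - half_diag, 0.0)
    return GapMap.from_distances(gaps)


def thickness_map(bolus: BinaryMask, body: BinaryMask, extent: BinaryMask) -> ThicknessMap:
    """Wall thickness sampled on the bolus inner surface inside the extent."""
    body.require_same_geometry(bolus, "body and bolus masks")
    body.require_same_geometry(extent, "body and extent masks")
    if not bolus.voxels.any():
        raise QaError("bolus mask is empty")

    solid = body.voxels | bolus.voxels
    dist_to_air = ndimage.distance_transform_edt(solid, sampling=body.spacing)
    touching_body = ndimage.binary_dilation(body.voxels, structure=_CONN6)
    inner = bolus.voxels & touching_body & extent.voxels
    if not inner.any():
        raise QaError("bolus has no inner-surface voxels touching the body inside the extent")
    return ThicknessMap.from_samples(dist_to_air[inner])
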