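"""External-contour segmentation and uniform-thickness shell construction.

This is the core of the workflow: from a head CT, segment the body (external
contour), restrict to the desired cap extent, and grow a shell of uniform
physical thickness ``t`` on the skin by thresholding an exact Euclidean
distance transform of the body mask:

    shell = { v outside body : dist(v, body) <= t } ∩ extent

The distance-transform formulation is the normative definition of the
"expansions, contractions and Boolean operations" of the workflow: unlike
iterated structuring-element dilation it yields a thickness that is uniform
in millimetres regardless of voxel anisotropy.  Voxels at exactly distance
``t`` are included (closed interval) for determinism.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .errors import SegmentationError, ShellError
from .grid import BinaryMask, CTVolume

#: 6-connectivity structuring element in 3D
_CONN6 = ndimage.generate_binary_structure(3, 1)


@dataclasses.dataclass(frozen=True)
class BolusParams:
    """Shell-construction parameters.

    thickness_mm : shell thickness t; 5 mm is the standard scalp-bolus value.
    body_threshold_hu : external-contour threshold; −400 HU separates tissue
        from air robustly for head protocols.
    closing_radius_mm : morphological closing radius applied to the body mask
        to regularize the skin surface before shell growth.
    """

    thickness_mm: float = 5.0
    body_threshold_hu: float = -400.0
    closing_radius_mm: float = 2.0

    def __post_init__(self) -> None:
        if self.thickness_mm <= 0:
            raise ShellError(f"thickness_mm must be > 0, got {self.thickness_mm}")
        if self.closing_radius_mm < 0:
            raise ShellError("closing_radius_mm must be >= 0")


@dataclasses.dataclass(frozen=True)
class CapExtent:
    """Axial clipping of the cap: no bolus below ``inferior_plane_mm``
    (patient-z, LPS mm).  ``edge_feather_mm`` optionally tapers the shell
    thickness to zero over that band above the plane so the printed rim
    feathers out instead of ending in a square edge."""

    inferior_plane_mm: float
    edge_feather_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.edge_feather_mm < 0:
            raise ShellError("edge_feather_mm must be >= 0")


def _ball(radius_mm: float, spacing: np.ndarray) -> np.ndarray:
    """Ellipsoidal structuring element covering a physical ball."""
    half = np.maximum(np.floor(radius_mm / spacing).astype(int), 0)
    if not half.any():
        return _CONN6
    zz, yy, xx = np.meshgrid(
        *(np.arange(-h, h + 1) * s for h, s in zip(half, spacing)), indexing="ij"
    )
    return zz**2 + yy**2 + xx**2 <= radius_mm**2 + 1e-9


def segment_body(ct: CTVolume, params: BolusParams | None = None) -> BinaryMask:
    """Segment the external body contour.

    Largest 6-connected component of {HU >= body_threshold_hu}, with internal
    cavities filled and the surface regularized by morphological closing.
    The result is a single connected component with no holes.
    """
    params = params or BolusParams()
    thresholded = ct.voxels >= params.body_threshold_hu
    if not thresholded.any():
        raise SegmentationError(
            f"no body found: no voxel at or above {params.body_threshold_hu:g} HU"
        )

    labels, n = ndimage.label(thresholded, structure=_CONN6)
    if n > 1:
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        body = labels == int(np.argmax(counts))
    else:
        body = thresholded

    faces = [body[0], body[-1], body[:, 0], body[:, -1], body[:, :, 0], body[:, :, -1]]
    if all(f.any() for f in faces):
        raise SegmentationError(
            "largest component touches all six grid faces; "
            "body threshold looks wrong for this volume"
        )

    body = ndimage.binary_fill_holes(body)
    if params.closing_radius_mm > 0:
        ball = _ball(params.closing_radius_mm, ct.spacing)
        body = ndimage.binary_closing(body, structure=ball)
        body = ndimage.binary_fill_holes(body)
    return BinaryMask.like(ct, body)


def make_cap_extent(body: BinaryMask, cap: CapExtent) -> BinaryMask:
    """Half-space mask at/above the cap's inferior axial plane, on the body
    grid.  Errors if the plane lies above the whole body (empty extent)."""
    z = body.world_z()
    body_top = float(z[body.voxels].max()) if body.voxels.any() else float(z.max())
    if cap.inferior_plane_mm > body_top:
        raise ShellError(
            f"cap extent is empty: inferior plane {cap.inferior_plane_mm:g} mm lies "
            f"above the body (top at {body_top:g} mm)"
        )
    return BinaryMask.like(body, z >= cap.inferior_plane_mm)


def distance_to_body(body: BinaryMask) -> np.ndarray:
    """Exact Euclidean distance (mm) from every voxel center to the nearest
    body voxel center; 0 inside the body."""
    return ndimage.distance_transform_edt(~body.voxels, sampling=body.spacing)


def build_bolus_shell(
    body: BinaryMask, params: BolusParams, extent: BinaryMask
) -> BinaryMask:
    """Grow the uniform-thickness bolus shell on the body surface.

    The shell is every voxel outside the body whose Euclidean distance to the
    body is at most ``thickness_mm``, clipped to the cap extent.  It is
    disjoint from the body by construction.
    """
    if not body.voxels.any():
        raise ShellError("body mask is empty")
    body.require_same_geometry(extent, "body and extent masks")
    t = params.thickness_mm
    if t < float(np.max(body.spacing)):
        raise ShellError(
            f"thickness {t:g} mm is smaller than one voxel "
            f"(coarsest spacing {np.max(body.spacing):g} mm); resample first"
        )
    dist = distance_to_body(body)
    shell = (dist > 0) & (dist <= t) & extent.voxels
    if not shell.any():
        raise ShellError("bolus shell is empty after clipping to the cap extent")
    return BinaryMask.like(body, shell)


def apply_rim_feather(
    shell: BinaryMask, body: BinaryMask, cap: CapExtent, params: BolusParams
) -> BinaryMask:
    """Taper the shell thickness linearly from 0 at the inferior plane to the
    full thickness at ``edge_feather_mm`` above it."""
    if cap.edge_feather_mm <= 0:
        return shell
    z = shell.world_z()
    ramp = np.clip((z - cap.inferior_plane_mm) / cap.edge_feather_mm, 0.0, 1.0)
    allowed = params.thickness_mm * ramp
    dist = distance_to_body(body)
    out = shell.voxels & (dist <= allowed)
    return BinaryMask.like(shell, out)
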