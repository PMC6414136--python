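"""Mask-to-mesh conversion, smoothing, and binary STL I/O.

The bolus mask becomes a watertight triangle mesh by marching cubes at
iso-level 0.5 of the (optionally Gaussian-presmoothed) mask, with vertices in
patient LPS millimetres — the frame and units the printed part is defined in;
no coordinate flip is applied on export.  Binary STL is the interchange
format: 80-byte header, little-endian 32-bit facet count, 50 bytes per facet,
per-facet normals recomputed from the winding.
"""

from __future__ import annotations

import os

import numpy as np
import trimesh
from scipy import ndimage
from skimage import measure

from .errors import MeshError, StlFormatError
from .grid import BinaryMask

_STL_FACET = np.dtype(
    [
        ("normal", "<f4", (3,)),
        ("v1", "<f4", (3,)),
        ("v2", "<f4", (3,)),
        ("v3", "<f4", (3,)),
        ("attr", "<u2"),
    ]
)


def validate_mesh(mesh: trimesh.Trimesh) -> None:
    """Raise unless the mesh is watertight, non-degenerate, and encloses a
    positive volume."""
    if len(mesh.faces) == 0:
        raise MeshError("mesh has no faces")
    if not mesh.is_watertight:
        raise MeshError("mesh is not watertight (open edges present)")
    areas = mesh.area_faces
    if np.any(areas <= 0):
        raise MeshError(f"mesh has {int(np.sum(areas <= 0))} degenerate faces")
    if mesh.volume <= 0:
        raise MeshError(f"mesh encloses non-positive volume {mesh.volume:g} mm^3")


def mask_to_mesh(mask: BinaryMask, presmooth_sigma_voxels: float = 0.5) -> trimesh.Trimesh:
    """Extract a watertight surface mesh from a binary mask.

    Marching cubes runs at level 0.5 on the mask (Gaussian-presmoothed by
    ``presmooth_sigma_voxels`` for sub-voxel surface placement; set 0 to
    disable).  Vertices are returned in LPS mm.  The mask must be a single
    connected component — a printable part is one piece.
    """
    if not mask.voxels.any():
        raise MeshError("cannot mesh an empty mask")
    _, n = ndimage.label(mask.voxels, structure=np.ones((3, 3, 3), dtype=bool))
    if n != 1:
        raise MeshError(f"mask has {n} connected components; expected a single part")

    vol = np.pad(mask.voxels, 1).astype(np.float32)
    if presmooth_sigma_voxels > 0:
        vol = ndimage.gaussian_filter(vol, presmooth_sigma_voxels)
        # keep the binary plateau so level 0.5 stays inside the data range
        vol = np.clip(vol, 0.0, 1.0)
    verts_idx, faces, _, _ = measure.marching_cubes(
        vol, level=0.5, spacing=tuple(mask.spacing)
    )
    verts_idx -= mask.spacing  # undo the one-voxel pad
    vertices = (verts_idx / mask.spacing) @ (mask.axes * mask.spacing[:, None]) + mask.origin

    mesh = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
    if mesh.volume < 0:
        mesh.invert()
    validate_mesh(mesh)
    return mesh


def smooth_mesh(
    mesh: trimesh.Trimesh, iterations: int = 10, max_deviation_mm: float = 0.5
) -> trimesh.Trimesh:
    """Volume-preserving Taubin smoothing with a hard cap on vertex motion.

    Displacements larger than ``max_deviation_mm`` are clamped to that bound,
    so the smoothed surface never departs from the voxel surface by more than
    the stated tolerance.  Watertightness is re-validated.
    """
    if iterations < 0:
        raise MeshError("iterations must be >= 0")
    out = mesh.copy()
    if iterations == 0:
        return out
    trimesh.smoothing.filter_taubin(out, lamb=0.5, nu=0.53, iterations=iterations)
    disp = np.asarray(out.vertices) - np.asarray(mesh.vertices)
    norms = np.linalg.norm(disp, axis=1)
    over = norms > max_deviation_mm
    if over.any():
        disp[over] *= (max_deviation_mm / norms[over])[:, None]
        out.vertices = np.asarray(mesh.vertices) + disp
    validate_mesh(out)
    return out


def write_stl(mesh: trimesh.Trimesh, path: str | os.PathLike) -> None:
    """Write a binary little-endian STL with per-facet normals recomputed
    from the face winding."""
    validate_mesh(mesh)
    tri = mesh.vertices[mesh.faces].astype(np.float32)  # (n, 3, 3)
    normals = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    lengths = np.linalg.norm(normals, axis=1, keepdims=True)
    normals = np.where(lengths > 0, normals / np.maximum(lengths, 1e-30), 0.0)

    facets = np.zeros(len(tri), dtype=_STL_FACET)
    facets["normal"] = normals.astype(np.float32)
    facets["v1"], facets["v2"], facets["v3"] = tri[:, 0], tri[:, 1], tri[:, 2]

    header = b"boluscap binary STL (units: mm, frame: LPS)"
    header = header + b"\0" * (80 - len(header))
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(np.uint32(len(tri)).tobytes())
        fh.write(facets.tobytes())


def read_stl(path: str | os.PathLike) -> trimesh.Trimesh:
    """Read a binary STL, checking the facet count against the file length,
    and rebuild an indexed mesh by merging exactly coincident vertices."""
    with open(path, "rb") as fh:
        data = fh.read()
    if len(data) < 84:
        raise StlFormatError(f"{path}: file too short for a binary STL header")
    n = int(np.frombuffer(data[80:84], dtype="<u4")[0])
    expected = 84 + 50 * n
    if len(data) != expected:
        raise StlFormatError(
            f"{path}: facet count {n} implies {expected} bytes but file has {len(data)}"
        )
    facets = np.frombuffer(data[84:], dtype=_STL_FACET)
    tri = np.stack([facets["v1"], facets["v2"], facets["v3"]], axis=1)  # (n, 3, 3)
    flat = tri.reshape(-1, 3)
    vertices, inverse = np.unique(flat, axis=0, return_inverse=True)
    faces = inverse.reshape(-1, 3)
    return trimesh.Trimesh(vertices=vertices.astype(np.float64), faces=faces, process=False)
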