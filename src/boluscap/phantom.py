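"""Synthetic head-CT phantom with closed-form ground truth.

The phantom is an analytic ellipsoidal "head": soft tissue inside the scalp
surface, a bone shell (skull) a fixed depth beneath it, air outside.  Because
the surface is analytic, point-to-surface distances, cap volumes and shell
volumes all have closed forms, which makes every downstream stage of the
pipeline (segmentation, shell construction, meshing, gap/thickness QA)
testable without any scan data.

Optional low-amplitude sinusoidal surface bumps turn the quadric into a
non-convex "scalp" for conformality stress tests.  Generation is a pure
function of the spec, including its seed.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import brentq
from scipy.spatial import cKDTree

from .errors import GridError
from .grid import AXIAL_AXES, HU_MAX, HU_MIN, BinaryMask, CTVolume


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic head phantom.

    ``head_radii`` are the ellipsoid semi-axes in mm, in patient (x, y, z)
    order.  The default geometry approximates an adult head scanned with a
    head-and-neck CT-simulation protocol: ~150 mm wide, ~180 mm deep,
    3 mm slices with ~1 mm in-plane pixels, mild quantum noise.
    """

    head_radii: tuple[float, float, float] = (75.0, 90.0, 80.0)
    tissue_hu: float = 40.0
    bone_hu: float = 700.0
    air_hu: float = -1000.0
    scalp_thickness_mm: float = 5.0
    bone_shell_mm: float = 7.0
    noise_sd_hu: float = 10.0
    seed: int = 0
    spacing: tuple[float, float, float] = (3.0, 1.0, 1.0)  # (z, y, x) mm
    margin_mm: float = 20.0
    bump_amplitude_mm: float = 0.0
    bump_cycles: int = 6

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.head_radii):
            raise GridError("head radii must be positive")
        if self.noise_sd_hu < 0:
            raise GridError("noise_sd_hu must be >= 0")
        if self.margin_mm < 10.0:
            raise GridError("head must fit inside the grid with >= 10 mm margin")
        if self.bump_amplitude_mm < 0:
            raise GridError("bump amplitude must be >= 0")


class HeadSurface:
    """Analytic scalp surface of a phantom, supporting distance queries.

    For a spherical head the signed distance is closed-form.  For a general
    ellipsoid the foot-point problem is solved per query point by root
    finding, accurate to ~1e-9 mm.  With surface bumps enabled the distance
    is evaluated against a dense surface sampling (KD-tree), accurate to the
    sampling resolution (~0.2 mm).
    """

    def __init__(self, spec: PhantomSpec, center_mm: np.ndarray):
        self.spec = spec
        self.center = np.asarray(center_mm, dtype=float)
        self.radii = np.asarray(spec.head_radii, dtype=float)
        self._is_sphere = np.allclose(self.radii, self.radii[0]) and (
            spec.bump_amplitude_mm == 0
        )
        self._tree: cKDTree | None = None
        if spec.bump_amplitude_mm > 0:
            self._tree = cKDTree(self._sample_surface(n_theta=720, n_phi=360))

    # -- geometry helpers --------------------------------------------------
    def radius_along(self, unit_dirs: np.ndarray) -> np.ndarray:
        """Distance from center to the surface along unit directions (N, 3)."""
        u = np.atleast_2d(unit_dirs)
        base = 1.0 / np.sqrt(np.sum((u / self.radii) ** 2, axis=1))
        if self.spec.bump_amplitude_mm > 0:
            base = base + self._bump(u)
        return base

    def _bump(self, u: np.ndarray) -> np.ndarray:
        m = self.spec.bump_cycles
        theta = np.arctan2(u[:, 1], u[:, 0])
        phi = np.arccos(np.clip(u[:, 2], -1.0, 1.0))
        return self.spec.bump_amplitude_mm * np.sin(m * theta) * np.sin(m * phi) ** 2

    def contains(self, points_mm: np.ndarray) -> np.ndarray:
        """True where points (N, 3) in LPS mm lie inside the scalp surface."""
        p = np.atleast_2d(points_mm) - self.center
        r = np.linalg.norm(p, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            u = np.where(r[:, None] > 0, p / np.maximum(r[:, None], 1e-12), 0.0)
        surf = np.where(r > 0, self.radius_along(u), np.inf)
        return r <= surf

    def signed_distance(self, points_mm: np.ndarray) -> np.ndarray:
        """Signed distance (mm) to the scalp surface; negative inside."""
        p = np.atleast_2d(points_mm) - self.center
        if self._tree is not None:
            d, _ = self._tree.query(p)
            inside = self.contains(np.atleast_2d(points_mm))
            return np.where(inside, -d, d)
        if self._is_sphere:
            return np.linalg.norm(p, axis=1) - self.radii[0]
        return np.array([self._ellipsoid_signed_distance(q) for q in p])

    def _ellipsoid_signed_distance(self, q: np.ndarray) -> float:
        a2 = self.radii**2
        qa = np.abs(q)
        if np.all(qa < 1e-12):
            return -float(self.radii.min())

        def g(t: float) -> float:
            return float(np.sum(a2 * qa**2 / (a2 + t) ** 2) - 1.0)

        inside = float(np.sum(qa**2 / a2)) <= 1.0
        lo = -float(a2.min()) + 1e-12 if inside else 0.0
        hi = float(self.radii.max() * (np.linalg.norm(qa) + self.radii.max()))
        if inside and g(0.0) <= 0:
            hi = 0.0
            lo = -float(a2.min()) * (1 - 1e-12)
        t = brentq(g, lo, hi, xtol=1e-12, maxiter=200)
        foot = a2 * qa / (a2 + t)
        d = float(np.linalg.norm(foot - qa))
        return -d if inside else d

    def _sample_surface(self, n_theta: int, n_phi: int) -> np.ndarray:
        theta = np.linspace(-np.pi, np.pi, n_theta, endpoint=False)
        phi = np.linspace(0, np.pi, n_phi)
        tt, pp = np.meshgrid(theta, phi, indexing="ij")
        u = np.column_stack(
            [
                (np.sin(pp) * np.cos(tt)).ravel(),
                (np.sin(pp) * np.sin(tt)).ravel(),
                np.cos(pp).ravel(),
            ]
        )
        return u * self.radius_along(u)[:, None]

    # -- analytic oracles --------------------------------------------------
    def volume_mm3(self) -> float:
        """Enclosed volume; exact for the un-bumped ellipsoid."""
        return float(4.0 / 3.0 * np.pi * np.prod(self.radii))


def generate_head_phantom(spec: PhantomSpec) -> tuple[CTVolume, HeadSurface]:
    """Build the phantom CT volume and its analytic surface description.

    HU assignment by depth below the scalp surface: air outside; soft tissue
    in the scalp layer and the head interior; bone in the skull shell between
    ``scalp_thickness_mm`` and ``scalp_thickness_mm + bone_shell_mm`` deep.
    Gaussian noise of ``noise_sd_hu`` is added with the spec's seed.
    """
    spacing = np.asarray(spec.spacing, dtype=float)  # (z, y, x)
    radii = np.asarray(spec.head_radii, dtype=float)  # (x, y, z)
    extent = 2 * (radii + spec.bump_amplitude_mm + spec.margin_mm)  # (x, y, z)
    shape = np.ceil(extent[::-1] / spacing).astype(int)  # (z, y, x)

    # head centered in the grid; origin = center of voxel (0,0,0)
    center_idx = (shape - 1) / 2.0
    origin = np.array([0.0, 0.0, 0.0])
    center_mm = origin + (center_idx * spacing) @ AXIAL_AXES
    surface = HeadSurface(spec, center_mm)

    kk, jj, ii = np.meshgrid(
        np.arange(shape[0]), np.arange(shape[1]), np.arange(shape[2]),
        indexing="ij", sparse=True,
    )
    # LPS coordinates relative to the head center (axial axes: x<-i, y<-j, z<-k)
    x = ii * spacing[2] - center_idx[2] * spacing[2]
    y = jj * spacing[1] - center_idx[1] * spacing[1]
    z = kk * spacing[0] - center_idx[0] * spacing[0]

    r = np.sqrt(x**2 + y**2 + z**2, dtype=np.float32)
    # radius of the surface along each voxel's direction: for the plain
    # ellipsoid this is r / q with q the scaled norm, no per-voxel unit
    # vectors needed
    q = np.sqrt(
        (x / radii[0]) ** 2 + (y / radii[1]) ** 2 + (z / radii[2]) ** 2,
        dtype=np.float32,
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        surf_r = np.where(q > 0, r / np.maximum(q, 1e-12), np.inf)
    if spec.bump_amplitude_mm > 0:
        r_safe = np.maximum(r, np.float32(1e-12))
        u = np.stack(
            np.broadcast_arrays(x / r_safe, y / r_safe, z / r_safe), axis=-1
        ).reshape(-1, 3)
        surf_r = surf_r + surface._bump(u).reshape(r.shape)

    depth = surf_r - r  # >0 inside the head
    if np.any(depth[0] > 0) or np.any(depth[-1] > 0) or np.any(
        depth[:, 0] > 0
    ) or np.any(depth[:, -1] > 0) or np.any(depth[:, :, 0] > 0) or np.any(
        depth[:, :, -1] > 0
    ):
        raise GridError("head exceeds the phantom grid")

    hu = np.full(tuple(shape), spec.air_hu, dtype=np.float32)
    hu[depth > 0] = spec.tissue_hu
    bone = (depth > spec.scalp_thickness_mm) & (
        depth <= spec.scalp_thickness_mm + spec.bone_shell_mm
    )
    hu[bone] = spec.bone_hu

    if spec.noise_sd_hu > 0:
        rng = np.random.default_rng(spec.seed)
        hu += rng.normal(0.0, spec.noise_sd_hu, size=hu.shape).astype(np.float32)
    np.clip(hu, HU_MIN, HU_MAX, out=hu)

    volume = CTVolume(voxels=hu, spacing=spacing, origin=origin)
    return volume, surface


def shift_mask(mask: BinaryMask, offset_mm) -> BinaryMask:
    """Translate a mask by the nearest-voxel equivalent of an LPS offset.

    The offset is given in patient (x, y, z) mm.  Raises if any set voxel
    would be pushed off the grid (truncation would silently change volumes
    the QA oracles rely on).
    """
    offset = np.asarray(offset_mm, dtype=float)
    if offset.shape != (3,):
        raise GridError("offset must be an (x, y, z) mm 3-vector")
    # voxel steps along array axes (k, j, i); assumes axial axes orientation
    steps_mm = mask.axes @ offset  # project onto each array-axis direction
    steps = np.round(steps_mm / mask.spacing).astype(int)

    out = np.zeros_like(mask.voxels)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for ax, s in enumerate(steps):
        n = mask.shape[ax]
        if abs(s) >= n:
            raise GridError(f"offset {offset} moves mask entirely off the grid")
        if s >= 0:
            src[ax], dst[ax] = slice(0, n - s), slice(s, n)
        else:
            src[ax], dst[ax] = slice(-s, n), slice(0, n + s)
    # voxels that would be truncated
    lost = mask.voxels.copy()
    lost[tuple(src)] = False
    if lost.any():
        raise GridError(
            f"offset {offset} truncates {int(lost.sum())} mask voxels at the grid boundary"
        )
    out[tuple(dst)] = mask.voxels[tuple(src)]
    return BinaryMask.like(mask, out)
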