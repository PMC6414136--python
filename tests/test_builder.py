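"""Body segmentation, cap extent, and uniform-thickness shell construction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial import cKDTree

import boluscap as bc
from boluscap.errors import SegmentationError, ShellError

FULL_EXTENT = bc.CapExtent(inferior_plane_mm=-1e6)


def _full_extent(body):
    return bc.make_cap_extent(body, FULL_EXTENT)


class TestSegmentBody:
    def test_all_air_volume_raises_no_body_found(self):
        vol = bc.CTVolume(np.full((10, 10, 10), -1000.0), spacing=(1, 1, 1),
                          origin=(0, 0, 0))
        with pytest.raises(SegmentationError, match="no body found"):
            bc.segment_body(vol)

    def test_sphere_volume_within_one_percent(self, sphere_phantom, sphere_masks):
        _, vol, _ = sphere_phantom
        body, _, _ = sphere_masks
        analytic = 4.0 / 3.0 * np.pi * 25.0**3
        assert body.volume_mm3 == pytest.approx(analytic, rel=0.01)

    def test_detached_speck_is_removed(self, sphere_phantom):
        _, vol, _ = sphere_phantom
        hu = vol.voxels.copy()
        hu[2, 2, 2:7] = 40.0  # 5-voxel speck of tissue far from the head
        speckled = bc.CTVolume(hu, spacing=vol.spacing, origin=vol.origin)
        body = bc.segment_body(speckled)
        assert not body.voxels[2, 2, 2:7].any()

    def test_internal_cavity_is_filled(self, sphere_phantom):
        _, vol, _ = sphere_phantom
        hu = vol.voxels.copy()
        c = tuple(s // 2 for s in hu.shape)
        hu[c[0] - 3 : c[0] + 3, c[1] - 3 : c[1] + 3, c[2] - 3 : c[2] + 3] = -1000.0
        body = bc.segment_body(bc.CTVolume(hu, spacing=vol.spacing, origin=vol.origin))
        assert body.voxels[c]

    def test_component_touching_all_faces_rejected(self):
        vol = bc.CTVolume(np.full((8, 8, 8), 40.0), spacing=(1, 1, 1), origin=(0, 0, 0))
        with pytest.raises(SegmentationError, match="six grid faces"):
            bc.segment_body(vol)


class TestCapExtent:
    def test_plane_below_grid_gives_full_mask(self, sphere_masks):
        body, _, _ = sphere_masks
        extent = bc.make_cap_extent(body, bc.CapExtent(inferior_plane_mm=-1e6))
        assert extent.voxels.all()

    def test_plane_through_center_selects_upper_half(self, sphere_masks):
        body, _, _ = sphere_masks
        z = body.world_z()
        center_z = float(z[body.voxels].mean())
        extent = bc.make_cap_extent(body, bc.CapExtent(inferior_plane_mm=center_z))
        np.testing.assert_array_equal(extent.voxels, z >= center_z)
        # half of the grid voxels (upper slices), up to the center slice
        assert extent.count == pytest.approx(extent.voxels.size / 2, rel=0.05)

    def test_spherical_cap_volume_formula(self, sphere_masks):
        # plane 10 mm above center of the r = 25 mm sphere: V = pi h^2 (3r - h)/3
        body, _, _ = sphere_masks
        z = body.world_z()
        center_z = float(np.mean(z[body.voxels]))
        plane = center_z + 10.0
        extent = bc.make_cap_extent(body, bc.CapExtent(inferior_plane_mm=plane))
        cap_voxels = int((body.voxels & extent.voxels).sum())
        h = 25.0 - 10.0
        analytic = np.pi * h**2 * (3 * 25.0 - h) / 3.0
        assert cap_voxels * body.voxel_volume_mm3 == pytest.approx(analytic, rel=0.02)

    def test_plane_above_body_rejected(self, sphere_masks):
        body, _, _ = sphere_masks
        with pytest.raises(ShellError, match="empty"):
            bc.make_cap_extent(body, bc.CapExtent(inferior_plane_mm=1e6))


def brute_force_shell(body: bc.BinaryMask, t: float, extent: bc.BinaryMask):
    """Independent oracle: for every non-body voxel, test the distance
    condition against every body voxel (via an exhaustive nearest-neighbour
    query on voxel centers in mm)."""
    body_idx = np.argwhere(body.voxels).astype(float) * body.spacing
    out_idx = np.argwhere(~body.voxels)
    d, _ = cKDTree(body_idx).query(out_idx.astype(float) * body.spacing)
    shell = np.zeros(body.shape, dtype=bool)
    shell[tuple(out_idx.T)] = d <= t
    return shell & extent.voxels


class TestBuildShell:
    def test_flat_slab_unit_thickness_is_one_layer(self):
        vox = np.zeros((8, 6, 6), dtype=bool)
        vox[:3] = True  # slab occupying the three lowest slices
        body = bc.BinaryMask(vox, spacing=(1, 1, 1), origin=(0, 0, 0))
        extent = bc.BinaryMask(np.ones_like(vox), spacing=(1, 1, 1), origin=(0, 0, 0))
        shell = bc.build_bolus_shell(body, bc.BolusParams(thickness_mm=1.0), extent)
        expected = np.zeros_like(vox)
        expected[3] = True
        np.testing.assert_array_equal(shell.voxels, expected)

    def test_shell_disjoint_from_body(self, sphere_masks):
        body, _, shell = sphere_masks
        assert not (shell.voxels & body.voxels).any()

    def test_every_shell_voxel_within_thickness_of_body(self, sphere_masks):
        body, _, shell = sphere_masks
        body_pts = np.argwhere(body.voxels).astype(float) * body.spacing
        shell_pts = np.argwhere(shell.voxels).astype(float) * shell.spacing
        d, _ = cKDTree(body_pts).query(shell_pts)
        assert d.max() <= 5.0 + 1e-9
        assert d.min() > 0

    def test_matches_brute_force_oracle_on_small_grids(self):
        rng = np.random.default_rng(11)
        for trial, t in [(0, 2.2), (1, 3.6), (2, 1.4)]:
            vox = np.zeros((20, 18, 16), dtype=bool)
            # random blobby body: a few overlapping boxes
            for _ in range(4):
                lo = rng.integers(2, 8, size=3)
                hi = lo + rng.integers(3, 8, size=3)
                vox[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
            body = bc.BinaryMask(vox, spacing=(1, 1, 1), origin=(0, 0, 0))
            extent = bc.BinaryMask(np.ones_like(vox), spacing=(1, 1, 1),
                                   origin=(0, 0, 0))
            shell = bc.build_bolus_shell(body, bc.BolusParams(thickness_mm=t), extent)
            np.testing.assert_array_equal(
                shell.voxels, brute_force_shell(body, t, extent)
            )

    def test_thickness_below_voxel_size_rejected(self, sphere_masks):
        body, extent, _ = sphere_masks
        with pytest.raises(ShellError, match="smaller than one voxel"):
            bc.build_bolus_shell(body, bc.BolusParams(thickness_mm=0.4), extent)

    def test_nonpositive_thickness_rejected(self):
        with pytest.raises(ShellError):
            bc.BolusParams(thickness_mm=0.0)

    def test_empty_after_clipping_rejected(self, sphere_masks):
        body, _, _ = sphere_masks
        empty_extent = bc.BinaryMask.like(body, np.zeros(body.shape, dtype=bool))
        with pytest.raises(ShellError, match="empty"):
            bc.build_bolus_shell(body, bc.BolusParams(), empty_extent)

    @settings(max_examples=12, deadline=None, derandomize=True)
    @given(
        t1=st.floats(min_value=1.0, max_value=4.0),
        t2=st.floats(min_value=0.0, max_value=3.0),
    )
    def test_shell_volume_nondecreasing_in_thickness(self, t1, t2):
        vox = np.zeros((14, 14, 14), dtype=bool)
        vox[4:9, 4:10, 5:9] = True
        body = bc.BinaryMask(vox, spacing=(1, 1, 1), origin=(0, 0, 0))
        extent = bc.BinaryMask(np.ones_like(vox), spacing=(1, 1, 1), origin=(0, 0, 0))
        a = bc.build_bolus_shell(body, bc.BolusParams(thickness_mm=t1), extent)
        b = bc.build_bolus_shell(body, bc.BolusParams(thickness_mm=t1 + t2), extent)
        assert b.count >= a.count
        assert b.voxels[a.voxels].all()  # larger shell contains the smaller


class TestRimFeather:
    def test_feather_tapers_thickness_near_plane(self, sphere_masks):
        body, _, _ = sphere_masks
        z = body.world_z()
        center_z = float(np.mean(z[body.voxels]))
        cap = bc.CapExtent(inferior_plane_mm=center_z, edge_feather_mm=10.0)
        extent = bc.make_cap_extent(body, cap)
        params = bc.BolusParams(thickness_mm=5.0)
        shell = bc.build_bolus_shell(body, params, extent)
        feathered = bc.builder.apply_rim_feather(shell, body, cap, params)
        assert feathered.count < shell.count
        # untouched far above the feather band
        high = z >= center_z + 12.0
        np.testing.assert_array_equal(
            feathered.voxels & high, shell.voxels & high
        )
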