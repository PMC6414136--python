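"""End-to-end pipeline: CT in, printable STL + QA report out.

Stages: read -> resample to the working resolution -> segment the body ->
cap extent -> uniform-thickness shell -> QA (air gap, wall thickness) ->
marching-cubes mesh -> optional smoothing -> binary STL.  Each stage is
logged with its parameters; any stage error aborts with the stage name.
Identical configuration (and phantom seed) yields a byte-identical STL.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from pathlib import Path

import numpy as np
import yaml

from . import builder, meshing, qa
from .builder import BolusParams, CapExtent
from .errors import BolusCapError
from .grid import BinaryMask, CTVolume, load_volume, read_ct_series, resample_isotropic, save_volume

log = logging.getLogger("boluscap")


@dataclasses.dataclass
class RunConfig:
    """Declarative configuration of one bolus-cap build."""

    input_path: str
    inferior_plane_mm: float
    thickness_mm: float = 5.0
    body_threshold_hu: float = -400.0
    closing_radius_mm: float = 2.0
    edge_feather_mm: float = 0.0
    working_spacing_mm: float = 1.0
    smooth_iterations: int = 10
    smooth_max_deviation_mm: float = 0.5
    stl_out: str | None = None
    shell_mask_out: str | None = None
    body_mask_out: str | None = None
    qa_report_out: str | None = None

    @classmethod
    def from_yaml(cls, path: str | os.PathLike, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise BolusCapError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    @property
    def bolus_params(self) -> BolusParams:
        return BolusParams(
            thickness_mm=self.thickness_mm,
            body_threshold_hu=self.body_threshold_hu,
            closing_radius_mm=self.closing_radius_mm,
        )

    @property
    def cap_extent(self) -> CapExtent:
        return CapExtent(
            inferior_plane_mm=self.inferior_plane_mm,
            edge_feather_mm=self.edge_feather_mm,
        )


@dataclasses.dataclass
class PipelineResult:
    body: BinaryMask
    shell: BinaryMask
    extent: BinaryMask
    mesh: object
    gap: qa.GapMap
    thickness: qa.ThicknessMap


def load_ct(path: str | os.PathLike) -> CTVolume:
    """Load a CT from a DICOM series directory or an NPZ fixture container."""
    p = Path(path)
    if p.is_dir():
        return read_ct_series(p)
    vol = load_volume(p)
    if not isinstance(vol, CTVolume):
        raise BolusCapError(f"{p} holds a mask, not a CT volume")
    return vol


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full build; see module docstring for the stage order."""
    stage = "read"
    try:
        ct = load_ct(config.input_path)
        log.info("read: %s voxels, spacing %s mm", ct.shape, ct.spacing)

        stage = "resample"
        ct = resample_isotropic(ct, config.working_spacing_mm)
        log.info("resample: working grid %s at %g mm", ct.shape, config.working_spacing_mm)

        stage = "segment"
        params = config.bolus_params
        body = builder.segment_body(ct, params)
        log.info("segment: body %.1f cm^3 (threshold %g HU)",
                 body.volume_mm3 / 1000.0, params.body_threshold_hu)

        stage = "extent"
        cap = config.cap_extent
        extent = builder.make_cap_extent(body, cap)
        log.info("extent: inferior plane z = %g mm", cap.inferior_plane_mm)

        stage = "shell"
        shell = builder.build_bolus_shell(body, params, extent)
        shell = builder.apply_rim_feather(shell, body, cap, params)
        log.info("shell: %.1f cm^3 at t = %g mm", shell.volume_mm3 / 1000.0, params.thickness_mm)

        stage = "qa"
        gap = qa.air_gap_map(body, shell, extent)
        thickness = qa.thickness_map(shell, body, extent)
        log.info("qa: max gap %.2f mm, median thickness %.2f mm",
                 gap.max_mm, thickness.median_mm)

        stage = "mesh"
        mesh = meshing.mask_to_mesh(shell)
        if config.smooth_iterations > 0:
            mesh = meshing.smooth_mesh(
                mesh, config.smooth_iterations, config.smooth_max_deviation_mm
            )
        log.info("mesh: %d facets, %.1f cm^3 enclosed", len(mesh.faces), mesh.volume / 1000.0)

        stage = "write"
        if config.stl_out:
            meshing.write_stl(mesh, config.stl_out)
            log.info("write: STL -> %s", config.stl_out)
        if config.shell_mask_out:
            save_volume(shell, config.shell_mask_out)
        if config.body_mask_out:
            save_volume(body, config.body_mask_out)
        if config.qa_report_out:
            write_qa_report(config.qa_report_out, gap, thickness)
            log.info("write: QA report -> %s", config.qa_report_out)
    except BolusCapError as err:
        raise BolusCapError(f"stage '{stage}' failed: {err}") from err

    return PipelineResult(body=body, shell=shell, extent=extent,
                          mesh=mesh, gap=gap, thickness=thickness)


def write_qa_report(path: str | os.PathLike, gap: qa.GapMap,
                    thickness: qa.ThicknessMap) -> None:
    """Delimited-text QA summary (metric, value_mm)."""
    rows = [
        ("air_gap_max_mm", gap.max_mm),
        ("air_gap_mean_mm", gap.mean_mm),
        ("air_gap_p95_mm", gap.p95_mm),
        ("thickness_median_mm", thickness.median_mm),
        ("thickness_min_mm", thickness.min_mm),
        ("thickness_max_mm", thickness.max_mm),
    ]
    with open(path, "w") as fh:
        fh.write("metric\tvalue\n")
        for name, value in rows:
            fh.write(f"{name}\t{value:.4f}\n")


def voxelize_stl(path: str | os.PathLike, like: BinaryMask | CTVolume) -> BinaryMask:
    """Voxelize an STL surface onto an existing grid (for QA of a scanned or
    externally produced bolus): a voxel is set when its center lies inside
    the closed surface."""
    mesh = meshing.read_stl(path)
    shape = like.shape
    kk, jj, ii = np.meshgrid(
        np.arange(shape[0]), np.arange(shape[1]), np.arange(shape[2]), indexing="ij"
    )
    idx = np.column_stack([kk.ravel(), jj.ravel(), ii.ravel()]).astype(float)
    points = like.world_coordinates(idx)
    inside = mesh.contains(points).reshape(shape)
    return BinaryMask.like(like, inside)
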