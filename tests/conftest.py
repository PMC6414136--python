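"""Shared fixtures: small synthetic phantoms and a DICOM series writer."""

from __future__ import annotations

import numpy as np
import pydicom
import pytest
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

import boluscap as bc


@pytest.fixture(scope="session")
def sphere_phantom():
    """Noise-free spherical head, r = 25 mm, 1 mm isotropic."""
    spec = bc.PhantomSpec(
        head_radii=(25.0, 25.0, 25.0), noise_sd_hu=0.0,
        spacing=(1.0, 1.0, 1.0), margin_mm=12.0,
    )
    volume, surface = bc.generate_head_phantom(spec)
    return spec, volume, surface


@pytest.fixture(scope="session")
def sphere_masks(sphere_phantom):
    """Body, full extent, and 5 mm shell for the r = 25 mm sphere."""
    _, volume, _ = sphere_phantom
    params = bc.BolusParams(thickness_mm=5.0)
    body = bc.segment_body(volume, params)
    extent = bc.make_cap_extent(body, bc.CapExtent(inferior_plane_mm=-1e6))
    shell = bc.build_bolus_shell(body, params, extent)
    return body, extent, shell


def write_ct_series(
    directory,
    hu: np.ndarray,
    spacing=(2.0, 1.0, 1.0),
    origin=(0.0, 0.0, 0.0),
    slope: float = 1.0,
    intercept: float = -1024.0,
    series_uid: str | None = None,
    skip_slices: tuple[int, ...] = (),
):
    """Write an axial CT DICOM series encoding the given HU grid."""
    series_uid = series_uid or generate_uid()
    stored = np.rint((np.asarray(hu, dtype=np.float64) - intercept) / slope)
    stored = stored.astype(np.uint16)
    nz = hu.shape[0]
    for k in range(nz):
        if k in skip_slices:
            continue
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.Modality = "CT"
        ds.SeriesInstanceUID = series_uid
        ds.InstanceNumber = k + 1
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.ImagePositionPatient = [
            float(origin[0]), float(origin[1]), float(origin[2] + k * spacing[0]),
        ]
        ds.SliceThickness = float(spacing[0])
        ds.PixelSpacing = [float(spacing[1]), float(spacing[2])]
        ds.Rows, ds.Columns = hu.shape[1], hu.shape[2]
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleSlope = slope
        ds.RescaleIntercept = intercept
        ds.PixelData = stored[k].tobytes()
        ds.save_as(directory / f"slice_{k:03d}.dcm", enforce_file_format=True)
    return series_uid


@pytest.fixture()
def dicom_series_dir(tmp_path):
    """A 10-slice synthetic CT series plus the HU grid it encodes."""
    rng = np.random.default_rng(7)
    hu = rng.integers(-1000, 2000, size=(10, 16, 12)).astype(np.float32)
    directory = tmp_path / "series"
    directory.mkdir()
    write_ct_series(directory, hu, spacing=(2.5, 0.8, 0.7), origin=(-5.0, 3.0, 10.0))
    return directory, hu
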