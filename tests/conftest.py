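"""Shared fixtures: small phantoms and programmatically built DICOM objects."""

from __future__ import annotations

import numpy as np
import pytest

from cbctalert import CourseSpec, GammaCriteria, PhantomSpec


@pytest.fixture
def small_phantom() -> PhantomSpec:
    """A 32-cube phantom cheap enough for per-test pipelines."""
    return PhantomSpec(
        shape=(32, 32, 32),
        spacing=(4.0, 4.0, 4.0),
        body_half_axes_mm=(40.0, 34.0, 38.0),
        structures=(
            {"half_axes": (34.0, 8.0, 8.0), "center_offset": (0.0, 16.0, 0.0), "hu": 700.0},
        ),
    )


@pytest.fixture
def quiet_phantom(small_phantom: PhantomSpec) -> PhantomSpec:
    """Noise-free variant for deterministic geometry checks."""
    from dataclasses import replace

    return replace(small_phantom, noise_sigma=0.0)


@pytest.fixture
def criteria() -> GammaCriteria:
    return GammaCriteria()


def make_ct_slice(z_mm: float, pixels: np.ndarray, spacing=(2.0, 2.0)):
    """Build one axial CT slice dataset entirely in memory."""
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = CTImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = CTImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "CT"
    ds.Rows, ds.Columns = pixels.shape
    ds.PixelSpacing = [spacing[0], spacing[1]]
    ds.ImagePositionPatient = [0.0, 0.0, z_mm]
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 1
    ds.RescaleSlope = 1.0
    ds.RescaleIntercept = -1000.0
    ds.PixelData = np.ascontiguousarray(pixels.astype(np.int16)).tobytes()
    return ds


@pytest.fixture
def dicom_series_dir(tmp_path):
    """Write a tiny 4-slice CT series; HU = stored - 1000."""
    rng = np.random.default_rng(7)
    stored = rng.integers(0, 2000, size=(4, 8, 8))
    d = tmp_path / "ct"
    d.mkdir()
    for k in range(4):
        ds = make_ct_slice(z_mm=10.0 + 3.0 * k, pixels=stored[k])
        ds.save_as(d / f"slice{k}.dcm", enforce_file_format=True)
    return d, stored.astype(float) - 1000.0
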