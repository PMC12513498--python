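"""Shared fixtures: small phantoms and synthetic DICOM series."""

from __future__ import annotations

import numpy as np
import pytest

from aafai import PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Deterministic phantom with zero noise and zero fat-HU spread."""
    spec = PhantomSpec(
        noise_sd=0.0,
        fat_hu_sd=0.0,
        fat_hu_mean=-80.0,
        grid_shape=(96, 96, 4),
        spacing=(0.7, 0.7, 5.0),
        lumen_radius=12.0,
        seed=11,
    )
    return spec, *make_phantom(spec)


def write_dicom_series(path, stored, spacing=(1.0, 1.0, 5.0), slopes=None, intercepts=None,
                       positions=None, series_uid="1.2.3.4", filenames=None):
    """Write a minimal CT DICOM series from a (rows, cols, slices) uint16 array."""
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    rows, cols, nslices = stored.shape
    slopes = slopes if slopes is not None else [1.0] * nslices
    intercepts = intercepts if intercepts is not None else [-1024.0] * nslices
    positions = positions if positions is not None else [k * spacing[2] for k in range(nslices)]
    filenames = filenames or [f"slice_{k:03d}.dcm" for k in range(nslices)]

    for k in range(nslices):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(filenames[k], {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = pydicom.uid.CTImageStorage
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.Modality = "CT"
        ds.InstanceNumber = k + 1
        ds.ImagePositionPatient = [0.0, 0.0, positions[k]]
        ds.PixelSpacing = [spacing[0], spacing[1]]
        ds.SliceThickness = spacing[2]
        if slopes[k] is not None:
            ds.RescaleSlope = slopes[k]
            ds.RescaleIntercept = intercepts[k]
        ds.Rows, ds.Columns = rows, cols
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.PixelData = np.ascontiguousarray(stored[:, :, k], dtype=np.uint16).tobytes()
        ds.save_as(path / filenames[k], enforce_file_format=True)
    return path
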