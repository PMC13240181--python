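import numpy as np
import pytest

from wetspr import (
    calibrate_from_sweep,
    phantom_sweep,
)

SWEEP_DIAMETERS = (75, 100, 125, 150, 175, 200, 225, 250, 275, 300, 325, 350, 375, 400)
SEED = 1
METHODS = ("tem-a", "tem-b1", "tem-b2")


@pytest.fixture(scope="session")
def default_sweep():
    """Zero-noise cylinder sweep with the default hardening model."""
    return phantom_sweep(SWEEP_DIAMETERS, seed=SEED)


@pytest.fixture(scope="session")
def default_curves(default_sweep):
    return {m: calibrate_from_sweep(default_sweep, m) for m in METHODS}


def write_ct_dicom(path, hu, spacing=(1.0, 1.0), z=0.0, instance=1, slope=1.0, intercept=-1024.0,
                   drop_rescale=False):
    """Write a minimal single-frame CT DICOM file with the given HU pixels."""
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

    stored = np.round((np.asarray(hu, dtype=np.float64) - intercept) / slope).astype("<i2")
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = CTImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = CTImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "CT"
    ds.InstanceNumber = instance
    ds.ImagePositionPatient = [0.0, 0.0, float(z)]
    ds.Rows, ds.Columns = stored.shape
    ds.PixelSpacing = [spacing[1], spacing[0]]  # DICOM order: (row, col)
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 1
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    if not drop_rescale:
        ds.RescaleSlope = slope
        ds.RescaleIntercept = intercept
    ds.PixelData = stored.tobytes()
    ds.save_as(path, enforce_file_format=True)
    return path
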