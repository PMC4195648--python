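import warnings

import numpy as np
import pytest

from adipoquant import PhantomSpec, make_phantom


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="divide by zero")
        yield


@pytest.fixture(scope="session")
def default_phantom():
    """One default phantom volume with ground truth (seed 0)."""
    return make_phantom(PhantomSpec(seed=0))


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise- and bias-free phantom: intensities equal tissue means."""
    return make_phantom(PhantomSpec(seed=0, noise_sigma=0.0, bias_amplitude=0.0))


def circle_sdf(shape, center, radius):
    """Analytic signed distance of a circle (negative inside)."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    return np.hypot(yy - center[0], xx - center[1]) - radius


def write_dicom_slice(path, pixels, position_z, instance, spacing=(0.2, 0.2),
                      thickness=1.6):
    """Write one minimal MR DICOM slice for read tests."""
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    ds = Dataset()
    ds.file_meta = FileMetaDataset()
    ds.file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds.file_meta.MediaStorageSOPClassUID = pydicom.uid.MRImageStorage
    ds.file_meta.MediaStorageSOPInstanceUID = generate_uid()
    ds.SOPClassUID = pydicom.uid.MRImageStorage
    ds.SOPInstanceUID = ds.file_meta.MediaStorageSOPInstanceUID
    ds.Modality = "MR"
    arr = np.asarray(pixels)
    ds.Rows, ds.Columns = arr.shape
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.PixelSpacing = [spacing[0], spacing[1]]
    ds.SliceThickness = thickness
    ds.ImagePositionPatient = [0.0, 0.0, position_z]
    ds.InstanceNumber = instance
    ds.PixelData = arr.astype(np.uint16).tobytes()
    ds.save_as(str(path), enforce_file_format=True)
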