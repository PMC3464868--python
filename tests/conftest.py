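import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

import cinestrain as cs


@pytest.fixture(scope="session")
def ring_phantom():
    """Default short-axis ring phantom, 20% true strain, moderate noise."""
    return cs.make_phantom(
        cs.PhantomSpec(geometry="short_axis_ring", true_peak_strain_percent=20.0,
                       noise_sd=0.05, seed=11)
    )


@pytest.fixture(scope="session")
def u_phantom():
    """Default four-chamber U phantom, 20% true strain, moderate noise."""
    return cs.make_phantom(
        cs.PhantomSpec(geometry="four_chamber_u", true_peak_strain_percent=20.0,
                       noise_sd=0.05, seed=12)
    )


@pytest.fixture(scope="session")
def validation_summary():
    """The default 20-phantom validation suite (both geometries, strains
    10-25%, noise 0-0.1), shared across tests that assess tracker accuracy
    and method agreement."""
    return cs.run_validate(cs.ValidateConfig(seed=7))


@pytest.fixture(scope="session")
def textured_image():
    """Smooth random texture with enough contrast for template matching."""
    rng = np.random.default_rng(42)
    return gaussian_filter(rng.random((80, 80)), 2.0) * 2.0


def make_dicom_frame(path, pixel_array, *, trigger_time=None, instance_number=None,
                     pixel_spacing=(1.0, 1.0), position=(0.0, 0.0, 0.0),
                     frame_time=None):
    """Write one minimal single-frame MR DICOM file (test helper)."""
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, MRImageStorage, generate_uid

    arr = np.asarray(pixel_array, dtype=np.uint16)
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = MRImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = MRImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "MR"
    ds.Rows, ds.Columns = arr.shape
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.PixelSpacing = [str(pixel_spacing[0]), str(pixel_spacing[1])]
    ds.ImagePositionPatient = [str(v) for v in position]
    if trigger_time is not None:
        ds.TriggerTime = str(trigger_time)
    if instance_number is not None:
        ds.InstanceNumber = instance_number
    if frame_time is not None:
        ds.FrameTime = str(frame_time)
    ds.PixelData = arr.tobytes()
    ds.save_as(path, enforce_file_format=True)
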