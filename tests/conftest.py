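import numpy as np
import pytest

from cacalib import (
    ArteryMask,
    CTVolume,
    Protocol,
    default_transfer_model,
    identity_transfer_model,
)


@pytest.fixture
def noiseless_transfer():
    """Default cubic spectral transfer with both protocol noises at zero."""
    return default_transfer_model(noise_sd_csct=0.0, noise_sd_ldct=0.0)


@pytest.fixture
def identity_transfer():
    return identity_transfer_model()


@pytest.fixture
def unit_volume_factory():
    """Build a small CTVolume from an array with 1x1 mm pixels, 3 mm slices."""

    def _make(arr, pixel_spacing=(1.0, 1.0), slice_thickness=3.0,
              protocol=Protocol.CSCT):
        arr = np.asarray(arr, dtype=float)
        if arr.ndim == 2:
            arr = arr[None]
        return CTVolume(
            voxels=arr,
            pixel_spacing=pixel_spacing,
            slice_thickness=slice_thickness,
            protocol=protocol,
        )

    return _make


@pytest.fixture
def full_mask_factory():
    """Mask assigning every voxel to one artery label."""

    def _make(shape, label=1):
        return ArteryMask(labels=np.full(shape, label, dtype=np.int16))

    return _make
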