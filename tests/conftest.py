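import numpy as np
import pytest

from flockvision import (
    CameraGeometry,
    FrameRecord,
    FrameSequence,
    SegmentationParams,
)


@pytest.fixture
def unit_geometry():
    """H=10 cm, α=90°, 20-px sensor → k = 1 cm/px exactly."""
    return CameraGeometry(mount_height_cm=10, lens_angle_deg=90, sensor_length_px=20)


@pytest.fixture
def default_params():
    return SegmentationParams()


@pytest.fixture
def fixed_params():
    """Fixed-threshold params for fully controlled fixtures."""
    return SegmentationParams(
        lowpass_sigma=0.0,
        threshold_method="fixed",
        fixed_threshold=100.0,
        min_blob_area_px=0,
    )


def make_frame(pixels, index=0, fps=1.0):
    return FrameRecord(
        index=index,
        timestamp_s=index / fps,
        pixels=np.asarray(pixels, dtype=np.uint8),
    )


def make_sequence(pixel_list, fps=1.0):
    return FrameSequence(
        frames=[make_frame(p, i, fps) for i, p in enumerate(pixel_list)],
        sample_rate_fps=fps,
    )


def disk_mask(shape, center, radius):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


@pytest.fixture
def two_squares_mask():
    """Two 10×10 filled squares whose centroids are exactly 60 px apart."""
    mask = np.zeros((50, 120), dtype=bool)
    mask[16:26, 16:26] = True  # centroid (20.5, 20.5)
    mask[16:26, 76:86] = True  # centroid (20.5, 80.5)
    return mask
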