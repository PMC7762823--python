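import numpy as np
import pytest

from sheetctl import AcquisitionConfig, CalibrationState, MaskSpec, PathConfig


@pytest.fixture
def calib():
    """Default calibration: 0.01 V/um X scale, 40 mV/um piezo and Z scales."""
    return CalibrationState()


@pytest.fixture
def paper_cfg():
    """The reference recording: 98 Hz, 50 planes at 2 um, 10 flyback frames."""
    return AcquisitionConfig()


@pytest.fixture
def small_cfg():
    """A light configuration for fast per-sample audits."""
    return AcquisitionConfig(n_planes=5, flyback_frames=2, n_volumes=2,
                             sample_rate_hz=9800, plane_rate_hz=98)


@pytest.fixture
def dual_cfg():
    return AcquisitionConfig(
        paths=(PathConfig(path_id=1, sheet_width_um=500.0),
               PathConfig(path_id=2, sheet_width_um=300.0)))


@pytest.fixture
def edge_mask():
    return MaskSpec(edge_enabled=True, edge_fraction=0.1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
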