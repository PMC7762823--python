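"""Acquisition planning arithmetic and optics calculators.

Pure, deterministic helpers for designing a scanned light-sheet recording:
volume rate from plane rate and flyback budget, camera data throughput and
storage splitting, pixel footprint at the sample, beam expansion, Gaussian
beam Rayleigh range, and the analogue-output channel budget of the DAC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .calibration import pixel_size_from_optics
from .config import AcquisitionConfig

__all__ = [
    "CameraSpec",
    "OpticsSpec",
    "volume_rate",
    "frame_period",
    "data_throughput",
    "pixel_footprint",
    "beam_expansion",
    "rayleigh_range",
    "channel_budget",
    "storage_plan",
    "SATA3_LIMIT_MB_S",
]

#: theoretical maximum of a SATA3 storage interface, MB/s (decimal MB)
SATA3_LIMIT_MB_S = 600.0


@dataclass(frozen=True)
class CameraSpec:
    """Scientific camera: a 4-megapixel sCMOS is 2048 x 2048."""

    n_pixels_x: int = 2048
    n_pixels_y: int = 2048
    bit_depth: int = 16
    max_rate_hz: float = 100.0
    sensor_side_mm: float = 13.0

    def __post_init__(self):
        if min(self.n_pixels_x, self.n_pixels_y) <= 0 or self.max_rate_hz <= 0:
            raise ValueError("pixel counts and rate must be > 0")
        if self.bit_depth not in (8, 12, 16):
            raise ValueError("bit_depth must be 8, 12 or 16")

    @property
    def bytes_per_frame(self) -> int:
        return self.n_pixels_x * self.n_pixels_y * self.bit_depth // 8


@dataclass(frozen=True)
class OpticsSpec:
    """Illumination/collection optics summary."""

    expander_f1_mm: float = 50.0
    expander_f2_mm: float = 125.0
    magnification: float = 16.0
    wavelength_nm: float = 488.0
    waist_um: float = 7.0


def volume_rate(plane_rate_hz: float, n_planes: int,
                flyback_frames: int = 0) -> float:
    """Volumes per second: plane_rate / (n_planes + flyback_frames).

    Flyback frames are sacrificed to let the piezo return gently, e.g.
    98 Hz with 50 planes plus a 10-frame flyback yields 1.6 volumes/s.
    """
    if plane_rate_hz <= 0 or n_planes <= 0 or flyback_frames < 0:
        raise ValueError("rates and counts must be positive (flyback >= 0)")
    return plane_rate_hz / (n_planes + flyback_frames)


def frame_period(plane_rate_hz: float) -> float:
    """Integration time per section in ms: 98 Hz -> 10.2 ms."""
    if plane_rate_hz <= 0:
        raise ValueError("plane rate must be > 0")
    return 1000.0 / plane_rate_hz


def data_throughput(camera: CameraSpec, rate_hz: float | None = None) -> float:
    """Sustained camera data rate in MB/s (decimal: 1 MB = 10^6 bytes).

    A 4-megapixel 16-bit camera at 100 Hz produces 838.9 MB/s — beyond the
    600 MB/s SATA3 limit, hence the recommendation for PCIe SSD storage.
    """
    if rate_hz is None:
        rate_hz = camera.max_rate_hz
    return camera.bytes_per_frame * rate_hz / 1e6


def exceeds_sata3(throughput_mb_s: float) -> bool:
    return throughput_mb_s > SATA3_LIMIT_MB_S


def pixel_footprint(camera: CameraSpec, magnification: float) -> tuple[float, float]:
    """(μm per pixel, μm² per pixel) at the sample plane."""
    size = pixel_size_from_optics(camera.sensor_side_mm, camera.n_pixels_x,
                                  magnification)
    return size, size * size


def beam_expansion(f1_mm: float, f2_mm: float) -> float:
    """Magnification of a two-lens beam expander: f2 / f1."""
    if f1_mm <= 0 or f2_mm <= 0:
        raise ValueError("focal lengths must be > 0")
    return f2_mm / f1_mm


def rayleigh_range(waist_radius_um: float, wavelength_nm: float) -> float:
    """Gaussian-beam Rayleigh range z_R = pi w0^2 / lambda, in μm.

    This is the standard formula; see the methods note for the mismatch
    between it and some published sheet-uniformity figures under obvious
    waist conventions.
    """
    if waist_radius_um <= 0 or wavelength_nm <= 0:
        raise ValueError("waist and wavelength must be > 0")
    return math.pi * waist_radius_um**2 / (wavelength_nm / 1000.0)


def channel_budget(cfg: AcquisitionConfig, shutter_modulated: bool = True) -> int:
    """Analogue DAC outputs required by a configuration.

    Per enabled path: X mirror, Z mirror and (if the laser is modulated) a
    shutter line; shared: the objective piezo and the camera trigger.  A
    full dual-path system needs 8 outputs; a single path needs 5; a single
    path with an unmodulated laser gets by on 4 with minimal functionality.
    """
    n_paths = len(cfg.enabled_paths)
    per_path = 3 if shutter_modulated else 2
    return n_paths * per_path + 2  # + piezo + camera trigger


def storage_plan(camera: CameraSpec, rate_hz: float, duration_s: float,
                 file_limit_bytes: float = 4e9) -> tuple[float, int]:
    """(total bytes, number of files) when splitting at a per-file limit.

    The default limit is 4 GB (decimal); 2**32 is the documented option for
    the classic TIFF limit.  A recording exactly at the limit fits one file.
    """
    if duration_s <= 0:
        raise ValueError("duration must be > 0")
    total = data_throughput(camera, rate_hz) * 1e6 * duration_s
    n_files = max(1, math.ceil(total / file_limit_bytes))
    return total, n_files
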