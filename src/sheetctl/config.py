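"""Acquisition configuration for scanned light-sheet volume recordings.

The configuration mirrors the knobs a light-sheet operator sets before an
acquisition: sheet geometry (width, planes, spacing), timing (plane rate,
scans per frame, flyback), the volume scan mode, laser masks, and one or two
independently calibrated illumination paths.  All physical quantities are in
micrometres, seconds and hertz; command signals are in volts.
"""

from __future__ import annotations

import enum
import tomllib
from dataclasses import dataclass, field, replace

from .errors import ConfigurationError

__all__ = [
    "ScanMode",
    "PathConfig",
    "MaskSpec",
    "SessionPlan",
    "AcquisitionConfig",
    "load_config",
]


class ScanMode(str, enum.Enum):
    """Volume acquisition ordering.

    ``scan_down`` acquires planes top-to-bottom and returns to the top during
    a flyback period; ``scan_up`` is its mirror image; ``bidirectional``
    alternates down/up volumes so that no flyback is needed at all.
    """

    SCAN_DOWN = "scan_down"
    SCAN_UP = "scan_up"
    BIDIRECTIONAL = "bidirectional"


@dataclass(frozen=True)
class PathConfig:
    """One illumination path (laser + X/Z mirror pair + shutter)."""

    path_id: int = 1
    sheet_width_um: float = 500.0
    enabled: bool = True

    def __post_init__(self):
        if self.path_id not in (1, 2):
            raise ConfigurationError(f"path_id must be 1 or 2, got {self.path_id}")
        if self.sheet_width_um < 0:
            raise ConfigurationError("sheet_width_um must be >= 0")


@dataclass(frozen=True)
class MaskSpec:
    """Software laser-blanking masks applied through the fast shutter.

    ``edge_fraction`` removes that fraction of the sheet at *each* end
    (cutting over-illumination where the mirror reverses direction);
    the eye mask blanks a chosen interior region, e.g. over the eye of a
    larval zebrafish; ``blank_return`` closes the shutter for every
    flyback/return sample.
    """

    edge_enabled: bool = False
    edge_fraction: float = 0.0
    eye_enabled: bool = False
    eye_center_um: float = 0.0
    eye_halfwidth_um: float = 0.0
    blank_return: bool = False

    def __post_init__(self):
        if not 0.0 <= self.edge_fraction < 0.5:
            raise ConfigurationError(
                f"edge_fraction must lie in [0, 0.5), got {self.edge_fraction}"
            )
        if self.eye_halfwidth_um < 0:
            raise ConfigurationError("eye_halfwidth_um must be >= 0")

    def validate_against_width(self, sheet_width_um: float) -> None:
        """The eye region must lie within the commanded sheet extent."""
        if not self.eye_enabled:
            return
        half = sheet_width_um / 2.0
        lo = self.eye_center_um - self.eye_halfwidth_um
        hi = self.eye_center_um + self.eye_halfwidth_um
        if lo < -half or hi > half:
            raise ConfigurationError(
                f"eye mask [{lo:g}, {hi:g}] um exceeds the sheet extent "
                f"[-{half:g}, {half:g}] um"
            )


@dataclass(frozen=True)
class SessionPlan:
    """Multi-recording session with optional light adaptation.

    Light adaptation parks the sheet near the top of the sample (shutter
    open, camera idle) before and between recordings so the animal never
    experiences a sudden light change.
    """

    n_recordings: int = 1
    adaptation_enabled: bool = False
    adaptation_depth_um: float = 0.0
    adaptation_duration_s: float = 0.5
    inter_recording_gap_s: float = 0.0

    def __post_init__(self):
        if self.n_recordings < 1:
            raise ConfigurationError("n_recordings must be >= 1")
        if self.adaptation_duration_s < 0 or self.inter_recording_gap_s < 0:
            raise ConfigurationError("session durations must be >= 0")


@dataclass(frozen=True)
class AcquisitionConfig:
    """Complete parameter set defining one volumetric recording."""

    sheet_width_um: float = 500.0
    n_planes: int = 50
    z_spacing_um: float = 2.0
    plane_rate_hz: float = 98.0
    scans_per_frame: int = 3
    scan_mode: ScanMode = ScanMode.SCAN_DOWN
    flyback_frames: int = 10
    n_volumes: int = 1
    masks: MaskSpec = field(default_factory=MaskSpec)
    paths: tuple[PathConfig, ...] = (PathConfig(),)
    sample_rate_hz: float = 98_000.0
    voltage_range_v: float = 10.0

    def __post_init__(self):
        if self.n_planes < 1:
            raise ConfigurationError("n_planes must be >= 1")
        if self.plane_rate_hz <= 0:
            raise ConfigurationError("plane_rate_hz must be > 0")
        if self.sample_rate_hz < 100 * self.plane_rate_hz:
            raise ConfigurationError(
                "sample_rate_hz must be at least 100x plane_rate_hz "
                f"({self.sample_rate_hz:g} < 100 x {self.plane_rate_hz:g})"
            )
        if self.scans_per_frame < 1:
            raise ConfigurationError("scans_per_frame must be >= 1")
        if self.flyback_frames < 0:
            raise ConfigurationError("flyback_frames must be >= 0")
        if self.z_spacing_um < 0:
            raise ConfigurationError("z_spacing_um must be >= 0")
        if self.n_volumes < 1:
            raise ConfigurationError("n_volumes must be >= 1")
        if not 1 <= len(self.paths) <= 2:
            raise ConfigurationError("between 1 and 2 paths required")
        if len({p.path_id for p in self.paths}) != len(self.paths):
            raise ConfigurationError("path_id values must be distinct")
        if self.voltage_range_v <= 0:
            raise ConfigurationError("voltage_range_v must be > 0")
        for p in self.paths:
            self.masks.validate_against_width(p.sheet_width_um)

    @property
    def enabled_paths(self) -> tuple[PathConfig, ...]:
        return tuple(p for p in self.paths if p.enabled)

    @property
    def dual_path(self) -> bool:
        return len(self.enabled_paths) == 2

    @property
    def volume_depth_um(self) -> float:
        """Depth of the deepest plane below the top of the volume."""
        return (self.n_planes - 1) * self.z_spacing_um

    def with_mode(self, mode: ScanMode | str) -> "AcquisitionConfig":
        return replace(self, scan_mode=ScanMode(mode))


def _mask_from_dict(d: dict) -> MaskSpec:
    return MaskSpec(
        edge_enabled=bool(d.get("edge_enabled", d.get("edge_fraction", 0) > 0)),
        edge_fraction=float(d.get("edge_fraction", 0.0)),
        eye_enabled=bool(d.get("eye_enabled", False)),
        eye_center_um=float(d.get("eye_center_um", 0.0)),
        eye_halfwidth_um=float(d.get("eye_halfwidth_um", 0.0)),
        blank_return=bool(d.get("blank_return", False)),
    )


def config_from_dict(data: dict) -> AcquisitionConfig:
    """Build an :class:`AcquisitionConfig` from a flat key-value mapping."""
    masks = _mask_from_dict(data.get("masks", {}))
    raw_paths = data.get("paths") or [{"path_id": 1}]
    default_width = float(data.get("sheet_width_um", 500.0))
    paths = tuple(
        PathConfig(
            path_id=int(p.get("path_id", i + 1)),
            sheet_width_um=float(p.get("sheet_width_um", default_width)),
            enabled=bool(p.get("enabled", True)),
        )
        for i, p in enumerate(raw_paths)
    )
    return AcquisitionConfig(
        sheet_width_um=default_width,
        n_planes=int(data.get("n_planes", 50)),
        z_spacing_um=float(data.get("z_spacing_um", 2.0)),
        plane_rate_hz=float(data.get("plane_rate_hz", 98.0)),
        scans_per_frame=int(data.get("scans_per_frame", 3)),
        scan_mode=ScanMode(data.get("scan_mode", "scan_down")),
        flyback_frames=int(data.get("flyback_frames", 10)),
        n_volumes=int(data.get("n_volumes", 1)),
        masks=masks,
        paths=paths,
        sample_rate_hz=float(data.get("sample_rate_hz", 98_000.0)),
        voltage_range_v=float(data.get("voltage_range_v", 10.0)),
    )


def session_from_dict(data: dict) -> SessionPlan:
    return SessionPlan(
        n_recordings=int(data.get("n_recordings", 1)),
        adaptation_enabled=bool(data.get("adaptation_enabled", False)),
        adaptation_depth_um=float(data.get("adaptation_depth_um", 0.0)),
        adaptation_duration_s=float(data.get("adaptation_duration_s", 0.5)),
        inter_recording_gap_s=float(data.get("inter_recording_gap_s", 0.0)),
    )


def load_config(path) -> tuple[AcquisitionConfig, SessionPlan]:
    """Read a TOML acquisition-configuration file.

    Top-level keys mirror :class:`AcquisitionConfig` field names; ``[masks]``
    and ``[session]`` tables mirror :class:`MaskSpec` and
    :class:`SessionPlan`; ``[[paths]]`` array tables define the paths.
    """
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    return config_from_dict(data), session_from_dict(data.get("session", {}))
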