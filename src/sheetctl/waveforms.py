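"""Synchronized command-signal synthesis for scanned light-sheet volumes.

One volumetric recording is a block of per-sample command signals on a
common timebase: a camera trigger (one rising edge per plane), a fast
triangle sweep on each X mirror that paints the sheet, staircase commands on
the Z mirror(s) and the objective piezo that step the sheet/focal plane
through the volume, and a software shutter per path implementing the laser
masks.  Volumes can be acquired top-to-bottom (with a slowed flyback return
that spares the piezo from ringing), bottom-to-top, or bidirectionally
(alternating, which needs no flyback at all).

Phase labels partition every sample of the timeline: plane index >= 0,
``FLYBACK`` (-1), ``ADAPTATION`` (-2, sheet parked for light adaptation) and
``IDLE`` (-3, inter-recording gap with the laser blanked).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.signal import sawtooth

from .calibration import CalibrationState
from .config import AcquisitionConfig, MaskSpec, PathConfig, ScanMode, SessionPlan
from .errors import ConfigurationError, RangeError

__all__ = [
    "FLYBACK",
    "ADAPTATION",
    "IDLE",
    "TimeBase",
    "DepthTrajectory",
    "WaveformSet",
    "make_timebase",
    "build_camera_trigger",
    "build_x_sweep",
    "build_depth_trajectory",
    "depth_to_commands",
    "build_shutter",
    "assemble_waveforms",
    "rising_edges",
]

FLYBACK = -1
ADAPTATION = -2
IDLE = -3


@dataclass(frozen=True)
class TimeBase:
    """Sample grid shared by every channel of a recording."""

    sample_rate_hz: float
    samples_per_frame: int
    frames_per_volume: int
    n_volumes: int
    plane_rate_hz: float          # actual rate after integer-sample adjustment
    requested_plane_rate_hz: float

    @property
    def sample_period_s(self) -> float:
        return 1.0 / self.sample_rate_hz

    @property
    def samples_per_volume(self) -> int:
        return self.frames_per_volume * self.samples_per_frame

    @property
    def total_samples(self) -> int:
        return self.samples_per_volume * self.n_volumes

    @property
    def frame_period_ms(self) -> float:
        return 1000.0 / self.plane_rate_hz

    @property
    def rate_was_adjusted(self) -> bool:
        return not np.isclose(self.plane_rate_hz, self.requested_plane_rate_hz,
                              rtol=1e-12)


@dataclass(frozen=True)
class DepthTrajectory:
    """Per-sample target sheet depth (μm) and phase label."""

    depth_um: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        if self.depth_um.shape != self.labels.shape:
            raise ConfigurationError("depth and labels must be equal length")

    @property
    def plane_mask(self) -> np.ndarray:
        return self.labels >= 0

    @property
    def flyback_mask(self) -> np.ndarray:
        return self.labels == FLYBACK


def make_timebase(cfg: AcquisitionConfig) -> TimeBase:
    """Lay out the sample grid so frame boundaries land on sample indices.

    The plane rate is adjusted to the nearest value giving an integer number
    of samples per frame (``TimeBase.rate_was_adjusted`` reports whether a
    change occurred).  Bidirectional mode needs no flyback, so any configured
    flyback frames are excluded from the volume length.
    """
    spf = int(round(cfg.sample_rate_hz / cfg.plane_rate_hz))
    if spf < 100:
        raise ConfigurationError(
            "sample_rate too low: need >= 100 samples per frame, got "
            f"{spf} at plane_rate {cfg.plane_rate_hz:g} Hz"
        )
    flyback = 0 if cfg.scan_mode is ScanMode.BIDIRECTIONAL else cfg.flyback_frames
    return TimeBase(
        sample_rate_hz=cfg.sample_rate_hz,
        samples_per_frame=spf,
        frames_per_volume=cfg.n_planes + flyback,
        n_volumes=cfg.n_volumes,
        plane_rate_hz=cfg.sample_rate_hz / spf,
        requested_plane_rate_hz=cfg.plane_rate_hz,
    )


def build_depth_trajectory(tb: TimeBase, cfg: AcquisitionConfig) -> DepthTrajectory:
    """Per-sample sheet depth for the configured scan mode.

    Plane labels use depth indexing (label i <=> depth i * z_spacing)
    regardless of acquisition order, so scan-up volumes carry descending
    labels.  Flyback is a linear ramp back to the starting depth spread over
    the configured flyback frames.
    """
    if cfg.scan_mode is ScanMode.BIDIRECTIONAL and cfg.flyback_frames > 0:
        warnings.warn(
            "bidirectional mode eliminates the flyback period; "
            f"ignoring flyback_frames={cfg.flyback_frames}",
            stacklevel=2,
        )
    spf = tb.samples_per_frame
    dz = cfg.z_spacing_um
    n = cfg.n_planes
    nf = 0 if cfg.scan_mode is ScanMode.BIDIRECTIONAL else cfg.flyback_frames

    down = np.arange(n)            # plane depth-indices top to bottom
    up = down[::-1]

    depth_parts: list[np.ndarray] = []
    label_parts: list[np.ndarray] = []
    for v in range(tb.n_volumes):
        if cfg.scan_mode is ScanMode.SCAN_DOWN:
            order = down
        elif cfg.scan_mode is ScanMode.SCAN_UP:
            order = up
        else:
            order = down if v % 2 == 0 else up
        depth_parts.append(np.repeat(order * dz, spf))
        label_parts.append(np.repeat(order, spf))
        if nf > 0:
            start = order[-1] * dz
            end = order[0] * dz
            ramp = np.linspace(start, end, nf * spf + 1)[1:]
            depth_parts.append(ramp)
            label_parts.append(np.full(nf * spf, FLYBACK, dtype=int))
    return DepthTrajectory(np.concatenate(depth_parts),
                           np.concatenate(label_parts).astype(int))


def _trigger_pulse_samples(tb: TimeBase) -> int:
    # pulse width: min(1 ms, 10% of a frame), at least one sample
    return max(1, min(int(round(1e-3 * tb.sample_rate_hz)),
                      tb.samples_per_frame // 10))


def build_camera_trigger(tb: TimeBase, cfg: AcquisitionConfig,
                         labels: np.ndarray | None = None) -> np.ndarray:
    """Binary trigger with exactly one rising edge per plane frame.

    The edge sits on the first sample of each plane frame, synchronized with
    the start of the X sweep; flyback, adaptation and gap frames carry no
    edges.
    """
    if labels is None:
        labels = build_depth_trajectory(tb, cfg).labels
    spf = tb.samples_per_frame
    if labels.size % spf != 0:
        raise ConfigurationError("label timeline is not frame-aligned")
    width = _trigger_pulse_samples(tb)
    trig = np.zeros(labels.size, dtype=np.uint8)
    starts = np.arange(0, labels.size, spf)
    plane_starts = starts[labels[starts] >= 0]
    for s in plane_starts:
        trig[s:s + width] = 1
    return trig


def _triangle_phase(n_samples: int, spf: int, scans_per_frame: int) -> np.ndarray:
    """Unit triangle (-1..+1), ``scans_per_frame`` out-and-back scans per frame."""
    j = np.arange(n_samples) % spf
    t = j / spf * scans_per_frame
    return sawtooth(2.0 * np.pi * t, width=0.5)


def build_x_sweep(tb: TimeBase, cfg: AcquisitionConfig, path: PathConfig,
                  calib: CalibrationState, n_samples: int | None = None) -> np.ndarray:
    """Triangle sweep of the X mirror painting the sheet within each frame.

    The mirror scans from one sheet edge to the other and back,
    ``scans_per_frame`` times per frame, symmetric about 0 V (the mirror's
    energized central position).  Amplitude is ±(width/2) x x_scale.
    """
    amp_v = path.sheet_width_um / 2.0 * calib.x_scale[path.path_id]
    if amp_v > cfg.voltage_range_v:
        raise RangeError(
            f"x_mirror_path{path.path_id}",
            f"sweep amplitude {amp_v:.3f} V exceeds +/-{cfg.voltage_range_v:g} V",
        )
    if n_samples is None:
        n_samples = tb.total_samples
    return amp_v * _triangle_phase(n_samples, tb.samples_per_frame,
                                   cfg.scans_per_frame)


def depth_to_commands(traj: DepthTrajectory, calib: CalibrationState,
                      path_id: int = 1,
                      voltage_range_v: float = 10.0) -> tuple[np.ndarray, np.ndarray]:
    """Convert a depth trajectory to synchronized Z-mirror and piezo voltages.

    Both outputs are affine in the same depth series — the synchronization
    contract that keeps the excitation sheet in the imaging focal plane:

        piezo(t)    = piezo_offset + depth(t) * piezo_scale / 1000
        z_mirror(t) = z_offset     + depth(t) * z_scale / 1000

    (scales in mV/μm, hence the /1000).
    """
    d = traj.depth_um
    z = calib.z_offset[path_id] + d * calib.z_scale[path_id] / 1000.0
    piezo = calib.piezo_offset + d * calib.piezo_scale / 1000.0
    for name, series in (("z_mirror_path%d" % path_id, z), ("piezo", piezo)):
        peak = float(np.max(np.abs(series))) if series.size else 0.0
        if peak > voltage_range_v:
            raise RangeError(name, f"command reaches {peak:.3f} V, "
                                   f"exceeds +/-{voltage_range_v:g} V")
    return z, piezo


def build_shutter(tb: TimeBase, cfg: AcquisitionConfig, masks: MaskSpec,
                  path: PathConfig, lag_s: float = 0.0,
                  labels: np.ndarray | None = None) -> np.ndarray:
    """Software laser shutter implementing edge/eye masks and blank-return.

    The shutter opens exactly when the lag-corrected mirror position — the
    commanded position evaluated ``lag_s`` seconds earlier, which is where a
    delay-lagged mirror actually sits — lies inside the unmasked sheet
    extent.  ``blank_return`` closes every flyback sample; gap (IDLE)
    samples are always closed; adaptation samples are open (the point of
    light adaptation is to keep the sheet on).
    """
    if lag_s < 0:
        raise ConfigurationError("lag must be >= 0")
    masks.validate_against_width(path.sheet_width_um)
    if labels is None:
        labels = build_depth_trajectory(tb, cfg).labels
    n = labels.size
    half = path.sheet_width_um / 2.0
    pos = half * _triangle_phase(n, tb.samples_per_frame, cfg.scans_per_frame)

    k = int(round(lag_s / tb.sample_period_s))
    if k > 0:
        pos = np.concatenate([np.full(k, pos[0]), pos[:-k]])

    open_ = labels >= 0
    if masks.blank_return:
        pass  # flyback stays closed
    else:
        open_ = open_ | (labels == FLYBACK)
    open_ = open_ | (labels == ADAPTATION)

    if masks.edge_enabled and masks.edge_fraction > 0:
        open_ &= np.abs(pos) <= (1.0 - 2.0 * masks.edge_fraction) * half
    if masks.eye_enabled:
        open_ &= ~(np.abs(pos - masks.eye_center_um) < masks.eye_halfwidth_um)
    return open_.astype(np.uint8)


@dataclass(frozen=True)
class WaveformSet:
    """Synchronized multi-channel command block on one timebase.

    Channel order is fixed and documented: ``camera_trigger``, then per-path
    ``laser_shutter``, ``x_mirror``, ``z_mirror`` (path 1 before path 2),
    then ``piezo`` — 8 channels for a dual-path configuration, 5 for single
    path.
    """

    timebase: TimeBase
    channel_order: tuple[str, ...]
    channels: dict[str, np.ndarray]
    labels: np.ndarray
    depth_um: np.ndarray

    def __post_init__(self):
        lengths = {c.size for c in self.channels.values()}
        lengths |= {self.labels.size, self.depth_um.size}
        if len(lengths) != 1:
            raise ConfigurationError("all channels must share one timebase")
        if set(self.channel_order) != set(self.channels):
            raise ConfigurationError("channel_order and channels disagree")

    @property
    def n_channels(self) -> int:
        return len(self.channel_order)

    @property
    def n_samples(self) -> int:
        return self.labels.size

    def as_array(self) -> np.ndarray:
        """Row-major (n_samples, n_channels) float64 array in channel order."""
        return np.column_stack([np.asarray(self.channels[c], dtype=float)
                                for c in self.channel_order])

    def to_csv(self, path) -> None:
        """Multi-column CSV: time in seconds plus one column per channel."""
        t = np.arange(self.n_samples) * self.timebase.sample_period_s
        data = np.column_stack([t, self.as_array()])
        header = ",".join(["time_s", *self.channel_order])
        np.savetxt(path, data, delimiter=",", header=header, comments="")

    def to_binary(self, directory, basename: str) -> tuple[Path, Path]:
        """Raw row-major float64 block plus a JSON header describing it."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        bin_path = directory / f"{basename}.bin"
        hdr_path = directory / f"{basename}.json"
        arr = self.as_array()
        arr.tofile(bin_path)
        header = {
            "dtype": "float64",
            "order": "C",
            "shape": list(arr.shape),
            "channel_order": list(self.channel_order),
            "sample_rate_hz": self.timebase.sample_rate_hz,
        }
        hdr_path.write_text(json.dumps(header, indent=2) + "\n")
        return bin_path, hdr_path


def rising_edges(binary: np.ndarray) -> np.ndarray:
    """Indices of 0->1 transitions (a high first sample counts as an edge)."""
    b = np.asarray(binary).astype(np.int8)
    edges = np.flatnonzero(np.diff(b) > 0) + 1
    if b.size and b[0] > 0:
        edges = np.concatenate([[0], edges])
    return edges


def _whole_frames(duration_s: float, tb: TimeBase) -> int:
    """Round a segment duration up to whole frames (keeps the sweep phase-locked)."""
    if duration_s <= 0:
        return 0
    frames = int(np.ceil(duration_s * tb.sample_rate_hz / tb.samples_per_frame))
    return frames


def assemble_waveforms(cfg: AcquisitionConfig, calib: CalibrationState,
                       session: SessionPlan | None = None) -> WaveformSet:
    """Assemble the full synchronized channel block for a session.

    Per recording: an optional light-adaptation segment (sheet parked at the
    adaptation depth, shutter open, no camera triggers), the recording
    itself, and an inter-recording gap in which adaptation continues if
    enabled or every shutter closes otherwise.  Segment durations are
    rounded up to whole frames so the X sweep stays phase-locked.
    """
    if session is None:
        session = SessionPlan()
    tb = make_timebase(cfg)
    rec = build_depth_trajectory(tb, cfg)
    spf = tb.samples_per_frame

    adapt_frames = (_whole_frames(session.adaptation_duration_s, tb)
                    if session.adaptation_enabled else 0)
    gap_frames = _whole_frames(session.inter_recording_gap_s, tb)

    depth_parts: list[np.ndarray] = []
    label_parts: list[np.ndarray] = []
    for r in range(session.n_recordings):
        if adapt_frames:
            depth_parts.append(np.full(adapt_frames * spf,
                                       session.adaptation_depth_um))
            label_parts.append(np.full(adapt_frames * spf, ADAPTATION, dtype=int))
        depth_parts.append(rec.depth_um)
        label_parts.append(rec.labels)
        if gap_frames and r < session.n_recordings - 1:
            if session.adaptation_enabled:
                gap_depth = session.adaptation_depth_um
                gap_label = ADAPTATION
            else:
                gap_depth = float(rec.depth_um[-1])
                gap_label = IDLE
            depth_parts.append(np.full(gap_frames * spf, gap_depth))
            label_parts.append(np.full(gap_frames * spf, gap_label, dtype=int))
    depth = np.concatenate(depth_parts)
    labels = np.concatenate(label_parts)
    traj = DepthTrajectory(depth, labels)

    try:
        trigger = build_camera_trigger(tb, cfg, labels=labels)
    except (ConfigurationError, RangeError) as exc:
        raise type(exc)(f"camera_trigger: {exc}") from exc

    paths = cfg.enabled_paths
    channels: dict[str, np.ndarray] = {"camera_trigger": trigger}
    order: list[str] = ["camera_trigger"]
    for p in paths:
        order.append(f"laser_shutter_path{p.path_id}")
        channels[order[-1]] = build_shutter(
            tb, cfg, cfg.masks, p, lag_s=calib.x_lag[p.path_id], labels=labels)
    for p in paths:
        order.append(f"x_mirror_path{p.path_id}")
        channels[order[-1]] = build_x_sweep(tb, cfg, p, calib,
                                            n_samples=labels.size)
    piezo = None
    for p in paths:
        order.append(f"z_mirror_path{p.path_id}")
        z, piezo = depth_to_commands(traj, calib, path_id=p.path_id,
                                     voltage_range_v=cfg.voltage_range_v)
        channels[order[-1]] = z
    order.append("piezo")
    channels["piezo"] = piezo
    return WaveformSet(timebase=tb, channel_order=tuple(order),
                       channels=channels, labels=labels, depth_um=depth)
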