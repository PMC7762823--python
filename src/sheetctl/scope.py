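"""A digital twin of the scanned light-sheet hardware.

Converts command waveforms into simulated mirror/stage motion, accumulated
illumination dose and camera frames.  It is the oracle the waveform engine
and the calibration estimators are tested against: galvo mirrors can be
ideal, pure-delay or first-order (a 1 kHz-bandwidth galvo has a ~0.16 ms
time constant), the objective piezo can ring as an underdamped second-order
stage, and frames of a uniform fluorescein bath reproduce the dose and
defocus phenomenology that the calibration procedures exploit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import cont2discrete, lfilter, lfilter_zi, sawtooth

from .calibration import CalibrationState
from .config import MaskSpec
from .errors import ConfigurationError
from .waveforms import WaveformSet, rising_edges

__all__ = [
    "GalvoDynamics",
    "PiezoDynamics",
    "SheetGeometry",
    "DoseProfile",
    "galvo_response",
    "piezo_response",
    "accumulate_dose",
    "median_normalize",
    "lag_calibration_profiles",
    "mask_overlap_mismatch",
    "render_frames",
]

#: time constant of a first-order galvo with 1 kHz small-signal bandwidth
DEFAULT_GALVO_TAU_S = 1.0 / (2.0 * np.pi * 1000.0)


@dataclass(frozen=True)
class GalvoDynamics:
    """Galvanometer mirror model: ideal, pure delay, or first-order lag."""

    model: str = "ideal"
    delay_s: float = 0.0
    time_constant_s: float = DEFAULT_GALVO_TAU_S
    max_deflection_deg: float = 0.2

    def __post_init__(self):
        if self.model not in ("ideal", "pure_delay", "first_order"):
            raise ValueError(f"unknown galvo model {self.model!r}")
        if self.delay_s < 0 or self.time_constant_s < 0:
            raise ValueError("delay and time constant must be >= 0")


@dataclass(frozen=True)
class PiezoDynamics:
    """Objective-scanner model: ideal or underdamped second-order stage."""

    model: str = "ideal"
    natural_frequency_hz: float = 150.0
    damping_ratio: float = 0.2
    travel_um: float = 400.0

    def __post_init__(self):
        if self.model not in ("ideal", "second_order"):
            raise ValueError(f"unknown piezo model {self.model!r}")
        if self.natural_frequency_hz <= 0 or self.damping_ratio <= 0:
            raise ValueError("natural frequency and damping must be > 0")


@dataclass(frozen=True)
class SheetGeometry:
    """Illumination sheet and scene: beam waist and fluorophore layout."""

    waist_thickness_um: float = 7.0
    field_width_um: float = 500.0
    fluorophore: str = "uniform_fluorescein"


@dataclass(frozen=True)
class DoseProfile:
    """Accumulated illumination dose binned along the sheet (x) axis."""

    bin_edges_um: np.ndarray
    dose: np.ndarray

    def __post_init__(self):
        if self.dose.size != self.bin_edges_um.size - 1:
            raise ValueError("need one more bin edge than dose bin")
        if np.any(self.dose < 0):
            raise ValueError("dose must be >= 0 everywhere")

    @property
    def centers_um(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_um[:-1] + self.bin_edges_um[1:])

    @property
    def total(self) -> float:
        return float(self.dose.sum())


def galvo_response(command: np.ndarray, dyn: GalvoDynamics,
                   sample_period_s: float) -> np.ndarray:
    """Mirror position produced by a command series.

    ``ideal`` is the identity; ``pure_delay`` shifts the command by a whole
    number of samples (holding the initial value); ``first_order`` applies
    exponential smoothing ``y[n] = y[n-1] + a (x[n] - y[n-1])`` with
    ``a = 1 - exp(-Ts / tau)``, started at steady state.
    """
    x = np.asarray(command, dtype=float)
    if dyn.model == "ideal":
        return x.copy()
    if dyn.model == "pure_delay":
        k = int(round(dyn.delay_s / sample_period_s))
        if k == 0 or x.size == 0:
            return x.copy()
        return np.concatenate([np.full(k, x[0]), x[:-k]])
    alpha = 1.0 - np.exp(-sample_period_s / dyn.time_constant_s)
    y, _ = lfilter([alpha], [1.0, alpha - 1.0], x, zi=[(1.0 - alpha) * x[0]])
    return y


def piezo_response(command_um: np.ndarray, dyn: PiezoDynamics,
                   sample_period_s: float) -> np.ndarray:
    """Stage position for a commanded position series (both in μm).

    The second-order model is the standard damped oscillator
    ``wn^2 / (s^2 + 2 zeta wn s + wn^2)`` discretized by the bilinear
    transform and started at steady state, so a fast return excites the
    ringing that the flyback ramp exists to avoid.  Commands beyond the
    travel range are clipped with a warning.
    """
    u = np.asarray(command_um, dtype=float)
    if np.any(u < 0) or np.any(u > dyn.travel_um):
        warnings.warn(
            f"piezo command outside 0..{dyn.travel_um:g} um travel; clipping",
            stacklevel=2,
        )
        u = np.clip(u, 0.0, dyn.travel_um)
    if dyn.model == "ideal":
        return u.copy()
    wn = 2.0 * np.pi * dyn.natural_frequency_hz
    num, den = [wn**2], [1.0, 2.0 * dyn.damping_ratio * wn, wn**2]
    (bz, az, _) = cont2discrete((num, den), sample_period_s, method="bilinear")
    bz, az = np.atleast_1d(np.squeeze(bz)), np.atleast_1d(np.squeeze(az))
    zi = lfilter_zi(bz, az) * (u[0] if u.size else 0.0)
    y, _ = lfilter(bz, az, u, zi=zi)
    return y


def accumulate_dose(x_position_um: np.ndarray, shutter: np.ndarray,
                    geometry: SheetGeometry, bins: int) -> DoseProfile:
    """Histogram of mirror position over open-shutter samples.

    Each open sample deposits one unit of dose at the mirror's current
    position; closed samples contribute nothing, so the total dose equals
    the open-shutter sample count whenever the motion stays inside the
    field.
    """
    if bins < 2:
        raise ValueError("need at least 2 bins")
    half = geometry.field_width_um / 2.0
    pos = np.asarray(x_position_um, dtype=float)
    open_ = np.asarray(shutter).astype(bool)
    counts, edges = np.histogram(pos[open_], bins=bins, range=(-half, half))
    return DoseProfile(edges, counts.astype(float))


def median_normalize(profile: DoseProfile) -> DoseProfile:
    """Divide every bin by the median bin so the output median is 1."""
    med = float(np.median(profile.dose))
    if med <= 0:
        raise ValueError("cannot median-normalize: median dose is zero")
    return DoseProfile(profile.bin_edges_um, profile.dose / med)


def _mask_open(pos_um: np.ndarray, masks: MaskSpec, width_um: float) -> np.ndarray:
    half = width_um / 2.0
    open_ = np.ones(pos_um.size, dtype=bool)
    if masks.edge_enabled and masks.edge_fraction > 0:
        open_ &= np.abs(pos_um) <= (1.0 - 2.0 * masks.edge_fraction) * half
    if masks.eye_enabled:
        open_ &= ~(np.abs(pos_um - masks.eye_center_um) < masks.eye_halfwidth_um)
    return open_


def lag_calibration_profiles(
    width_um: float,
    masks: MaskSpec,
    galvo: GalvoDynamics,
    sample_period_s: float,
    samples_per_scan: int = 2000,
    n_scans: int = 8,
    compensation_lag_s: float = 0.0,
) -> tuple[DoseProfile, DoseProfile]:
    """Forward-only and reverse-only dose profiles of the same masked sweep.

    This is the automated counterpart of displaying a distinct mask and
    sweeping it in both directions: the mirror trails its command, so the
    dose pattern lands short of the commanded mask on the forward sweep
    (toward −x) and short of it on the reverse sweep (toward +x), and the
    two profiles separate by twice the lag.  The bin grid is
    chosen so one bin equals one sample of mirror travel, which makes the
    separation an integer bin count and lets
    :func:`sheetctl.calibration.estimate_x_lag` recover a pure sample delay
    exactly.  ``compensation_lag_s`` applies the lag correction to the
    shutter pattern (the commanded position evaluated that much earlier), to
    verify that an estimated lag really re-overlaps the masks.
    """
    S = int(samples_per_scan)
    if S % 2:
        raise ValueError("samples_per_scan must be even")
    half = width_um / 2.0
    n = S * n_scans
    jm = np.arange(n) % S
    v = 2.0 * width_um / S  # travel per sample
    centers = -half + v * np.arange(S // 2 + 1)
    # both sweep directions index the same value grid, so a position computed
    # on the way up is bit-identical to the same position on the way down
    cmd = centers[np.where(jm < S // 2, jm, S - jm)]

    k_comp = int(round(compensation_lag_s / sample_period_s))
    cmd_eval = cmd
    if k_comp > 0:
        cmd_eval = np.concatenate([np.full(k_comp, cmd[0]), cmd[:-k_comp]])
    open_ = _mask_open(cmd_eval, masks, width_um)

    actual = galvo_response(cmd, galvo, sample_period_s)
    rising = jm < S // 2

    edges = np.concatenate([centers - v / 2.0, [centers[-1] + v / 2.0]])
    fwd, _ = np.histogram(actual[rising & open_], bins=edges)
    rev, _ = np.histogram(actual[~rising & open_], bins=edges)
    return (DoseProfile(edges, fwd.astype(float)),
            DoseProfile(edges, rev.astype(float)))


def mask_overlap_mismatch(forward: DoseProfile, reverse: DoseProfile) -> float:
    """Mean squared difference between forward and reverse dose profiles.

    Zero when the masks from the two sweep directions overlap perfectly.
    """
    if forward.dose.size != reverse.dose.size:
        raise ValueError("profiles must share one bin grid")
    return float(np.mean((forward.dose - reverse.dose) ** 2))


def render_frames(
    wfs: WaveformSet,
    galvo: GalvoDynamics,
    piezo: PiezoDynamics,
    scene: SheetGeometry,
    truth: CalibrationState,
    path_id: int = 1,
    frame_shape: tuple[int, int] = (16, 64),
    density_fn=None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate camera frames from a command block.

    One frame is produced per camera-trigger rising edge.  Each open-shutter
    sample deposits dose at the simulated mirror position, weighted by a
    Gaussian defocus penalty on the distance between the sheet depth
    (Z-mirror command through the scope's true scale) and the objective
    focal depth (simulated piezo position); the penalty scale is half the
    sheet waist.  Rows replicate the dose profile (the scene is uniform
    along y); ``density_fn(x_centers_um, depth_um)`` can modulate the
    fluorophore density per frame.  Optional Poisson noise via ``rng``.

    Returns ``(stack, actual_depth_um, nominal_depth_um)`` with one entry
    per frame.
    """
    tb = wfs.timebase
    ts = tb.sample_period_s
    spf = tb.samples_per_frame
    pid = path_id

    x_cmd_um = wfs.channels[f"x_mirror_path{pid}"] / truth.x_scale[pid]
    x_act = galvo_response(x_cmd_um, galvo, ts)
    shutter = wfs.channels[f"laser_shutter_path{pid}"].astype(bool)
    sheet_um = ((wfs.channels[f"z_mirror_path{pid}"] - truth.z_offset[pid])
                / (truth.z_scale[pid] / 1000.0))
    piezo_cmd_um = ((wfs.channels["piezo"] - truth.piezo_offset)
                    / (truth.piezo_scale / 1000.0))
    obj_um = piezo_response(piezo_cmd_um, piezo, ts)

    sigma_d = scene.waist_thickness_um / 2.0
    defocus = np.exp(-((sheet_um - obj_um) ** 2) / (2.0 * sigma_d**2))

    edges_idx = rising_edges(wfs.channels["camera_trigger"])
    bad = edges_idx[wfs.labels[edges_idx] < 0]
    if bad.size:
        raise ConfigurationError(
            f"camera trigger at sample {int(bad[0])} outside a plane frame")

    n_y, n_x = frame_shape
    half = scene.field_width_um / 2.0
    bin_edges = np.linspace(-half, half, n_x + 1)
    centers = 0.5 * (bin_edges[:-1] + bin_edges[1:])

    stack = np.zeros((edges_idx.size, n_y, n_x))
    actual_depth = np.zeros(edges_idx.size)
    nominal_depth = np.zeros(edges_idx.size)
    for f, e in enumerate(edges_idx):
        sl = slice(e, e + spf)
        w = defocus[sl] * shutter[sl]
        profile, _ = np.histogram(x_act[sl], bins=bin_edges, weights=w)
        if density_fn is not None:
            profile = profile * density_fn(centers, float(wfs.depth_um[e]))
        frame = np.tile(profile, (n_y, 1))
        if rng is not None:
            frame = rng.poisson(frame).astype(float)
        stack[f] = frame
        actual_depth[f] = float(np.mean(obj_um[sl]))
        nominal_depth[f] = float(wfs.depth_um[e])
    return stack, actual_depth, nominal_depth
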