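"""Calibration of the scan hardware: scales, offsets and mirror lag.

Four procedures convert physical units into command voltages:

* **X-mirror scale** (V per μm at the sample plane) — adjusted so that a
  commanded sheet width matches the width measured on the camera, using the
  pixel size derived from sensor size and magnification.
* **Piezo scale/offset** — factory values (e.g. 40 mV/μm for a PIFOC
  objective scanner) entered by the user, validated only.
* **Z-mirror scale** (mV per μm) — a straight line fitted to a table of
  (stage depth, in-focus Z-mirror voltage) pairs collected by stepping the
  stage through the volume and refocusing the sheet at each level.
* **X-mirror lag** — the galvanometer's mechanical delay behind its command,
  estimated automatically from illumination-dose profiles of the same mask
  swept forward-only and reverse-only: the lag shifts the two profiles in
  opposite directions, so half the profile-to-profile shift is the lag.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import CalibrationError, EstimationError

__all__ = [
    "CalibrationState",
    "FocusTable",
    "ZScaleFit",
    "pixel_size_from_optics",
    "solve_x_scale",
    "fit_z_scale",
    "estimate_x_lag",
]

CALIBRATION_SCHEMA_VERSION = 1


@dataclass
class CalibrationState:
    """Per-path scales, offsets and lags converting physical units to volts.

    Units: ``x_scale`` V/μm (sample plane), ``z_scale`` and ``piezo_scale``
    mV/μm, offsets V, lags seconds, ``pixel_size_um`` μm per camera pixel.
    """

    x_scale: dict[int, float] = field(default_factory=lambda: {1: 0.01, 2: 0.01})
    z_scale: dict[int, float] = field(default_factory=lambda: {1: 40.0, 2: 40.0})
    z_offset: dict[int, float] = field(default_factory=lambda: {1: 0.0, 2: 0.0})
    x_lag: dict[int, float] = field(default_factory=lambda: {1: 0.0, 2: 0.0})
    piezo_scale: float = 40.0  # mV/um, PIFOC factory value
    piezo_offset: float = 0.0
    pixel_size_um: float = 0.397

    def __post_init__(self):
        for path, s in {**self.x_scale}.items():
            if s <= 0:
                raise CalibrationError(f"x_scale[{path}] must be > 0")
        for path, s in {**self.z_scale}.items():
            if s <= 0:
                raise CalibrationError(f"z_scale[{path}] must be > 0")
        for path, lag in {**self.x_lag}.items():
            if lag < 0:
                raise CalibrationError(f"x_lag[{path}] must be >= 0")
        if self.piezo_scale <= 0:
            raise CalibrationError("piezo_scale must be > 0")
        if self.pixel_size_um <= 0:
            raise CalibrationError("pixel_size_um must be > 0")

    # -- persistence -------------------------------------------------------

    def to_json(self, path) -> None:
        doc = {"schema_version": CALIBRATION_SCHEMA_VERSION}
        d = asdict(self)
        for key in ("x_scale", "z_scale", "z_offset", "x_lag"):
            d[key] = {str(k): v for k, v in d[key].items()}
        doc.update(d)
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2, sort_keys=False)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "CalibrationState":
        with open(path) as fh:
            doc = json.load(fh)
        doc.pop("schema_version", None)
        for key in ("x_scale", "z_scale", "z_offset", "x_lag"):
            if key in doc:
                doc[key] = {int(k): float(v) for k, v in doc[key].items()}
        return cls(**doc)


@dataclass(frozen=True)
class FocusTable:
    """Rows of (stage depth μm, in-focus Z-mirror voltage V)."""

    depth_um: np.ndarray
    voltage_v: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.depth_um, dtype=float)
        v = np.asarray(self.voltage_v, dtype=float)
        if d.shape != v.shape or d.ndim != 1:
            raise CalibrationError("depth and voltage must be 1-D and equal length")
        object.__setattr__(self, "depth_um", d)
        object.__setattr__(self, "voltage_v", v)

    @classmethod
    def from_csv(cls, path) -> "FocusTable":
        data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        return cls(data[:, 0], data[:, 1])

    def to_csv(self, path) -> None:
        header = "depth_um,voltage_V"
        np.savetxt(path, np.column_stack([self.depth_um, self.voltage_v]),
                   delimiter=",", header=header, comments="")


@dataclass(frozen=True)
class ZScaleFit:
    """Result of the Z-mirror straight-line calibration."""

    z_scale_mv_per_um: float
    z_offset_v: float
    residual_sd_v: float
    scale_stderr_mv_per_um: float
    n_levels: int


def pixel_size_from_optics(sensor_side_mm: float, n_pixels: int,
                           magnification: float) -> float:
    """Pixel footprint at the sample: sensor side / pixel count / magnification.

    Returns μm per pixel, e.g. a 13 mm sensor with 2048 pixels behind a 16x
    objective gives 0.397 μm/px (a ~0.16 μm² footprint per pixel).
    """
    if sensor_side_mm <= 0 or n_pixels <= 0 or magnification <= 0:
        raise ValueError("sensor size, pixel count and magnification must be > 0")
    return sensor_side_mm * 1000.0 / n_pixels / magnification


def solve_x_scale(commanded_width_um: float, measured_width_px: float,
                  pixel_size_um: float, current_scale_v_per_um: float) -> float:
    """One-step X-mirror scale update from a width measurement.

    A sheet commanded to ``commanded_width_um`` was measured as
    ``measured_width_px`` camera pixels.  Under the (linear) galvo model the
    corrected scale makes a re-measurement match exactly:

        new_scale = current_scale * commanded / (measured_px * pixel_size)
    """
    if measured_width_px <= 0:
        raise CalibrationError("measured width must be > 0 pixels")
    if commanded_width_um <= 0 or pixel_size_um <= 0 or current_scale_v_per_um <= 0:
        raise CalibrationError("widths, pixel size and scale must be > 0")
    measured_um = measured_width_px * pixel_size_um
    return current_scale_v_per_um * commanded_width_um / measured_um


def fit_z_scale(table: FocusTable) -> ZScaleFit:
    """Fit voltage = z_offset + depth * z_scale/1000 by ordinary least squares.

    The residual standard deviation (V) is reported as a calibration-quality
    metric: a visibly non-zero residual flags a nonlinear mirror response.
    """
    d, v = table.depth_um, table.voltage_v
    if np.unique(d).size < 2:
        raise CalibrationError("need at least 2 distinct depths to fit a line")
    slope, intercept = np.polyfit(d, v, 1)
    resid = v - (intercept + slope * d)
    n = d.size
    dof = n - 2
    if dof > 0:
        residual_sd = float(np.sqrt(np.sum(resid**2) / dof))
        sxx = float(np.sum((d - d.mean()) ** 2))
        stderr = residual_sd / np.sqrt(sxx)
    else:
        residual_sd = 0.0
        stderr = 0.0
    return ZScaleFit(
        z_scale_mv_per_um=float(slope * 1000.0),
        z_offset_v=float(intercept),
        residual_sd_v=residual_sd,
        scale_stderr_mv_per_um=float(stderr * 1000.0),
        n_levels=int(n),
    )


def estimate_x_lag(dose_forward: np.ndarray, dose_reverse: np.ndarray,
                   sample_period_s: float, max_lag_samples: int = 50) -> float:
    """Estimate the mirror lag from forward-only / reverse-only dose profiles.

    Both profiles must be binned on a common position grid whose bin width
    equals one sample of mirror travel (see
    :func:`sheetctl.scope.lag_calibration_profiles`).  A mirror delay of
    ``k`` samples makes the dose trail the command: the forward profile
    shifts by −k bins and the reverse profile by +k bins, so the two
    separate by 2k bins; the lag is half the separation minimizing the
    summed squared mismatch, times the sample period.  Exhaustive search
    over integer shifts replaces the original manual
    adjust-until-the-masks-overlap loop.

    Antisymmetric by construction: swapping the profiles negates the result.
    """
    f = np.asarray(dose_forward, dtype=float).ravel()
    r = np.asarray(dose_reverse, dtype=float).ravel()
    if f.shape != r.shape:
        raise EstimationError("profiles must share one bin grid")
    if np.ptp(f) == 0 or np.ptp(r) == 0:
        raise EstimationError("featureless profile: no mask edge to align on")
    n = f.size
    best_s, best_cost = 0, np.inf
    for s in range(-2 * max_lag_samples, 2 * max_lag_samples + 1):
        # compare f[i] with r[i - s] over the overlapping support
        if s >= 0:
            a, b = f[s:], r[: n - s]
        else:
            a, b = f[: n + s], r[-s:]
        if a.size < n // 2:
            continue
        cost = float(np.mean((a - b) ** 2))
        if cost < best_cost - 1e-15 or (
            abs(cost - best_cost) <= 1e-15 and abs(s) < abs(best_s)
        ):
            best_cost, best_s = cost, s
    # f trails by -k bins and r by +k, so the best alignment has s = -2k
    return -best_s / 2.0 * sample_period_s
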