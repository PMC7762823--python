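"""Metadata sidecar and size-limited image-stack I/O.

Every recording is described by a JSON sidecar carrying the volume geometry
(enough to reconstruct the acquisition configuration exactly), a snapshot of
the calibration state, the session plan, free-text user annotations and
provenance.  Image stacks are written as multi-page TIFF files split at a
configurable per-file size limit (4 GB by default, mirroring common
acquisition software), in acquisition order, and reassemble exactly on read.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .calibration import CalibrationState
from .config import (AcquisitionConfig, SessionPlan, config_from_dict,
                     session_from_dict)
from .errors import ConfigurationError

__all__ = [
    "METADATA_SCHEMA_VERSION",
    "MetadataRecord",
    "write_metadata",
    "read_metadata",
    "write_stack",
    "read_stack",
]

METADATA_SCHEMA_VERSION = 1


def _volume_block(cfg: AcquisitionConfig) -> dict:
    return {
        "n_planes": cfg.n_planes,
        "z_spacing_um": cfg.z_spacing_um,
        "plane_rate_hz": cfg.plane_rate_hz,
        "scan_mode": cfg.scan_mode.value,
        "flyback_frames": cfg.flyback_frames,
        "n_volumes": cfg.n_volumes,
        "scans_per_frame": cfg.scans_per_frame,
        "sample_rate_hz": cfg.sample_rate_hz,
        "voltage_range_v": cfg.voltage_range_v,
        "sheet_width_um": cfg.sheet_width_um,
        "paths": [
            {"path_id": p.path_id, "sheet_width_um": p.sheet_width_um,
             "enabled": p.enabled}
            for p in cfg.paths
        ],
        "masks": {
            "edge_enabled": cfg.masks.edge_enabled,
            "edge_fraction": cfg.masks.edge_fraction,
            "eye_enabled": cfg.masks.eye_enabled,
            "eye_center_um": cfg.masks.eye_center_um,
            "eye_halfwidth_um": cfg.masks.eye_halfwidth_um,
            "blank_return": cfg.masks.blank_return,
        },
    }


@dataclass
class MetadataRecord:
    """Sidecar describing one recording: geometry, calibration, annotations."""

    volume: dict
    calibration: dict | None = None
    session: dict | None = None
    user: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)

    @classmethod
    def from_config(cls, cfg: AcquisitionConfig,
                    calib: CalibrationState | None = None,
                    session: SessionPlan | None = None,
                    user: dict | None = None,
                    seed: int | None = None) -> "MetadataRecord":
        from . import __version__

        cal = None
        if calib is not None:
            cal = dataclasses.asdict(calib)
            for key in ("x_scale", "z_scale", "z_offset", "x_lag"):
                cal[key] = {str(k): v for k, v in cal[key].items()}
        sess = dataclasses.asdict(session) if session is not None else None
        prov = {
            "software": "sheetctl",
            "software_version": __version__,
            "created": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        }
        if seed is not None:
            prov["seed"] = seed
        return cls(volume=_volume_block(cfg), calibration=cal, session=sess,
                   user=dict(user or {}), provenance=prov)

    def to_config(self) -> AcquisitionConfig:
        """Reconstruct the acquisition geometry (exact round-trip)."""
        return config_from_dict(self.volume)

    def to_session(self) -> SessionPlan:
        return session_from_dict(self.session or {})


_REQUIRED_VOLUME_KEYS = ("n_planes", "z_spacing_um", "plane_rate_hz",
                         "scan_mode", "flyback_frames")
_KNOWN_KEYS = ("schema_version", "volume", "calibration", "session", "user",
               "provenance")


def write_metadata(record: MetadataRecord, destination) -> Path:
    """Write the sidecar as schema-versioned JSON with stable key order."""
    doc = {
        "schema_version": METADATA_SCHEMA_VERSION,
        "volume": record.volume,
        "calibration": record.calibration,
        "session": record.session,
        "user": record.user,
        "provenance": record.provenance,
    }
    doc = {k: v for k, v in doc.items() if v is not None}
    doc.update(record.extras)
    destination = Path(destination)
    destination.write_text(json.dumps(doc, indent=2) + "\n")
    return destination


def read_metadata(source) -> MetadataRecord:
    """Read and validate a sidecar; unknown keys land in ``extras``.

    A newer schema version triggers a warning and a best-effort parse.
    """
    with open(source) as fh:
        doc = json.load(fh)
    version = doc.get("schema_version", METADATA_SCHEMA_VERSION)
    if version > METADATA_SCHEMA_VERSION:
        warnings.warn(
            f"metadata schema version {version} is newer than supported "
            f"({METADATA_SCHEMA_VERSION}); parsing best-effort", stacklevel=2)
    if "volume" not in doc:
        raise ConfigurationError("metadata parse error: missing 'volume' block")
    for key in _REQUIRED_VOLUME_KEYS:
        if key not in doc["volume"]:
            raise ConfigurationError(
                f"metadata parse error: volume block missing field {key!r}")
    extras = {k: v for k, v in doc.items() if k not in _KNOWN_KEYS}
    return MetadataRecord(
        volume=doc["volume"],
        calibration=doc.get("calibration"),
        session=doc.get("session"),
        user=doc.get("user", {}),
        provenance=doc.get("provenance", {}),
        extras=extras,
    )


def write_stack(frames: np.ndarray, directory, basename: str = "stack",
                file_limit_bytes: float = 4e9,
                record: MetadataRecord | None = None) -> list[Path]:
    """Write a frame stack as size-limited multi-page TIFFs plus one sidecar.

    Frames (first axis) are packed in acquisition order into
    ``basename_000.tif``, ``basename_001.tif``, ... each holding at most
    ``file_limit_bytes`` of pixel data; the metadata sidecar
    ``basename_meta.json`` is written once beside them.
    """
    frames = np.asarray(frames)
    if frames.ndim != 3 or frames.shape[0] == 0:
        raise ConfigurationError("frames must be a non-empty (n, y, x) stack")
    per_frame = frames[0].nbytes
    if per_frame > file_limit_bytes:
        raise ConfigurationError(
            f"a single {per_frame}-byte frame exceeds the "
            f"{int(file_limit_bytes)}-byte file limit")
    per_file = int(file_limit_bytes // per_frame)
    n_files = math.ceil(frames.shape[0] / per_file)
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i in range(n_files):
        chunk = frames[i * per_file:(i + 1) * per_file]
        path = directory / f"{basename}_{i:03d}.tif"
        tifffile.imwrite(path, chunk, photometric="minisblack")
        paths.append(path)
    if record is not None:
        write_metadata(record, directory / f"{basename}_meta.json")
    return paths


def read_stack(directory, basename: str = "stack") -> np.ndarray:
    """Reassemble a split stack; exact inverse of :func:`write_stack`."""
    directory = Path(directory)
    paths = sorted(directory.glob(f"{basename}_[0-9][0-9][0-9].tif"))
    if not paths:
        raise FileNotFoundError(f"no {basename}_NNN.tif files in {directory}")
    parts = [tifffile.imread(p) for p in paths]
    parts = [p if p.ndim == 3 else p[np.newaxis] for p in parts]
    return np.concatenate(parts, axis=0)
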