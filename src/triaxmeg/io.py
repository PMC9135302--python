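"""Data containers and on-disk formats.

The package stores everything in three self-describing formats:

* recordings — HDF5 with ``/data`` (channels x samples, float64, tesla),
  a ``/channels`` table (sensor_id, axis_label), an optional ``/events``
  table, and root attributes ``fs`` (Hz), ``unit`` ("T") and ``t0`` (s);
* sensor layouts — CSV, one row per sensor with position, the three
  sensitive-axis unit vectors (rows of an orthonormal frame), an axis
  enable mask and the beam offset;
* head models — JSON with the best-fit sphere, scalp/brain radii and the
  scalp-to-brain gap.

All quantities are SI (tesla, metre, second, ampere-metre); the only
non-SI unit in the package is the fT/sqrt(Hz) scale of amplitude spectral
densities, handled in :mod:`triaxmeg.spectral`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .errors import FormatError, GeometryError, UnitError, ValidationError

__all__ = [
    "Recording",
    "SensorPose",
    "HeadModel",
    "read_recording",
    "write_recording",
    "read_sensor_layout",
    "write_sensor_layout",
    "read_head_model",
    "write_head_model",
]

#: default spatial separation of the two laser beams inside the vapour
#: cell (metres); the x/z field components are effectively measured at
#: two points this far apart, while y is measured at both and averaged.
DEFAULT_BEAM_OFFSET = 0.65e-3

_AXIS_LABELS = ("r", "theta", "phi")


@dataclass
class Recording:
    """Multichannel magnetic time series in tesla.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Magnetic field in tesla.
    fs : float
        Sampling rate in Hz (1200 Hz throughout the synthetic studies).
    channel_meta : pandas.DataFrame
        One row per channel with columns ``sensor_id`` and ``axis_label``
        (``r``/``theta``/``phi`` or ``x``/``y``/``z``).
    events : list of (int, str)
        Sample-index/label markers (trial onsets, R-peaks, ...).
    t0 : float
        Acquisition start time in seconds.
    """

    data: np.ndarray
    fs: float
    channel_meta: pd.DataFrame
    events: list = field(default_factory=list)
    t0: float = 0.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValidationError("data must be 2-D (channels x samples)")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Record length in seconds (n_samples / fs)."""
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    def validate(self) -> None:
        """Raise :class:`ValidationError` on any invariant violation."""
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise ValidationError(f"fs must be positive, got {self.fs}")
        if len(self.channel_meta) != self.n_channels:
            raise ValidationError(
                f"channel_meta has {len(self.channel_meta)} rows for "
                f"{self.n_channels} data rows"
            )
        for col in ("sensor_id", "axis_label"):
            if col not in self.channel_meta.columns:
                raise ValidationError(f"channel_meta lacks column {col!r}")
        for s, _label in self.events:
            if not 0 <= int(s) < self.n_samples:
                raise ValidationError(f"event sample {s} outside [0, {self.n_samples})")


@dataclass
class SensorPose:
    """Position and orthonormal sensitive-axis frame of one sensor.

    ``frame`` rows are the sensitive axes — (r_hat, theta_hat, phi_hat)
    for head-mounted sensors, or the cell-local (x, y, z) otherwise.
    ``axis_mask`` selects which axes are recorded (triaxial = all three).
    """

    position: np.ndarray
    frame: np.ndarray
    beam_offset: float = DEFAULT_BEAM_OFFSET
    axis_mask: np.ndarray = field(default_factory=lambda: np.ones(3, dtype=bool))

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        self.frame = np.asarray(self.frame, dtype=float).reshape(3, 3)
        self.axis_mask = np.asarray(self.axis_mask, dtype=bool).reshape(3)
        if self.beam_offset < 0:
            raise ValidationError("beam_offset must be >= 0")

    def validate(self, tol: float = 1e-10) -> None:
        g = self.frame @ self.frame.T
        if not np.allclose(g, np.eye(3), atol=tol):
            raise GeometryError("frame rows are not orthonormal")


def orthonormalize_frame(frame: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    """Project ``frame`` onto the nearest orthonormal matrix.

    Uses the polar decomposition (SVD with singular values replaced by
    one). Frames farther than ``tol`` from orthonormal are rejected with
    :class:`GeometryError` — a layout file that badly violates
    orthogonality is corrupt, not merely rounded.
    """
    frame = np.asarray(frame, dtype=float).reshape(3, 3)
    if np.linalg.matrix_rank(frame, tol=1e-8) < 3:
        raise GeometryError("frame is rank-deficient")
    u, _s, vt = np.linalg.svd(frame)
    ortho = u @ vt
    if np.max(np.abs(frame - ortho)) > tol:
        raise GeometryError(f"frame deviates from orthonormal by more than {tol:g}")
    return ortho


@dataclass
class HeadModel:
    """Spherical head description used by the forward model.

    The synthetic heads are parametric: concentric scalp and brain
    spheres around ``sphere_center``, with ``scalp_brain_gap`` between
    them. ``sphere_center``/``sphere_radius`` are the best-fit sphere of
    the scalp (identical to it for parametric heads).
    """

    sphere_center: np.ndarray
    sphere_radius: float
    scalp_radius: float
    brain_radius: float
    scalp_brain_gap: float

    def __post_init__(self):
        self.sphere_center = np.asarray(self.sphere_center, dtype=float).reshape(3)

    def validate(self) -> None:
        if self.sphere_radius <= 0:
            raise ValidationError("sphere_radius must be positive")
        if not self.brain_radius < self.scalp_radius:
            raise ValidationError("brain must lie strictly inside the scalp")


# ---------------------------------------------------------------------------
# HDF5 recordings


def write_recording(rec: Recording, path) -> None:
    """Write a :class:`Recording` to ``path`` (HDF5)."""
    rec.validate()
    with h5py.File(path, "w") as f:
        d = f.create_dataset("data", data=rec.data.astype(np.float64))
        d.attrs["unit"] = "T"
        ch = f.create_group("channels")
        ch.create_dataset(
            "sensor_id",
            data=np.asarray(rec.channel_meta["sensor_id"], dtype="S32"),
        )
        ch.create_dataset(
            "axis_label",
            data=np.asarray(rec.channel_meta["axis_label"], dtype="S16"),
        )
        ev = f.create_group("events")
        ev.create_dataset(
            "sample", data=np.asarray([int(s) for s, _ in rec.events], dtype=np.int64)
        )
        ev.create_dataset(
            "label", data=np.asarray([str(l) for _, l in rec.events], dtype="S64")
        )
        f.attrs["fs"] = float(rec.fs)
        f.attrs["unit"] = "T"
        f.attrs["t0"] = float(rec.t0)
        f.attrs["duration"] = rec.duration


def read_recording(path) -> Recording:
    """Read a :class:`Recording` written by :func:`write_recording`."""
    with h5py.File(path, "r") as f:
        for member in ("data", "channels"):
            if member not in f:
                raise FormatError(f"recording file lacks /{member}")
        if "unit" not in f.attrs and "unit" not in f["data"].attrs:
            raise UnitError("recording file lacks a unit attribute")
        if "fs" not in f.attrs:
            raise FormatError("recording file lacks the fs attribute")
        data = np.asarray(f["data"], dtype=float)
        ch = f["channels"]
        for member in ("sensor_id", "axis_label"):
            if member not in ch:
                raise FormatError(f"recording file lacks /channels/{member}")
        meta = pd.DataFrame(
            {
                "sensor_id": [s.decode() for s in ch["sensor_id"][()]],
                "axis_label": [s.decode() for s in ch["axis_label"][()]],
            }
        )
        events = []
        if "events" in f:
            samples = f["events"]["sample"][()]
            labels = f["events"]["label"][()]
            events = [(int(s), l.decode()) for s, l in zip(samples, labels)]
        rec = Recording(
            data=data,
            fs=float(f.attrs["fs"]),
            channel_meta=meta,
            events=events,
            t0=float(f.attrs.get("t0", 0.0)),
        )
    rec.validate()
    return rec


# ---------------------------------------------------------------------------
# Sensor layout CSV

_LAYOUT_COLUMNS = (
    ["sensor_id", "px", "py", "pz"]
    + [f"e{a}{i}" for i in (1, 2, 3) for a in ("x", "y", "z")]
    + ["axis_mask", "beam_offset"]
)


def write_sensor_layout(poses, path) -> None:
    """Write sensor poses to a layout CSV (documented fixed columns)."""
    rows = []
    for i, p in enumerate(poses):
        row = {"sensor_id": f"S{i:03d}", "px": p.position[0], "py": p.position[1], "pz": p.position[2]}
        for j in range(3):
            for k, a in enumerate(("x", "y", "z")):
                row[f"e{a}{j + 1}"] = p.frame[j, k]
        row["axis_mask"] = "".join("1" if m else "0" for m in p.axis_mask)
        row["beam_offset"] = p.beam_offset
        rows.append(row)
    pd.DataFrame(rows, columns=_LAYOUT_COLUMNS).to_csv(path, index=False)


def read_sensor_layout(path) -> list:
    """Read a layout CSV into a list of :class:`SensorPose`.

    Frames within 1e-6 of orthonormal are re-orthonormalized; anything
    worse raises :class:`GeometryError`.
    """
    df = pd.read_csv(path, dtype={"axis_mask": str}, float_precision="round_trip")
    missing = [c for c in _LAYOUT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"layout CSV lacks columns: {missing}")
    poses = []
    for _, row in df.iterrows():
        frame = np.array(
            [[row[f"e{a}{j + 1}"] for a in ("x", "y", "z")] for j in range(3)]
        )
        frame = orthonormalize_frame(frame)
        mask = np.array([c == "1" for c in str(row["axis_mask"])], dtype=bool)
        poses.append(
            SensorPose(
                position=[row.px, row.py, row.pz],
                frame=frame,
                beam_offset=float(row.beam_offset),
                axis_mask=mask,
            )
        )
    return poses


# ---------------------------------------------------------------------------
# Head model JSON


def write_head_model(head: HeadModel, path) -> None:
    head.validate()
    payload = {
        "center": list(map(float, head.sphere_center)),
        "radius": float(head.sphere_radius),
        "scalp_radius": float(head.scalp_radius),
        "brain_radius": float(head.brain_radius),
        "gap": float(head.scalp_brain_gap),
    }
    with open(path, "w") as f:
        json.dump(payload, f, indent=1)


def read_head_model(path) -> HeadModel:
    with open(path) as f:
        payload = json.load(f)
    for key in ("center", "radius", "gap"):
        if key not in payload:
            raise FormatError(f"head model JSON lacks key {key!r}")
    head = HeadModel(
        sphere_center=payload["center"],
        sphere_radius=payload["radius"],
        scalp_radius=payload.get("scalp_radius", payload["radius"]),
        brain_radius=payload.get("brain_radius", payload["radius"] - payload["gap"]),
        scalp_brain_gap=payload["gap"],
    )
    head.validate()
    return head
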