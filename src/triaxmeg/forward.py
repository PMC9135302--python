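"""Analytic current-dipole forward models and lead-field assembly.

Two field models are provided:

* homogeneous conducting sphere (Sarvas closed form) — the conductor
  model for all head/phantom work.  Volume currents are included; they
  cancel the field of radial dipoles entirely and never contribute to
  the radial field component outside the conductor;
* free space (primary-current Biot–Savart term only) — used to
  synthesise cardiac fields where no conductor model is attempted.

Lead fields are channels x sources x 2 arrays in tesla per A·m, the two
source orientations being the tangential unit vectors (theta_hat_s,
phi_hat_s).  Optionally the two laser beams' measurement points are
separated by the cell's beam offset: the theta channel is read at beam
1's centroid, the r channel at beam 2's, and the phi (y) channel is the
mean of the two — mirroring which physical beam carries each axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError, GeometryError
from .geometry import SensorArray, SourceSpace

__all__ = [
    "MU0",
    "CurrentDipole",
    "LeadField",
    "dipole_field_sphere",
    "dipole_field_freespace",
    "assemble_lead_field",
]

MU0 = 4e-7 * np.pi  # vacuum permeability, T m / A

_AXIS_NAMES = np.array(["r", "theta", "phi"])


@dataclass
class CurrentDipole:
    """A current dipole: position (m) and moment (A·m)."""

    position: np.ndarray
    moment: np.ndarray

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        self.moment = np.asarray(self.moment, dtype=float).reshape(3)


@dataclass
class LeadField:
    """channels x sources x 2 forward fields (tesla per unit A·m).

    Orientation index 0 is theta_hat_s, index 1 is phi_hat_s.
    ``channel_sensor`` / ``channel_axis`` describe the row enumeration
    (sensor-major, axes in (r, theta, phi) order, disabled axes skipped).
    """

    matrix: np.ndarray
    channel_sensor: np.ndarray
    channel_axis: np.ndarray  # array of "r"/"theta"/"phi"
    source_positions: np.ndarray

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sources(self) -> int:
        return self.matrix.shape[1]

    def select_axes(self, selection: str) -> "LeadField":
        """Restrict rows to an axis selection (``r``, ``r+theta``,
        ``r+phi`` or ``triaxial``)."""
        from .geometry import axis_selection_mask

        mask = axis_selection_mask(selection)
        wanted = {name for name, m in zip(_AXIS_NAMES, mask) if m}
        rows = np.array([ax in wanted for ax in self.channel_axis])
        if not rows.any():
            raise GeometryError("axis selection removed every channel")
        return LeadField(
            matrix=self.matrix[rows],
            channel_sensor=self.channel_sensor[rows],
            channel_axis=self.channel_axis[rows],
            source_positions=self.source_positions,
        )


def dipole_field_sphere(
    d: CurrentDipole,
    points: np.ndarray,
    center: np.ndarray = (0.0, 0.0, 0.0),
    conductor_radius: float | None = None,
) -> np.ndarray:
    """Magnetic field of a current dipole in a homogeneous conducting
    sphere, evaluated at external ``points`` (k x 3, metres) -> k x 3 T.

    Closed form:  with r0 the dipole position and r the field point
    (both relative to the sphere centre), a = r - r0,

        F = a (r a + r^2 - r0·r)
        grad F = (a^2/r + a·r/a + 2a + 2r) r - (a + 2r + a·r/a) r0
        B = mu0 / (4 pi F^2) * (F Q x r0 - (Q x r0 · r) grad F)

    A dipole at the centre (Q x r0 = 0) produces zero field; radial
    dipoles are externally silent.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    center = np.asarray(center, dtype=float).reshape(3)
    r0 = d.position - center
    r = points - center
    if conductor_radius is not None:
        if np.linalg.norm(r0) >= conductor_radius:
            raise DomainError("dipole lies outside the conducting sphere")
        if np.any(np.linalg.norm(r, axis=1) <= conductor_radius * (1 - 1e-12)):
            raise DomainError("field point inside the conducting sphere")

    q_x_r0 = np.cross(d.moment, r0)
    if np.allclose(q_x_r0, 0.0) and np.allclose(r0, 0.0):
        return np.zeros_like(r)

    a_vec = r - r0
    a = np.linalg.norm(a_vec, axis=1)
    rn = np.linalg.norm(r, axis=1)
    if np.any(a <= 0):
        raise DomainError("field point coincides with the dipole")
    ar = np.einsum("ij,ij->i", a_vec, r)
    r0r = r @ r0
    F = a * (rn * a + rn**2 - r0r)
    if np.any(np.abs(F) < 1e-30):
        raise DomainError("field point on the Sarvas singular surface")
    c1 = a**2 / rn + ar / a + 2.0 * a + 2.0 * rn
    c2 = a + 2.0 * rn + ar / a
    gradF = c1[:, None] * r - c2[:, None] * r0
    qxr0_dot_r = r @ q_x_r0
    B = (MU0 / (4.0 * np.pi * F**2))[:, None] * (
        F[:, None] * q_x_r0 - qxr0_dot_r[:, None] * gradF
    )
    return B


def dipole_field_freespace(d: CurrentDipole, points: np.ndarray) -> np.ndarray:
    """Primary-current (Biot–Savart) field of a current dipole in free
    space: B = mu0/(4 pi) Q x (r - r0) / |r - r0|^3."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    rel = points - d.position
    dist = np.linalg.norm(rel, axis=1)
    if np.any(dist <= 0):
        raise DomainError("field point coincides with the dipole")
    return (MU0 / (4.0 * np.pi)) * np.cross(d.moment, rel) / dist[:, None] ** 3


def _measurement_points(array: SensorArray, beam_displacement: bool):
    """Per-sensor measurement points for each axis channel.

    Returns (points_theta, points_r, points_phi_pair) where the phi
    channel averages the field over the two returned point sets.
    Without displacement all coincide with the cell centres.
    """
    p = array.positions
    if not beam_displacement:
        return p, p, (p, p)
    # each beam's measurement point sits at the cell centre +/- the beam
    # offset along that beam's propagation axis: beam 1 travels along
    # the stem (radial) axis and senses theta and y; beam 2 travels
    # along the tangential theta axis and senses r and y
    r_axis = array.frames[:, 0, :]
    th_axis = array.frames[:, 1, :]
    off = array.beam_offset
    p1 = p + off * r_axis  # beam 1: senses theta (x) and phi (y)
    p2 = p - off * th_axis  # beam 2: senses r (z) and phi (y)
    return p1, p2, (p1, p2)


def assemble_lead_field(
    array: SensorArray,
    src: SourceSpace,
    model: str = "sphere",
    beam_displacement: bool = False,
    center: np.ndarray = (0.0, 0.0, 0.0),
) -> LeadField:
    """Assemble the lead field for ``array`` over ``src``.

    Entry (i, j, o) is the projection, onto channel i's sensitive axis,
    of the field of a unit (1 A·m) dipole at source j oriented along
    tangential orientation o (0 = theta_hat_s, 1 = phi_hat_s).
    """
    if model not in ("sphere", "freespace"):
        raise GeometryError(f"unknown field model {model!r}")
    center = np.asarray(center, dtype=float).reshape(3)
    pairs = array.channel_index()
    n_chan = len(pairs)
    n_src = src.n_sources
    matrix = np.zeros((n_chan, n_src, 2))

    pts_theta, pts_r, (pts_y1, pts_y2) = _measurement_points(array, beam_displacement)
    # unique evaluation point sets (all identical when undisplaced)
    eval_sets = {"r": pts_r, "theta": pts_theta}

    def field(dipole, pts):
        if model == "sphere":
            return dipole_field_sphere(dipole, pts, center=center)
        return dipole_field_freespace(dipole, pts)

    chan_i = np.array([i for i, _ in pairs])
    chan_k = np.array([k for _, k in pairs])
    chan_axes = array.frames[chan_i, chan_k, :]  # (C, 3)

    for j in range(n_src):
        pos = src.positions[j]
        for o, row in enumerate((1, 2)):  # theta_hat_s, phi_hat_s
            dipole = CurrentDipole(position=pos, moment=src.frames[j, row, :])
            B_r = field(dipole, eval_sets["r"])
            if beam_displacement:
                B_theta = field(dipole, eval_sets["theta"])
                B_phi = 0.5 * (B_theta + B_r)  # y read by both beams
            else:
                B_theta = B_r
                B_phi = B_r
            per_axis = np.stack((B_r, B_theta, B_phi))  # (3, n_sensors, 3)
            matrix[:, j, o] = np.einsum(
                "ck,ck->c", per_axis[chan_k, chan_i, :], chan_axes
            )

    return LeadField(
        matrix=matrix,
        channel_sensor=np.array([i for i, _ in pairs]),
        channel_axis=_AXIS_NAMES[[k for _, k in pairs]],
        source_positions=src.positions.copy(),
    )
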