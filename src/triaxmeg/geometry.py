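"""Head/array geometry: sphere fitting, equidistant sensor placement,
local radial/polar/azimuth frames, and eroded source surfaces.

Conventions: right-handed head-centred coordinates in metres; the polar
angle theta is measured from the +z (vertex) axis and the azimuth phi
from +x. The local frame at any point p relative to the sphere centre c
is (r_hat, theta_hat, phi_hat) with r_hat pointing outward.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GeometryError
from .io import DEFAULT_BEAM_OFFSET, HeadModel, SensorPose

__all__ = [
    "SensorArray",
    "SourceSpace",
    "fit_sphere",
    "equidistant_sphere_points",
    "build_sensor_array",
    "erode_source_surface",
    "local_frame",
]

#: default polar-angle cut below which sensors on the underside of the
#: sphere are discarded (radians); with the 77-point lattice a full
#: sphere retains 55 sensors, matching the scale of a practical array.
DEFAULT_CUT_POLAR_ANGLE = np.deg2rad(115.0)


@dataclass
class SensorArray:
    """A set of sensors with positions, frames and axis-enable masks.

    ``frames[i]`` rows are the sensitive axes of sensor *i* in the order
    (r_hat, theta_hat, phi_hat) with respect to the best-fit sphere.
    """

    positions: np.ndarray  # (n, 3) metres
    frames: np.ndarray  # (n, 3, 3)
    axis_mask: np.ndarray  # (n, 3) bool
    beam_offset: float = DEFAULT_BEAM_OFFSET

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.frames = np.asarray(self.frames, dtype=float).reshape(-1, 3, 3)
        self.axis_mask = np.atleast_2d(np.asarray(self.axis_mask, dtype=bool))

    @property
    def n_sensors(self) -> int:
        return self.positions.shape[0]

    @property
    def n_channels(self) -> int:
        return int(self.axis_mask.sum())

    def channel_index(self):
        """(sensor_index, axis_index) pairs in channel enumeration order.

        Channels are enumerated sensor-major, axes in frame-row order
        (r, theta, phi), skipping disabled axes.
        """
        pairs = []
        for i in range(self.n_sensors):
            for k in range(3):
                if self.axis_mask[i, k]:
                    pairs.append((i, k))
        return pairs

    def with_axes(self, selection: str) -> "SensorArray":
        """Return a copy restricted to an axis selection.

        ``selection`` is one of ``"r"``, ``"r+theta"``, ``"r+phi"``,
        ``"triaxial"``.
        """
        mask = axis_selection_mask(selection)
        return SensorArray(
            positions=self.positions.copy(),
            frames=self.frames.copy(),
            axis_mask=np.tile(mask, (self.n_sensors, 1)) & self.axis_mask,
            beam_offset=self.beam_offset,
        )

    def poses(self) -> list:
        return [
            SensorPose(
                position=self.positions[i],
                frame=self.frames[i],
                beam_offset=self.beam_offset,
                axis_mask=self.axis_mask[i],
            )
            for i in range(self.n_sensors)
        ]

    @classmethod
    def from_poses(cls, poses) -> "SensorArray":
        return cls(
            positions=np.array([p.position for p in poses]),
            frames=np.array([p.frame for p in poses]),
            axis_mask=np.array([p.axis_mask for p in poses]),
            beam_offset=poses[0].beam_offset if poses else DEFAULT_BEAM_OFFSET,
        )


def axis_selection_mask(selection: str) -> np.ndarray:
    table = {
        "r": (True, False, False),
        "r+theta": (True, True, False),
        "r+phi": (True, False, True),
        "triaxial": (True, True, True),
    }
    try:
        return np.array(table[selection], dtype=bool)
    except KeyError:
        raise GeometryError(
            f"unknown axis selection {selection!r}; expected one of {sorted(table)}"
        ) from None


@dataclass
class SourceSpace:
    """Candidate dipole locations with tangential source frames.

    ``frames[j]`` rows are (r_hat_s, theta_hat_s, phi_hat_s) at source
    *j* with respect to the best-fit sphere; dipoles are oriented along
    the two tangential rows.
    """

    positions: np.ndarray  # (m, 3) metres
    frames: np.ndarray  # (m, 3, 3)
    depth: float = 0.0  # metres below the brain surface

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.frames = np.asarray(self.frames, dtype=float).reshape(-1, 3, 3)

    @property
    def n_sources(self) -> int:
        return self.positions.shape[0]


def fit_sphere(points: np.ndarray):
    """Least-squares algebraic sphere fit.

    Solves ``|p|^2 = 2 c . p + (r^2 - |c|^2)`` for the centre ``c`` and
    radius ``r``. Returns ``(center, radius, rms_residual)`` where the
    residual is the rms radial distance of the points from the fitted
    sphere.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[0] < 4:
        raise GeometryError("sphere fit needs at least 4 points")
    A = np.column_stack([2.0 * points, np.ones(len(points))])
    b = np.sum(points**2, axis=1)
    # coplanar/degenerate clouds make the normal system rank-deficient
    if np.linalg.matrix_rank(A - A.mean(axis=0), tol=1e-9 * max(1.0, np.abs(A).max())) < 3:
        raise GeometryError("points are coplanar or otherwise degenerate")
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0:
        raise GeometryError("sphere fit produced a non-positive radius")
    radius = float(np.sqrt(r2))
    residual = float(np.sqrt(np.mean((np.linalg.norm(points - center, axis=1) - radius) ** 2)))
    return center, radius, residual


def equidistant_sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere.

    Fibonacci (golden-angle) lattice: points at z_i = 1 - (2i+1)/n,
    azimuth i * golden angle. Nearest-neighbour separations are within a
    constant factor of the hexagonal-packing ideal sqrt(8*pi/(sqrt(3) n)).
    """
    if n < 2:
        raise GeometryError("need at least 2 points")
    if n == 2:  # the lattice formula is poor at n=2; the optimum is exact
        return np.array([[0.0, 0.0, 1.0], [0.0, 0.0, -1.0]])
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    s = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def local_frame(points: np.ndarray, center: np.ndarray) -> np.ndarray:
    """(r_hat, theta_hat, phi_hat) frames at each point w.r.t. ``center``.

    theta_hat points toward increasing polar angle (away from +z),
    phi_hat toward increasing azimuth. At the poles, where the azimuth is
    undefined, phi = 0 is used.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    center = np.asarray(center, dtype=float).reshape(3)
    d = points - center
    r = np.linalg.norm(d, axis=1)
    if np.any(r <= 0):
        raise GeometryError("point coincides with the sphere centre")
    r_hat = d / r[:, None]
    cos_t = np.clip(r_hat[:, 2], -1.0, 1.0)
    sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 0.0, None))
    polar = sin_t > 1e-12
    cos_p = np.where(polar, r_hat[:, 0] / np.where(polar, sin_t, 1.0), 1.0)
    sin_p = np.where(polar, r_hat[:, 1] / np.where(polar, sin_t, 1.0), 0.0)
    theta_hat = np.column_stack([cos_t * cos_p, cos_t * sin_p, -sin_t])
    phi_hat = np.column_stack([-sin_p, cos_p, np.zeros_like(sin_p)])
    frames = np.stack([r_hat, theta_hat, phi_hat], axis=1)
    return frames


def build_sensor_array(
    head: HeadModel,
    n: int = 77,
    standoff: float = 6e-3,
    cut_polar_angle: float = DEFAULT_CUT_POLAR_ANGLE,
    beam_offset: float = DEFAULT_BEAM_OFFSET,
) -> SensorArray:
    """Place an OPM array around a head.

    ``n`` lattice points on the best-fit sphere are projected radially
    onto the scalp, the sensitive volume is put ``standoff`` metres above
    the scalp (6 mm: the cell sits inside the sensor housing), and
    points on the underside of the sphere (polar angle beyond
    ``cut_polar_angle``) are removed. Frames are (r, theta, phi) w.r.t.
    the best-fit sphere; all axes enabled.
    """
    head.validate()
    unit = equidistant_sphere_points(n)
    polar = np.arccos(np.clip(unit[:, 2], -1.0, 1.0))
    keep = polar <= cut_polar_angle
    unit = unit[keep]
    if unit.shape[0] == 0:
        raise GeometryError("cut_polar_angle removed every sensor")
    radius = head.scalp_radius + standoff
    positions = head.sphere_center + radius * unit
    frames = local_frame(positions, head.sphere_center)
    return SensorArray(
        positions=positions,
        frames=frames,
        axis_mask=np.ones((len(positions), 3), dtype=bool),
        beam_offset=beam_offset,
    )


def erode_source_surface(
    head: HeadModel, depth: float = 5e-3, spacing: float = 8e-3
) -> SourceSpace:
    """Quasi-uniform source shell ``depth`` metres below the brain surface.

    For the parametric spherical heads the 5 mm erosion of the brain
    volume reduces to shrinking the brain radius by ``depth``. The
    number of sources is set by the requested inter-source ``spacing``
    via the area estimate 4*pi*r^2 / spacing^2.
    """
    head.validate()
    if depth >= head.brain_radius:
        raise GeometryError("erosion depth exceeds the brain radius")
    r_src = head.brain_radius - depth
    n = max(2, int(round(4.0 * np.pi * r_src**2 / spacing**2)))
    unit = equidistant_sphere_points(n)
    positions = head.sphere_center + r_src * unit
    frames = local_frame(positions, head.sphere_center)
    return SourceSpace(positions=positions, frames=frames, depth=depth)
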