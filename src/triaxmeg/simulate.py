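"""Synthetic datasets for every analysis stage.

Four generator families:

* parametric head models for an adult, a 4-year-old and a 2-year-old
  (spherical scalp from the head circumference; brain a concentric
  sphere 15/10/5 mm deeper);
* the 25-slot saline-phantom experiment — a 7-Hz, 2-uA·m tangential
  current dipole in a 5.5-cm conducting sphere, recorded by triaxial
  sensors with optional placement perturbations (2 mm / 2 degrees) and
  white sensor noise;
* a 4 x 5 magnetocardiography grid over a PQRST-like free-space dipole,
  recorded sequentially with a stationary reference channel;
* 50-trial beta-band epochs from a single cortical source with
  movement-related desynchronisation, a post-movement rebound, and
  discrete amplitude bursts.

Every generator takes an explicit seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import ConfigurationError, DomainError
from .forward import CurrentDipole, dipole_field_freespace, dipole_field_sphere
from .geometry import SensorArray, local_frame
from .io import HeadModel, Recording, SensorPose

__all__ = [
    "PhantomTruth",
    "EpochSet",
    "make_head_model",
    "phantom_slot_poses",
    "make_phantom_truth",
    "make_phantom_recording",
    "make_cardiac_grid",
    "average_beat",
    "make_beta_epochs",
]

#: scalp circumference (m) and scalp-to-brain gap (m) per age group
HEAD_GEOMETRY = {
    "adult": (0.58, 0.015),
    "four_year": (0.50, 0.010),
    "two_year": (0.47, 0.005),
}

PHANTOM_RADIUS = 0.055  # saline sphere radius, m
PHANTOM_DIPOLE_MOMENT = 2e-6  # A·m (2 V through 10 kOhm across 1 cm)
PHANTOM_DRIVE_FREQ = 7.0  # Hz


def phantom_dipole_moment(
    voltage: float = 2.0, resistance: float = 1e4, separation: float = 0.01
) -> float:
    """Current-dipole moment of the driven phantom, A·m.

    The drive voltage across the series resistor sets the ionic current
    I = V/R; the moment is Q = I * d for electrode separation d.  The
    defaults (2 V, 10 kOhm, 1 cm) give 2e-6 A·m.
    """
    return voltage / resistance * separation


def phantom_head_model(radius: float = PHANTOM_RADIUS) -> HeadModel:
    """Conducting-sphere model of the saline phantom.

    The ``brain`` compartment here is just the dipole search volume,
    nominally 5 mm inside the saline boundary.
    """
    return HeadModel(
        sphere_center=np.zeros(3),
        sphere_radius=radius,
        scalp_radius=radius,
        brain_radius=radius - 0.005,
        scalp_brain_gap=0.005,
    )


def make_head_model(age: str) -> HeadModel:
    """Parametric spherical head for one of the three age groups.

    Scalp radius = circumference / (2 pi); the brain sphere is
    concentric, ``gap`` metres deeper (15 mm adult, 10 mm 4-year-old,
    5 mm 2-year-old).
    """
    try:
        circumference, gap = HEAD_GEOMETRY[age]
    except KeyError:
        raise ConfigurationError(
            f"unknown age {age!r}; expected one of {sorted(HEAD_GEOMETRY)}"
        ) from None
    scalp_r = circumference / (2.0 * np.pi)
    return HeadModel(
        sphere_center=np.zeros(3),
        sphere_radius=scalp_r,
        scalp_radius=scalp_r,
        brain_radius=scalp_r - gap,
        scalp_brain_gap=gap,
    )


# ---------------------------------------------------------------------------
# Phantom


@dataclass
class PhantomTruth:
    """Ground truth of a synthetic phantom run."""

    dipole: CurrentDipole
    drive_freq: float
    slot_poses_true: list
    slot_poses_perturbed: list
    noise_density: float
    seed: int | None

    def __post_init__(self):
        if self.drive_freq <= 0:
            raise ConfigurationError("drive_freq must be positive")


def phantom_slot_poses(
    n_slots: int = 25,
    radius: float = PHANTOM_RADIUS,
    standoff: float = 6e-3,
) -> list:
    """Quasi-uniform triaxial sensor slots over the upper hemisphere.

    A golden-angle lattice restricted to z > 0 puts ``n_slots`` cells at
    ``radius + standoff`` from the phantom centre, each with its local
    (r, theta, phi) frame and all three axes enabled.
    """
    i = np.arange(n_slots)
    z = 1.0 - (2.0 * i + 1.0) / (2.0 * n_slots)  # upper hemisphere only
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    s = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    unit = np.column_stack([s * np.cos(phi), s * np.sin(phi), z])
    positions = (radius + standoff) * unit
    frames = local_frame(positions, np.zeros(3))
    return [
        SensorPose(position=positions[k], frame=frames[k])
        for k in range(n_slots)
    ]


def _rotation_about(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    K = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    return np.eye(3) + np.sin(angle) * K + (1.0 - np.cos(angle)) * (K @ K)


def make_phantom_truth(
    n_slots: int = 25,
    radius: float = PHANTOM_RADIUS,
    standoff: float = 6e-3,
    dipole_depth: float = 0.03,
    moment: float = PHANTOM_DIPOLE_MOMENT,
    drive_freq: float = PHANTOM_DRIVE_FREQ,
    position_sigma: float = 2e-3,
    angle_error_deg: float = 2.0,
    noise_density: float = 15e-15,
    perturb: bool = True,
    seed: int | None = None,
) -> PhantomTruth:
    """Assemble the ground truth of a phantom run.

    The dipole sits ``dipole_depth`` below the surface in the upper left
    octant, oriented tangentially (along the local azimuth).  When
    ``perturb`` is set, each slot's position is jittered by an isotropic
    Gaussian of total rms ``position_sigma`` and its frame rotated by
    ``angle_error_deg`` about a random axis — the stated placement
    tolerance of sensors in the phantom slots.
    """
    if (perturb or noise_density > 0) and seed is None:
        raise ConfigurationError("perturbed/noisy phantom truth requires a seed")
    poses_true = phantom_slot_poses(n_slots=n_slots, radius=radius, standoff=standoff)

    u = np.array([-0.55, 0.25, 0.80])
    u /= np.linalg.norm(u)
    pos = (radius - dipole_depth) * u
    ori = local_frame(pos[None, :], np.zeros(3))[0, 2, :]  # azimuthal, tangential
    dipole = CurrentDipole(position=pos, moment=moment * ori)

    if perturb:
        rng = np.random.default_rng(seed)
        poses_pert = []
        for p in poses_true:
            dp = rng.normal(0.0, position_sigma / np.sqrt(3.0), 3)
            axis = rng.normal(size=3)
            R = _rotation_about(axis, np.deg2rad(angle_error_deg))
            poses_pert.append(
                SensorPose(
                    position=p.position + dp,
                    frame=p.frame @ R.T,
                    beam_offset=p.beam_offset,
                    axis_mask=p.axis_mask,
                )
            )
    else:
        poses_pert = [
            SensorPose(
                position=p.position.copy(),
                frame=p.frame.copy(),
                beam_offset=p.beam_offset,
                axis_mask=p.axis_mask,
            )
            for p in poses_true
        ]

    return PhantomTruth(
        dipole=dipole,
        drive_freq=drive_freq,
        slot_poses_true=poses_true,
        slot_poses_perturbed=poses_pert,
        noise_density=noise_density,
        seed=seed,
    )


def make_phantom_recording(
    truth: PhantomTruth,
    duration: float = 5.0,
    fs: float = 1200.0,
    phantom_radius: float = PHANTOM_RADIUS,
):
    """Simulate the phantom run described by ``truth``.

    Channel signals are the conducting-sphere field of the sinusoidally
    driven dipole, evaluated at the *perturbed* sensor poses (where the
    sensors physically sit) and projected on the perturbed axes, plus
    seeded white noise.  Returns ``(Recording, truth)``.
    """
    if np.linalg.norm(truth.dipole.position) >= phantom_radius:
        raise DomainError("dipole lies outside the phantom sphere")
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    drive = np.sin(2.0 * np.pi * truth.drive_freq * t)

    rows, meta_sensor, meta_axis = [], [], []
    for k, pose in enumerate(truth.slot_poses_perturbed):
        B = dipole_field_sphere(truth.dipole, pose.position[None, :])[0]
        for a, label in enumerate(("r", "theta", "phi")):
            if pose.axis_mask[a]:
                rows.append((B @ pose.frame[a]) * drive)
                meta_sensor.append(f"S{k:03d}")
                meta_axis.append(label)
    data = np.array(rows)

    if truth.noise_density > 0:
        rng = np.random.default_rng(
            None if truth.seed is None else truth.seed + 1
        )
        data = data + rng.normal(
            0.0, truth.noise_density * np.sqrt(fs / 2.0), data.shape
        )

    rec = Recording(
        data=data,
        fs=fs,
        channel_meta=pd.DataFrame(
            {"sensor_id": meta_sensor, "axis_label": meta_axis}
        ),
    )
    rec.validate()
    return rec, truth


# ---------------------------------------------------------------------------
# Cardiac grid

#: PQRST template: (delay re R-peak s, Gaussian sigma s, relative amplitude)
PQRST_COMPONENTS = (
    (-0.200, 0.025, 0.15),  # P
    (-0.025, 0.010, -0.15),  # Q
    (0.000, 0.012, 1.00),  # R
    (0.025, 0.010, -0.25),  # S
    (0.250, 0.040, 0.35),  # T
)


def _pqrst_waveform(t: np.ndarray, beat_times: np.ndarray) -> np.ndarray:
    """Sum-of-Gaussians PQRST moment time course (dimensionless, R = 1)."""
    w = np.zeros_like(t)
    for t_b in beat_times:
        for delay, sigma, amp in PQRST_COMPONENTS:
            w += amp * np.exp(-0.5 * ((t - t_b - delay) / sigma) ** 2)
    return w


def make_cardiac_grid(
    n_rows: int = 4,
    n_cols: int = 5,
    extent: float = 0.20,
    beat_rate: float = 1.2,
    n_beats: int = 12,
    fs: float = 1200.0,
    moment: float = 20e-6,
    heart_depth: float = 0.10,
    noise_density: float = 1e-13,
    seed: int | None = None,
):
    """Sequential triaxial recordings over a 4 x 5 chest grid.

    A free-space current dipole at ``heart_depth`` behind the grid
    plane, with its dominant (QRS) moment along the grid's x direction,
    is driven by a PQRST Gaussian-sum template at ``beat_rate``.  Each
    grid position is "visited" in turn for ``n_beats / beat_rate``
    seconds; a stationary reference channel spans the whole session and
    carries the R-peak events.

    Returns ``(recordings, reference, truth)`` where ``recordings`` is
    one triaxial Recording per grid position (time offsets ``t0`` encode
    the sequential acquisition) and ``truth`` holds dipole and beat
    times.
    """
    if noise_density > 0 and seed is None:
        raise ConfigurationError("noisy cardiac simulation requires a seed")
    rng = np.random.default_rng(seed)

    seg_dur = n_beats / beat_rate
    n_seg = int(round(seg_dur * fs))
    n_pos = n_rows * n_cols
    total = n_pos * n_seg

    xs = np.linspace(-extent / 2.0, extent / 2.0, n_cols)
    ys = np.linspace(-extent / 2.0, extent / 2.0, n_rows)
    grid = np.array([(x, y, 0.0) for y in ys for x in xs])

    dipole_pos = np.array([0.0, 0.0, -heart_depth])
    # dominant current flow along x, slight tilt for realism
    ori = np.array([1.0, 0.12, 0.05])
    ori /= np.linalg.norm(ori)

    t_all = np.arange(total) / fs
    # beats at the nominal rate with a small seeded timing jitter
    beat_times = []
    t_b = 0.45
    while t_b < t_all[-1] - 0.5:
        beat_times.append(t_b + rng.normal(0.0, 0.01))
        t_b += 1.0 / beat_rate
    beat_times = np.asarray(beat_times)
    waveform = _pqrst_waveform(t_all, beat_times)

    sigma = noise_density * np.sqrt(fs / 2.0)
    axes = np.eye(3)  # sensors aligned with the board axes
    recordings = []
    for p in range(n_pos):
        sl = slice(p * n_seg, (p + 1) * n_seg)
        B = dipole_field_freespace(
            CurrentDipole(position=dipole_pos, moment=moment * ori),
            grid[p][None, :],
        )[0]
        data = np.outer(B @ axes.T, waveform[sl])
        if sigma > 0:
            data = data + rng.normal(0.0, sigma, data.shape)
        recordings.append(
            Recording(
                data=data,
                fs=fs,
                channel_meta=pd.DataFrame(
                    {
                        "sensor_id": [f"G{p:02d}"] * 3,
                        "axis_label": ["x", "y", "z"],
                    }
                ),
                t0=p * seg_dur,
            )
        )

    # stationary chest reference: close to the heart, carries R events
    ref_gain = 5e-10  # tesla per unit template at the chest sensor
    ref_data = (ref_gain * waveform)[None, :]
    if sigma > 0:
        ref_data = ref_data + rng.normal(0.0, sigma, ref_data.shape)
    r_samples = np.round(beat_times * fs).astype(int)
    reference = Recording(
        data=ref_data,
        fs=fs,
        channel_meta=pd.DataFrame({"sensor_id": ["REF"], "axis_label": ["y"]}),
        events=[(int(s), "R") for s in r_samples],
    )
    truth = {
        "dipole_position": dipole_pos,
        "dipole_orientation": ori,
        "moment": moment,
        "beat_times": beat_times,
        "grid_positions": grid,
        "seed": seed,
    }
    return recordings, reference, truth


def average_beat(recordings, reference, window=(-0.4, 0.6)):
    """Realign sequential grid recordings on the reference R-peaks and
    average over beats.

    Returns ``(avg, times, channel_meta)`` where ``avg`` has one row per
    grid channel (n_positions x 3) and ``times`` is relative to the
    R-peak.
    """
    fs = reference.fs
    i0 = int(round(window[0] * fs))
    i1 = int(round(window[1] * fs))
    n_win = i1 - i0
    r_samples = np.array([s for s, label in reference.events if label == "R"])

    rows, sensor_ids, axis_labels = [], [], []
    for rec in recordings:
        start = int(round(rec.t0 * fs))
        local = r_samples - start
        local = local[(local + i0 >= 0) & (local + i1 <= rec.n_samples)]
        segs = np.stack([rec.data[:, s + i0 : s + i1] for s in local])
        avg = segs.mean(axis=0)
        rows.append(avg)
        sensor_ids.extend(rec.channel_meta["sensor_id"])
        axis_labels.extend(rec.channel_meta["axis_label"])
    avg = np.vstack(rows)
    times = (np.arange(n_win) + i0) / fs
    meta = pd.DataFrame({"sensor_id": sensor_ids, "axis_label": axis_labels})
    return avg, times, meta


# ---------------------------------------------------------------------------
# Beta epochs


@dataclass
class EpochSet:
    """Trial-segmented sensor data with full generative ground truth."""

    epochs: np.ndarray  # (n_trials, n_channels, n_samples), tesla
    fs: float
    window: tuple  # (start, end) seconds relative to onset
    channel_sensor: np.ndarray
    channel_axis: np.ndarray
    truth: dict = field(default_factory=dict)

    def __post_init__(self):
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ConfigurationError("epochs must be (trials, channels, samples)")
        if self.epochs.shape[0] < 1:
            raise ConfigurationError("need at least one trial")

    @property
    def n_trials(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]

    @property
    def n_samples(self) -> int:
        return self.epochs.shape[2]

    @property
    def times(self) -> np.ndarray:
        return self.window[0] + np.arange(self.n_samples) / self.fs


def _band_limited_noise(rng, n, fs, band):
    """Unit-variance Gaussian noise band-limited to ``band`` (Hz)."""
    lo, hi = band
    if not 0 < lo < hi < fs / 2.0:
        raise ConfigurationError(f"band {band} not inside (0, fs/2)")
    x = rng.standard_normal(n)
    sos = sps.butter(4, [lo, hi], btype="band", fs=fs, output="sos")
    y = sps.sosfiltfilt(sos, x)
    return y / y.std()


def _smooth_envelope(t, segments, fs, smooth_s=0.1):
    """Piecewise-constant envelope (list of (start, end, value), baseline
    1 elsewhere) smoothed by a Gaussian kernel."""
    env = np.ones_like(t)
    for start, end, value in segments:
        env[(t >= start) & (t < end)] = value
    n_k = int(round(6 * smooth_s * fs)) | 1
    k = np.exp(-0.5 * ((np.arange(n_k) - n_k // 2) / (smooth_s * fs)) ** 2)
    k /= k.sum()
    pad = n_k // 2
    padded = np.concatenate([np.full(pad, env[0]), env, np.full(pad, env[-1])])
    return np.convolve(padded, k, mode="valid")


def make_beta_epochs(
    head: HeadModel,
    array: SensorArray,
    source_position: np.ndarray,
    source_orientation: np.ndarray,
    n_trials: int = 50,
    fs: float = 1200.0,
    band=(13.0, 30.0),
    window=(-1.0, 4.0),
    desync_window=(0.2, 1.2),
    rebound_window=(1.5, 2.5),
    desync_depth: float = 0.5,
    rebound_gain: float = 1.5,
    burst_rate: float = 0.4,
    burst_amp=(3.0, 5.0),
    burst_sigma: float = 0.05,
    moment_rms: float = 10e-9,
    noise_density: float = 15e-15,
    seed: int | None = None,
) -> EpochSet:
    """Simulate a 50-trial movement-task beta experiment.

    The source time course is band-limited Gaussian noise multiplied by
    a deterministic envelope — baseline 1, ``desync_depth`` during the
    movement window, ``rebound_gain`` during the rebound window — plus
    discrete bursts at Poisson times (Gaussian amplitude window of
    ``burst_sigma`` s, amplitude 3-5 x baseline).  The source (moment
    rms ``moment_rms`` A·m) is projected through the conducting-sphere
    forward model onto every enabled channel of ``array``; white sensor
    noise of ``noise_density`` T/rtHz is added.

    Truth records the source pose, per-trial envelope, and burst times.
    """
    if burst_rate < 0 or desync_depth < 0 or rebound_gain < 0:
        raise ConfigurationError("rates/gains must be non-negative")
    if seed is None:
        raise ConfigurationError("epoch simulation requires a seed")
    source_position = np.asarray(source_position, dtype=float).reshape(3)
    source_orientation = np.asarray(source_orientation, dtype=float).reshape(3)
    source_orientation = source_orientation / np.linalg.norm(source_orientation)
    if (
        np.linalg.norm(source_position - head.sphere_center)
        >= head.brain_radius
    ):
        raise DomainError("source lies outside the brain")

    rng = np.random.default_rng(seed)
    n = int(round((window[1] - window[0]) * fs))
    t = window[0] + np.arange(n) / fs

    # per-channel gains of a unit dipole at the source
    dipole = CurrentDipole(position=source_position, moment=source_orientation)
    pairs = array.channel_index()
    B = dipole_field_sphere(dipole, array.positions, center=head.sphere_center)
    gains = np.array([B[i] @ array.frames[i, k, :] for i, k in pairs])

    env_base = _smooth_envelope(
        t,
        [
            (desync_window[0], desync_window[1], desync_depth),
            (rebound_window[0], rebound_window[1], rebound_gain),
        ],
        fs,
    )

    sigma_noise = noise_density * np.sqrt(fs / 2.0)
    epochs = np.empty((n_trials, len(pairs), n))
    burst_times = []
    envelopes = np.empty((n_trials, n))
    source_tcs = np.empty((n_trials, n))
    margin = 0.3  # keep bursts clear of the trial edges
    for trial in range(n_trials):
        carrier = _band_limited_noise(rng, n, fs, band)
        env = env_base.copy()
        n_bursts = rng.poisson(burst_rate * (window[1] - window[0] - 2 * margin))
        times_b = np.sort(
            rng.uniform(window[0] + margin, window[1] - margin, n_bursts)
        )
        for t_b in times_b:
            amp = rng.uniform(*burst_amp)
            env = env + amp * np.exp(-0.5 * ((t - t_b) / burst_sigma) ** 2)
        burst_times.append(times_b)
        envelopes[trial] = env
        source_tc = moment_rms * carrier * env
        source_tcs[trial] = source_tc
        epochs[trial] = gains[:, None] * source_tc[None, :]
        if sigma_noise > 0:
            epochs[trial] += rng.normal(0.0, sigma_noise, epochs[trial].shape)

    return EpochSet(
        epochs=epochs,
        fs=fs,
        window=window,
        channel_sensor=np.array([i for i, _ in pairs]),
        channel_axis=np.array(["r", "theta", "phi"])[[k for _, k in pairs]],
        truth={
            "source_position": source_position,
            "source_orientation": source_orientation,
            "moment_rms": moment_rms,
            "band": tuple(band),
            "desync_window": tuple(desync_window),
            "rebound_window": tuple(rebound_window),
            "desync_depth": desync_depth,
            "rebound_gain": rebound_gain,
            "burst_times": burst_times,
            "envelopes": envelopes,
            "source_timecourses": source_tcs,
            "noise_density": noise_density,
            "seed": seed,
        },
    )
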