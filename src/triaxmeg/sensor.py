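"""Dual-beam triaxial OPM readout simulation.

A zero-field OPM infers the local field from the transmission of
circularly polarised light through an alkali vapour under a sinusoidal
modulation field.  The demodulated (lock-in) response to a field B
perpendicular to a beam is the dispersive Lorentzian

    r(B) = gain0 * (gamma B tau) / (1 + (gamma B tau)^2),

linear near B = 0 with slope gain0 * gamma * tau.  The triaxial sensor
runs two orthogonal beams through one cell: beam 1 senses x and y, beam
2 senses y and z.  The y modulation is 90 degrees out of phase with the
x/z modulation, so phase-sensitive detection at the modulation frequency
separates the in-phase (y) and quadrature (x or z) channels of each
photodetector; the two y estimates are averaged.

The cell is treated as a point here; the spatial offset between the two
beams enters the forward model (:mod:`triaxmeg.forward`), not the
readout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import CalibrationError, ConfigurationError

__all__ = [
    "OPMPhysicsConfig",
    "TriaxOutput",
    "lockin_response",
    "simulate_triax_readout",
    "crosstalk_calibration",
]

#: effective gyromagnetic ratio of the 87Rb ground state, rad s^-1 T^-1
#: (g_F mu_B / hbar with g_F = 1/2; ~7 Hz/nT).
GAMMA_RB87 = 4.397e10


@dataclass
class OPMPhysicsConfig:
    """Physical constants of the readout.

    tau is the polarisation relaxation time (~3 ms coherence time);
    B1 the modulation amplitude; gain0 a lumped dimensionless constant
    absorbing the equilibrium polarisation and the two Bessel-function
    factors J0(gamma B1 / (2 pi f_mod)) * J1(...), which are constants
    for fixed modulation parameters.  noise_density is the white output
    noise per axis in T/sqrt(Hz); the defaults are the measured floors
    of the triaxial sensor this module emulates.
    """

    gamma: float = GAMMA_RB87
    tau: float = 3e-3
    f_mod: float = 1000.0
    B1: float = 1.4e-7
    gain0: float = 1.0
    noise_density: tuple = (13.5e-15, 9.9e-15, 14.9e-15)

    def __post_init__(self):
        if self.tau <= 0 or self.f_mod <= 0:
            raise ConfigurationError("tau and f_mod must be positive")
        if any(n < 0 for n in self.noise_density):
            raise ConfigurationError("noise_density must be >= 0")


@dataclass
class TriaxOutput:
    """Demodulated field estimates (tesla, per sample).

    ``by`` is the unweighted mean of the two beams' y estimates, which
    are kept (noise-free) in ``by_beam1``/``by_beam2`` for diagnostics.
    """

    bx: np.ndarray
    by: np.ndarray
    bz: np.ndarray
    by_beam1: np.ndarray = None
    by_beam2: np.ndarray = None
    raw_v1: np.ndarray = None
    raw_v2: np.ndarray = None


def lockin_response(B, cfg: OPMPhysicsConfig):
    """Demodulated response to a static perpendicular field B (tesla).

    Odd in B, bounded by gain0/2, maximal at gamma*B*tau = 1.
    """
    x = cfg.gamma * np.asarray(B, dtype=float) * cfg.tau
    return cfg.gain0 * x / (1.0 + x**2)


def _demod_lowpass(x: np.ndarray, fs: float, f_mod: float) -> np.ndarray:
    """Post-demodulation filter: 4th-order Butterworth at f_mod/5,
    applied forward-backward (zero phase)."""
    sos = sps.butter(4, f_mod / 5.0, btype="low", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def simulate_triax_readout(
    field_txs: np.ndarray,
    cfg: OPMPhysicsConfig,
    fs: float,
    seed: int | None = None,
) -> TriaxOutput:
    """Simulate the full modulation/demodulation chain.

    Parameters
    ----------
    field_txs : ndarray, shape (3, n_samples)
        True (bx, by, bz) field at the cell, tesla.
    fs : float
        Simulation rate in Hz; must exceed 4 * f_mod so the modulation
        sidebands are resolvable.
    seed : int or None
        Seed for the white output noise.  Required whenever any axis has
        a nonzero noise density (stochastic stages never run unseeded).

    Returns
    -------
    TriaxOutput
        Field estimates in tesla, obtained by synthesising both
        photodetector traces, phase-sensitive detection at f_mod with 0
        and 90 degree references, low-pass filtering, and inversion of
        the small-signal gain gain0 * gamma * tau / ... (the in-phase
        demodulated product of two unit sinusoids averages to 1/2, which
        the reference amplitude of 2 restores).
    """
    field_txs = np.asarray(field_txs, dtype=float)
    if field_txs.ndim != 2 or field_txs.shape[0] != 3:
        raise ConfigurationError("field must have shape (3, n_samples)")
    if fs <= 4.0 * cfg.f_mod:
        raise ConfigurationError(
            f"fs = {fs} Hz cannot resolve demodulation at f_mod = {cfg.f_mod} Hz"
        )
    if any(n > 0 for n in cfg.noise_density) and seed is None:
        raise ConfigurationError("noisy readout simulation requires a seed")

    bx, by, bz = field_txs
    n = field_txs.shape[1]
    t = np.arange(n) / fs
    ref0 = np.sin(2.0 * np.pi * cfg.f_mod * t)  # y modulation phase
    ref90 = np.cos(2.0 * np.pi * cfg.f_mod * t)  # x and z modulation phase

    # photodetector traces: superpositions of the two in-quadrature
    # dispersive responses each beam is sensitive to
    v1 = lockin_response(by, cfg) * ref0 + lockin_response(bx, cfg) * ref90
    v2 = lockin_response(by, cfg) * ref0 + lockin_response(bz, cfg) * ref90

    slope = cfg.gain0 * cfg.gamma * cfg.tau  # small-signal gain, 1/T

    def demod(v, ref):
        return _demod_lowpass(2.0 * v * ref, fs, cfg.f_mod) / slope

    bx_est = demod(v1, ref90)
    by1 = demod(v1, ref0)
    by2 = demod(v2, ref0)
    bz_est = demod(v2, ref90)
    by_est = 0.5 * (by1 + by2)

    if any(nd > 0 for nd in cfg.noise_density):
        rng = np.random.default_rng(seed)
        sigma = np.asarray(cfg.noise_density) * np.sqrt(fs / 2.0)
        bx_est = bx_est + rng.normal(0.0, sigma[0], n)
        by_est = by_est + rng.normal(0.0, sigma[1], n)
        bz_est = bz_est + rng.normal(0.0, sigma[2], n)

    return TriaxOutput(
        bx=bx_est,
        by=by_est,
        bz=bz_est,
        by_beam1=by1,
        by_beam2=by2,
        raw_v1=v1,
        raw_v2=v2,
    )


def crosstalk_calibration(measured_response: np.ndarray) -> np.ndarray:
    """Three-pulse crosstalk correction.

    ``measured_response[i, j]`` is the output on axis i per unit test
    pulse applied on coil axis j.  The correction matrix is its inverse:
    applying it to subsequent readouts removes both gain and orientation
    errors caused by inter-sensor modulation-field crosstalk.
    """
    m = np.asarray(measured_response, dtype=float).reshape(3, 3)
    cond = np.linalg.cond(m)
    if not np.isfinite(cond) or cond >= 1e6:
        raise CalibrationError(
            f"crosstalk response is ill-conditioned (cond = {cond:.3g})"
        )
    return np.linalg.inv(m)
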