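"""Spectral analysis: noise-floor ASD, time-frequency spectra, and the
windowed SNR metrics used for the cardiac and child recordings.

The noise floor is characterised as a median amplitude spectral density:
the record is cut into non-overlapping 10-s windows, a flattop-windowed
periodogram PSD is computed per window (0.1 Hz resolution at 10 s), and
the median across windows taken — robust to transients in any single
window.  ASD = sqrt(PSD), reported in fT/sqrt(Hz) (1 T = 1e15 fT).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import ConfigurationError
from .io import Recording
from .simulate import EpochSet

__all__ = [
    "SpectrumSet",
    "TFS",
    "median_asd",
    "default_tfs_bands",
    "tfs",
    "snr_windowed",
    "snr_cardiac",
]

T_TO_FT = 1e15  # tesla -> femtotesla


@dataclass
class SpectrumSet:
    """Per-channel amplitude spectral density in fT/sqrt(Hz)."""

    freqs: np.ndarray  # Hz
    asd: np.ndarray  # (n_channels, n_freqs), fT/sqrt(Hz)
    window_count: int

    def band_mean(self, lo: float, hi: float, exclude=None) -> np.ndarray:
        """Mean ASD per channel over [lo, hi] Hz, optionally excluding a
        sub-band (e.g. mains interference around 50 Hz)."""
        sel = (self.freqs >= lo) & (self.freqs <= hi)
        if exclude is not None:
            sel &= ~((self.freqs >= exclude[0]) & (self.freqs <= exclude[1]))
        return self.asd[:, sel].mean(axis=1)


@dataclass
class TFS:
    """Trial-averaged time-frequency spectrum of one channel:
    fractional amplitude change versus baseline per band and sample."""

    band_centers: np.ndarray  # Hz
    times: np.ndarray  # s relative to trial onset
    amplitude_change: np.ndarray  # (n_bands, n_samples)


def median_asd(
    rec: Recording, window_s: float = 10.0, f_max: float = 100.0
) -> SpectrumSet:
    """Median flattop-periodogram amplitude spectral density.

    Non-overlapping ``window_s`` windows; frequency resolution
    1/window_s (0.1 Hz at the 10-s default); output restricted to
    [0, f_max] Hz.
    """
    if rec.duration < window_s:
        raise ConfigurationError(
            f"recording ({rec.duration:.1f} s) shorter than one "
            f"{window_s:.0f}-s window"
        )
    nper = int(round(window_s * rec.fs))
    n_win = rec.n_samples // nper
    # median across non-overlapping flattop periodograms, with the
    # chi-square median bias correction so white noise is estimated
    # without the sqrt(ln 2) downward bias of a raw median
    freqs, psd_med = sps.welch(
        rec.data[:, : n_win * nper],
        fs=rec.fs,
        window="flattop",
        nperseg=nper,
        noverlap=0,
        scaling="density",
        average="median",
        detrend=False,
        axis=-1,
    )
    sel = freqs <= f_max
    return SpectrumSet(
        freqs=freqs[sel],
        asd=np.sqrt(psd_med[:, sel]) * T_TO_FT,
        window_count=n_win,
    )


def default_tfs_bands(lo: float = 2.0, hi: float = 48.0, step: float = 2.0, width: float = 4.0):
    """Overlapping bands: centres ``lo..hi`` in ``step`` Hz steps, each
    ``width`` Hz wide."""
    centers = np.arange(lo, hi + step / 2.0, step)
    return [(max(c - width / 2.0, 0.5), c + width / 2.0) for c in centers]


def _band_envelope(x: np.ndarray, fs: float, band) -> np.ndarray:
    """Zero-phase bandpass + analytic-signal magnitude along the last axis."""
    lo, hi = band
    if not 0 < lo < hi < fs / 2.0:
        raise ConfigurationError(f"band {band} outside (0, Nyquist)")
    sos = sps.butter(4, [lo, hi], btype="band", fs=fs, output="sos")
    filtered = sps.sosfiltfilt(sos, x, axis=-1)
    return np.abs(sps.hilbert(filtered, axis=-1))


def tfs(
    epochs: EpochSet,
    bands=None,
    baseline_window=None,
    channel: int = 0,
) -> TFS:
    """Trial-averaged time-frequency spectrum of one channel.

    Per band: zero-phase bandpass, Hilbert envelope, trial mean, then
    fractional change relative to the baseline mean (full-epoch mean
    when no ``baseline_window`` is given).
    """
    if bands is None:
        bands = default_tfs_bands()
    t = epochs.times
    if baseline_window is not None:
        base_sel = (t >= baseline_window[0]) & (t < baseline_window[1])
        if not base_sel.any():
            raise ConfigurationError("baseline window outside the epoch")
    else:
        base_sel = np.ones_like(t, dtype=bool)

    x = epochs.epochs[:, channel, :]  # (trials, samples)
    rows = []
    for band in bands:
        env = _band_envelope(x, epochs.fs, band).mean(axis=0)
        base = env[base_sel].mean()
        rows.append((env - base) / base)
    return TFS(
        band_centers=np.array([(lo + hi) / 2.0 for lo, hi in bands]),
        times=t,
        amplitude_change=np.array(rows),
    )


def snr_windowed(
    epochs: EpochSet,
    band=(10.0, 20.0),
    signal_window=(-0.5, 0.5),
    noise_window=(2.5, 3.5),
) -> np.ndarray:
    """Per-channel oscillatory SNR.

    Signal: |mean band envelope in ``signal_window`` minus mean in
    ``noise_window``|; noise: standard deviation of the trial-averaged
    band envelope within ``noise_window``.  Channels whose noise window
    has zero variance get NaN (undefined SNR).
    """
    t = epochs.times
    s1 = (t >= signal_window[0]) & (t < signal_window[1])
    s2 = (t >= noise_window[0]) & (t < noise_window[1])
    if not s1.any() or not s2.any():
        raise ConfigurationError("SNR windows fall outside the epoch")
    snr = np.empty(epochs.n_channels)
    for c in range(epochs.n_channels):
        env = _band_envelope(epochs.epochs[:, c, :], epochs.fs, band).mean(axis=0)
        sd = env[s2].std()
        if sd == 0:
            snr[c] = np.nan
            continue
        snr[c] = np.abs(env[s1].mean() - env[s2].mean()) / sd
    return snr


def snr_cardiac(
    avg_beat: np.ndarray,
    times: np.ndarray,
    qrs_window=(-0.05, 0.05),
    tp_window=(0.40, 0.70),
) -> np.ndarray:
    """Per-channel cardiac SNR: peak |signal| within the QRS window
    divided by the standard deviation within the (quiescent) TP
    interval.  Zero-variance TP windows yield NaN."""
    avg_beat = np.atleast_2d(np.asarray(avg_beat, dtype=float))
    times = np.asarray(times, dtype=float)
    qrs = (times >= qrs_window[0]) & (times < qrs_window[1])
    tp = (times >= tp_window[0]) & (times < tp_window[1])
    if not qrs.any() or not tp.any():
        raise ConfigurationError("QRS/TP windows fall outside the beat epoch")
    peak = np.max(np.abs(avg_beat[:, qrs]), axis=1)
    sd = np.std(avg_beat[:, tp], axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = np.where(sd > 0, peak / sd, np.nan)
    return snr
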