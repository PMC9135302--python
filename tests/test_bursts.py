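"""Burst detection, phase alignment, and burst-peak field snapshots."""

import numpy as np
import pytest

from triaxmeg.bursts import (
    align_average_bursts,
    burst_raster,
    detect_bursts,
    field_at_burst_peak,
)
from triaxmeg.errors import ConfigurationError
from triaxmeg.forward import CurrentDipole, dipole_field_sphere


class TestDetectBursts:
    def test_constant_envelope_yields_no_bursts(self):
        bs = detect_bursts(np.ones(1000))
        assert bs.n_bursts == 0

    def test_intervals_supra_threshold_and_disjoint(self):
        rng = np.random.default_rng(0)
        env = np.abs(rng.normal(1.0, 0.2, 5000))
        env[1000:1050] += 3.0
        env[3000:3060] += 2.5
        bs = detect_bursts(env)
        prev_end = -1
        for (s, e), p in zip(bs.intervals, bs.peak_samples):
            assert s > prev_end
            prev_end = e
            assert np.all(env[s:e] > bs.threshold)
            assert s <= p < e
            if s > 0:
                assert env[s - 1] <= bs.threshold
            if e < env.size:
                assert env[e] <= bs.threshold

    def test_injected_bursts_recovered(self):
        """>= 9 of 10 injected 5-sd bumps recovered on average with
        interval Jaccard > 0.5 and <= 2 false detections, over 20
        seeds.  The baseline is a smooth (band-limited) envelope, as a
        Hilbert amplitude is in practice."""
        from scipy import signal as sps

        fs = 600.0
        hits_all, fps_all = [], []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = int(fs * 120)
            sos = sps.butter(4, 4.0, fs=fs, output="sos")
            slow = sps.sosfiltfilt(sos, rng.standard_normal(n))
            env = np.clip(1.0 + 0.08 * slow / slow.std(), 0.0, None)
            sd0 = env.std()
            sig = 0.07 * fs
            truth = []
            for k in range(10):
                c = int(fs * 3 + k * fs * 11.5)
                window = np.arange(int(c - 4 * sig), int(c + 4 * sig))
                env[window] += 5.0 * sd0 * np.exp(-0.5 * ((window - c) / sig) ** 2)
                truth.append((int(c - 0.9 * sig), int(c + 0.9 * sig)))
            bs = detect_bursts(env, k=3.0)
            hits = 0
            matched = set()
            for ts, te in truth:
                best, best_i = 0.0, None
                for bi, (s, e) in enumerate(bs.intervals):
                    inter = max(0, min(te, e) - max(ts, s))
                    union = max(te, e) - min(ts, s)
                    if inter / union > best:
                        best, best_i = inter / union, bi
                if best > 0.5:
                    hits += 1
                    matched.add(best_i)
            hits_all.append(hits)
            fps_all.append(bs.n_bursts - len(matched))
        assert np.mean(hits_all) >= 9
        assert np.mean(fps_all) <= 2

    def test_threshold_monotone_in_k(self):
        rng = np.random.default_rng(3)
        env = np.abs(rng.normal(1.0, 0.3, 20000))
        counts = [detect_bursts(env, k=k).n_bursts for k in (2.0, 3.0, 4.0, 5.0)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_negative_envelope_rejected(self):
        with pytest.raises(ConfigurationError):
            detect_bursts(np.array([-1.0, 0.0, 1.0]))


class TestAlignment:
    FS = 600.0

    def _cosine_burst_train(self, n_bursts=5, f=20.0, identical=True, seed=0):
        rng = np.random.default_rng(seed)
        n = int(self.FS * (2.0 * n_bursts + 2.0))
        t = np.arange(n) / self.FS
        tc = np.zeros(n)
        centers = 1.0 + 2.0 * np.arange(n_bursts)
        for c in centers:
            phase = 0.0 if identical else rng.uniform(0, 2 * np.pi)
            tc += np.exp(-0.5 * ((t - c) / 0.08) ** 2) * np.cos(
                2 * np.pi * f * (t - c) + phase
            )
        return tc

    def test_identical_bursts_average_equals_single(self):
        tc = self._cosine_burst_train(identical=True)
        env = np.abs(tc)
        from scipy.signal import hilbert

        env = np.abs(hilbert(tc))
        bs = detect_bursts(env, k=2.0)
        assert bs.n_bursts == 5
        out = align_average_bursts(tc, bs, self.FS, half_window_s=0.2)
        hw = int(0.2 * self.FS)
        single = tc[out.aligned_samples[0] - hw : out.aligned_samples[0] + hw + 1]
        np.testing.assert_allclose(out.average_timecourse, single, atol=1e-10)

    def test_aligned_average_peaks_at_center(self):
        tc = self._cosine_burst_train(identical=True)
        from scipy.signal import hilbert

        bs = detect_bursts(np.abs(hilbert(tc)), k=2.0)
        out = align_average_bursts(tc, bs, self.FS, half_window_s=0.2)
        center = out.average_timecourse.size // 2
        assert np.argmax(out.average_timecourse) == center

    def test_alignment_near_envelope_peak(self):
        tc = self._cosine_burst_train(identical=False, seed=4)
        from scipy.signal import hilbert

        bs = detect_bursts(np.abs(hilbert(tc)), k=2.0)
        out = align_average_bursts(tc, bs, self.FS, half_window_s=0.2)
        period = self.FS / 20.0
        for align, peak in zip(out.aligned_samples, bs.peak_samples):
            assert abs(align - peak) <= period + 1

    def test_phase_alignment_beats_peak_alignment(self):
        """Random-phase bursts: phase-aligned averaging preserves the
        carrier; envelope-peak alignment averages incoherently."""
        from scipy.signal import hilbert

        gains = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n_bursts = 50
            fs = self.FS
            n = int(fs * (n_bursts + 2))
            t = np.arange(n) / fs
            tc = np.zeros(n)
            centers = 1.0 + np.arange(n_bursts)
            for c in centers:
                tc += np.exp(-0.5 * ((t - c) / 0.08) ** 2) * np.cos(
                    2 * np.pi * 20.0 * (t - c) + rng.uniform(0, 2 * np.pi)
                )
            bs = detect_bursts(np.abs(hilbert(tc)), k=2.0)
            out = align_average_bursts(tc, bs, fs, half_window_s=0.2)
            hw = int(0.2 * fs)
            unaligned = np.mean(
                [
                    tc[p - hw : p + hw + 1]
                    for p in bs.peak_samples
                    if p - hw >= 0 and p + hw + 1 <= n
                ],
                axis=0,
            )
            gains.append(
                np.max(np.abs(out.average_timecourse)) / np.max(np.abs(unaligned))
            )
        assert np.mean(gains) >= 2.0

    def test_no_bursts_rejected(self):
        bs = detect_bursts(np.ones(100))
        with pytest.raises(ConfigurationError):
            align_average_bursts(np.ones(100), bs, self.FS)


class TestBurstRaster:
    def test_shape_and_thresholding(self):
        rng = np.random.default_rng(0)
        env = np.abs(rng.normal(1, 0.1, (5, 1000)))
        env[2, 300:320] += 5.0
        raster = burst_raster(env)
        assert raster.shape == (5, 1000)
        assert raster[2, 305]
        assert raster.mean() < 0.05


class TestFieldAtBurstPeak:
    def _array(self, phantom_array):
        return phantom_array

    def test_zero_data_gives_zero_vectors(self, phantom_array):
        data = np.zeros((phantom_array.n_channels, 100))
        pairs = phantom_array.channel_index()
        vec, kept = field_at_burst_peak(
            data,
            np.array([i for i, _ in pairs]),
            np.array(["r", "theta", "phi"] * phantom_array.n_sensors),
            np.array([10, 50]),
            phantom_array,
        )
        assert vec.shape == (phantom_array.n_sensors, 3)
        assert np.all(vec == 0)

    def test_vectors_match_forward_field(self, phantom_array):
        """Burst-peak vectors reconstruct the generating dipole's field
        at every triaxial sensor."""
        dip = CurrentDipole([0.0, 0.02, 0.02], [2e-6, 0, 0])
        B = dipole_field_sphere(dip, phantom_array.positions)
        pairs = phantom_array.channel_index()
        chan = np.array(
            [B[i] @ phantom_array.frames[i, k] for i, k in pairs]
        )
        data = np.tile(chan[:, None], (1, 50))
        vec, kept = field_at_burst_peak(
            data,
            np.array([i for i, _ in pairs]),
            np.array([("r", "theta", "phi")[k] for _, k in pairs]),
            np.array([5, 25, 45]),
            phantom_array,
        )
        # projecting channel triplets back through the frames recovers B
        corr = np.corrcoef(vec.ravel(), B[kept].ravel())[0, 1]
        assert corr > 0.95
        np.testing.assert_allclose(vec, B[kept], rtol=1e-10)

    def test_scaling_linearity(self, phantom_array):
        rng = np.random.default_rng(0)
        data = rng.normal(0, 1e-12, (phantom_array.n_channels, 60))
        pairs = phantom_array.channel_index()
        sensors = np.array([i for i, _ in pairs])
        axes = np.array([("r", "theta", "phi")[k] for _, k in pairs])
        v1, _ = field_at_burst_peak(data, sensors, axes, np.array([7]), phantom_array)
        v2, _ = field_at_burst_peak(3 * data, sensors, axes, np.array([7]), phantom_array)
        np.testing.assert_allclose(v2, 3 * v1, rtol=1e-12)

    def test_sensor_missing_axis_skipped(self, phantom_array):
        data = np.zeros((phantom_array.n_channels - 1, 10))
        pairs = phantom_array.channel_index()[:-1]  # drop one axis row
        sensors = np.array([i for i, _ in pairs])
        axes = np.array([("r", "theta", "phi")[k] for _, k in pairs])
        with pytest.warns(UserWarning):
            vec, kept = field_at_burst_peak(
                data, sensors, axes, np.array([3]), phantom_array
            )
        assert len(kept) == phantom_array.n_sensors - 1
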