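"""Sweep preprocessing: averaging, baselines, spikes, window-restricted peaks."""

import numpy as np
import pytest

from dsgckit import synth, traces
from dsgckit.errors import InvalidArgumentError, InvalidInputError
from dsgckit.traces import ResponseWindows, SweepSet

FS = 1000.0


def _sweepset(blocks, mode="voltage_clamp", fs=FS):
    return SweepSet(
        directions=np.arange(len(blocks)) * 45.0,
        traces=np.asarray(blocks, dtype=float),
        sampling_rate=fs,
        recording_mode=mode,
    )


class TestAveraging:
    def test_identical_trials_average_to_one_trial(self):
        trial = np.sin(np.linspace(0, 4, 100))
        s = _sweepset([[trial, trial, trial]])
        np.testing.assert_allclose(traces.average_trials(s)[0], trial)

    def test_constant_trials_average(self):
        s = _sweepset([[np.zeros(50), np.full(50, 2.0)]])
        np.testing.assert_allclose(traces.average_trials(s)[0], 1.0)

    def test_noise_suppression_scales_with_trials(self, fast_windows):
        sigma, n_trials = 20.0, 16
        spec = synth.TuningSpec(peak_pd=0.0, peak_nd=0.0, noise_sd=sigma,
                                n_trials=n_trials)
        s = synth.gen_psc_sweeps(spec, [0.0], 3, windows=fast_windows,
                                 sampling_rate=2000.0, duration=1.8)
        resid_sd = traces.average_trials(s)[0].std()
        assert resid_sd == pytest.approx(sigma / np.sqrt(n_trials), rel=0.1)

    def test_commutes_with_baseline_subtraction(self, fast_windows):
        spec = synth.TuningSpec(noise_sd=5.0, n_trials=3)
        s = synth.gen_psc_sweeps(spec, [0.0, 90.0], 4, windows=fast_windows,
                                 sampling_rate=2000.0, duration=1.8)
        mean_then_sub = traces.baseline_subtract(
            traces.average_trials(s), fast_windows, s.sampling_rate
        )
        sub_then_mean = traces.baseline_subtract(
            s.traces, fast_windows, s.sampling_rate
        ).mean(axis=1)
        np.testing.assert_allclose(mean_then_sub, sub_then_mean, atol=1e-10)


class TestBaseline:
    def test_constant_trace_zeroed(self, windows):
        out = traces.baseline_subtract(np.full(5000, 5.0), windows, FS)
        np.testing.assert_allclose(out, 0.0)

    def test_step_preserved_relative_to_baseline(self, windows):
        tr = np.concatenate([np.full(600, 2.0), np.full(4400, 12.0)])
        out = traces.baseline_subtract(tr, windows, FS)
        assert out[0] == pytest.approx(0.0)
        assert out[-1] == pytest.approx(10.0)

    def test_idempotent(self, windows):
        rng = np.random.default_rng(0)
        tr = rng.normal(3.0, 1.0, 5000)
        once = traces.baseline_subtract(tr, windows, FS)
        twice = traces.baseline_subtract(once, windows, FS)
        np.testing.assert_allclose(once, twice, atol=1e-12)

    def test_baseline_longer_than_trace_rejected(self, windows):
        with pytest.raises(InvalidInputError):
            traces.baseline_subtract(np.zeros(10), windows, FS)


class TestSpikeDetection:
    def test_flat_trace_no_spikes(self):
        out = traces.detect_spikes(np.zeros(50000), 10_000.0, threshold=5.0)
        assert out.size == 0

    def test_noiseless_synthetic_train_recovered_exactly(self, fast_windows):
        spec = synth.TuningSpec(preferred_direction=0.0, peak_pd=30.0, peak_nd=30.0,
                                noise_sd=0.0, n_trials=1)
        sweeps, truth = synth.gen_spike_sweeps(
            spec, [0.0], 11, windows=fast_windows, sampling_rate=10_000.0,
            duration=1.8, min_isi=0.004,
        )
        detected = traces.detect_spikes(sweeps.traces[0, 0], 10_000.0,
                                        threshold=10.0, refractory=0.002)
        true_times = truth[0.0][0]
        assert detected.size == true_times.size
        assert np.max(np.abs(detected - true_times)) <= 2 / 10_000.0

    def test_refractory_merges_close_crossings(self):
        fs = 10_000.0
        tr = np.zeros(2000)
        for k in (500, 505):  # 0.5 ms apart
            tr[k : k + 5] = 10.0
        out = traces.detect_spikes(tr, fs, threshold=3.0, refractory=0.001)
        assert out.size == 1

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(InvalidArgumentError):
            traces.detect_spikes(np.zeros(100), 1000.0, band=(80.0, 2000.0))


class TestMaxFiringRate:
    def test_no_spikes_zero(self, windows):
        assert traces.max_firing_rate([], windows, "ON") == 0.0

    def test_regular_train_rate(self, windows):
        spikes = np.arange(windows.on_start, windows.on_start + windows.width, 0.01)
        assert traces.max_firing_rate(spikes, windows, "ON", 0.1) == pytest.approx(100.0)

    def test_single_spike(self, windows):
        assert traces.max_firing_rate([windows.on_start + 0.5], windows, "ON", 0.1) \
            == pytest.approx(10.0)

    def test_spikes_outside_window_ignored(self, windows):
        assert traces.max_firing_rate([0.1, 4.4], windows, "ON", 0.1) == 0.0


class TestPeakExtraction:
    def _bump(self, height, center_s, windows, n=5000):
        t = np.arange(n) / FS
        return height * np.exp(-((t - center_s) ** 2) / (2 * 0.05**2))

    def test_ipsc_peak_is_window_max(self, windows):
        tr = self._bump(600.0, 1.0, windows)
        val, t_pk = traces.peak_current(tr, windows, "ON", "IPSC", FS)
        assert val == pytest.approx(600.0)
        assert t_pk == pytest.approx(1.0, abs=1e-3)

    def test_epsc_peak_is_window_min(self, windows):
        val, _ = traces.peak_current(self._bump(-300.0, 1.2, windows), windows,
                                     "ON", "EPSC", FS)
        assert val == pytest.approx(-300.0)

    def test_bump_outside_window_not_seen(self, windows):
        # response landing between the windows: neither window reports it
        tr = self._bump(600.0, 2.2, windows)
        on_val, _ = traces.peak_current(tr, windows, "ON", "IPSC", FS)
        off_val, _ = traces.peak_current(tr, windows, "OFF", "IPSC", FS)
        assert on_val < 600.0 * 0.9
        assert off_val < 600.0 * 0.9

    def test_earliest_sample_wins_ties(self, windows):
        tr = np.zeros(5000)
        tr[600] = tr[900] = 5.0
        _, t_pk = traces.peak_current(tr, windows, "ON", "IPSC", FS)
        assert t_pk == pytest.approx(0.6)


class TestSubthresholdVm:
    def test_spike_free_depolarization_passes_through(self, windows):
        t = np.arange(5000) / FS
        tr = 12.0 * np.exp(-((t - 1.0) ** 2) / (2 * 0.2**2))
        out = traces.remove_spikes_and_peak_vm(tr, windows, "ON", FS)
        assert out == pytest.approx(12.0, rel=0.05)

    def test_brief_spikes_filtered_out(self, windows):
        # action-potential-like transients: 1 ms depolarization followed by a
        # shallow afterhyperpolarization, riding on a 12 mV slow envelope
        fs = 10_000.0
        t = np.arange(50_000) / fs
        tr = 12.0 * np.exp(-((t - 1.0) ** 2) / (2 * 0.2**2))
        for k in range(9000, 12000, 600):
            tr[k : k + 10] += 60.0
            tr[k + 10 : k + 20] -= 60.0
        out = traces.remove_spikes_and_peak_vm(tr, windows, "ON", fs,
                                               lowpass_cutoff=50.0)
        assert out == pytest.approx(12.0, rel=0.10)

    def test_flat_trace_zero(self, windows):
        assert traces.remove_spikes_and_peak_vm(np.zeros(5000), windows, "ON", FS) \
            == pytest.approx(0.0, abs=1e-9)

    def test_cutoff_above_nyquist_rejected(self, windows):
        with pytest.raises(InvalidArgumentError):
            traces.remove_spikes_and_peak_vm(np.zeros(5000), windows, "ON", FS,
                                             lowpass_cutoff=600.0)
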