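import numpy as np
import pytest
from scipy import signal

from synint.preprocess import (
    average_sweeps,
    blank_artifacts,
    blank_spikes,
    lowpass_filter,
    subtract_baseline,
)
from synint.synth import ap_template, get_preset, simulate_synaptic_train
from synint.synth.params import SpikeParams
from synint.trace_model import StimulusTrain, SweepSet


def _flat_set(values, n=2000, dt=0.02, units="mV", stim_at=10.0):
    sweeps = np.array([[v] * n for v in values], dtype=float)
    stim = StimulusTrain(onsets=np.array([stim_at]))
    return SweepSet(sweeps, dt=dt, units=units, stimulus=stim)


class TestSubtractBaseline:
    def test_constant_sweep_becomes_zero(self):
        out = subtract_baseline(_flat_set([5.0]), window=(0.0, 8.0))
        assert np.allclose(out.sweeps, 0.0, atol=1e-12)

    def test_dc_invariance(self, simple_sweepset):
        a = subtract_baseline(simple_sweepset, window=(0.0, 4.0))
        shifted = simple_sweepset.with_sweeps(simple_sweepset.sweeps + 7.3)
        b = subtract_baseline(shifted, window=(0.0, 4.0))
        assert np.allclose(a.sweeps, b.sweeps, atol=1e-12)

    def test_two_offsets_both_zero_mean(self):
        out = subtract_baseline(_flat_set([1.0, 2.0]), window=(0.0, 8.0))
        t = out.time
        sel = (t >= 0.0) & (t <= 8.0)
        assert np.abs(out.sweeps[:, sel].mean(axis=1)).max() < 1e-12

    def test_idempotent(self, simple_sweepset):
        once = subtract_baseline(simple_sweepset, window=(0.0, 4.0))
        twice = subtract_baseline(once, window=(0.0, 4.0))
        assert np.allclose(once.sweeps, twice.sweeps, atol=1e-12)

    def test_window_after_stimulus_rejected(self, simple_sweepset):
        with pytest.raises(ValueError):
            subtract_baseline(simple_sweepset, window=(0.0, 10.0))

    def test_window_outside_sweep_rejected(self):
        with pytest.raises(ValueError):
            subtract_baseline(_flat_set([1.0], stim_at=50.0), window=(-5.0, 2.0))


class TestLowpassFilter:
    def test_dc_unchanged(self):
        out = lowpass_filter(_flat_set([3.0]), cutoff=1000.0)
        assert np.allclose(out.sweeps, 3.0, atol=1e-9)

    def test_100hz_sinusoid_attenuation_below_1pct(self):
        # oracle: evaluate the designed filter's squared magnitude response
        dt = 0.02
        fs = 1000.0 / dt
        sos = signal.butter(4, 1000.0 / (fs / 2), btype="low", output="sos")
        _, h = signal.sosfreqz(sos, worN=[100.0], fs=fs)
        expected_gain = np.abs(h[0]) ** 2  # forward-backward pass
        t = dt * np.arange(50000)
        x = np.sin(2 * np.pi * 100.0 * t / 1000.0)
        s = SweepSet(x[None, :], dt=dt, units="mV")
        out = lowpass_filter(s, cutoff=1000.0).sweeps[0]
        mid = slice(10000, 40000)
        measured_gain = out[mid].std() / x[mid].std()
        assert measured_gain == pytest.approx(expected_gain, abs=1e-3)
        assert 1.0 - measured_gain < 0.01

    def test_zero_phase_peak_shift_below_dt(self):
        dt = 0.02
        t = dt * np.arange(10000)
        x = np.exp(-((t - 100.0) / 3.0) ** 2)
        s = SweepSet(x[None, :], dt=dt, units="mV")
        out = lowpass_filter(s, cutoff=1000.0).sweeps[0]
        assert abs(np.argmax(out) - np.argmax(x)) * dt <= dt

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            lowpass_filter(_flat_set([1.0]), cutoff=30000.0)


class TestAverageSweeps:
    def test_identical_sweeps(self):
        s = _flat_set([2.0, 2.0, 2.0])
        avg = average_sweeps(s)
        assert np.allclose(avg.samples, 2.0)
        assert avg.meta["n_averaged"] == 3

    def test_symmetric_offsets_cancel(self, simple_sweepset):
        base = simple_sweepset.sweeps[0]
        avg = average_sweeps(simple_sweepset)
        assert np.allclose(avg.samples, base, atol=1e-12)

    def test_clt_convergence(self, rng):
        # 200 noisy copies of a kernel: pointwise error consistent with CLT
        n, trials, sd = 3000, 200, 0.5
        t = 0.02 * np.arange(n)
        kernel = np.exp(-((t - 30.0) / 5.0) ** 2)
        sweeps = kernel + rng.normal(0, sd, size=(trials, n))
        avg = average_sweeps(SweepSet(sweeps, dt=0.02, units="mV"))
        err = np.abs(avg.samples - kernel)
        se = sd / np.sqrt(trials)
        assert np.mean(err < 3 * se) > 0.99
        assert err.max() < 6 * se

    def test_empty_selection_errors(self, simple_sweepset):
        with pytest.raises(ValueError):
            average_sweeps(simple_sweepset, condition="nope")


class TestBlankSpikes:
    @pytest.fixture
    def clean_epsp_set(self):
        preset = get_preset("fig1_invitro", seed=3)
        train = StimulusTrain.regular(20.0, 1, start=20.0)
        return preset, simulate_synaptic_train(preset, train, n_trials=5,
                                               post_ms=300.0)

    def test_spike_free_trace_unchanged(self, clean_epsp_set):
        _, s = clean_epsp_set
        out, report = blank_spikes(s)
        assert report.n_events == 0
        assert np.array_equal(out.sweeps, s.sweeps)

    def test_known_time_ap_removed_noise_free(self):
        preset = get_preset("fig1_invitro", seed=3).replace(noise_sd=0.0)
        train = StimulusTrain.regular(20.0, 1, start=20.0)
        twin = simulate_synaptic_train(preset, train, n_trials=1, post_ms=300.0)
        tpl = ap_template(SpikeParams(amplitude=80.0), twin.dt)
        sw = twin.sweeps.copy()
        idx = int(31.0 / twin.dt)
        sw[:, idx:idx + tpl.size] += tpl
        out, report = blank_spikes(twin.with_sweeps(sw))
        assert report.n_events >= 1
        assert np.abs(out.sweeps - twin.sweeps).max() < 0.1

    def test_ap_removed_with_noise(self, clean_epsp_set):
        preset, twin = clean_epsp_set
        tpl = ap_template(SpikeParams(amplitude=80.0), twin.dt)
        sw = twin.sweeps.copy()
        idx = int(31.0 / twin.dt)
        sw[:, idx:idx + tpl.size] += tpl
        out, report = blank_spikes(twin.with_sweeps(sw))
        # blanked samples lose their noise: bound by a few noise SDs
        assert np.abs(out.sweeps - twin.sweeps).max() < 4 * preset.noise_sd

    def test_two_aps_reported_near_insertions(self, clean_epsp_set):
        _, twin = clean_epsp_set
        tpl = ap_template(SpikeParams(amplitude=80.0), twin.dt)
        sw = twin.sweeps.copy()
        inserted = (31.0, 80.0)
        for t0 in inserted:
            i0 = int(t0 / twin.dt)
            sw[:, i0:i0 + tpl.size] += tpl
        _, report = blank_spikes(twin.with_sweeps(sw))
        times = sorted(e[1] for e in report.events)
        for t0 in inserted:
            assert min(abs(t - t0) for t in times) < 0.5

    def test_untouched_outside_reported_spans(self, clean_epsp_set):
        _, twin = clean_epsp_set
        tpl = ap_template(SpikeParams(amplitude=80.0), twin.dt)
        sw = twin.sweeps.copy()
        idx = int(31.0 / twin.dt)
        sw[:, idx:idx + tpl.size] += tpl
        spiky = twin.with_sweeps(sw)
        out, report = blank_spikes(spiky)
        mask = np.zeros_like(sw, dtype=bool)
        for sweep_i, t_cross, span in report.events:
            a = int((t_cross - 0.1) / twin.dt) - 2
            b = int((t_cross + span) / twin.dt) + 2
            mask[sweep_i, a:b] = True
        assert np.array_equal(out.sweeps[~mask], spiky.sweeps[~mask])

    def test_requires_mv(self):
        s = SweepSet(np.zeros((1, 100)), dt=0.02, units="pA")
        with pytest.raises(ValueError):
            blank_spikes(s)


class TestBlankArtifacts:
    def test_flat_region_unchanged(self):
        s = _flat_set([1.5], stim_at=50.0)
        out = blank_artifacts(s, [(5.0, 6.0)])
        assert np.allclose(out.sweeps, 1.5, atol=1e-12)

    def test_artifact_removed_continuously(self):
        s = _flat_set([0.0], stim_at=50.0)
        sw = s.sweeps.copy()
        sw[0, 500:520] = 40.0  # artifact at 10.0-10.4 ms
        out = blank_artifacts(s.with_sweeps(sw), [(9.8, 10.6)])
        assert np.abs(out.sweeps).max() < 1e-9

    def test_overlapping_windows_merged_with_warning(self):
        s = _flat_set([0.0], stim_at=50.0)
        with pytest.warns(UserWarning, match="merged"):
            blank_artifacts(s, [(5.0, 7.0), (6.0, 8.0)])

    def test_window_over_onset_warns(self):
        s = _flat_set([0.0], stim_at=10.0)
        with pytest.warns(UserWarning, match="onset"):
            blank_artifacts(s, [(9.0, 11.0)])

    def test_onset_shift_hazard(self):
        # blanking across response onset shifts the measured latency
        from synint import kinetics
        preset = get_preset("fig1_invitro", seed=0).replace(noise_sd=0.0)
        train = StimulusTrain.regular(20.0, 1, start=20.0)
        s = simulate_synaptic_train(preset, train, n_trials=1, post_ms=300.0)
        w0 = s.sweep(0)
        amp, tpk, _ = kinetics.peak_amplitude(w0, (1.0, 50.0), 20.0)
        lat0 = kinetics.onset_latency(w0, 20.0, tpk, amp)
        with pytest.warns(UserWarning):
            blanked = blank_artifacts(s, [(19.0, 25.0)])
        w1 = blanked.sweep(0)
        amp1, tpk1, _ = kinetics.peak_amplitude(w1, (1.0, 50.0), 20.0)
        lat1 = kinetics.onset_latency(w1, 20.0, tpk1, amp1)
        assert lat1 != pytest.approx(lat0, abs=0.05)
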