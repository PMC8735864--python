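import numpy as np
import pytest

from synint import kinetics, summation
from synint.summation import (
    expected_linear_train,
    extract_tonic,
    fit_ahp,
    per_pulse_ratios,
)
from synint.synth import get_preset, make_epsp_kernel, simulate_synaptic_train
from synint.synth.params import SlowComponents
from synint.trace_model import StimulusTrain, Waveform

DT = 0.02


def _single_and_train(preset, rate, n_pulses=10, post=400.0):
    train = StimulusTrain.regular(rate, n_pulses, start=20.0)
    obs = simulate_synaptic_train(preset, train, n_trials=1, post_ms=post).sweep(0)
    single_train = StimulusTrain.regular(rate, 1, start=20.0)
    nodep = preset.replace(depression=preset.depression.__class__(U=0.0))
    single = simulate_synaptic_train(nodep, single_train, n_trials=1,
                                     post_ms=post).sweep(0)
    return single, obs, train


class TestExpectedLinearTrain:
    def test_one_pulse_returns_scaled_single(self):
        p = get_preset("fig1_invitro", seed=0).replace(noise_sd=0.0)
        single, _, _ = _single_and_train(p, 20.0, n_pulses=1)
        train = StimulusTrain(onsets=np.array([0.0]))
        exp = expected_linear_train(single, train, first_observed_peak=7.0,
                                    single_onset=20.0)
        amp, _, _ = kinetics.peak_amplitude(exp, (0.0, 100.0), 0.0)
        assert amp == pytest.approx(7.0, abs=0.01)

    def test_well_separated_pulses_have_equal_peaks(self):
        p = get_preset("fig1_invitro", seed=0).replace(noise_sd=0.0)
        single, _, _ = _single_and_train(p, 20.0, n_pulses=1, post=2000.0)
        train = StimulusTrain(onsets=np.array([0.0, 1000.0]))  # >> decay
        exp = expected_linear_train(single, train, first_observed_peak=3.5,
                                    single_onset=20.0)
        p1, _, _ = kinetics.peak_amplitude(exp, (0.0, 500.0), 0.0)
        p2, _, _ = kinetics.peak_amplitude(exp, (1000.0, 1500.0), 0.0)
        assert p2 == pytest.approx(p1, rel=1e-3)

    def test_geometric_series_steady_state(self):
        # instant-rise exponential kernel: expected steady-state peak /
        # single peak -> 1 / (1 - exp(-ISI/tau))
        tau, isi = 30.0, 20.0
        t = DT * np.arange(int(200.0 / DT))
        single = Waveform(np.exp(-t / tau), dt=DT)
        n_pulses = 60
        train = StimulusTrain(onsets=isi * np.arange(n_pulses))
        exp = expected_linear_train(single, train, first_observed_peak=1.0,
                                    single_onset=0.0)
        k_last = int(train.onsets[-1] / DT)
        peak_last = exp.samples[k_last:k_last + int(isi / DT)].max()
        closed_form = 1.0 / (1.0 - np.exp(-isi / tau))
        assert peak_last == pytest.approx(closed_form, rel=1e-3)

    def test_additivity_of_superposition(self):
        p = get_preset("fig1_invitro", seed=0).replace(noise_sd=0.0)
        single, _, _ = _single_and_train(p, 20.0, n_pulses=1)
        t1 = StimulusTrain(onsets=np.array([0.0, 50.0]))
        t2 = StimulusTrain(onsets=np.array([100.0, 150.0]))
        both = StimulusTrain(onsets=np.array([0.0, 50.0, 100.0, 150.0]))
        e1 = expected_linear_train(single, t1, 3.5, single_onset=20.0)
        e2 = expected_linear_train(single, t2, 3.5, single_onset=20.0)
        eb = expected_linear_train(single, both, 3.5, single_onset=20.0)
        n = min(e1.n, eb.n)
        combo = e1.samples[:n].copy()
        combo += e2.samples[:n]
        assert np.allclose(eb.samples[:n], combo, atol=1e-9)

    def test_empty_train_rejected(self):
        with pytest.raises(Exception):
            StimulusTrain(onsets=np.array([]))


class TestPerPulseRatios:
    def test_observed_equals_expected_gives_unit_ratios(self):
        p = get_preset("fig1_invitro", seed=0).replace(noise_sd=0.0)
        _, obs, train = _single_and_train(
            p.replace(depression=p.depression.__class__(U=0.0)), 20.0)
        tm = per_pulse_ratios(obs, obs, train)
        assert np.allclose(tm.ratios, 1.0, atol=1e-12)

    def test_calibrated_20hz_ratio10(self):
        p = get_preset("fig4_20hz")  # embeds ratio_10 = 0.92
        single, obs, train = _single_and_train(p, 20.0)
        first_peak, _, _ = kinetics.peak_amplitude(obs, (0.0, train.isi), 20.0)
        exp = expected_linear_train(single, train, first_peak, single_onset=20.0)
        tm = per_pulse_ratios(obs, exp, train)
        assert tm.ratios[-1] == pytest.approx(0.92, abs=0.02)

    def test_calibrated_50hz_trough_to_peak(self):
        p = get_preset("fig4_50hz_ttp")  # embeds ttp_10/ttp_1 = 0.39
        single, obs, train = _single_and_train(p, 50.0)
        first_peak, _, _ = kinetics.peak_amplitude(obs, (0.0, train.isi), 20.0)
        exp = expected_linear_train(single, train, first_peak, single_onset=20.0)
        tm = per_pulse_ratios(obs, exp, train)
        ttp = tm.trough_to_peak
        assert ttp[-1] / ttp[0] == pytest.approx(0.39, abs=0.02)


class TestExtractTonic:
    def test_pure_phasic_fast_kernel_tonic_near_zero(self):
        # kernel decays almost fully between pulses at 10 Hz
        p = get_preset("fig1_invivo", seed=0).replace(noise_sd=0.0)
        train = StimulusTrain.regular(10.0, 25, start=100.0)
        obs = simulate_synaptic_train(p, train, n_trials=1, post_ms=300.0).sweep(0)
        _, amp = extract_tonic(obs, train)
        assert abs(amp) < 0.1

    def test_ramp_only_recovers_plateau(self):
        p = get_preset("fig1_invivo", seed=0).replace(
            noise_sd=0.0,
            kernel=p_amp_zero(get_preset("fig1_invivo").kernel),
            slow=SlowComponents(tonic_amp=1.5, tonic_tau=200.0),
        )
        train = StimulusTrain.regular(20.0, 80, start=100.0)
        obs = simulate_synaptic_train(p, train, n_trials=1, post_ms=500.0).sweep(0)
        _, amp = extract_tonic(obs, train)
        assert amp == pytest.approx(1.5, abs=0.01)

    def test_calibrated_plateau_recovered(self):
        p = get_preset("fig4_tonic")  # embeds plateau 1.18 mV
        train = StimulusTrain.regular(20.0, 80, start=100.0)
        obs = simulate_synaptic_train(p, train, n_trials=1, post_ms=6050.0).sweep(0)
        _, amp = extract_tonic(obs, train)
        assert amp == pytest.approx(1.18, abs=0.03)

    def test_short_train_warns_and_shrinks(self):
        p = get_preset("fig1_invivo", seed=0).replace(noise_sd=0.0)
        train = StimulusTrain.regular(20.0, 5, start=20.0)
        obs = simulate_synaptic_train(p, train, n_trials=1, post_ms=300.0).sweep(0)
        with pytest.warns(UserWarning, match="steady window"):
            extract_tonic(obs, train)

    def test_slow_component_decomposition_property(self, rng):
        """Tonic extraction separates a slow ramp from phasic trains across
        random generator draws."""
        for _ in range(10):
            tonic = float(rng.uniform(0.3, 2.0))
            p = get_preset("fig1_invivo", seed=int(rng.integers(1000)))
            p = p.replace(
                noise_sd=0.0,
                slow=SlowComponents(tonic_amp=tonic, tonic_tau=150.0),
                depression=p.depression.__class__(U=0.2, tau_rec=250.0),
            )
            train = StimulusTrain.regular(20.0, 60, start=100.0)
            obs = simulate_synaptic_train(p, train, n_trials=1,
                                          post_ms=300.0).sweep(0)
            _, amp = extract_tonic(obs, train)
            # exact decomposition: plateau = slow ramp + phasic anchor residue
            from synint.synth import oracle_tonic_plateau
            phasic_only = p.replace(slow=SlowComponents())
            span = float(train.onsets[-1]) + 300.0
            residue = oracle_tonic_plateau(phasic_only, train, span,
                                           steady_window=1000.0)
            assert amp == pytest.approx(tonic + residue, abs=0.02)


def p_amp_zero(kernel):
    import dataclasses
    return dataclasses.replace(kernel, amplitude=0.0)


class TestFitAHP:
    def _tonic_train_sweep(self, **slow_kwargs):
        p = get_preset("fig4_tonic")
        if slow_kwargs:
            import dataclasses
            p = p.replace(slow=dataclasses.replace(p.slow, **slow_kwargs))
        train = StimulusTrain.regular(20.0, 80, start=100.0)
        obs = simulate_synaptic_train(p, train, n_trials=1, post_ms=6050.0).sweep(0)
        return obs, float(train.onsets[-1]) + train.isi

    def test_onset_tau_recovered(self):
        obs, train_end = self._tonic_train_sweep()
        ahp = fit_ahp(obs, train_end)
        assert ahp.present
        assert ahp.onset_tau == pytest.approx(76.5, abs=3.0)

    def test_recovery_tau_recovered(self):
        obs, train_end = self._tonic_train_sweep()
        ahp = fit_ahp(obs, train_end)
        assert ahp.recovery_tau == pytest.approx(2600.0, abs=100.0)

    def test_zero_ahp_gives_no_ahp_result(self):
        obs, train_end = self._tonic_train_sweep(ahp_amp=-1e-12)
        ahp = fit_ahp(obs, train_end, min_depth_sd=0.05)
        assert not ahp.present
        assert ahp.onset_tau is None and ahp.recovery_tau is None
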