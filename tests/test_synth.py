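import numpy as np
import pytest

from synint import kinetics
from synint.synth import (
    CalibrationError,
    DepressionParams,
    KernelParams,
    ReleaseParams,
    SynthPreset,
    bisect_parameter,
    depression_amplitudes,
    depression_steady_state,
    get_preset,
    make_epsp_kernel,
    oracle_train_ratio,
    shape_fwhm,
    simulate_dual_pathway,
    simulate_extracellular,
    simulate_minimal_stim,
    simulate_synaptic_train,
)
from synint.synth.simulate import clean_train_trace
from synint.trace_model import StimulusTrain

DT = 0.02


class TestKernelConstruction:
    def test_peak_equals_amplitude_exactly(self):
        k = KernelParams(tau_rise=1.0, tau_decay=30.0, latency=3.0, amplitude=3.5)
        w = make_epsp_kernel(k, dt=DT, span=300.0)
        assert abs(w.samples.max() - 3.5) < 1e-9

    def test_fwhm_matches_bruteforce_scan(self):
        # tau_rise 1, tau_decay 30: FWHM from root-finding on the closed form
        w = make_epsp_kernel(
            KernelParams(tau_rise=1.0, tau_decay=30.0, latency=0.0, amplitude=1.0),
            dt=DT, span=400.0)
        amp, tpk, _ = kinetics.peak_amplitude(w, (0.1, 399.0), 0.0)
        measured = kinetics.half_width(w, tpk, amp)
        assert measured == pytest.approx(shape_fwhm(1.0, 30.0), abs=0.05)

    def test_zero_amplitude_gives_zero_waveform(self):
        k = KernelParams(tau_rise=1.0, tau_decay=30.0, amplitude=0.0)
        w = make_epsp_kernel(k, dt=DT, span=100.0)
        assert np.all(w.samples == 0.0)

    def test_tau_order_enforced(self):
        with pytest.raises(ValueError):
            KernelParams(tau_rise=30.0, tau_decay=1.0)


class TestDepressionRecursion:
    def test_resources_in_unit_interval(self):
        for U in (0.1, 0.5, 0.9):
            amps = depression_amplitudes(DepressionParams(U=U, tau_rec=100.0),
                                         isi=20.0, n_pulses=50)
            assert np.all(amps > 0.0) and np.all(amps <= 1.0)

    def test_non_increasing_at_fixed_isi(self):
        amps = depression_amplitudes(DepressionParams(U=0.3, tau_rec=200.0),
                                     isi=20.0, n_pulses=30)
        assert np.all(np.diff(amps) <= 1e-12)

    def test_steady_state_closed_form(self):
        dep = DepressionParams(U=0.35, tau_rec=150.0)
        amps = depression_amplitudes(dep, isi=20.0, n_pulses=400)
        assert amps[-1] == pytest.approx(depression_steady_state(dep, 20.0),
                                         rel=1e-9)

    def test_no_depression_limit(self):
        amps = depression_amplitudes(DepressionParams(U=0.0), isi=20.0,
                                     n_pulses=10)
        assert np.all(amps == 1.0)


class TestSimulateTrainProperties:
    def test_determinism_same_seed(self):
        p = get_preset("fig1_invitro", seed=11)
        train = StimulusTrain.regular(20.0, 5, start=20.0)
        a = simulate_synaptic_train(p, train, n_trials=3)
        b = simulate_synaptic_train(p, train, n_trials=3)
        assert np.array_equal(a.sweeps, b.sweeps)

    def test_different_seeds_differ(self):
        train = StimulusTrain.regular(20.0, 5, start=20.0)
        a = simulate_synaptic_train(get_preset("fig1_invitro", seed=1), train, 2)
        b = simulate_synaptic_train(get_preset("fig1_invitro", seed=2), train, 2)
        assert not np.array_equal(a.sweeps, b.sweeps)

    def test_non_depressing_sums_linearly(self):
        # U -> 0: observed/expected ratio 1.0 for every pulse
        p = get_preset("fig1_invitro", seed=0).replace(noise_sd=0.0)
        ratio = oracle_train_ratio(p, 50.0, pulse=10)
        assert ratio == pytest.approx(1.0, abs=0.02)

    def test_depression_calibration_oracle(self):
        # preset calibrated so the last/first trough-to-peak ratio is 0.39
        from synint.synth import oracle_trough_to_peak_ratio
        p = get_preset("fig4_50hz_ttp")
        assert oracle_trough_to_peak_ratio(p, 50.0) == pytest.approx(0.39, abs=2e-3)


class TestConservation:
    def test_dual_pathway_gain1_is_exact_sum(self):
        asc = get_preset("fig8_asc", seed=5).replace(noise_sd=0.0)
        desc = get_preset("fig8_desc", seed=5).replace(noise_sd=0.0)
        a, d, c = simulate_dual_pathway(asc, desc, offset=0.0, gain=1.0,
                                        n_trials=1)
        assert np.abs(c.sweeps[0] - (a.sweeps[0] + d.sweeps[0])).max() < 1e-9

    def test_identical_presets_offset0_double(self):
        p = get_preset("fig8_desc", seed=5).replace(noise_sd=0.0)
        a, d, c = simulate_dual_pathway(p, p, offset=0.0, gain=1.0, n_trials=1)
        assert np.allclose(c.sweeps[0], 2 * a.sweeps[0], atol=1e-9)


class TestMinimalStim:
    def test_failure_rate_within_binomial_ci(self):
        p = get_preset("fig2_minstim", seed=1)
        s = simulate_minimal_stim(p, n_trials=500, intensities=[1.0])
        fails = np.mean([not m["true_success"] for m in s.per_sweep_meta])
        # binomial 95% CI half-width at p=0.44, n=500 is ~0.044
        assert fails == pytest.approx(0.44, abs=0.05)

    def test_all_failures_when_p_fail_1(self):
        p = get_preset("fig2_minstim", seed=2)
        p = p.replace(release=ReleaseParams(p_fail=1.0, unitary_mean=0.84))
        s = simulate_minimal_stim(p, n_trials=50, intensities=[1.0])
        assert all(not m["true_success"] for m in s.per_sweep_meta)
        # noise-only sweeps: nothing above a few noise SDs
        assert s.sweeps.max() < 6 * p.noise_sd

    def test_recruitment_monotonic_in_intensity(self):
        p = get_preset("fig2_minstim", seed=3).replace(noise_sd=0.0)
        s = simulate_minimal_stim(p, n_trials=100,
                                  intensities=[1.0, 2.0, 3.0, 4.0])
        means = []
        for i in (1.0, 2.0, 3.0, 4.0):
            sel = [j for j, m in enumerate(s.per_sweep_meta)
                   if m["intensity"] == i]
            means.append(s.sweeps[sel].max(axis=1).mean())
        assert all(b >= a - 1e-9 for a, b in zip(means, means[1:]))

    def test_p_fail_validation(self):
        with pytest.raises(ValueError):
            ReleaseParams(p_fail=1.5)


class TestExtracellularGenerator:
    def test_determinism(self):
        a = simulate_extracellular(n_trials=3, seed=9)
        b = simulate_extracellular(n_trials=3, seed=9)
        assert np.array_equal(a.sweeps, b.sweeps)

    def test_lfp_scale_invariant_onset(self):
        from synint import extracellular as ex
        base = {"onset": 9.7, "amplitude": -120.0, "slope": 12.0}
        double = {"onset": 9.7, "amplitude": -240.0, "slope": 24.0}
        onsets = []
        for lfp in (base, double):
            s = simulate_extracellular(lfp=lfp, mua={}, n_trials=20,
                                       noise_sd=2.0, seed=4)
            avg = ex.lfp_preprocess(s)
            onset, _ = ex.lfp_onset_and_slope(avg, 50.0)
            onsets.append(onset)
        assert onsets[0] == pytest.approx(onsets[1], abs=0.1)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            simulate_extracellular(mua={"baseline_rate": -1.0}, n_trials=1)


class TestCalibration:
    def test_trivial_target_returns_lower_bound(self):
        # ratio target 1.0 -> no depression: U at (or near) the lower bound
        base = SynthPreset(kernel=get_preset("fig1_invitro").kernel,
                           depression=DepressionParams(U=0.5, tau_rec=250.0),
                           noise_sd=0.0)
        from synint.synth import calibrate_preset
        preset, res = calibrate_preset("train_ratio", 1.0, base,
                                       bounds=(1e-4, 0.9), rate_hz=20.0,
                                       rtol=5e-3)
        assert preset.depression.U < 0.01

    def test_unreachable_target_raises_with_bracket(self):
        with pytest.raises(CalibrationError, match="metric"):
            bisect_parameter(lambda x: x * 0.1, target=100.0, bounds=(0.0, 1.0))

    def test_bisect_converges(self):
        res = bisect_parameter(lambda x: x ** 2, target=2.0, bounds=(0.0, 2.0))
        assert res.value == pytest.approx(np.sqrt(2.0), rel=1e-3)
        assert len(res.trace) >= 3


class TestPresetRegistry:
    def test_unknown_preset_lists_known(self):
        with pytest.raises(KeyError, match="fig1_invitro"):
            get_preset("nope")

    def test_preset_json_round_trip(self, tmp_path):
        p = get_preset("fig2_minstim", seed=7)
        path = tmp_path / "preset.json"
        p.save(path)
        q = SynthPreset.load(path)
        assert q == p

    def test_tonic_preset_embeds_target(self):
        from synint.synth import oracle_tonic_plateau
        p = get_preset("fig4_tonic")
        train = StimulusTrain.regular(20.0, 80, start=100.0)
        span = float(train.onsets[-1]) + 6050.0
        assert oracle_tonic_plateau(p, train, span) == pytest.approx(1.18, abs=5e-3)


class TestSlowComponentScaling:
    def test_nmda_fraction_partitions_integral(self):
        p = get_preset("fig6_pharm_asc", seed=0)
        train = StimulusTrain.regular(50.0, 5, start=50.0)
        span = float(train.onsets[-1]) + 300.0
        fast, slow, other = clean_train_trace(p, train, span, dt=DT,
                                              components=True)
        w0, w1 = int(50.0 / DT), int((train.onsets[-1] + 100.0) / DT)
        int_fast = np.trapezoid(fast[w0:w1 + 1], dx=DT)
        int_slow = np.trapezoid(slow[w0:w1 + 1], dx=DT)
        frac = int_slow / (int_fast + int_slow)
        assert frac == pytest.approx(p.slow.nmda_fraction, rel=1e-6)
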