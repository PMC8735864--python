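"""Synthetic sweep generation.

Every simulator is deterministic given the preset seed: per-trial noise
streams are spawned as ``default_rng([seed, stream, trial])`` so that the
same preset always yields bit-identical SweepSets and different conditions
of one experiment share no noise samples.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as _signal

from ..trace_model import StimulusTrain, SweepSet, Waveform
from .kernels import (
    ap_template,
    depression_amplitudes,
    make_epsc_kernel,
    make_epsp_kernel,
)
from .params import SynthPreset

__all__ = [
    "simulate_synaptic_train",
    "simulate_minimal_stim",
    "simulate_dual_pathway",
    "simulate_extracellular",
    "clean_train_trace",
]

DEFAULT_DT = 0.02  # ms; 50 kHz


def _filtered_noise(rng: np.random.Generator, n: int, dt: float, sd: float,
                    cutoff: float = 1000.0) -> np.ndarray:
    """Gaussian noise low-passed at ``cutoff`` Hz and rescaled to sd."""
    if sd == 0:
        return np.zeros(n)
    pad = 2000  # discard filter edge transients
    white = rng.standard_normal(n + 2 * pad)
    nyq = 1000.0 / dt / 2.0
    if cutoff < nyq:
        sos = _signal.butter(4, cutoff / nyq, btype="low", output="sos")
        white = _signal.sosfiltfilt(sos, white)
    core = white[pad:pad + n]
    return core * (sd / core.std())


def _trial_rng(seed: int, stream: int, trial: int) -> np.random.Generator:
    return np.random.default_rng([seed, stream, trial])


def _pulse_amplitudes(preset: SynthPreset, onsets: np.ndarray) -> np.ndarray:
    """Relative per-pulse amplitudes (first pulse = 1) from the depression
    recursion, supporting irregular trains."""
    n = onsets.size
    dep = preset.depression
    if n == 1 or dep.U == 0:
        return np.ones(n)
    isis = np.diff(onsets)
    if np.allclose(isis, isis[0]):
        return depression_amplitudes(dep, float(isis[0]), n)
    amps = np.empty(n)
    R = 1.0
    for k in range(n):
        amps[k] = R
        if k < n - 1:
            e = np.exp(-isis[k] / dep.tau_rec)
            R = 1.0 - (1.0 - R * (1.0 - dep.U)) * e
    return amps


def _add_at(trace: np.ndarray, kernel: np.ndarray, idx: int, scale: float) -> None:
    stop = min(idx + kernel.size, trace.size)
    if stop > idx >= 0:
        trace[idx:stop] += scale * kernel[: stop - idx]


def _make_mode_kernel(preset: SynthPreset, dt: float, span: float, mode: str) -> Waveform:
    k = preset.kernel
    if mode == "voltage_clamp":
        # tau_rise doubles as the 10-90% rise time of the smoothstep front
        return make_epsc_kernel(
            [(f, tau) for f, tau in k.tau_decay],
            rise_10_90=k.tau_rise, latency=k.latency,
            amplitude=k.amplitude, dt=dt, span=span,
        )
    return make_epsp_kernel(k, dt=dt, span=span)


def clean_train_trace(
    preset: SynthPreset,
    train: StimulusTrain,
    span: float,
    dt: float = DEFAULT_DT,
    mode: str = "current_clamp",
    components: bool = False,
):
    """Noise-free membrane trajectory for a stimulus train.

    Returns the summed trace, or (fast, slow, tonic_plus_ahp) component
    traces when ``components`` is True.  The slow NMDA-like component is
    scaled so it carries ``slow.nmda_fraction`` of the cumulative integral
    over [first onset, last onset + 100 ms].
    """
    n = int(round(span / dt))
    t = dt * np.arange(n)
    onsets = train.onsets
    max_tau = max(tau for _, tau in preset.kernel.tau_decay)
    kspan = min(span, preset.kernel.latency + 12.0 * max_tau)
    kernel = _make_mode_kernel(preset, dt, kspan, mode).samples
    amps = _pulse_amplitudes(preset, onsets)

    fast = np.zeros(n)
    for onset, a in zip(onsets, amps):
        _add_at(fast, kernel, int(round(onset / dt)), a)

    slow = np.zeros(n)
    sl = preset.slow
    if sl.nmda_fraction > 0:
        from .kernels import kernel_shape

        ks = min(span, 10.0 * sl.nmda_tau)
        kt = dt * np.arange(int(round(ks / dt)))
        sk = kernel_shape(kt - preset.kernel.latency, sl.nmda_rise,
                          ((1.0, sl.nmda_tau),))
        sk /= sk.max()
        for onset, a in zip(onsets, amps):
            _add_at(slow, sk, int(round(onset / dt)), a)
        w0 = int(round(onsets[0] / dt))
        w1 = min(int(round((onsets[-1] + 100.0) / dt)), n - 1)
        int_fast = np.trapezoid(fast[w0:w1 + 1], dx=dt)
        int_slow = np.trapezoid(slow[w0:w1 + 1], dx=dt)
        if int_slow > 0 and int_fast != 0:
            slow *= (sl.nmda_fraction / (1.0 - sl.nmda_fraction)) * int_fast / int_slow

    other = np.zeros(n)
    isi_last = float(onsets[-1] - onsets[-2]) if onsets.size > 1 else 50.0
    train_end = float(onsets[-1] + isi_last)
    if sl.tonic_amp != 0:
        during = (t >= onsets[0]) & (t < train_end)
        other[during] = sl.tonic_amp * (
            1.0 - np.exp(-(t[during] - onsets[0]) / sl.tonic_tau)
        )
        # tonic drive collapses with the train; its offset dynamics are
        # folded into the AHP component (fixture simplification)
    if sl.ahp_amp != 0:
        after = t >= train_end
        d = t[after] - train_end
        d_trough = 5.0 * sl.ahp_onset_tau
        trough_val = sl.ahp_amp * (1.0 - np.exp(-5.0))
        onset_phase = sl.ahp_amp * (1.0 - np.exp(-d / sl.ahp_onset_tau))
        rec_phase = trough_val * np.exp(-(d - d_trough) / sl.ahp_recovery_tau)
        other[after] += np.where(d <= d_trough, onset_phase, rec_phase)

    if components:
        return fast, slow, other
    return fast + slow + other


def simulate_synaptic_train(
    preset: SynthPreset,
    train: StimulusTrain,
    n_trials: int = 10,
    mode: str = "current_clamp",
    span: float | None = None,
    dt: float = DEFAULT_DT,
    post_ms: float = 500.0,
    condition: str = "control",
    noise_stream: int = 0,
) -> SweepSet:
    """Simulate evoked sweeps for a stimulus train.

    Each trial is the noise-free trajectory from :func:`clean_train_trace`
    plus 1 kHz-filtered Gaussian noise; when the spike threshold is finite,
    an AP template is inserted at each suprathreshold crossing.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if mode not in ("current_clamp", "voltage_clamp"):
        raise ValueError(f"unknown mode {mode!r}")
    if span is None:
        span = float(train.onsets[-1]) + post_ms
    clean = clean_train_trace(preset, train, span, dt=dt, mode=mode)
    n = clean.size
    units = "pA" if mode == "voltage_clamp" else "mV"
    template = ap_template(preset.spike, dt)
    refractory = max(int(round(2.0 / dt)), template.size)
    sweeps = np.empty((n_trials, n))
    for i in range(n_trials):
        rng = _trial_rng(preset.seed, noise_stream, i)
        x = clean + _filtered_noise(rng, n, dt, preset.noise_sd)
        if np.isfinite(preset.spike.threshold) and units == "mV":
            # Schmitt trigger: re-arm only after the trace falls a noise
            # margin below threshold, so noise wiggles near threshold do not
            # trigger AP cascades
            thr = preset.spike.threshold
            hyst = max(3.0 * preset.noise_sd, 0.05)
            armed = True
            last = -refractory
            j = 1
            while j < x.size:
                if armed and x[j] >= thr > x[j - 1] and j - last >= refractory:
                    _add_at(x, template, j, 1.0)
                    last = j
                    armed = False
                    j += template.size
                    continue
                if not armed and x[j] < thr - hyst:
                    armed = True
                j += 1
        sweeps[i] = x
    meta = tuple(
        {"condition": condition, "intensity": None, "seed": preset.seed}
        for _ in range(n_trials)
    )
    return SweepSet(sweeps, dt=dt, units=units, stimulus=train, per_sweep_meta=meta)


def simulate_minimal_stim(
    preset: SynthPreset,
    n_trials: int,
    intensities=(1.0,),
    dt: float = DEFAULT_DT,
    span: float = 120.0,
    stim_onset: float = 20.0,
) -> SweepSet:
    """Minimal-stimulation trials: Bernoulli successes with lognormal size.

    At the threshold (lowest) intensity each trial succeeds with probability
    ``1 - p_fail`` and draws its amplitude from a lognormal with mean
    ``unitary_mean`` and CV ``unitary_cv``; at higher intensities the draw
    is scaled by the recruited fiber count.  Ground-truth labels are stored
    in the per-sweep metadata.
    """
    intensities = list(intensities)
    if not intensities:
        raise ValueError("intensities must be non-empty")
    rel = preset.release
    train = StimulusTrain(onsets=np.array([stim_onset]),
                          width=preset.kernel.latency, kind="light")
    kernel = make_epsp_kernel(
        preset.kernel, dt=dt,
        span=span - stim_onset,
    ).samples
    kpeak = np.max(np.abs(kernel))
    if kpeak > 0:
        kernel = kernel / kpeak  # unit-amplitude kernel; scaled per trial
    n = int(round(span / dt))
    onset_idx = int(round(stim_onset / dt))
    sigma = float(np.sqrt(np.log1p(rel.unitary_cv ** 2)))
    mu = float(np.log(rel.unitary_mean) - sigma ** 2 / 2.0)
    base_fibers = rel.fibers_at(min(intensities))

    sweeps, meta = [], []
    for j, intensity in enumerate(sorted(intensities)):
        scale = rel.fibers_at(intensity) / base_fibers
        for i in range(n_trials):
            rng = _trial_rng(preset.seed, 100 + j, i)
            success = rng.random() >= rel.p_fail
            x = _filtered_noise(rng, n, dt, preset.noise_sd)
            amp = 0.0
            if success:
                amp = float(rng.lognormal(mu, sigma)) * scale
                _add_at(x, kernel, onset_idx, amp)
            sweeps.append(x)
            meta.append({
                "condition": "control",
                "intensity": float(intensity),
                "true_success": bool(success),
                "true_amplitude": amp,
                "seed": preset.seed,
            })
    return SweepSet(np.asarray(sweeps), dt=dt, units="mV", stimulus=train,
                    per_sweep_meta=tuple(meta))


def _shift_trace(x: np.ndarray, dt: float, offset: float) -> np.ndarray:
    """Delay ``x`` by ``offset`` ms with linear interpolation (zero fill)."""
    if offset == 0:
        return x.copy()
    t = dt * np.arange(x.size)
    return np.interp(t - offset, t, x, left=0.0, right=0.0)


def simulate_dual_pathway(
    preset_asc: SynthPreset,
    preset_desc: SynthPreset,
    offset: float,
    gain: float = 1.0,
    n_trials: int = 10,
    train: StimulusTrain | None = None,
    dt: float = DEFAULT_DT,
    span: float | None = None,
) -> tuple[SweepSet, SweepSet, SweepSet]:
    """Ascending-alone, descending-alone and combined-pathway sweep sets.

    The combined clean trace is ``gain * (asc(t) + desc(t - offset))``:
    its cumulative integral is exactly ``gain`` times the integral of the
    arithmetic sum, so ``gain = 1`` models the NMDA-blocked condition.
    """
    if gain <= 0:
        raise ValueError("gain must be > 0")
    if train is None:
        train = StimulusTrain.regular(50.0, 5, start=50.0)
    if span is None:
        span = float(train.onsets[-1]) + 300.0
    asc_clean = clean_train_trace(preset_asc, train, span, dt=dt)
    desc_clean = clean_train_trace(preset_desc, train, span, dt=dt)
    comb_clean = gain * (asc_clean + _shift_trace(desc_clean, dt, offset))

    desc_train = StimulusTrain(onsets=train.onsets + offset,
                               width=train.width, kind=train.kind)

    def _mk(clean, stream, cond, stim, seed):
        n = clean.size
        sweeps = np.empty((n_trials, n))
        for i in range(n_trials):
            rng = _trial_rng(seed, stream, i)
            sweeps[i] = clean + _filtered_noise(rng, n, dt, preset_asc.noise_sd)
        meta = tuple({"condition": cond, "pathway_offset_ms": offset,
                      "gain": gain, "seed": seed} for _ in range(n_trials))
        return SweepSet(sweeps, dt=dt, units="mV", stimulus=stim,
                        per_sweep_meta=meta)

    asc = _mk(asc_clean, 201, "asc_alone", train, preset_asc.seed)
    desc = _mk(desc_clean, 202, "desc_alone", train, preset_desc.seed)
    comb = _mk(comb_clean, 203, "combined", desc_train, preset_asc.seed)
    return asc, desc, comb


def _biphasic_spike(dt: float, amplitude: float, width: float = 1.0) -> np.ndarray:
    """Extracellular spike: negative-leading biphasic waveform."""
    n = max(int(round(width / dt)), 6)
    u = np.arange(n) / n
    neg = -np.sin(np.pi * np.clip(u / 0.5, 0, 1)) ** 2
    pos = 0.4 * np.sin(np.pi * np.clip((u - 0.5) / 0.5, 0, 1)) ** 2
    return abs(amplitude) * (neg * (u < 0.5) + pos * (u >= 0.5))


def simulate_extracellular(
    click_times=(50.0,),
    lfp: dict | None = None,
    mua: dict | None = None,
    n_trials: int = 300,
    dt: float = DEFAULT_DT,
    span: float = 200.0,
    noise_sd: float = 4.0,
    seed: int = 0,
) -> SweepSet:
    """Broadband extracellular sweeps: slow LFP deflection + Poisson MUA.

    ``lfp``: onset (ms after click, defined as the 20%-of-peak time), slope
    (uV/ms over the rising phase), amplitude (negative uV), decay_tau.
    ``mua``: baseline_rate / evoked_rate (Hz), evoked_onset (ms after
    click), evoked_duration, spike_amplitude (uV).  Ground-truth spike
    times are stored in per-sweep metadata.
    """
    lfp = dict(lfp or {})
    mua = dict(mua or {})
    lfp_onset = lfp.get("onset", 9.7)
    lfp_amp = lfp.get("amplitude", -120.0)
    lfp_slope = lfp.get("slope", 12.0)
    lfp_tau = lfp.get("decay_tau", 25.0)
    rate0 = mua.get("baseline_rate", 0.0)
    rate1 = mua.get("evoked_rate", 0.0)
    ev_onset = mua.get("evoked_onset", 15.0)
    ev_dur = mua.get("evoked_duration", 30.0)
    spike_amp = mua.get("spike_amplitude", -40.0)
    if rate0 < 0 or rate1 < 0:
        raise ValueError("firing rates must be >= 0")

    n = int(round(span / dt))
    t = dt * np.arange(n)
    clean = np.zeros(n)
    if lfp_amp != 0 and lfp_slope > 0:
        rise = abs(lfp_amp) / lfp_slope
        for ct in click_times:
            start = ct + lfp_onset - 0.2 * rise
            u = t - start
            ramp = np.clip(u / rise, 0.0, 1.0)
            deflect = np.where(
                u < rise, ramp, np.exp(-(u - rise) / lfp_tau)
            )
            deflect[u < 0] = 0.0
            clean += lfp_amp * deflect

    spike = _biphasic_spike(dt, spike_amp)
    sweeps = np.empty((n_trials, n))
    meta = []
    for i in range(n_trials):
        rng = np.random.default_rng([seed, 300, i])
        x = clean + rng.standard_normal(n) * noise_sd
        times = []
        if rate0 > 0:
            k = rng.poisson(rate0 * span / 1000.0)
            times.extend(rng.uniform(0.0, span, k))
        if rate1 > rate0:
            for ct in click_times:
                k = rng.poisson((rate1 - rate0) * ev_dur / 1000.0)
                times.extend(rng.uniform(ct + ev_onset, ct + ev_onset + ev_dur, k))
        times = sorted(float(x_) for x_ in times)
        for st in times:
            _add_at(x, spike, int(round(st / dt)), 1.0)
        sweeps[i] = x
        meta.append({"condition": "control", "spike_times": times, "seed": seed})
    stim = StimulusTrain(onsets=np.asarray(click_times, dtype=float),
                         width=0.2, kind="click")
    return SweepSet(sweeps, dt=dt, units="uV", stimulus=stim,
                    per_sweep_meta=tuple(meta))
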