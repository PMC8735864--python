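"""Train-response analysis.

Builds the expected-linear waveform by superposing the cell's own
single-pulse response at each pulse onset, measures per-pulse observed and
expected amplitudes (from pre-train baseline and trough-to-peak), extracts
the slow tonic component by inter-flash interpolation and smoothing, and
fits the post-train after-hyperpolarization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from . import kinetics
from .trace_model import StimulusTrain, Waveform

__all__ = [
    "TrainMetrics",
    "AHPFit",
    "expected_linear_train",
    "per_pulse_ratios",
    "extract_tonic",
    "fit_ahp",
]


@dataclass
class TrainMetrics:
    """Per-pulse train summary."""

    observed_peaks: np.ndarray
    expected_peaks: np.ndarray
    ratios: np.ndarray  # observed_k / expected_k; NaN where undefined
    trough_to_peak: np.ndarray
    peak_times: np.ndarray
    tonic_amplitude: float | None = None
    ahp: "AHPFit | None" = None


@dataclass
class AHPFit:
    onset_tau: float | None
    recovery_tau: float | None
    trough: float
    trough_time: float | None = None
    present: bool = True
    extras: dict = field(default_factory=dict)


def expected_linear_train(
    single: Waveform, train: StimulusTrain, first_observed_peak: float,
    single_onset: float = 0.0,
) -> Waveform:
    """Expected waveform under linear summation.

    The single-pulse response (stimulus at ``single_onset`` in its own time
    frame) is scaled so its peak equals ``first_observed_peak``, then
    superposed at each pulse onset of ``train`` -- the discrete convolution
    of the scaled single response with unit impulses at the onsets.
    """
    if train.n_pulses == 0:
        raise ValueError("stimulus train is empty")
    amp, _, _ = kinetics.peak_amplitude(
        single, search_window=(0.0, single.duration - single_onset - single.dt),
        stimulus_onset=single_onset,
    )
    if amp == 0:
        raise ValueError("single response has zero peak; cannot normalize")
    scaled = single.samples * (first_observed_peak / amp)
    # response portion starting at the single's stimulus onset
    k0 = single.index_of(single_onset)
    resp = scaled[k0:]
    dt = single.dt
    isi = train.isi if train.n_pulses > 1 else 0.0
    n = int(round((train.onsets[-1] + max(isi, 0) ) / dt)) + resp.size
    out = np.zeros(n)
    for onset in train.onsets:
        i = int(round(onset / dt))
        stop = min(i + resp.size, n)
        out[i:stop] += resp[: stop - i]
    return Waveform(out, dt=dt, t0=0.0, units=single.units,
                    meta={"first_observed_peak": first_observed_peak})


def _pulse_windows(train: StimulusTrain, t_last: float) -> list[tuple]:
    """Per-pulse peak-search windows: (onset_k, onset_{k+1}); the final
    window spans one ISI (or the remaining trace for single pulses)."""
    onsets = train.onsets
    if train.n_pulses == 1:
        return [(float(onsets[0]), t_last)]
    isi = float(np.diff(onsets).mean())
    bounds = list(onsets) + [float(onsets[-1]) + isi]
    return [(float(bounds[k]), float(bounds[k + 1])) for k in range(train.n_pulses)]


def per_pulse_ratios(
    observed: Waveform,
    expected: Waveform,
    train: StimulusTrain,
    noise_floor: float = 0.0,
) -> TrainMetrics:
    """Per-pulse observed and expected peaks, their ratios, and
    trough-to-peak amplitudes.

    Peaks are measured from the pre-train baseline (traces are assumed
    baseline-subtracted) within each pulse window; the trough-to-peak
    amplitude subtracts the local minimum between the previous and current
    onset.  Ratios where the expected peak is at/below ``noise_floor`` are
    NaN.
    """
    windows = _pulse_windows(train, observed.time[-1])
    n = train.n_pulses
    obs = np.full(n, np.nan)
    exp = np.full(n, np.nan)
    t_pk = np.full(n, np.nan)
    ttp = np.full(n, np.nan)
    for k, (lo, hi) in enumerate(windows):
        try:
            obs[k], t_pk[k], _ = kinetics.peak_amplitude(
                observed, search_window=(lo, min(hi, observed.time[-1])),
                stimulus_onset=0.0,
            )
            exp[k], _, _ = kinetics.peak_amplitude(
                expected, search_window=(lo, min(hi, expected.time[-1])),
                stimulus_onset=0.0,
            )
        except ValueError:
            continue
        prev = windows[k - 1][0] if k > 0 else max(lo - (hi - lo), observed.t0)
        i0 = observed.index_of(prev)
        i1 = observed.index_of(lo) + 1
        trough = float(observed.samples[i0:i1].min())
        ttp[k] = obs[k] - trough
    with np.errstate(invalid="ignore", divide="ignore"):
        ratios = np.where(exp > noise_floor, obs / exp, np.nan)
    if np.any(np.isnan(ratios)):
        warnings.warn("some pulses have undefined observed/expected ratios",
                      stacklevel=2)
    return TrainMetrics(observed_peaks=obs, expected_peaks=exp, ratios=ratios,
                        trough_to_peak=ttp, peak_times=t_pk)


def extract_tonic(
    observed: Waveform,
    train: StimulusTrain,
    smooth_window: float = 50.0,
    steady_window: float = 1000.0,
) -> tuple[Waveform, float]:
    """Slow (tonic) component of a train response.

    The sample immediately preceding each pulse onset anchors a piecewise-
    linear interpolation across the train (removing the phasic component);
    the interpolated trace is boxcar-smoothed over ``smooth_window`` ms and
    the tonic amplitude is its mean over the final ``steady_window`` ms of
    stimulation.
    """
    t = observed.time
    dt = observed.dt
    train_span = float(train.onsets[-1] - train.onsets[0])
    if train_span < steady_window:
        warnings.warn(
            f"train ({train_span:.0f} ms) shorter than steady window; "
            "using the full train", stacklevel=2)
        steady_window = train_span
    anchor_idx = np.array(
        [max(observed.index_of(o) - 1, 0) for o in train.onsets]
    )
    anchor_t = t[anchor_idx]
    anchor_v = observed.samples[anchor_idx]
    interp = np.interp(t, anchor_t, anchor_v)
    m = max(int(round(smooth_window / dt)), 1)
    kernel = np.ones(m) / m
    smoothed = np.convolve(interp, kernel, mode="same")
    tonic = Waveform(smoothed, dt=dt, t0=observed.t0, units=observed.units)
    t_end = float(train.onsets[-1])
    sel = (t >= t_end - steady_window) & (t <= t_end)
    amplitude = float(smoothed[sel].mean())
    return tonic, amplitude


def _sat_exp(t, a, tau):
    return a * (1.0 - np.exp(-t / tau))


def _dec_exp(t, a, tau):
    return a * np.exp(-t / tau)


def fit_ahp(
    observed: Waveform,
    train_end: float,
    baseline: float = 0.0,
    min_depth_sd: float = 0.0,
) -> AHPFit:
    """Post-train after-hyperpolarization fit.

    Finds the sub-baseline trough after ``train_end``; fits
    ``a (1 - exp(-t/tau))`` from the first sub-baseline crossing to the
    trough (onset tau) and ``a exp(-t/tau)`` from the trough onward
    (recovery tau).  Returns a no-AHP result when the trace never dips
    below baseline (or below ``min_depth_sd`` worth of noise).
    """
    k0 = observed.index_of(train_end)
    x = observed.samples[k0:] - baseline
    t = observed.time[k0:] - observed.time[k0]
    k_tr = int(np.argmin(x))
    trough = float(x[k_tr])
    if trough >= -abs(min_depth_sd) or k_tr == 0:
        return AHPFit(onset_tau=None, recovery_tau=None, trough=trough,
                      present=False)
    below = np.flatnonzero(x[: k_tr + 1] < 0)
    k_cross = int(below[0]) if below.size else 0

    # onset fit in the train-end time frame; the window starts at the
    # sub-baseline crossing so decaying phasic tails do not bias the fit
    onset_tau = None
    seg_t = t[k_cross:k_tr + 1]
    seg_x = x[k_cross:k_tr + 1]
    if seg_t.size >= 4:
        step = max(seg_t.size // 5000, 1)
        try:
            popt, _ = curve_fit(
                _sat_exp, seg_t[::step], seg_x[::step],
                p0=[trough, max(seg_t[-1] / 3.0, observed.dt)], maxfev=10000,
            )
            onset_tau = float(popt[1])
        except RuntimeError:
            pass

    recovery_tau = None
    rec_t = t[k_tr:] - t[k_tr]
    rec_x = x[k_tr:]
    if rec_t.size >= 4:
        step = max(rec_t.size // 5000, 1)
        try:
            popt, _ = curve_fit(
                _dec_exp, rec_t[::step], rec_x[::step],
                p0=[trough, max(rec_t[-1] / 3.0, observed.dt)], maxfev=10000,
            )
            recovery_tau = float(popt[1])
        except RuntimeError:
            pass
    return AHPFit(onset_tau=onset_tau, recovery_tau=recovery_tau,
                  trough=trough, trough_time=float(observed.time[k0 + k_tr]))
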