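"""Single-response kinetic metrics.

Amplitude, half-width, onset latency, 10-90% rise time, exponential decay
fitting (1 or 2 components with an amplitude-weighted time constant) and the
cumulative integral.  Metrics operate on baseline-subtracted averaged
traces; EPSC (pA) waveforms are handled polarity-aware (the "peak" is the
most negative excursion).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .trace_model import Waveform

__all__ = [
    "EPSPMetrics",
    "peak_amplitude",
    "half_width",
    "onset_latency",
    "rise_time_10_90",
    "fit_decay",
    "cumulative_integral",
    "measure_epsp",
    "UnresolvedMetricError",
    "DecayFitError",
]

# default peak-search windows after stimulus onset, ms
PEAK_WINDOW_IN_VITRO = (1.0, 50.0)
PEAK_WINDOW_IN_VIVO = (1.0, 100.0)


class UnresolvedMetricError(ValueError):
    """A metric's defining crossing does not exist in the trace."""


class DecayFitError(RuntimeError):
    """Decay fit failed to converge; carries the residual report."""


@dataclass
class EPSPMetrics:
    """Kinetic summary of a single averaged response."""

    peak_amplitude: float
    peak_time: float
    half_width: float | None = None
    onset_latency: float | None = None
    rise_10_90: float | None = None
    weighted_tau: float | None = None
    components: list = field(default_factory=list)  # (amplitude, tau) pairs
    integral: float | None = None
    below_noise: bool = False
    units: str = "mV"


def _polarity(w: Waveform) -> float:
    """+1 for potentials (mV/uV), -1 for currents at negative holding (pA)."""
    return -1.0 if w.units == "pA" else 1.0


def peak_amplitude(
    w: Waveform,
    search_window: tuple = PEAK_WINDOW_IN_VITRO,
    stimulus_onset: float = 0.0,
    avg_halfwidth: float = 0.1,
    baseline_sd: float | None = None,
    noise_multiplier: float = 3.0,
) -> tuple[float, float, bool]:
    """Locate the response peak and measure its amplitude.

    The local extremum is found within ``stimulus_onset + search_window``
    and the amplitude is the mean of the samples within ``avg_halfwidth``
    (0.1 ms by default) on either side of it.  For pA waveforms the minimum
    is used.  Returns ``(amplitude, peak_time, below_noise)``; the flag is
    set when ``baseline_sd`` is given and the amplitude is smaller than
    ``noise_multiplier * baseline_sd``.
    """
    lo = stimulus_onset + search_window[0]
    hi = stimulus_onset + search_window[1]
    t = w.time
    mask = (t >= lo) & (t <= hi)
    if not np.any(mask):
        raise ValueError(f"empty peak-search window ({lo}, {hi}) ms")
    pol = _polarity(w)
    idx = np.flatnonzero(mask)
    rel = np.argmax(pol * w.samples[idx])
    k = idx[rel]
    halo = max(int(round(avg_halfwidth / w.dt)), 0)
    a, b = max(k - halo, 0), min(k + halo + 1, w.samples.size)
    amp = float(w.samples[a:b].mean())
    below = False
    if baseline_sd is not None and pol * amp < noise_multiplier * baseline_sd:
        below = True
    return amp, float(t[k]), below


def _cross_time(t: np.ndarray, x: np.ndarray, level: float, rising: bool) -> float:
    """First linear-interpolated crossing of ``level``.

    ``rising`` selects upward (x goes from below to >= level) vs downward
    crossings.  Raises if no crossing exists.
    """
    if rising:
        hit = (x[:-1] < level) & (x[1:] >= level)
    else:
        hit = (x[:-1] >= level) & (x[1:] < level)
    idx = np.flatnonzero(hit)
    if idx.size == 0:
        raise UnresolvedMetricError(f"no {'rising' if rising else 'falling'} "
                                    f"crossing of level {level:g}")
    i = idx[0]
    x0, x1 = x[i], x[i + 1]
    frac = 0.0 if x1 == x0 else (level - x0) / (x1 - x0)
    return float(t[i] + frac * (t[i + 1] - t[i]))


def half_width(w: Waveform, peak_time: float, peak_value: float | None = None) -> float:
    """Full width at half maximum via interpolated crossings on both flanks."""
    pol = _polarity(w)
    x = pol * w.samples
    t = w.time
    k = w.index_of(peak_time)
    peak = pol * peak_value if peak_value is not None else x[k]
    half = peak / 2.0
    t_up = _cross_time(t[: k + 1], x[: k + 1], half, rising=True)
    try:
        t_down = _cross_time(t[k:], x[k:], half, rising=False)
    except UnresolvedMetricError as e:
        raise UnresolvedMetricError(
            "trace never falls below half-maximum after the peak"
        ) from e
    return t_down - t_up


def onset_latency(
    w: Waveform, stimulus_onset: float, peak_time: float,
    peak_value: float | None = None, fraction: float = 0.2,
) -> float:
    """Latency from stimulus onset to the ``fraction``-of-peak crossing."""
    pol = _polarity(w)
    x = pol * w.samples
    t = w.time
    k0 = w.index_of(stimulus_onset)
    k1 = w.index_of(peak_time) + 1
    peak = pol * peak_value if peak_value is not None else x[w.index_of(peak_time)]
    t_cross = _cross_time(t[k0:k1], x[k0:k1], fraction * peak, rising=True)
    return t_cross - stimulus_onset


def rise_time_10_90(
    w: Waveform, peak_time: float, peak_value: float | None = None,
    start_time: float = 0.0,
) -> float:
    """10% -> 90% of-peak interval on the rising flank (first crossings)."""
    pol = _polarity(w)
    x = pol * w.samples
    t = w.time
    k0 = w.index_of(start_time)
    k1 = w.index_of(peak_time) + 1
    peak = pol * peak_value if peak_value is not None else x[w.index_of(peak_time)]
    seg_t, seg_x = t[k0:k1], x[k0:k1]
    t10 = _cross_time(seg_t, seg_x, 0.1 * peak, rising=True)
    t90 = _cross_time(seg_t, seg_x, 0.9 * peak, rising=True)
    # non-monotone flanks: first crossings are used; warn if the segment dips
    after10 = seg_x[seg_t >= t10]
    if after10.size and np.min(after10[: int((t90 - t10) / w.dt) + 1]) < 0.05 * peak:
        warnings.warn("non-monotone rising flank; using first crossings",
                      stacklevel=2)
    return t90 - t10


def _multiexp(t, *params):
    n = len(params) // 2
    out = np.zeros_like(t, dtype=float)
    for i in range(n):
        out += params[2 * i] * np.exp(-t / params[2 * i + 1])
    return out


def fit_decay(
    w: Waveform,
    peak_time: float,
    n_components: int = 1,
    fit_span: float | None = None,
) -> tuple[list[tuple[float, float]], float]:
    """Fit the post-peak decay with a sum of exponentials.

    Least-squares fit of ``sum_i A_i exp(-t/tau_i)`` to the trace from the
    peak onward (optionally limited to ``fit_span`` ms), initialized from a
    log-linear fit of the tail.  Returns the ``(amplitude, tau)`` components
    sorted by tau and the amplitude-weighted time constant
    ``sum(|A_i| tau_i) / sum(|A_i|)``.
    """
    if n_components not in (1, 2):
        raise ValueError("n_components must be 1 or 2")
    pol = _polarity(w)
    k = w.index_of(peak_time)
    x = pol * w.samples[k:]
    t = w.time[k:] - w.time[k]
    if fit_span is not None:
        m = t <= fit_span
        t, x = t[m], x[m]
    if x.size < 4 * n_components:
        raise DecayFitError("too few samples after peak for decay fit")
    peak = x[0]
    if peak <= 0:
        raise DecayFitError("non-positive peak; cannot fit decay")

    # initial guess: log-linear fit on the tail (positive part only)
    pos = x > 0.05 * peak
    tail = slice(x.size // 2, None)
    tt, xx = t[tail][pos[tail]], x[tail][pos[tail]]
    if tt.size >= 2:
        slope, intercept = np.polyfit(tt, np.log(xx), 1)
        tau_slow = -1.0 / slope if slope < 0 else t[-1] / 2
    else:
        tau_slow = t[-1] / 3
    tau_slow = float(np.clip(tau_slow, w.dt, 100 * t[-1]))

    if n_components == 1:
        p0 = [peak, tau_slow]
    else:
        p0 = [0.6 * peak, max(tau_slow / 5, 2 * w.dt), 0.4 * peak, tau_slow]
    # decimate very long traces for speed; decay structure is preserved
    step = max(x.size // 20000, 1)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                _multiexp, t[::step], x[::step], p0=p0, maxfev=20000,
                bounds=([-np.inf, w.dt / 10] * n_components,
                        [np.inf, np.inf] * n_components),
            )
    except RuntimeError as e:
        resid = float(np.sqrt(np.mean((x - _multiexp(t, *p0)) ** 2)))
        raise DecayFitError(f"decay fit did not converge (rms residual of "
                            f"initial guess: {resid:.3g})") from e
    comps = sorted(
        [(pol * popt[2 * i], float(popt[2 * i + 1])) for i in range(n_components)],
        key=lambda c: c[1],
    )
    amps = np.array([abs(a) for a, _ in comps])
    taus = np.array([tau for _, tau in comps])
    if t[-1] < 5 * taus.max():
        warnings.warn("fewer than 5 decay constants of data after the peak; "
                      "tau estimates may be unstable", stacklevel=2)
    weighted_tau = float((amps * taus).sum() / amps.sum())
    return comps, weighted_tau


def cumulative_integral(
    w: Waveform, window: tuple | None = None
) -> tuple[float, Waveform]:
    """Trapezoidal integral over ``window`` (ms) and the running integral.

    Returns ``(total, running)`` where ``running`` is a Waveform of the
    cumulative integral (units x ms) over the window.
    """
    t = w.time
    if window is None:
        sl = slice(None)
    else:
        i0 = w.index_of(window[0])
        i1 = w.index_of(window[1]) + 1
        sl = slice(i0, i1)
    seg = w.samples[sl]
    tt = t[sl]
    running = np.concatenate(
        [[0.0], np.cumsum(0.5 * (seg[1:] + seg[:-1]) * np.diff(tt))]
    )
    total = float(running[-1])
    return total, Waveform(running, dt=w.dt, t0=float(tt[0]), units=w.units)


def measure_epsp(
    w: Waveform,
    stimulus_onset: float = 0.0,
    search_window: tuple = PEAK_WINDOW_IN_VITRO,
    baseline_sd: float | None = None,
    n_decay_components: int = 1,
    integral_window: tuple | None = None,
) -> EPSPMetrics:
    """Full kinetic summary of one averaged response.

    Convenience wrapper running peak, half-width, onset, rise time, decay
    fit and integral in one pass; individual failures of the crossing-based
    metrics leave those fields None rather than aborting the others.
    """
    amp, t_peak, below = peak_amplitude(
        w, search_window, stimulus_onset, baseline_sd=baseline_sd
    )
    m = EPSPMetrics(peak_amplitude=amp, peak_time=t_peak, below_noise=below,
                    units=w.units)
    if below:
        return m
    for name, fn in (
        ("half_width", lambda: half_width(w, t_peak, amp)),
        ("onset_latency", lambda: onset_latency(w, stimulus_onset, t_peak, amp)),
        ("rise_10_90", lambda: rise_time_10_90(w, t_peak, amp, stimulus_onset)),
    ):
        try:
            setattr(m, name, fn())
        except UnresolvedMetricError:
            pass
    try:
        m.components, m.weighted_tau = fit_decay(w, t_peak, n_decay_components)
    except DecayFitError:
        pass
    m.integral, _ = cumulative_integral(
        w, integral_window or (stimulus_onset, w.time[-1])
    )
    return m
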