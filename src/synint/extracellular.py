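"""Extracellular analysis: LFP conditioning and onset/slope, multiunit
detection, PSTH construction and conduction-velocity arithmetic.

Onset latencies follow the 20%-of-peak convention throughout; LFP traces
are analyzed after baseline subtraction and 500 Hz low-pass filtering, MUA
after 300-5000 Hz band-pass filtering with a MAD-based threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .preprocess import average_sweeps, subtract_baseline
from .trace_model import SweepSet, Waveform

__all__ = [
    "ExtracellularResult",
    "lfp_preprocess",
    "lfp_onset_and_slope",
    "detect_mua",
    "build_psth",
    "psth_onset",
    "conduction_velocity",
]


@dataclass
class ExtracellularResult:
    lfp_onset: float | None = None
    lfp_slope: float | None = None
    mua_onset: float | None = None
    psth_bins: np.ndarray | None = None
    psth_rates: np.ndarray | None = None
    spike_times: list = field(default_factory=list)


def lfp_preprocess(
    s: SweepSet,
    cutoff: float = 500.0,
    baseline_window: tuple | None = None,
) -> Waveform:
    """Baseline-subtract, zero-phase low-pass at ``cutoff`` Hz, and average."""
    if baseline_window is None:
        first = float(s.stimulus.onsets[0]) if s.stimulus is not None else s.duration
        baseline_window = (s.t0, s.t0 + max(first - s.t0 - 1.0, 2 * s.dt))
    sub = subtract_baseline(s, baseline_window)
    fs = 1000.0 / s.dt
    sos = signal.butter(4, cutoff / (fs / 2.0), btype="low", output="sos")
    filtered = signal.sosfiltfilt(sos, sub.sweeps, axis=1)
    return average_sweeps(sub.with_sweeps(filtered))


def lfp_onset_and_slope(
    lfp: Waveform,
    click_time: float,
    noise_multiplier: float = 5.0,
    baseline_window: tuple | None = None,
) -> tuple[float | None, float | None]:
    """Onset (20%-of-peak crossing after the click, ms re click) and slope
    (least-squares line over the 20-80% rising segment, units/ms).

    Returns ``(None, None)`` when no deflection exceeds the baseline noise.
    """
    t = lfp.time
    if baseline_window is None:
        baseline_window = (t[0], max(click_time - 1.0, t[0] + 2 * lfp.dt))
    bsel = (t >= baseline_window[0]) & (t <= baseline_window[1])
    noise_sd = float(lfp.samples[bsel].std())
    post = t >= click_time
    seg = lfp.samples[post]
    seg_t = t[post]
    k = int(np.argmax(np.abs(seg)))
    peak = float(seg[k])
    if abs(peak) <= noise_multiplier * noise_sd:
        return None, None
    sign = np.sign(peak)
    x = sign * seg  # peak-positive view
    pk = sign * peak

    def _first_cross(level):
        hit = np.flatnonzero((x[:-1] < level) & (x[1:] >= level))
        hit = hit[hit <= k]
        if hit.size == 0:
            return None
        i = hit[0]
        frac = (level - x[i]) / (x[i + 1] - x[i])
        return float(seg_t[i] + frac * (seg_t[i + 1] - seg_t[i]))

    t20 = _first_cross(0.2 * pk)
    t80 = _first_cross(0.8 * pk)
    if t20 is None:
        return None, None
    onset = t20 - click_time
    slope = None
    if t80 is not None and t80 > t20:
        sel = (seg_t >= t20) & (seg_t <= t80)
        if sel.sum() >= 2:
            slope = float(np.polyfit(seg_t[sel], seg[sel], 1)[0])
    return onset, slope


def detect_mua(
    s: SweepSet,
    band: tuple = (300.0, 5000.0),
    threshold_multiplier: float = 4.0,
    refractory: float = 1.0,
    polarity: str = "negative",
) -> list[np.ndarray]:
    """Per-trial spike times (ms) from threshold crossings of the band-passed
    trace.

    The threshold is ``threshold_multiplier`` times a robust (MAD-based)
    noise SD estimated per trial; crossings within ``refractory`` ms merge.
    """
    fs = 1000.0 / s.dt
    nyq = fs / 2.0
    if not (0 < band[0] < band[1] < nyq):
        raise ValueError(f"band {band} Hz invalid for Nyquist {nyq} Hz")
    sos = signal.butter(4, (band[0] / nyq, band[1] / nyq), btype="band",
                        output="sos")
    filtered = signal.sosfiltfilt(sos, s.sweeps, axis=1)
    sign = -1.0 if polarity == "negative" else 1.0
    out = []
    ref = max(int(round(refractory / s.dt)), 1)
    guard = max(int(round(1.0 / s.dt)), 1)  # skip filtfilt edge transients
    for row in filtered:
        x = sign * row
        sd = float(np.median(np.abs(row[guard:-guard])) / 0.6745)
        thr = threshold_multiplier * sd
        above = x >= thr
        crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
        crossings = crossings[(crossings >= guard)
                              & (crossings < x.size - guard)]
        times = []
        last = -ref
        for c in crossings:
            if c - last >= ref:
                times.append(s.t0 + c * s.dt)
                last = c
        out.append(np.asarray(times))
    return out


def build_psth(
    spike_times: list,
    span: tuple,
    bin_width: float = 0.1,
    smooth: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Peristimulus time histogram.

    Rates are per-bin spike counts normalized by ``trials * bin_width`` (in
    Hz), boxcar-smoothed over ``smooth`` ms.  Returns (bin centers, rates).
    """
    if len(spike_times) == 0:
        raise ValueError("need at least one trial")
    edges = np.arange(span[0], span[1] + bin_width / 2, bin_width)
    counts = np.zeros(edges.size - 1)
    for trial in spike_times:
        c, _ = np.histogram(trial, bins=edges)
        counts += c
    n_trials = len(spike_times)
    rates = counts / (n_trials * bin_width * 1e-3)  # Hz
    m = max(int(round(smooth / bin_width)), 1)
    rates = np.convolve(rates, np.ones(m) / m, mode="same")
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, rates


def psth_onset(
    centers: np.ndarray,
    rates: np.ndarray,
    click_time: float,
    noise_multiplier: float = 3.0,
) -> float | None:
    """20%-of-(peak - baseline) crossing after the click; baseline is the
    pre-click mean rate.  None when the PSTH shows no evoked peak."""
    pre = centers < click_time
    baseline = float(rates[pre].mean()) if pre.any() else 0.0
    base_sd = float(rates[pre].std()) if pre.any() else 0.0
    post = centers >= click_time
    seg = rates[post] - baseline
    seg_t = centers[post]
    k = int(np.argmax(seg))
    peak = float(seg[k])
    if peak <= noise_multiplier * base_sd or peak <= 0:
        return None
    level = 0.2 * peak
    hit = np.flatnonzero((seg[:-1] < level) & (seg[1:] >= level))
    hit = hit[hit <= k]
    if hit.size == 0:
        return None
    i = hit[0]
    frac = (level - seg[i]) / (seg[i + 1] - seg[i])
    return float(seg_t[i] + frac * (seg_t[i + 1] - seg_t[i]) - click_time)


def conduction_velocity(
    path_length_mm: float,
    onset_latency_ms: float,
    release_delay_ms: float,
) -> float:
    """Minimum conduction velocity in m/s: path / (latency - release delay)."""
    dt = onset_latency_ms - release_delay_ms
    if dt <= 0:
        raise ValueError("onset latency must exceed the release delay")
    return path_length_mm / dt  # mm/ms == m/s
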