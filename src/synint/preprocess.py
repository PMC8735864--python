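"""Deterministic trace conditioning: baseline subtraction, zero-phase
low-pass filtering, trial averaging, spike blanking and artifact removal.

All operations return new objects; inputs are never mutated.  Spike and
artifact removal replace contaminated samples by linear interpolation so
that averaged traces are free of regenerative events.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .trace_model import SweepSet, Waveform

__all__ = [
    "BlankingReport",
    "subtract_baseline",
    "lowpass_filter",
    "average_sweeps",
    "blank_spikes",
    "blank_artifacts",
]


@dataclass
class BlankingReport:
    """Record of spike-blanking events.

    ``events`` holds ``(sweep_index, crossing_time_ms, span_ms)`` tuples;
    ``threshold_used`` is the dV/dt criterion in mV/ms.
    """

    events: list = field(default_factory=list)
    threshold_used: float = 20.0

    @property
    def n_events(self) -> int:
        return len(self.events)


def _window_slice(n: int, dt: float, t0: float, window: tuple) -> slice:
    lo, hi = window
    i0 = int(np.ceil((lo - t0) / dt))
    i1 = int(np.floor((hi - t0) / dt)) + 1
    if i0 < 0 or i1 > n or i1 - i0 < 1:
        raise ValueError(f"window {window} ms outside sweep range")
    return slice(i0, i1)


def subtract_baseline(s: SweepSet, window: tuple) -> SweepSet:
    """Subtract the per-sweep mean over ``window`` (ms) from each sweep.

    The window must precede the first stimulus onset when a stimulus is
    attached.  Idempotent: applying it twice equals applying it once.
    """
    if s.stimulus is not None and window[1] > s.stimulus.onsets[0]:
        raise ValueError(
            f"baseline window {window} extends past first stimulus onset "
            f"{s.stimulus.onsets[0]} ms"
        )
    sl = _window_slice(s.n_samples, s.dt, s.t0, window)
    baselines = s.sweeps[:, sl].mean(axis=1, keepdims=True)
    return s.with_sweeps(s.sweeps - baselines)


def lowpass_filter(s: SweepSet, cutoff: float = 1000.0) -> SweepSet:
    """Zero-phase 4th-order Butterworth low-pass at ``cutoff`` Hz.

    Forward-backward filtering (sosfiltfilt) so symmetric pulses keep their
    peak times.
    """
    fs = 1000.0 / s.dt  # Hz
    nyq = fs / 2.0
    if cutoff >= nyq:
        raise ValueError(f"cutoff {cutoff} Hz >= Nyquist {nyq} Hz")
    sos = signal.butter(4, cutoff / nyq, btype="low", output="sos")
    filtered = signal.sosfiltfilt(sos, s.sweeps, axis=1)
    return s.with_sweeps(filtered)


def lowpass_waveform(w: Waveform, cutoff: float = 1000.0) -> Waveform:
    """Zero-phase Butterworth low-pass for a single Waveform."""
    fs = 1000.0 / w.dt
    nyq = fs / 2.0
    if cutoff >= nyq:
        raise ValueError(f"cutoff {cutoff} Hz >= Nyquist {nyq} Hz")
    sos = signal.butter(4, cutoff / nyq, btype="low", output="sos")
    return w.with_samples(signal.sosfiltfilt(sos, w.samples))


def average_sweeps(s: SweepSet, **criteria) -> Waveform:
    """Sample-wise mean across sweeps, optionally filtered by metadata.

    Keyword criteria are matched against ``per_sweep_meta`` (e.g.
    ``condition="control"``).  The returned waveform records how many sweeps
    were averaged in ``meta["n_averaged"]``.
    """
    sub = s.select(**criteria) if criteria else s
    avg = sub.sweeps.mean(axis=0)
    return Waveform(avg, dt=s.dt, t0=s.t0, units=s.units,
                    meta={"n_averaged": sub.n_sweeps})


def _dvdt(x: np.ndarray, dt: float) -> np.ndarray:
    """Central-difference derivative, mV/ms."""
    return np.gradient(x, dt)


def blank_spikes(
    s: SweepSet,
    dvdt_threshold: float = 20.0,
    span: float = 0.2,
    dvdt_filter_cutoff: float = 1000.0,
) -> tuple[SweepSet, BlankingReport]:
    """Remove action potentials by linear interpolation.

    dV/dt is computed by central differences on a 1 kHz-filtered copy; at
    each upward crossing of ``dvdt_threshold`` (mV/ms) the samples from the
    crossing are replaced, for at least ``span`` ms and extended until the
    trace falls back below its pre-crossing value.  Samples outside the
    reported spans are untouched.
    """
    if s.units != "mV":
        raise ValueError("blank_spikes requires a current-clamp (mV) SweepSet")
    if not (0.1 <= span <= 0.2):
        raise ValueError(f"span must lie in [0.1, 0.2] ms, got {span}")
    out = s.sweeps.copy()
    report = BlankingReport(threshold_used=dvdt_threshold)
    min_gap = max(int(round(span / s.dt)), 1)
    smoothed = lowpass_filter(s, cutoff=dvdt_filter_cutoff).sweeps
    for i in range(s.n_sweeps):
        x = out[i]
        d = _dvdt(smoothed[i], s.dt)
        above = d >= dvdt_threshold
        crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
        j_done = -1
        for c in crossings:
            if c <= j_done:
                continue
            pre_idx = max(c - 1, 0)
            pre_val = x[pre_idx]
            j = c + min_gap
            # extend until the trace returns below its pre-crossing level
            # and dV/dt has fallen back below threshold (the zero-phase
            # filter spreads the upstroke slightly ahead of the crossing)
            while j < x.size - 1 and (x[j] > pre_val or d[j] >= dvdt_threshold):
                j += 1
            j = min(j, x.size - 1)
            x[pre_idx + 1:j] = np.interp(
                np.arange(pre_idx + 1, j), [pre_idx, j], [x[pre_idx], x[j]]
            )
            report.events.append(
                (i, s.t0 + c * s.dt, (j - pre_idx - 1) * s.dt)
            )
            j_done = j
    return s.with_sweeps(out), report


def blank_artifacts(s: SweepSet, windows: list[tuple]) -> SweepSet:
    """Linearly interpolate across stimulus-artifact windows (ms).

    Overlapping windows are merged (a warning notes the merge).  A window
    covering response onset biases downstream latency estimates; the caller
    is warned if a window overlaps a stimulus onset.
    """
    if not windows:
        return s
    ivs = sorted((float(a), float(b)) for a, b in windows)
    merged = [list(ivs[0])]
    for a, b in ivs[1:]:
        if a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
            warnings.warn("overlapping artifact windows merged", stacklevel=2)
        else:
            merged.append([a, b])
    if s.stimulus is not None:
        for a, b in merged:
            if np.any((s.stimulus.onsets >= a) & (s.stimulus.onsets <= b)):
                warnings.warn(
                    f"artifact window ({a}, {b}) ms covers a stimulus onset; "
                    "downstream onset latencies may shift",
                    stacklevel=2,
                )
    out = s.sweeps.copy()
    for a, b in merged:
        sl = _window_slice(s.n_samples, s.dt, s.t0, (a, b))
        i0 = max(sl.start - 1, 0)
        i1 = min(sl.stop, s.n_samples - 1)
        idx = np.arange(sl.start, sl.stop)
        out[:, sl] = np.array(
            [np.interp(idx, [i0, i1], [row[i0], row[i1]]) for row in out]
        )
    return s.with_sweeps(out)
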