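"""Preset calibration.

A calibrated preset embeds a target summary value as generator ground
truth.  Calibration metrics are computed here with deliberately simple,
self-contained numpy code (dense scans, window argmax/argmin, raw anchor
means) so that the analysis pipeline proper, which later re-measures the
same quantities with its interpolating estimators, remains an independent
check.  Every search records its trace in ``CalibrationResult.trace``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..trace_model import StimulusTrain
from .kernels import kernel_shape
from .params import SynthPreset
from .simulate import DEFAULT_DT, clean_train_trace

__all__ = [
    "CalibrationError",
    "CalibrationResult",
    "bisect_parameter",
    "shape_fwhm",
    "oracle_train_ratio",
    "oracle_trough_to_peak_ratio",
    "oracle_tonic_plateau",
    "calibrate_preset",
]


class CalibrationError(RuntimeError):
    """Target unreachable within bounds; message lists the bracket values."""


@dataclass
class CalibrationResult:
    value: float
    target: float
    achieved: float
    trace: list = field(default_factory=list)  # (param, metric) pairs


def bisect_parameter(
    metric_fn,
    target: float,
    bounds: tuple,
    rtol: float = 1e-3,
    max_iter: int = 80,
) -> CalibrationResult:
    """Monotone 1-D search for ``metric_fn(x) == target`` within ``bounds``.

    Works for either monotone direction.  Raises :class:`CalibrationError`
    with the bracket metric values when the target is not enclosed.
    """
    lo, hi = float(bounds[0]), float(bounds[1])
    f_lo, f_hi = metric_fn(lo), metric_fn(hi)
    trace = [(lo, f_lo), (hi, f_hi)]
    if not (min(f_lo, f_hi) <= target <= max(f_lo, f_hi)):
        # allow returning a bound that already meets tolerance
        for x, f in ((lo, f_lo), (hi, f_hi)):
            if abs(f - target) <= rtol * max(abs(target), 1e-12):
                return CalibrationResult(x, target, f, trace)
        raise CalibrationError(
            f"target {target:g} outside reachable range: metric({lo:g})={f_lo:g}, "
            f"metric({hi:g})={f_hi:g}"
        )
    increasing = f_hi > f_lo
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = metric_fn(mid)
        trace.append((mid, f_mid))
        if abs(f_mid - target) <= rtol * max(abs(target), 1e-12):
            return CalibrationResult(mid, target, f_mid, trace)
        if (f_mid < target) == increasing:
            lo = mid
        else:
            hi = mid
    mid = 0.5 * (lo + hi)
    return CalibrationResult(mid, target, metric_fn(mid), trace)


# ---------------------------------------------------------------------------
# closed-form / dense-scan oracles
# ---------------------------------------------------------------------------

def shape_fwhm(tau_rise: float, decays, span: float | None = None) -> float:
    """Full width at half maximum of the difference-of-exponentials shape,
    by dense scan of the closed-form expression."""
    if isinstance(decays, (int, float)):
        decays = ((1.0, float(decays)),)
    if span is None:
        span = 12.0 * max(tau for _, tau in decays)
    t = np.linspace(0.0, span, 400001)
    s = kernel_shape(t, tau_rise, decays)
    k = int(np.argmax(s))
    half = 0.5 * s[k]
    up = np.flatnonzero((s[:-1] < half) & (s[1:] >= half))
    dn = np.flatnonzero((s[:-1] >= half) & (s[1:] < half))
    if up.size == 0 or dn.size == 0:
        raise CalibrationError("shape never crosses half maximum")

    def _x(i, level):
        return t[i] + (level - s[i]) / (s[i + 1] - s[i]) * (t[i + 1] - t[i])

    return _x(dn[-1], half) - _x(up[0], half)


def _window_peaks(trace: np.ndarray, dt: float, onsets: np.ndarray,
                  span_end: float) -> np.ndarray:
    """Per-pulse window maxima (from zero baseline), plain argmax."""
    bounds = list(onsets) + [min(span_end, 2 * onsets[-1] - onsets[-2])
                             if onsets.size > 1 else span_end]
    peaks = np.empty(onsets.size)
    for k in range(onsets.size):
        i0, i1 = int(bounds[k] / dt), int(bounds[k + 1] / dt)
        peaks[k] = trace[i0:i1].max()
    return peaks


def oracle_train_ratio(preset: SynthPreset, rate_hz: float, n_pulses: int = 10,
                       pulse: int = 10, dt: float = DEFAULT_DT) -> float:
    """Observed/expected peak ratio of pulse ``pulse`` on noise-free traces.

    Expected = superposition of the non-depressing kernel train (first-pulse
    peaks match by construction); peaks are plain window maxima.
    """
    train = StimulusTrain.regular(rate_hz, n_pulses, start=20.0)
    span = float(train.onsets[-1]) + 1000.0 / rate_hz + 200.0
    observed = clean_train_trace(preset, train, span, dt=dt)
    linear = clean_train_trace(
        preset.replace(depression=preset.depression.__class__(U=0.0)),
        train, span, dt=dt,
    )
    obs = _window_peaks(observed, dt, train.onsets, span)
    exp = _window_peaks(linear, dt, train.onsets, span)
    return float(obs[pulse - 1] / exp[pulse - 1])


def oracle_trough_to_peak_ratio(
    preset: SynthPreset, rate_hz: float, n_pulses: int = 10,
    dt: float = DEFAULT_DT,
) -> float:
    """Trough-to-peak amplitude ratio of last/first pulse, plain numpy."""
    train = StimulusTrain.regular(rate_hz, n_pulses, start=20.0)
    span = float(train.onsets[-1]) + 1000.0 / rate_hz + 200.0
    x = clean_train_trace(preset, train, span, dt=dt)
    onsets = train.onsets
    isi = train.isi

    def ttp(k):
        o = onsets[k]
        i_prev = int((o - isi) / dt) if k > 0 else 0
        i_on = int(o / dt)
        i_next = int((o + isi) / dt)
        trough = x[i_prev:i_on + 1].min() if k > 0 else x[max(i_on - 10, 0):i_on + 1].min()
        return x[i_on:i_next].max() - trough

    return float(ttp(n_pulses - 1) / ttp(0))


def oracle_tonic_plateau(
    preset: SynthPreset, train: StimulusTrain, span: float,
    steady_window: float = 1000.0, dt: float = DEFAULT_DT,
) -> float:
    """Mean of the pre-onset anchor samples over the final ``steady_window``
    of the train (raw anchor average, no interpolation or smoothing)."""
    x = clean_train_trace(preset, train, span, dt=dt)
    t_end = float(train.onsets[-1])
    anchors = [
        x[int(round(o / dt)) - 1]
        for o in train.onsets
        if o >= t_end - steady_window
    ]
    return float(np.mean(anchors))


# ---------------------------------------------------------------------------
# public entry point
# ---------------------------------------------------------------------------

def calibrate_preset(
    metric: str,
    target: float,
    base: SynthPreset,
    bounds: tuple,
    rate_hz: float = 50.0,
    rtol: float = 1e-3,
    **metric_kwargs,
) -> tuple[SynthPreset, CalibrationResult]:
    """Tune one generator parameter so a noise-free oracle metric hits
    ``target``.

    ``metric`` is one of ``train_ratio`` (observed/expected of the 10th
    pulse; tunes U), ``ttp_ratio`` (last/first trough-to-peak; tunes U) or
    ``tonic_plateau`` (steady-state anchor mean; tunes tonic_amp, solved in
    one step since the relation is linear).
    """
    if metric == "train_ratio":
        def fn(u):
            p = base.replace(depression=base.depression.__class__(
                U=u, tau_rec=base.depression.tau_rec))
            return oracle_train_ratio(p, rate_hz, **metric_kwargs)
        res = bisect_parameter(fn, target, bounds, rtol=rtol)
        preset = base.replace(depression=base.depression.__class__(
            U=res.value, tau_rec=base.depression.tau_rec))
        return preset, res
    if metric == "ttp_ratio":
        def fn(u):
            p = base.replace(depression=base.depression.__class__(
                U=u, tau_rec=base.depression.tau_rec))
            return oracle_trough_to_peak_ratio(p, rate_hz, **metric_kwargs)
        res = bisect_parameter(fn, target, bounds, rtol=rtol)
        preset = base.replace(depression=base.depression.__class__(
            U=res.value, tau_rec=base.depression.tau_rec))
        return preset, res
    if metric == "tonic_plateau":
        train = metric_kwargs.pop("train")
        span = metric_kwargs.pop("span")
        # plateau(tonic_amp) = tonic_amp + phasic residue: linear, one solve
        zero = base.replace(slow=base.slow.__class__(
            **{**_slow_dict(base), "tonic_amp": 0.0}))
        residue = oracle_tonic_plateau(zero, train, span, **metric_kwargs)
        value = target - residue
        if not (bounds[0] <= value <= bounds[1]):
            raise CalibrationError(
                f"required tonic_amp {value:g} outside bounds {bounds}; "
                f"phasic residue is {residue:g}"
            )
        preset = base.replace(slow=base.slow.__class__(
            **{**_slow_dict(base), "tonic_amp": value}))
        achieved = oracle_tonic_plateau(preset, train, span, **metric_kwargs)
        return preset, CalibrationResult(value, target, achieved,
                                         [(0.0, residue), (value, achieved)])
    raise ValueError(f"unknown calibration metric {metric!r}")


def _slow_dict(p: SynthPreset) -> dict:
    import dataclasses
    return dataclasses.asdict(p.slow)
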