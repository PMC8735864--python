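"""Two-pathway integration analysis.

Timing offset from single-pathway kinetics, the arithmetic-sum expected
waveform, per-pulse and integral supralinearity indices, and
fraction-remaining pharmacology comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import kinetics, summation
from .kinetics import EPSPMetrics
from .trace_model import StimulusTrain, Waveform

__all__ = [
    "DualPathwayResult",
    "PharmacologyComparison",
    "OFFSET_BOUNDS_MS",
    "compute_offset",
    "expected_sum",
    "supralinearity_index",
    "fraction_remaining",
]

# configured bounds for the descending-vs-ascending timing offset, ms
OFFSET_BOUNDS_MS = (-1.3, 16.4)

# integral window: first stimulus onset to this long after the last pulse, ms
INTEGRAL_TAIL_MS = 100.0


@dataclass
class DualPathwayResult:
    offset: float
    observed: Waveform
    expected: Waveform
    per_pulse_ratio: np.ndarray
    integral_ratio: float


@dataclass
class PharmacologyComparison:
    metric: str
    control_value: float
    drug_value: float
    fraction_remaining: float | None


def compute_offset(
    ascending: EPSPMetrics,
    descending: EPSPMetrics,
    bounds: tuple = OFFSET_BOUNDS_MS,
) -> float:
    """Timing offset placing descending onset at the ascending peak.

    ``offset = ascending.peak_time - descending.onset_latency`` in the
    stimulus frame (both metrics measured with stimulus at t=0).  Values
    outside ``bounds`` are clamped with a warning.
    """
    if ascending.peak_time is None or descending.onset_latency is None:
        raise ValueError("unresolved single-pathway metrics")
    dt = float(ascending.peak_time - descending.onset_latency)
    lo, hi = bounds
    if not (lo <= dt <= hi):
        clamped = min(max(dt, lo), hi)
        warnings.warn(
            f"offset {dt:.2f} ms outside bounds {bounds}; clamped to "
            f"{clamped:.2f} ms", stacklevel=2)
        return clamped
    return dt


def expected_sum(asc_avg: Waveform, desc_avg: Waveform, offset: float) -> Waveform:
    """Arithmetic sum of single-pathway averages, descending delayed by
    ``offset`` ms (linear interpolation for sub-sample shifts)."""
    if asc_avg.dt != desc_avg.dt:
        raise ValueError("waveforms must share dt")
    if asc_avg.units != desc_avg.units:
        raise ValueError("waveforms must share units")
    t = asc_avg.time
    desc_t = desc_avg.time
    if t[-1] < desc_t[0] + offset:
        raise ValueError("insufficient overlap between pathways at this offset")
    shifted = np.interp(t - offset, desc_t, desc_avg.samples, left=0.0, right=0.0)
    return Waveform(asc_avg.samples + shifted, dt=asc_avg.dt, t0=asc_avg.t0,
                    units=asc_avg.units)


def supralinearity_index(
    observed: Waveform,
    expected: Waveform,
    train: StimulusTrain,
    integral_window: tuple | None = None,
) -> tuple[np.ndarray, float]:
    """Per-pulse observed/expected peak ratios and the cumulative-integral
    observed/expected ratio over the train window.

    The default integral window runs from the first stimulus onset to
    ``INTEGRAL_TAIL_MS`` after the last pulse.
    """
    tm = summation.per_pulse_ratios(observed, expected, train)
    if integral_window is None:
        integral_window = (
            float(train.onsets[0]),
            min(float(train.onsets[-1]) + INTEGRAL_TAIL_MS,
                float(observed.time[-1])),
        )
    obs_int, _ = kinetics.cumulative_integral(observed, integral_window)
    exp_int, _ = kinetics.cumulative_integral(expected, integral_window)
    if exp_int <= 0:
        warnings.warn("expected integral <= 0; integral ratio undefined",
                      stacklevel=2)
        return tm.ratios, float("nan")
    return tm.ratios, float(obs_int / exp_int)


def fraction_remaining(
    control: Waveform,
    drug: Waveform,
    metric: str = "integral",
    train: StimulusTrain | None = None,
    window: tuple | None = None,
    noise_floor: float = 0.0,
) -> PharmacologyComparison:
    """Drug/control ratio of one metric computed identically on both traces.

    ``metric`` is ``integral`` (cumulative integral over ``window``, or the
    train window), ``peak`` or ``half_width``.  The ratio is None when the
    control value does not exceed ``noise_floor``.
    """
    if window is None:
        if train is not None:
            window = (
                float(train.onsets[0]),
                min(float(train.onsets[-1]) + INTEGRAL_TAIL_MS,
                    float(control.time[-1])),
            )
        else:
            window = (float(control.time[0]), float(control.time[-1]))

    def _value(w: Waveform) -> float:
        if metric == "integral":
            total, _ = kinetics.cumulative_integral(w, window)
            return total
        amp, t_pk, _ = kinetics.peak_amplitude(
            w, search_window=window, stimulus_onset=0.0)
        if metric == "peak":
            return amp
        if metric == "half_width":
            return kinetics.half_width(w, t_pk, amp)
        raise ValueError(f"unknown metric {metric!r}")

    c = _value(control)
    d = _value(drug)
    frac = None
    if abs(c) > noise_floor:
        frac = float(d / c)
    else:
        warnings.warn("control metric at/below noise floor; fraction undefined",
                      stacklevel=2)
    return PharmacologyComparison(metric=metric, control_value=c,
                                  drug_value=d, fraction_remaining=frac)
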