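"""Minimal-stimulation analysis.

Trial-by-trial success/failure classification against a noise-based
threshold, failure rate and unitary amplitude, an intensity-response Hill
fit, and the max/min convergence ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .trace_model import SweepSet

__all__ = [
    "MinStimResult",
    "HillFit",
    "classify_success_failure",
    "unitary_stats",
    "fit_hill",
    "max_min_ratio",
]


@dataclass
class HillFit:
    emax: float
    i50: float
    n: float
    covariance: np.ndarray | None = None
    flagged: bool = False

    def __call__(self, intensity):
        i = np.asarray(intensity, dtype=float)
        return self.emax * i ** self.n / (self.i50 ** self.n + i ** self.n)


@dataclass
class MinStimResult:
    labels: np.ndarray  # bool, True = success
    peaks: np.ndarray  # per-trial response-window peak
    decision_threshold: float
    criterion_multiplier: float
    failure_rate: float | None = None
    unitary_amplitude: float | None = None
    max_min_ratio: float | None = None
    hill: HillFit | None = None
    extras: dict = field(default_factory=dict)


def classify_success_failure(
    s: SweepSet,
    response_window: tuple,
    baseline_window: tuple,
    criterion_multiplier: float = 3.0,
    stat_window: float = 1.0,
) -> MinStimResult:
    """Label each trial success or failure.

    The per-trial amplitude is the mean over a ``stat_window``-ms window
    centered on the peak of the trial-average trace (located within
    ``response_window``); the decision threshold is ``criterion_multiplier``
    times the SD of identically sized windowed means computed on
    ``baseline_window`` data.  Using the same matched-window statistic for
    signal and noise makes the failure-trial statistic Gaussian, so the
    false-positive rate follows the analytic normal tail for the chosen
    multiplier.  Trials are assumed baseline-subtracted; windows in ms.
    """
    if response_window[0] < baseline_window[1]:
        raise ValueError(
            f"response window {response_window} overlaps baseline window "
            f"{baseline_window}"
        )
    t = s.time
    bsel = (t >= baseline_window[0]) & (t <= baseline_window[1])
    rsel = (t >= response_window[0]) & (t <= response_window[1])
    if not bsel.any() or not rsel.any():
        raise ValueError("empty baseline or response window")

    avg = s.sweeps.mean(axis=0)
    ridx = np.flatnonzero(rsel)
    k_peak = ridx[int(np.argmax(avg[ridx]))]
    half = max(int(round(stat_window / 2.0 / s.dt)), 1)
    a = max(k_peak - half, 0)
    b = min(k_peak + half + 1, s.n_samples)
    peaks = s.sweeps[:, a:b].mean(axis=1)

    # SD of the same windowed-mean statistic on baseline data
    bidx = np.flatnonzero(bsel)
    width = b - a
    n_chunks = bidx.size // width
    if n_chunks < 1:
        raise ValueError("baseline window shorter than the statistic window")
    chunks = s.sweeps[:, bidx[: n_chunks * width]].reshape(s.n_sweeps, n_chunks, width)
    baseline_sd = float(chunks.mean(axis=2).std())
    threshold = criterion_multiplier * baseline_sd
    labels = peaks > threshold
    return MinStimResult(
        labels=labels, peaks=peaks, decision_threshold=threshold,
        criterion_multiplier=criterion_multiplier,
        extras={"baseline_sd": baseline_sd, "peak_time": float(t[k_peak]),
                "stat_window": stat_window},
    )


def unitary_stats(labels: np.ndarray, amplitudes: np.ndarray) -> tuple[float, float | None]:
    """Failure rate and mean success amplitude.

    ``amplitudes`` are the per-trial response-window peaks; the unitary
    amplitude is the mean over success trials only (None when there are no
    successes).
    """
    labels = np.asarray(labels, dtype=bool)
    amplitudes = np.asarray(amplitudes, dtype=float)
    if labels.size == 0:
        raise ValueError("no trials")
    if labels.size != amplitudes.size:
        raise ValueError("labels and amplitudes differ in length")
    failure_rate = float(np.mean(~labels))
    if not labels.any():
        warnings.warn("no success trials; unitary amplitude undefined",
                      stacklevel=2)
        return failure_rate, None
    return failure_rate, float(amplitudes[labels].mean())


def _hill(i, emax, i50, n):
    return emax * i ** n / (i50 ** n + i ** n)


def fit_hill(intensities: np.ndarray, responses: np.ndarray) -> HillFit:
    """Least-squares Hill fit E(I) = Emax I^n / (I50^n + I^n).

    Requires >= 4 distinct intensities.  Decreasing data produce a flagged
    fit (exponent pinned near zero) rather than silently nonsensical
    parameters.
    """
    intensities = np.asarray(intensities, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if np.unique(intensities).size < 4:
        raise ValueError("Hill fit needs >= 4 distinct intensities")
    if np.polyfit(intensities, responses, 1)[0] < 0:
        warnings.warn("responses decrease with intensity; Hill fit flagged",
                      stacklevel=2)
        return HillFit(emax=float(responses.max()), i50=float(np.median(intensities)),
                       n=0.0, flagged=True)
    p0 = [float(responses.max()), float(np.median(intensities)), 2.0]
    try:
        popt, pcov = curve_fit(
            _hill, intensities, responses, p0=p0, maxfev=20000,
            bounds=([0.0, 1e-9, 1e-3], [np.inf, np.inf, 20.0]),
        )
    except RuntimeError as e:
        raise RuntimeError(f"Hill fit did not converge: {e}") from e
    return HillFit(emax=float(popt[0]), i50=float(popt[1]), n=float(popt[2]),
                   covariance=pcov)


def max_min_ratio(threshold_mean: float, maximal_mean: float) -> float | None:
    """Ratio of maximal-intensity to threshold-intensity mean success EPSP."""
    if threshold_mean is None or threshold_mean <= 0:
        warnings.warn("threshold-intensity mean <= 0; ratio undefined",
                      stacklevel=2)
        return None
    return float(maximal_mean / threshold_mean)
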