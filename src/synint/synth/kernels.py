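"""Response kernels and the depression recursion.

EPSP kernels are differences of exponentials; EPSC kernels use a smoothstep
rise followed by an exactly multi-exponential decay so that post-peak decay
fits have closed-form ground truth.  The depression recursion implements
the standard resource-depletion model

    a_k = A * R_k * U,   R_1 = 1,
    R_{k+1} = 1 - (1 - R_k (1 - U)) * exp(-ISI / tau_rec),

with steady state R_inf = (1 - e) / (1 - (1 - U) e), e = exp(-ISI/tau_rec).
"""

from __future__ import annotations

import numpy as np

from ..trace_model import Waveform
from .params import DepressionParams, KernelParams, SpikeParams

__all__ = [
    "kernel_shape",
    "make_epsp_kernel",
    "make_epsc_kernel",
    "ap_template",
    "depression_amplitudes",
    "depression_steady_state",
]


def kernel_shape(t: np.ndarray, tau_rise: float, decays) -> np.ndarray:
    """Unnormalized difference-of-exponentials: sum_i f_i e^{-t/tau_i} - e^{-t/tau_r}.

    Zero for t < 0.  ``decays`` is a sequence of (fraction, tau) pairs whose
    fractions sum to 1, guaranteeing shape(0) = 0.
    """
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t >= 0
    tp = t[pos]
    acc = -np.exp(-tp / tau_rise)
    for f, tau in decays:
        acc = acc + f * np.exp(-tp / tau)
    out[pos] = acc
    return out


def _shape_peak_and_t20(tau_rise: float, decays, span: float) -> tuple[float, float]:
    """Peak value and 20%-of-peak crossing time of the unit shape (dense scan)."""
    tt = np.linspace(0.0, span, 200001)
    s = kernel_shape(tt, tau_rise, decays)
    k = int(np.argmax(s))
    peak = float(s[k])
    level = 0.2 * peak
    idx = np.flatnonzero((s[:-1] < level) & (s[1:] >= level))
    i = idx[0]
    frac = (level - s[i]) / (s[i + 1] - s[i])
    return peak, float(tt[i] + frac * (tt[i + 1] - tt[i]))


def make_epsp_kernel(k: KernelParams, dt: float, span: float) -> Waveform:
    """Sampled EPSP kernel with exact peak value ``k.amplitude``.

    The shape is shifted so that its 20%-of-peak crossing lands at
    ``k.latency`` (the latency parameter is thus directly comparable to the
    measured onset latency), then peak-normalized so the sampled maximum
    equals ``k.amplitude`` exactly.
    """
    if span <= k.latency:
        raise ValueError("span must exceed the kernel latency")
    t = dt * np.arange(int(round(span / dt)))
    if k.amplitude == 0:
        return Waveform(np.zeros_like(t), dt=dt, units=k.units)
    scan_span = min(span, k.latency + 12 * max(tau for _, tau in k.tau_decay))
    _, t20 = _shape_peak_and_t20(k.tau_rise, k.tau_decay, scan_span)
    start = k.latency - t20
    s = kernel_shape(t - start, k.tau_rise, k.tau_decay)
    m = float(np.max(np.abs(s)))
    return Waveform(s * (k.amplitude / m), dt=dt, units=k.units)


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def smoothstep_rise_duration(rise_10_90: float) -> float:
    """Total smoothstep duration giving the requested 10-90% rise time."""
    # crossings of 3u^2 - 2u^3 = 0.1 and 0.9 (symmetric about 0.5)
    roots = np.roots([-2.0, 3.0, 0.0, -0.1])
    u10 = float(min(r.real for r in roots if abs(r.imag) < 1e-12 and 0 < r.real < 1))
    return rise_10_90 / (1.0 - 2.0 * u10)


def make_epsc_kernel(
    decays,
    rise_10_90: float,
    latency: float,
    amplitude: float,
    dt: float,
    span: float,
) -> Waveform:
    """EPSC kernel: smoothstep rise, then an exactly multi-exponential decay.

    ``decays`` is a sequence of (weight, tau) pairs; from the peak onward the
    trace is exactly ``sum_i w_i exp(-t/tau_i)`` (scaled), so a post-peak
    decay fit recovers the construction's amplitude-weighted tau
    ``sum(w_i tau_i)/sum(w_i)`` exactly.  ``amplitude`` < 0 gives a pA
    (inward-current) kernel.
    """
    t = dt * np.arange(int(round(span / dt)))
    if amplitude == 0:
        return Waveform(np.zeros_like(t), dt=dt, units="pA")
    T = smoothstep_rise_duration(rise_10_90)
    u = t - latency
    rise = _smoothstep(u / T)
    decay = np.zeros_like(t)
    post = u >= T
    total_w = sum(w for w, _ in decays)
    for w, tau in decays:
        decay[post] += (w / total_w) * np.exp(-(u[post] - T) / tau)
    shape = np.where(post, decay, rise)
    shape[u < 0] = 0.0
    m = float(np.max(np.abs(shape)))
    return Waveform(shape * (amplitude / m), dt=dt, units="pA")


def ap_template(spike: SpikeParams, dt: float) -> np.ndarray:
    """Stereotyped action-potential waveform (samples, mV).

    Sharp sinusoidal upstroke (first 30% of the width) followed by a smooth
    repolarization back to baseline; additive and non-negative so that a
    blanked trace rejoins the underlying synaptic trajectory at the
    template's end.
    """
    n = max(int(round(spike.width / dt)), 6)
    t = np.arange(n) / n  # 0..1
    up = np.sin(0.5 * np.pi * np.clip(t / 0.3, 0, 1)) ** 2
    down = np.cos(0.5 * np.pi * np.clip((t - 0.3) / 0.7, 0, 1)) ** 2
    return spike.amplitude * np.where(t < 0.3, up, down)


def depression_amplitudes(
    dep: DepressionParams, isi: float, n_pulses: int, a1: float = 1.0
) -> np.ndarray:
    """Per-pulse amplitudes of the depression recursion, normalized to a1.

    With U = 0 the synapse does not depress and every amplitude equals a1.
    """
    if dep.U == 0:
        return np.full(n_pulses, a1)
    e = np.exp(-isi / dep.tau_rec)
    R = 1.0
    amps = np.empty(n_pulses)
    for k in range(n_pulses):
        amps[k] = R  # a_k = A R_k U; a_1 = A U, so a_k / a_1 = R_k
        R = 1.0 - (1.0 - R * (1.0 - dep.U)) * e
    return a1 * amps


def depression_steady_state(dep: DepressionParams, isi: float) -> float:
    """Closed-form steady-state resource R_inf."""
    e = np.exp(-isi / dep.tau_rec)
    return float((1.0 - e) / (1.0 - (1.0 - dep.U) * e))
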