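"""Named generator presets.

Each preset embeds a published summary statistic as generator ground truth
(e.g. a depression level calibrated so the 10th-pulse observed/expected
ratio is exactly 0.92 at 20 Hz on noise-free traces); the analysis pipeline
must then recover that value through its own estimators.  Calibrations are
lazy and cached per process.
"""

from __future__ import annotations

from functools import lru_cache

from ..trace_model import StimulusTrain
from .calibrate import bisect_parameter, calibrate_preset, shape_fwhm
from .params import (
    DepressionParams,
    KernelParams,
    ReleaseParams,
    SlowComponents,
    SynthPreset,
)

__all__ = ["get_preset", "preset_names", "EXTRACELLULAR_DEFAULTS", "DUAL_PATHWAY_DEFAULTS"]


@lru_cache(maxsize=None)
def _epsp_tau_decay_for_fwhm(fwhm: float, tau_rise: float) -> float:
    """Decay constant giving the requested kernel FWHM (dense-scan oracle)."""
    res = bisect_parameter(
        lambda tau: shape_fwhm(tau_rise, tau), fwhm,
        bounds=(tau_rise * 1.05, 400.0), rtol=1e-5,
    )
    return res.value


def _invitro_kernel(amplitude: float = 3.5) -> KernelParams:
    # slice EPSP: onset 3.0 ms, peak 3.5 mV, FWHM 39.6 ms
    tau = _epsp_tau_decay_for_fwhm(39.6, 2.0)
    return KernelParams(tau_rise=2.0, tau_decay=tau, latency=3.0,
                        amplitude=amplitude)


def _invivo_kernel(amplitude: float = 3.5, latency: float = 10.3) -> KernelParams:
    # in vivo EPSP: faster membrane, FWHM 18.4 ms
    tau = _epsp_tau_decay_for_fwhm(18.4, 1.5)
    return KernelParams(tau_rise=1.5, tau_decay=tau, latency=latency,
                        amplitude=amplitude)


def _fig1_invitro(seed: int) -> SynthPreset:
    return SynthPreset(kernel=_invitro_kernel(), noise_sd=0.15, seed=seed,
                       name="fig1_invitro")


def _fig1_invivo(seed: int) -> SynthPreset:
    return SynthPreset(kernel=_invivo_kernel(), noise_sd=0.15, seed=seed,
                       name="fig1_invivo")


def _fig1s4(seed: int) -> SynthPreset:
    # EPSC: 10-90% rise 1.3 ms; peak -48.1 pA; amplitude-weighted decay
    # tau of 5.8 ms from components (tau 2, 20 ms): w1/w2 = (20-5.8)/(5.8-2)
    w1 = (20.0 - 5.8) / (5.8 - 2.0)
    kernel = KernelParams(
        tau_rise=1.3, tau_decay=((w1, 2.0), (1.0, 20.0)),
        latency=1.0, amplitude=-48.1, units="pA",
    )
    return SynthPreset(kernel=kernel, noise_sd=2.0, seed=seed, name="fig1s4")


def _fig2_minstim(seed: int) -> SynthPreset:
    kernel = KernelParams(tau_rise=2.0, tau_decay=15.0, latency=3.0,
                          amplitude=1.0)
    release = ReleaseParams(
        p_fail=0.44, unitary_mean=0.84, unitary_cv=0.3,
        n_fibers=((1.0, 1), (2.0, 2), (3.0, 3), (4.0, 4)),
    )
    return SynthPreset(kernel=kernel, release=release, noise_sd=0.15,
                       seed=seed, name="fig2_minstim")


def _calibrated_train(seed: int, rate: float, target: float, name: str,
                      metric: str = "train_ratio") -> SynthPreset:
    base = SynthPreset(
        kernel=_invitro_kernel(),
        depression=DepressionParams(U=0.2, tau_rec=250.0),
        noise_sd=0.0, seed=seed, name=name,
    )
    preset, _ = calibrate_preset(metric, target, base, bounds=(1e-3, 0.98),
                                 rate_hz=rate)
    return preset.replace(name=name)


def _fig4_tonic(seed: int) -> SynthPreset:
    # 4 s of 20 Hz; tonic plateau calibrated to 1.18 mV as read out at the
    # pre-flash anchor points; AHP with onset/recovery taus 76.5 ms / 2.6 s
    train = StimulusTrain.regular(20.0, 80, start=100.0)
    span = float(train.onsets[-1]) + 50.0 + 6000.0
    base = SynthPreset(
        kernel=_invivo_kernel(amplitude=2.0, latency=3.0),
        depression=DepressionParams(U=0.25, tau_rec=250.0),
        slow=SlowComponents(tonic_amp=1.0, tonic_tau=300.0,
                            ahp_amp=-1.5, ahp_onset_tau=76.5,
                            ahp_recovery_tau=2600.0),
        noise_sd=0.0, seed=seed, name="fig4_tonic",
    )
    preset, _ = calibrate_preset("tonic_plateau", 1.18, base,
                                 bounds=(-5.0, 5.0), train=train, span=span)
    return preset.replace(name="fig4_tonic")


def _fig5_nmda(seed: int) -> SynthPreset:
    kernel = _invitro_kernel(amplitude=3.3)
    return SynthPreset(
        kernel=kernel,
        slow=SlowComponents(nmda_fraction=0.3, nmda_tau=80.0),
        noise_sd=0.15, seed=seed, name="fig5_nmda",
    )


def _pharm_preset(seed: int, fraction_remaining: float, name: str) -> SynthPreset:
    # slow NMDA-like share such that removing it leaves `fraction_remaining`
    # of the train integral: nmda_fraction = 1 - fraction_remaining
    kernel = _invitro_kernel(amplitude=3.0)
    return SynthPreset(
        kernel=kernel,
        depression=DepressionParams(U=0.15, tau_rec=250.0),
        slow=SlowComponents(nmda_fraction=1.0 - fraction_remaining,
                            nmda_tau=80.0),
        noise_sd=0.0, seed=seed, name=name,
    )


def _fig8_asc(seed: int) -> SynthPreset:
    # ascending (central IC, electrical): short latency, fast kinetics
    tau = _epsp_tau_decay_for_fwhm(30.0, 1.5)
    kernel = KernelParams(tau_rise=1.5, tau_decay=tau, latency=2.0,
                          amplitude=2.5)
    return SynthPreset(kernel=kernel, noise_sd=0.0, seed=seed, name="fig8_asc")


def _fig8_desc(seed: int) -> SynthPreset:
    return SynthPreset(kernel=_invitro_kernel(amplitude=2.0), noise_sd=0.0,
                       seed=seed, name="fig8_desc")


_BUILDERS = {
    "fig1_invitro": _fig1_invitro,
    "fig1_invivo": _fig1_invivo,
    "fig1s4": _fig1s4,
    "fig2_minstim": _fig2_minstim,
    "fig4_20hz": lambda s: _calibrated_train(s, 20.0, 0.92, "fig4_20hz"),
    "fig4_50hz": lambda s: _calibrated_train(s, 50.0, 0.78, "fig4_50hz"),
    "fig4_50hz_ttp": lambda s: _calibrated_train(
        s, 50.0, 0.39, "fig4_50hz_ttp", metric="ttp_ratio"),
    "fig4_tonic": _fig4_tonic,
    "fig5_nmda": _fig5_nmda,
    "fig6_pharm_asc": lambda s: _pharm_preset(s, 0.44, "fig6_pharm_asc"),
    "fig6_pharm_desc": lambda s: _pharm_preset(s, 0.78, "fig6_pharm_desc"),
    "fig8_asc": _fig8_asc,
    "fig8_desc": _fig8_desc,
}

# control-condition interaction gain and timing bounds for dual-pathway runs
DUAL_PATHWAY_DEFAULTS = {
    "gain_control": 1.39,
    "gain_nmda_blocked": 1.02,
    "offset_bounds_ms": (-1.3, 16.4),
}

# click-evoked LFP/MUA generator settings (LFP onset ground truth 9.7 ms)
EXTRACELLULAR_DEFAULTS = {
    "click_times": (50.0,),
    "lfp": {"onset": 9.7, "amplitude": -120.0, "slope": 12.0, "decay_tau": 25.0},
    "mua": {"baseline_rate": 20.0, "evoked_rate": 200.0, "evoked_onset": 15.0,
            "evoked_duration": 30.0, "spike_amplitude": -40.0},
    "noise_sd": 4.0,
    "span": 200.0,
}


def preset_names() -> list[str]:
    return sorted(_BUILDERS)


@lru_cache(maxsize=None)
def get_preset(name: str, seed: int = 0) -> SynthPreset:
    """Fetch (and lazily calibrate) a named preset."""
    try:
        builder = _BUILDERS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; known presets: {', '.join(preset_names())}"
        ) from None
    return builder(seed)
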