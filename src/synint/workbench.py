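"""Configuration-driven end-to-end runs and fixture generation.

A :class:`RunConfig` lists stages to execute; every parameter that affects
a number lands in the emitted run manifest (JSON) so that replaying the
manifest reproduces the report bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, dual_pathway, extracellular, kinetics, summation, unitary
from .preprocess import average_sweeps, subtract_baseline
from .synth import (
    DUAL_PATHWAY_DEFAULTS,
    EXTRACELLULAR_DEFAULTS,
    get_preset,
    simulate_dual_pathway,
    simulate_extracellular,
    simulate_minimal_stim,
    simulate_synaptic_train,
)
from .trace_model import StimulusTrain, load_sweepset, save_sweepset

__all__ = ["RunConfig", "run", "make_fixtures", "FIXTURE_NAMES", "demo_suite_config"]

log = logging.getLogger("synint.workbench")

FIXTURE_NAMES = (
    "fig1_invitro", "fig1s4", "fig2_minstim", "fig4_20hz", "fig4_50hz_ttp",
    "fig4_tonic", "fig5_nmda", "fig6_pharm", "fig7_extracellular", "fig8_dual",
)


@dataclass
class RunConfig:
    stages: list = field(default_factory=list)
    outdir: str = "synint_run"
    seed: int = 0
    overrides: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**data)


def _train_for(cfg: dict) -> StimulusTrain:
    return StimulusTrain.regular(
        cfg.get("rate_hz", 20.0), cfg.get("n_pulses", 10),
        start=cfg.get("start_ms", 20.0), width=cfg.get("width_ms", 2.0),
    )


def _stage_simulate(stage: dict, outdir: Path, seed: int) -> dict:
    preset = get_preset(stage["preset"], seed=seed)
    kind = stage.get("protocol", "train")
    if kind == "train":
        train = _train_for(stage)
        s = simulate_synaptic_train(
            preset, train, n_trials=stage.get("n_trials", 10),
            post_ms=stage.get("post_ms", 500.0),
        )
    elif kind == "minstim":
        s = simulate_minimal_stim(
            preset, n_trials=stage.get("n_trials", 100),
            intensities=stage.get("intensities", [1.0]),
        )
    elif kind == "extracellular":
        cfg = {**EXTRACELLULAR_DEFAULTS, **stage.get("params", {})}
        s = simulate_extracellular(
            click_times=cfg["click_times"], lfp=cfg["lfp"], mua=cfg["mua"],
            n_trials=stage.get("n_trials", 300), noise_sd=cfg["noise_sd"],
            span=cfg["span"], seed=seed,
        )
    else:
        raise ValueError(f"unknown simulate protocol {kind!r}")
    path = outdir / f"{stage.get('name', stage['preset'])}.csv"
    save_sweepset(s, path)
    return {"file": str(path), "n_sweeps": s.n_sweeps}


def _stage_epsp(stage: dict, outdir: Path, seed: int) -> dict:
    s = load_sweepset(stage["input"])
    onset = float(s.stimulus.onsets[0])
    s = subtract_baseline(s, (s.t0, onset - 1.0))
    avg = average_sweeps(s)
    m = kinetics.measure_epsp(avg, stimulus_onset=onset)
    row = dataclasses.asdict(m)
    row.pop("components")
    df = pd.DataFrame([row])
    path = outdir / f"{stage.get('name', 'epsp')}_metrics.csv"
    df.to_csv(path, index=False)
    return {"file": str(path), **{k: row[k] for k in ("peak_amplitude", "half_width")}}


def _stage_train(stage: dict, outdir: Path, seed: int) -> dict:
    s = load_sweepset(stage["input"])
    train = s.stimulus
    onset = float(train.onsets[0])
    s = subtract_baseline(s, (s.t0, onset - 1.0))
    avg = average_sweeps(s)
    single = load_sweepset(stage["single_input"]) if "single_input" in stage else None
    if single is not None:
        sonset = float(single.stimulus.onsets[0])
        single_avg = average_sweeps(
            subtract_baseline(single, (single.t0, sonset - 1.0)))
    else:  # fall back: first-pulse window of the train itself
        single_avg, sonset = avg, onset
    first_peak, _, _ = kinetics.peak_amplitude(
        avg, search_window=(0.0, train.isi), stimulus_onset=onset)
    expected = summation.expected_linear_train(single_avg, train, first_peak,
                                              single_onset=0.0)
    tm = summation.per_pulse_ratios(avg, expected, train)
    _, tonic_amp = summation.extract_tonic(avg, train)
    df = pd.DataFrame({
        "pulse": np.arange(1, train.n_pulses + 1),
        "observed_peak": tm.observed_peaks,
        "expected_peak": tm.expected_peaks,
        "ratio": tm.ratios,
        "trough_to_peak": tm.trough_to_peak,
    })
    path = outdir / f"{stage.get('name', 'train')}_metrics.csv"
    df.to_csv(path, index=False)
    return {"file": str(path), "tonic_amplitude": tonic_amp,
            "ratio_last": float(tm.ratios[-1])}


def _stage_minstim(stage: dict, outdir: Path, seed: int) -> dict:
    s = load_sweepset(stage["input"])
    onset = float(s.stimulus.onsets[0])
    s = subtract_baseline(s, (s.t0, onset - 2.0))
    res = unitary.classify_success_failure(
        s, response_window=(onset, onset + stage.get("window_ms", 50.0)),
        baseline_window=(s.t0, onset - 2.0),
        criterion_multiplier=stage.get("criterion", 3.0),
    )
    fr, ua = unitary.unitary_stats(res.labels, res.peaks)
    df = pd.DataFrame({
        "trial": np.arange(s.n_sweeps),
        "peak": res.peaks,
        "label": np.where(res.labels, "success", "failure"),
        "intensity": [m.get("intensity") for m in s.per_sweep_meta],
    })
    path = outdir / f"{stage.get('name', 'minstim')}_diary.csv"
    df.to_csv(path, index=False)
    return {"file": str(path), "failure_rate": fr, "unitary_amplitude": ua,
            "criterion_multiplier": res.criterion_multiplier}


def _stage_extracellular(stage: dict, outdir: Path, seed: int) -> dict:
    s = load_sweepset(stage["input"])
    click = float(s.stimulus.onsets[0])
    lfp = extracellular.lfp_preprocess(s)
    onset, slope = extracellular.lfp_onset_and_slope(lfp, click)
    spikes = extracellular.detect_mua(s)
    centers, rates = extracellular.build_psth(spikes, span=(s.t0, s.t0 + s.duration))
    mua_onset = extracellular.psth_onset(centers, rates, click)
    df = pd.DataFrame({"bin_center_ms": centers, "rate_hz": rates})
    path = outdir / f"{stage.get('name', 'extracellular')}_psth.csv"
    df.to_csv(path, index=False)
    return {"file": str(path), "lfp_onset": onset, "lfp_slope": slope,
            "mua_onset": mua_onset}


def _stage_dual(stage: dict, outdir: Path, seed: int) -> dict:
    def _avg(path):
        s = load_sweepset(path)
        onset = float(s.stimulus.onsets[0])
        return average_sweeps(subtract_baseline(s, (s.t0, onset - 1.0))), s.stimulus

    asc_avg, asc_train = _avg(stage["asc_input"])
    desc_avg, _ = _avg(stage["desc_input"])
    comb_avg, _ = _avg(stage["combined_input"])
    onset = float(asc_train.onsets[0])
    asc_m = kinetics.measure_epsp(asc_avg, stimulus_onset=onset,
                                  search_window=(1.0, asc_train.isi))
    desc_m = kinetics.measure_epsp(desc_avg, stimulus_onset=onset,
                                   search_window=(1.0, asc_train.isi))
    offset = stage.get("offset_ms")
    if offset is None:
        asc_rel = dataclasses.replace(asc_m, peak_time=asc_m.peak_time - onset)
        offset = dual_pathway.compute_offset(asc_rel, desc_m)
    expected = dual_pathway.expected_sum(asc_avg, desc_avg, offset)
    ratios, integral_ratio = dual_pathway.supralinearity_index(
        comb_avg, expected, asc_train)
    df = pd.DataFrame({"time_ms": comb_avg.time, "observed": comb_avg.samples,
                       "expected": expected.samples})
    path = outdir / f"{stage.get('name', 'dual')}_overlay.csv"
    df.to_csv(path, index=False)
    return {"file": str(path), "offset_ms": float(offset),
            "integral_ratio": integral_ratio,
            "per_pulse_ratio": [float(r) for r in ratios]}


_STAGES = {
    "simulate": _stage_simulate,
    "dual": _stage_dual,
    "epsp": _stage_epsp,
    "train": _stage_train,
    "minstim": _stage_minstim,
    "extracellular": _stage_extracellular,
}


def run(config: RunConfig) -> Path:
    """Execute the configured stages and write metrics + run manifest.

    Deterministic given the config (stage parameters + seed): re-running
    reproduces every CSV bit-identically.  A stage failure stops the run
    with partial outputs retained and the error recorded in the manifest.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "stages": [],
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    # validate the whole plan before any stage runs
    declared_outputs = set()
    for st in config.stages:
        if st.get("kind") not in _STAGES:
            raise ValueError(f"unknown stage kind {st.get('kind')!r}")
        if st.get("kind") == "simulate":
            declared_outputs.add(
                str(outdir / f"{st.get('name', st.get('preset'))}.csv"))
        for key in ("input", "single_input"):
            p = st.get(key)
            if p and not Path(p).exists() and str(Path(p)) not in {
                str(Path(x)) for x in declared_outputs
            }:
                raise FileNotFoundError(f"stage input does not exist: {p}")
    try:
        for stage in config.stages:
            kind = stage["kind"]
            log.info("stage %s (%s)", stage.get("name", kind), kind)
            result = _STAGES[kind]({**stage, **config.overrides.get(kind, {})},
                                   outdir, config.seed)
            manifest["stages"].append({"stage": stage, "result": result})
    except Exception as e:
        manifest["error"] = repr(e)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return outdir


def demo_suite_config(outdir: str, seed: int = 1) -> RunConfig:
    """Demo configuration touching every simulation/analysis stage."""
    return RunConfig(
        outdir=outdir,
        seed=seed,
        stages=[
            {"kind": "simulate", "name": "single", "preset": "fig1_invitro",
             "protocol": "train", "rate_hz": 20.0, "n_pulses": 1,
             "n_trials": 12},
            {"kind": "epsp", "name": "single", "input": f"{outdir}/single.csv"},
            {"kind": "simulate", "name": "train20", "preset": "fig4_20hz",
             "protocol": "train", "rate_hz": 20.0, "n_pulses": 10,
             "n_trials": 5},
            {"kind": "train", "name": "train20", "input": f"{outdir}/train20.csv",
             "single_input": f"{outdir}/single.csv"},
            {"kind": "simulate", "name": "minstim", "preset": "fig2_minstim",
             "protocol": "minstim", "n_trials": 100},
            {"kind": "minstim", "name": "minstim", "input": f"{outdir}/minstim.csv"},
            {"kind": "simulate", "name": "clicks", "preset": "fig1_invitro",
             "protocol": "extracellular", "n_trials": 60},
            {"kind": "extracellular", "name": "clicks",
             "input": f"{outdir}/clicks.csv"},
        ],
    )


def make_fixtures(names, outdir: str | Path, seed: int = 0) -> list[Path]:
    """Write SweepSet fixture files for the named presets."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name in names:
        if name not in FIXTURE_NAMES:
            raise ValueError(
                f"unknown fixture {name!r}; known: {', '.join(FIXTURE_NAMES)}")
        written.extend(_make_fixture(name, outdir, seed))
    return written


def _make_fixture(name: str, outdir: Path, seed: int) -> list[Path]:
    def _save(s, suffix=""):
        path = outdir / f"{name}{suffix}.csv"
        save_sweepset(s, path)
        return path

    if name in ("fig1_invitro", "fig1s4", "fig5_nmda"):
        preset = get_preset(name, seed=seed)
        mode = "voltage_clamp" if name == "fig1s4" else "current_clamp"
        train = StimulusTrain.regular(20.0, 1, start=20.0)
        s = simulate_synaptic_train(preset, train, n_trials=12, mode=mode,
                                    post_ms=300.0)
        return [_save(s)]
    if name == "fig2_minstim":
        preset = get_preset(name, seed=seed)
        s = simulate_minimal_stim(preset, n_trials=60,
                                  intensities=[1.0, 2.0, 3.0, 4.0])
        return [_save(s)]
    if name in ("fig4_20hz", "fig4_50hz_ttp"):
        preset = get_preset(name, seed=seed)
        rate = 20.0 if name == "fig4_20hz" else 50.0
        train = StimulusTrain.regular(rate, 10, start=20.0)
        s = simulate_synaptic_train(preset, train, n_trials=5, post_ms=300.0)
        return [_save(s)]
    if name == "fig4_tonic":
        preset = get_preset(name, seed=seed)
        train = StimulusTrain.regular(20.0, 80, start=100.0)
        s = simulate_synaptic_train(preset, train, n_trials=1, post_ms=6050.0)
        return [_save(s)]
    if name == "fig6_pharm":
        preset = get_preset("fig6_pharm_asc", seed=seed)
        train = StimulusTrain.regular(50.0, 5, start=50.0)
        ctrl = simulate_synaptic_train(preset, train, n_trials=5,
                                       post_ms=400.0, condition="control")
        slow = preset.slow.__class__(**{**dataclasses.asdict(preset.slow),
                                        "nmda_fraction": 0.0})
        drug = simulate_synaptic_train(preset.replace(slow=slow), train,
                                       n_trials=5, post_ms=400.0,
                                       condition="R-CPP", noise_stream=1)
        return [_save(ctrl, "_control"), _save(drug, "_rcpp")]
    if name == "fig7_extracellular":
        cfg = EXTRACELLULAR_DEFAULTS
        s = simulate_extracellular(
            click_times=cfg["click_times"], lfp=cfg["lfp"], mua=cfg["mua"],
            n_trials=60, noise_sd=cfg["noise_sd"], span=cfg["span"], seed=seed,
        )
        return [_save(s)]
    if name == "fig8_dual":
        asc_p = get_preset("fig8_asc", seed=seed)
        desc_p = get_preset("fig8_desc", seed=seed)
        asc, desc, comb = simulate_dual_pathway(
            asc_p, desc_p, offset=8.0,
            gain=DUAL_PATHWAY_DEFAULTS["gain_control"], n_trials=5,
        )
        return [_save(asc, "_asc"), _save(desc, "_desc"), _save(comb, "_combined")]
    raise AssertionError(name)
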