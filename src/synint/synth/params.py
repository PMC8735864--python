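"""Parameter types for the synthetic-trace generator.

A :class:`SynthPreset` is a complete, serializable description of one
simulated experiment: the response kernel, short-term depression, release
statistics, slow components (NMDA-like tail, tonic build-up, post-train
AHP), noise level, spike insertion and the RNG seed.

All generator parameters are fixture-level choices that realize target
summary statistics; none are claims about underlying biology.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "KernelParams",
    "DepressionParams",
    "ReleaseParams",
    "SlowComponents",
    "SpikeParams",
    "SynthPreset",
]


def _as_decay_list(tau_decay) -> tuple[tuple[float, float], ...]:
    """Normalize tau_decay to ((fraction, tau), ...) summing to 1."""
    if isinstance(tau_decay, (int, float)):
        return ((1.0, float(tau_decay)),)
    pairs = tuple((float(f), float(tau)) for f, tau in tau_decay)
    total = sum(f for f, _ in pairs)
    if total <= 0:
        raise ValueError("decay component fractions must sum to > 0")
    return tuple((f / total, tau) for f, tau in pairs)


@dataclass(frozen=True)
class KernelParams:
    """Difference-of-exponentials response kernel.

    ``tau_decay`` may be a scalar or a list of ``(fraction, tau)`` pairs.
    ``latency`` is where the 20%-of-peak crossing of the kernel lands
    (matching how onset latency is measured downstream).  ``amplitude`` is
    the exact sampled peak value: positive mV for EPSPs, negative pA for
    EPSCs at negative holding.
    """

    tau_rise: float
    tau_decay: object
    latency: float = 3.0
    amplitude: float = 1.0
    units: str = "mV"

    def __post_init__(self) -> None:
        decays = _as_decay_list(self.tau_decay)
        object.__setattr__(self, "tau_decay", decays)
        if self.tau_rise <= 0 or any(tau <= 0 for _, tau in decays):
            raise ValueError("time constants must be positive")
        if self.tau_rise >= min(tau for _, tau in decays):
            raise ValueError(
                f"tau_rise ({self.tau_rise} ms) must be smaller than the "
                f"fastest decay component ({min(t for _, t in decays)} ms)"
            )
        if self.units == "mV" and self.amplitude < 0:
            raise ValueError("EPSP amplitude must be >= 0 mV")
        if self.units == "pA" and self.amplitude > 0:
            raise ValueError("EPSC amplitude must be <= 0 pA at negative holding")


@dataclass(frozen=True)
class DepressionParams:
    """Release-fraction / recovery parameters of the depression recursion."""

    U: float = 0.0
    tau_rec: float = 200.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.U <= 1.0):
            raise ValueError(f"U must lie in [0, 1], got {self.U}")
        if self.tau_rec <= 0:
            raise ValueError("tau_rec must be > 0")


@dataclass(frozen=True)
class ReleaseParams:
    """Trial-by-trial release statistics for minimal stimulation.

    ``n_fibers`` maps stimulus intensity (arbitrary LED units) to the number
    of recruited fibers; it must be non-decreasing in intensity.
    """

    p_fail: float = 0.0
    unitary_mean: float = 0.84
    unitary_cv: float = 0.3
    n_fibers: tuple = ((1.0, 1),)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_fail <= 1.0):
            raise ValueError(f"p_fail must lie in [0, 1], got {self.p_fail}")
        if self.unitary_mean <= 0:
            raise ValueError("unitary_mean must be > 0")
        table = tuple(sorted((float(i), int(n)) for i, n in self.n_fibers))
        counts = [n for _, n in table]
        if any(b < a for a, b in zip(counts, counts[1:])):
            raise ValueError("n_fibers must be non-decreasing in intensity")
        object.__setattr__(self, "n_fibers", table)

    def fibers_at(self, intensity: float) -> int:
        """Step-interpolated fiber count at ``intensity``."""
        n = self.n_fibers[0][1]
        for i, c in self.n_fibers:
            if intensity >= i:
                n = c
        return n


@dataclass(frozen=True)
class SlowComponents:
    """Slow NMDA-like tail, tonic build-up and post-train AHP."""

    nmda_fraction: float = 0.0  # fraction of windowed integral in the slow tail
    nmda_tau: float = 80.0
    nmda_rise: float = 5.0
    tonic_amp: float = 0.0
    tonic_tau: float = 300.0
    ahp_amp: float = 0.0  # negative mV
    ahp_onset_tau: float = 76.5
    ahp_recovery_tau: float = 2600.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.nmda_fraction < 1.0):
            raise ValueError("nmda_fraction must lie in [0, 1)")
        for name in ("nmda_tau", "nmda_rise", "tonic_tau",
                     "ahp_onset_tau", "ahp_recovery_tau"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.ahp_amp > 0:
            raise ValueError("ahp_amp is a hyperpolarization; must be <= 0")


@dataclass(frozen=True)
class SpikeParams:
    """Threshold-triggered action-potential insertion (for blanking tests)."""

    threshold: float = float("inf")  # mV; inf disables insertion
    amplitude: float = 80.0
    width: float = 1.0  # ms, total biphasic width


@dataclass(frozen=True)
class SynthPreset:
    """Complete parameterization of one simulated experiment."""

    kernel: KernelParams
    depression: DepressionParams = DepressionParams()
    release: ReleaseParams = ReleaseParams()
    slow: SlowComponents = SlowComponents()
    spike: SpikeParams = SpikeParams()
    noise_sd: float = 0.15
    interaction_gain: float = 1.0
    seed: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.interaction_gain <= 0:
            raise ValueError("interaction_gain must be > 0")

    def replace(self, **changes) -> "SynthPreset":
        return dataclasses.replace(self, **changes)

    # -- JSON round trip ----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["kernel"]["tau_decay"] = [list(p) for p in self.kernel.tau_decay]
        d["release"]["n_fibers"] = [list(p) for p in self.release.n_fibers]
        d["spike"]["threshold"] = (
            None if self.spike.threshold == float("inf") else self.spike.threshold
        )
        return d

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, d: dict) -> "SynthPreset":
        k = dict(d["kernel"])
        k["tau_decay"] = [tuple(p) for p in k["tau_decay"]]
        spike = dict(d.get("spike", {}))
        if spike.get("threshold") is None:
            spike["threshold"] = float("inf")
        rel = dict(d.get("release", {}))
        if "n_fibers" in rel:
            rel["n_fibers"] = tuple(tuple(p) for p in rel["n_fibers"])
        return cls(
            kernel=KernelParams(**k),
            depression=DepressionParams(**d.get("depression", {})),
            release=ReleaseParams(**rel),
            slow=SlowComponents(**d.get("slow", {})),
            spike=SpikeParams(**spike),
            noise_sd=d.get("noise_sd", 0.15),
            interaction_gain=d.get("interaction_gain", 1.0),
            seed=d.get("seed", 0),
            name=d.get("name", ""),
        )

    @classmethod
    def load(cls, path: str | Path) -> "SynthPreset":
        return cls.from_dict(json.loads(Path(path).read_text()))
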