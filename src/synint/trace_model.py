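"""Core data types and on-disk formats for sweep sets and stimulus protocols.

The universal currency of the package is the :class:`SweepSet` -- a trial x
sample matrix in physical units with a fixed sampling interval -- together
with the :class:`StimulusTrain` describing when stimuli occurred.  Averaged
traces are carried as :class:`Waveform` objects.

On disk a sweep set is a plain CSV matrix (one row per sweep) plus a JSON
sidecar (``<path>.json``) holding ``dt_ms``, ``units``, ``t0_ms``, the
stimulus train and per-sweep metadata.  An equivalent HDF5 layout is
supported for ``.h5``/``.hdf5`` paths.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "Units",
    "Waveform",
    "StimulusTrain",
    "SweepSet",
    "load_sweepset",
    "save_sweepset",
    "SweepSetFormatError",
    "SweepSetValidationError",
]

VALID_UNITS = ("mV", "pA", "uV")
VALID_STIM_KINDS = ("light", "shock", "click")

Units = str


class SweepSetFormatError(ValueError):
    """Raised when an on-disk sweep set is malformed (e.g. missing sidecar)."""


class SweepSetValidationError(ValueError):
    """Raised when data violate a SweepSet/Waveform invariant."""


def _check_units(units: str) -> str:
    if units not in VALID_UNITS:
        raise SweepSetValidationError(
            f"unknown units {units!r}; expected one of {VALID_UNITS}"
        )
    return units


@dataclass(frozen=True)
class Waveform:
    """A single trace: amplitude samples on a uniform time grid.

    Parameters
    ----------
    samples : array of float
        Amplitude series in ``units``.
    dt : float
        Sample interval in ms (> 0).
    t0 : float
        Time of the first sample in ms.
    units : {"mV", "pA", "uV"}
    """

    samples: np.ndarray
    dt: float
    t0: float = 0.0
    units: Units = "mV"
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.dt <= 0:
            raise SweepSetValidationError(f"dt must be > 0, got {self.dt}")
        if samples.ndim != 1 or samples.size < 2:
            raise SweepSetValidationError("samples must be 1-D with length >= 2")
        if not np.all(np.isfinite(samples)):
            raise SweepSetValidationError("samples contain non-finite values")
        _check_units(self.units)

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def time(self) -> np.ndarray:
        """Time axis t0 + k*dt, ms."""
        return self.t0 + self.dt * np.arange(self.samples.size)

    @property
    def duration(self) -> float:
        """Span covered by the samples, ms (n*dt)."""
        return self.samples.size * self.dt

    def index_of(self, t: float) -> int:
        """Nearest sample index for time ``t`` (ms), clipped to range."""
        k = int(round((t - self.t0) / self.dt))
        return min(max(k, 0), self.samples.size - 1)

    def with_samples(self, samples: np.ndarray) -> "Waveform":
        return replace(self, samples=np.asarray(samples, dtype=float))


@dataclass(frozen=True)
class StimulusTrain:
    """Ordered stimulus pulse onsets with a common width.

    ``onsets`` are in the same time frame as the sweeps they accompany
    (t=0 at sweep start).
    """

    onsets: np.ndarray
    width: float = 2.0
    kind: str = "light"

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onsets, dtype=float)
        object.__setattr__(self, "onsets", onsets)
        if onsets.ndim != 1 or onsets.size == 0:
            raise SweepSetValidationError("onsets must be a non-empty 1-D array")
        if onsets.size > 1 and not np.all(np.diff(onsets) > 0):
            raise SweepSetValidationError("onsets must be strictly increasing")
        if self.width < 0:
            raise SweepSetValidationError("pulse width must be >= 0")
        if self.kind not in VALID_STIM_KINDS:
            raise SweepSetValidationError(
                f"unknown stimulus kind {self.kind!r}; expected one of {VALID_STIM_KINDS}"
            )

    @property
    def n_pulses(self) -> int:
        return self.onsets.size

    @property
    def isi(self) -> float:
        """Inter-stimulus interval (ms); requires a regular train."""
        if self.onsets.size < 2:
            raise ValueError("ISI undefined for a single-pulse train")
        d = np.diff(self.onsets)
        if not np.allclose(d, d[0], rtol=1e-9, atol=1e-9):
            raise ValueError("train is not regular; ISI undefined")
        return float(d[0])

    @classmethod
    def regular(
        cls, rate_hz: float, n_pulses: int, start: float = 0.0,
        width: float = 2.0, kind: str = "light",
    ) -> "StimulusTrain":
        """Regular train at ``rate_hz`` with ``n_pulses`` pulses from ``start`` ms."""
        isi = 1000.0 / rate_hz
        return cls(onsets=start + isi * np.arange(n_pulses), width=width, kind=kind)

    def to_dict(self) -> dict:
        return {
            "onsets_ms": [float(x) for x in self.onsets],
            "width_ms": float(self.width),
            "kind": self.kind,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusTrain":
        return cls(
            onsets=np.asarray(d["onsets_ms"], dtype=float),
            width=float(d.get("width_ms", 0.0)),
            kind=d.get("kind", "light"),
        )


@dataclass(frozen=True)
class SweepSet:
    """Trial x sample matrix with shared sampling metadata.

    Invariants: all sweeps have equal length, one metadata dict per sweep,
    a single ``dt`` for the whole set.
    """

    sweeps: np.ndarray
    dt: float
    units: Units = "mV"
    stimulus: StimulusTrain | None = None
    per_sweep_meta: tuple = ()
    t0: float = 0.0

    def __post_init__(self) -> None:
        sweeps = np.asarray(self.sweeps, dtype=float)
        if sweeps.ndim == 1:
            sweeps = sweeps[None, :]
        object.__setattr__(self, "sweeps", sweeps)
        if sweeps.ndim != 2 or sweeps.shape[0] < 1 or sweeps.shape[1] < 2:
            raise SweepSetValidationError(
                f"sweeps must be a 2-D (trials x samples) matrix, got shape {sweeps.shape}"
            )
        if not np.all(np.isfinite(sweeps)):
            raise SweepSetValidationError("sweeps contain non-finite values")
        if self.dt <= 0:
            raise SweepSetValidationError(f"dt must be > 0, got {self.dt}")
        _check_units(self.units)
        meta = tuple(self.per_sweep_meta) if self.per_sweep_meta else tuple(
            {} for _ in range(sweeps.shape[0])
        )
        if len(meta) != sweeps.shape[0]:
            raise SweepSetValidationError(
                f"per_sweep_meta has {len(meta)} entries for {sweeps.shape[0]} sweeps"
            )
        object.__setattr__(self, "per_sweep_meta", meta)

    @property
    def n_sweeps(self) -> int:
        return self.sweeps.shape[0]

    @property
    def n_samples(self) -> int:
        return self.sweeps.shape[1]

    @property
    def time(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n_samples)

    @property
    def duration(self) -> float:
        return self.n_samples * self.dt

    def sweep(self, i: int) -> Waveform:
        return Waveform(self.sweeps[i], dt=self.dt, t0=self.t0, units=self.units,
                        meta=dict(self.per_sweep_meta[i]))

    def select(self, **criteria) -> "SweepSet":
        """Subset of sweeps whose metadata match all keyword criteria."""
        idx = [
            i for i, m in enumerate(self.per_sweep_meta)
            if all(m.get(k) == v for k, v in criteria.items())
        ]
        if not idx:
            raise SweepSetValidationError(f"no sweeps match criteria {criteria}")
        return replace(
            self,
            sweeps=self.sweeps[idx],
            per_sweep_meta=tuple(self.per_sweep_meta[i] for i in idx),
        )

    def with_sweeps(self, sweeps: np.ndarray) -> "SweepSet":
        return replace(self, sweeps=np.asarray(sweeps, dtype=float))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def save_sweepset(s: SweepSet, path: str | Path) -> Path:
    """Write a SweepSet to ``path``.

    ``.h5``/``.hdf5`` suffixes select the HDF5 layout; anything else writes a
    CSV matrix (one row per sweep, full float precision) plus a JSON sidecar
    at ``<path>.json``.  ``load_sweepset`` inverts either layout exactly.
    """
    path = Path(path)
    if not isinstance(s, SweepSet):
        raise SweepSetValidationError("save_sweepset expects a SweepSet")
    if path.suffix.lower() in (".h5", ".hdf5"):
        return _save_hdf5(s, path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, s.sweeps, delimiter=",", fmt="%.17g")
    sidecar = {
        "dt_ms": s.dt,
        "units": s.units,
        "t0_ms": s.t0,
        "stimulus": s.stimulus.to_dict() if s.stimulus is not None else None,
        "per_sweep_meta": [dict(m) for m in s.per_sweep_meta],
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def load_sweepset(path: str | Path) -> SweepSet:
    """Load a SweepSet written by :func:`save_sweepset`."""
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        return _load_hdf5(path)
    if not path.exists():
        raise SweepSetFormatError(f"no such sweep matrix file: {path}")
    sidecar_path = _sidecar_path(path)
    if not sidecar_path.exists():
        raise SweepSetFormatError(f"missing JSON sidecar: {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    try:
        matrix = np.loadtxt(path, delimiter=",", ndmin=2)
    except ValueError as e:  # ragged rows
        raise SweepSetValidationError(f"malformed sweep matrix in {path}: {e}") from e
    meta = sidecar.get("per_sweep_meta") or []
    if meta and len(meta) != matrix.shape[0]:
        raise SweepSetValidationError(
            f"sidecar declares {len(meta)} sweeps but matrix has {matrix.shape[0]} rows"
        )
    stim = sidecar.get("stimulus")
    return SweepSet(
        sweeps=matrix,
        dt=float(sidecar["dt_ms"]),
        units=sidecar["units"],
        t0=float(sidecar.get("t0_ms", 0.0)),
        stimulus=StimulusTrain.from_dict(stim) if stim else None,
        per_sweep_meta=tuple(meta) if meta else (),
    )


def _save_hdf5(s: SweepSet, path: Path) -> Path:
    import h5py

    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        d = f.create_dataset("sweeps", data=s.sweeps)
        d.attrs["dt_ms"] = s.dt
        d.attrs["units"] = s.units
        d.attrs["t0_ms"] = s.t0
        if s.stimulus is not None:
            g = f.create_group("stimulus")
            g.create_dataset("onsets_ms", data=s.stimulus.onsets)
            g.attrs["width_ms"] = s.stimulus.width
            g.attrs["kind"] = s.stimulus.kind
        f.attrs["per_sweep_meta"] = json.dumps([dict(m) for m in s.per_sweep_meta])
    return path


def _load_hdf5(path: Path) -> SweepSet:
    import h5py

    if not path.exists():
        raise SweepSetFormatError(f"no such file: {path}")
    with h5py.File(path, "r") as f:
        d = f["sweeps"]
        stim = None
        if "stimulus" in f:
            g = f["stimulus"]
            stim = StimulusTrain(
                onsets=np.asarray(g["onsets_ms"]),
                width=float(g.attrs["width_ms"]),
                kind=str(g.attrs["kind"]),
            )
        meta = json.loads(f.attrs.get("per_sweep_meta", "[]"))
        return SweepSet(
            sweeps=np.asarray(d),
            dt=float(d.attrs["dt_ms"]),
            units=str(d.attrs["units"]),
            t0=float(d.attrs.get("t0_ms", 0.0)),
            stimulus=stim,
            per_sweep_meta=tuple(meta) if meta else (),
        )
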