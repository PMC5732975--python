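"""Shared waveform containers and plain-text I/O.

All amplitudes are in microvolts (µV), all times in milliseconds unless a
name says otherwise.  Waveform files are two-column TSV (``time_ms``,
``amplitude_uv``) with a JSON sidecar carrying the sampling rate and any
extra metadata; sweep matrices are plain TSV (sweeps × samples) with the
same sidecar convention.  Everything is text so results survive
copy/diff/versioning.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


@dataclass(frozen=True)
class TransientAEP:
    """A single-stimulus evoked waveform, time origin at stimulus onset."""

    waveform: np.ndarray  # µV
    fs: float  # Hz

    def __post_init__(self) -> None:
        object.__setattr__(self, "waveform", np.asarray(self.waveform, dtype=float))
        if self.waveform.ndim != 1:
            raise ValidationError("TransientAEP waveform must be 1-D")
        if self.fs <= 0:
            raise ValidationError("sampling rate must be positive")

    @property
    def n(self) -> int:
        return self.waveform.size

    @property
    def duration_ms(self) -> float:
        return 1000.0 * self.n / self.fs

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.n) * 1000.0 / self.fs

    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.waveform**2)))


@dataclass(frozen=True)
class SweepSet:
    """A stack of equal-length EEG epochs for one paradigm, pre-averaging."""

    data: np.ndarray  # sweeps × samples, µV
    fs: float
    paradigm: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "data", np.atleast_2d(np.asarray(self.data, dtype=float)))
        if self.fs <= 0:
            raise ValidationError("sampling rate must be positive")

    @property
    def n_sweeps(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class SteadyStateRecord:
    """An averaged periodic (or quasi-periodic) steady-state response.

    ``structure`` lists ``(segment_samples, isi_ms)`` pairs; for a plain
    periodic record there is one pair per cycle.
    """

    waveform: np.ndarray
    fs: float
    structure: tuple = field(default_factory=tuple)
    n_cycles: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "waveform", np.asarray(self.waveform, dtype=float))
        object.__setattr__(self, "structure", tuple((int(n), float(isi)) for n, isi in self.structure))
        if self.structure:
            total = sum(n for n, _ in self.structure)
            if total != self.waveform.size:
                raise ValidationError(
                    f"waveform length {self.waveform.size} != sum of segment lengths {total}"
                )

    @property
    def n(self) -> int:
        return self.waveform.size


def save_waveform(path: str | Path, waveform: np.ndarray, fs: float, **meta) -> None:
    path = Path(path)
    waveform = np.asarray(waveform, dtype=float)
    t = np.arange(waveform.size) * 1000.0 / fs
    header = "time_ms\tamplitude_uv"
    np.savetxt(path, np.column_stack([t, waveform]), delimiter="\t",
               header=header, comments="", fmt="%.10g")
    _sidecar(path).write_text(json.dumps({"fs_hz": fs, **meta}, indent=2))


def load_waveform(path: str | Path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    arr = np.loadtxt(path, delimiter="\t", skiprows=1)
    meta = {}
    if _sidecar(path).exists():
        meta = json.loads(_sidecar(path).read_text())
    return np.atleast_2d(arr)[:, 1].copy() if arr.ndim > 1 else arr, meta


def save_sweeps(path: str | Path, sweeps: SweepSet, **meta) -> None:
    path = Path(path)
    np.savetxt(path, sweeps.data, delimiter="\t", fmt="%.10g")
    _sidecar(path).write_text(json.dumps(
        {"fs_hz": sweeps.fs, "paradigm": sweeps.paradigm, **meta}, indent=2))


def load_sweeps(path: str | Path) -> SweepSet:
    path = Path(path)
    data = np.loadtxt(path, delimiter="\t", ndmin=2)
    meta = json.loads(_sidecar(path).read_text())
    return SweepSet(data=data, fs=float(meta["fs_hz"]), paradigm=meta.get("paradigm", ""))
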