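"""Sweep-level preprocessing: artifact rejection, averaging, assembly.

Turns raw sweep stacks into the averaged records downstream stages
consume: the transient-paradigm average, the multi-ISI steady-state
average, the eight per-rate one-cycle averages spliced into the
multi-rate record, and the four-cycle classical steady-state record.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import SteadyStateRecord, SweepSet, ValidationError
from .sequences import isi_to_samples


@dataclass(frozen=True)
class RejectionReport:
    threshold_uv: float
    rejected_indices: tuple
    n_in: int

    @property
    def n_rejected(self) -> int:
        return len(self.rejected_indices)

    @property
    def n_kept(self) -> int:
        return self.n_in - self.n_rejected


def reject_artifacts(
    sweeps: SweepSet, threshold_uv: float = 40.0
) -> tuple[SweepSet, RejectionReport]:
    """Drop sweeps containing any sample with |amplitude| > threshold.

    The inequality is strict: a sweep peaking at exactly the threshold is
    kept.  Raises if nothing survives.
    """
    if threshold_uv <= 0:
        raise ValidationError("threshold must be positive")
    peaks = np.max(np.abs(sweeps.data), axis=1)
    rejected = np.flatnonzero(peaks > threshold_uv)
    report = RejectionReport(threshold_uv, tuple(int(i) for i in rejected),
                             sweeps.n_sweeps)
    if report.n_kept == 0:
        raise ValidationError(
            "all sweeps rejected: review the threshold or the noise level")
    kept = np.delete(sweeps.data, rejected, axis=0)
    return SweepSet(data=kept, fs=sweeps.fs, paradigm=sweeps.paradigm), report


def average_sweeps(sweeps: SweepSet) -> tuple[np.ndarray, float | None]:
    """Ensemble mean plus an odd/even split-half consistency score.

    Consistency is the Pearson correlation between the averages of the
    odd- and even-indexed sweeps; ``None`` (flagged) for a single sweep.
    """
    mean = sweeps.data.mean(axis=0)
    if sweeps.n_sweeps < 2:
        return mean, None
    odd = sweeps.data[1::2].mean(axis=0)
    even = sweeps.data[0::2].mean(axis=0)
    so, se = odd.std(), even.std()
    if so == 0 or se == 0:
        consistency = 1.0 if np.allclose(odd, even) else 0.0
    else:
        consistency = float(np.corrcoef(odd, even)[0, 1])
    return mean, consistency


def fold_cycles(
    waveform: np.ndarray, period_samples: int, discard_cycles: int = 0
) -> np.ndarray:
    """Average the full cycles of a periodic record into one cycle.

    ``discard_cycles`` leading cycles are excluded (onset suppression).
    """
    waveform = np.asarray(waveform, dtype=float)
    if period_samples < 1:
        raise ValidationError("period must be >= 1 sample")
    n_cycles = waveform.size // period_samples
    if n_cycles * period_samples != waveform.size:
        raise ValidationError(
            f"record length {waveform.size} is not an integer multiple of "
            f"period {period_samples}")
    if discard_cycles >= n_cycles:
        raise ValidationError(
            f"cannot discard {discard_cycles} of {n_cycles} cycles")
    cycles = waveform.reshape(n_cycles, period_samples)[discard_cycles:]
    return cycles.mean(axis=0)


def build_multi_rate_assr(
    per_rate: dict,
    clad_isis: list[float],
    fs: float,
) -> SteadyStateRecord:
    """Splice per-rate one-cycle averages into the multi-rate record.

    ``per_rate`` maps ISI (ms) → one-cycle waveform; segments are
    concatenated in the order of ``clad_isis`` so the spliced record has
    exactly the loop-sweep duration.
    """
    segments = []
    structure = []
    for isi in clad_isis:
        key = float(isi)
        if key not in {float(k) for k in per_rate}:
            raise ValidationError(f"missing one-cycle average for ISI {isi} ms")
        cycle = np.asarray(per_rate[key] if key in per_rate else per_rate[isi], dtype=float)
        expected = isi_to_samples(key, fs)
        if cycle.size != expected:
            raise ValidationError(
                f"one-cycle average for ISI {isi} ms has {cycle.size} samples, "
                f"expected {expected} at fs={fs}")
        segments.append(cycle)
        structure.append((expected, key))
    return SteadyStateRecord(
        waveform=np.concatenate(segments), fs=fs, structure=tuple(structure))


def build_rassr(
    average: np.ndarray, isi_ms: float, fs: float, n_cycles: int = 4,
    discard_cycles: int = 0,
) -> SteadyStateRecord:
    """Fold an isochronic average to one cycle and tile ``n_cycles`` of it."""
    period = isi_to_samples(isi_ms, fs)
    cycle = fold_cycles(np.asarray(average, dtype=float), period, discard_cycles)
    waveform = np.tile(cycle, n_cycles)
    return SteadyStateRecord(
        waveform=waveform, fs=fs,
        structure=tuple((period, float(isi_ms)) for _ in range(n_cycles)),
        n_cycles=n_cycles)
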