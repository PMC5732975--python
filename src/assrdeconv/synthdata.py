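"""Synthetic ground truth: transient AEP templates and sweep-level EEG.

Templates are sums of Gaussian lobes, one per named component (V, Na, Pa,
Nb, Pb), so peak latency and amplitude are exactly controllable.  Sweeps
are the circular convolution of an impulse train with the template plus
band-limited Gaussian noise; occasional artifact sweeps carry a >40 µV
spike so the rejection rule has something to catch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import signal

from .core import SweepSet, TransientAEP, ValidationError, save_sweeps
from .sequences import ImpulseTrain

#: Canonical component order (early to late).
COMPONENT_ORDER = ("V", "Na", "Pa", "Nb", "Pb")

_POSITIVE = {"V", "Pa", "Pb"}
_NEGATIVE = {"Na", "Nb"}


@dataclass(frozen=True)
class GaussianComponent:
    name: str
    latency_ms: float
    amplitude_uv: float  # signed
    width_ms: float  # Gaussian sigma


@dataclass(frozen=True)
class TemplateSpec:
    """Parameterization of a transient AEP as Gaussian lobes.

    Wave V defaults to (7.05 ms, 0.44 µV); Pa sits near 25 ms.  The later
    component defaults are free parameters of the simulator, not published
    values.
    """

    components: tuple = (
        GaussianComponent("V", 7.05, 0.44, 0.8),
        GaussianComponent("Na", 16.5, -0.45, 2.2),
        GaussianComponent("Pa", 25.0, 0.90, 3.0),
        GaussianComponent("Nb", 40.0, -0.60, 4.0),
        GaussianComponent("Pb", 55.0, 0.50, 5.0),
    )
    duration_ms: float = 80.0
    fs: float = 20000.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "components", tuple(self.components))
        if self.duration_ms > 204.8 + 1e-9:
            raise ValidationError("template duration must not exceed the 204.8 ms sweep")
        names = [c.name for c in self.components]
        known = [n for n in names if n in COMPONENT_ORDER]
        if known != sorted(known, key=COMPONENT_ORDER.index):
            raise ValidationError(f"components out of canonical order: {names}")
        lat = [c.latency_ms for c in self.components]
        if any(b <= a for a, b in zip(lat, lat[1:])):
            raise ValidationError("component latencies must be strictly increasing")
        for c in self.components:
            if not (0.0 <= c.latency_ms <= self.duration_ms):
                raise ValidationError(
                    f"component {c.name} at {c.latency_ms} ms lies outside "
                    f"[0, {self.duration_ms}] ms")
            if c.name in _POSITIVE and c.amplitude_uv <= 0:
                raise ValidationError(f"{c.name} amplitude must be positive")
            if c.name in _NEGATIVE and c.amplitude_uv >= 0:
                raise ValidationError(f"{c.name} amplitude must be negative")

    def scaled(self, name: str, factor: float) -> "TemplateSpec":
        """Return a copy with one component's amplitude multiplied by ``factor``."""
        comps = tuple(
            replace(c, amplitude_uv=c.amplitude_uv * factor) if c.name == name else c
            for c in self.components)
        return replace(self, components=comps)

    def shifted(self, delta_ms: float) -> "TemplateSpec":
        """Return a copy with every latency shifted by ``delta_ms``."""
        comps = tuple(replace(c, latency_ms=c.latency_ms + delta_ms) for c in self.components)
        return replace(self, components=comps)


@dataclass(frozen=True)
class NoiseSpec:
    rms_uv: float = 1.0
    band: tuple[float, float] = (10.0, 1000.0)
    order: int = 4  # Butterworth order, applied zero-phase

    def __post_init__(self) -> None:
        if self.rms_uv < 0:
            raise ValidationError("noise rms must be >= 0")


@dataclass(frozen=True)
class SubjectSpec:
    """Per-subject generation settings.

    ``templates`` maps a paradigm name to its TemplateSpec; a single shared
    spec emulates perfect superposition, per-paradigm overrides emulate
    rate/sequencing-dependent transient responses.
    """

    templates: dict = field(default_factory=dict)
    n_sweeps: int = 200
    noise: NoiseSpec = NoiseSpec()
    artifact_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_sweeps < 1:
            raise ValidationError("n_sweeps must be >= 1")


def make_template(spec: TemplateSpec) -> TransientAEP:
    """Render a TemplateSpec to a waveform (sum of signed Gaussian lobes)."""
    n = int(round(spec.duration_ms * spec.fs / 1000.0))
    t = np.arange(n) * 1000.0 / spec.fs
    w = np.zeros(n)
    for c in spec.components:
        w += c.amplitude_uv * np.exp(-0.5 * ((t - c.latency_ms) / c.width_ms) ** 2)
    return TransientAEP(waveform=w, fs=spec.fs)


def band_limited_noise(
    shape: int | tuple, fs: float, spec: NoiseSpec, rng: np.random.Generator
) -> np.ndarray:
    """Zero-mean Gaussian noise filtered to ``spec.band``, scaled to target RMS.

    ``shape`` may be an int (one trace) or ``(n_traces, n_samples)``; each
    trace is independently generated, zero-meaned and scaled to the exact
    requested RMS along its last axis.
    """
    lo, hi = spec.band
    if not (0 < lo < hi < fs / 2):
        raise ValidationError(f"noise band {spec.band} outside (0, fs/2) at fs={fs}")
    if spec.rms_uv == 0:
        return np.zeros(shape)
    white = rng.standard_normal(shape)
    sos = signal.butter(spec.order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, white, axis=-1)
    x = x - x.mean(axis=-1, keepdims=True)
    rms = np.sqrt(np.mean(x**2, axis=-1, keepdims=True))
    return x * (spec.rms_uv / rms)


def circular_convolve(template: np.ndarray, train: ImpulseTrain) -> np.ndarray:
    """Circular convolution of a template with an impulse train of length N.

    The template may be longer than the train; it is folded modulo N first
    (steady-state wrap-around), so a single-click train of length P yields
    the one-cycle steady-state response at period P.
    """
    n = train.n
    x = np.asarray(template, dtype=float)
    folded = np.zeros(n)
    np.add.at(folded, np.arange(x.size) % n, x)
    return np.real(np.fft.ifft(np.fft.fft(folded) * np.fft.fft(train.samples)))


def simulate_sweeps(
    template: TransientAEP,
    train: ImpulseTrain,
    n_sweeps: int,
    noise: NoiseSpec,
    rng: np.random.Generator,
    artifact_rate: float = 0.0,
    artifact_uv: float = 50.0,
    paradigm: str = "",
) -> SweepSet:
    """Simulate sweep epochs: signal + band-limited noise (+ rare artifacts)."""
    if abs(template.fs - train.fs) > 1e-9:
        raise ValidationError(
            f"template fs {template.fs} != train fs {train.fs}")
    clean = circular_convolve(template.waveform, train)
    data = clean + band_limited_noise((n_sweeps, train.n), train.fs, noise, rng)
    if artifact_rate > 0:
        hit = rng.random(n_sweeps) < artifact_rate
        positions = rng.integers(train.n, size=n_sweeps)
        for i in np.flatnonzero(hit):
            data[i, positions[i]] += artifact_uv
    return SweepSet(data=data, fs=train.fs, paradigm=paradigm)


def simulate_study(
    subjects: list[SubjectSpec],
    sequences: dict,
    out_dir: str | Path,
    seed: int,
    fs: float,
) -> dict:
    """Write per-subject, per-paradigm sweep files plus a JSON manifest.

    ``sequences`` maps paradigm name → ImpulseTrain (for the 'msad'
    paradigm, a list of ImpulseTrains, one per rate).  Returns the
    manifest dict; files are TSV matrices with JSON sidecars.
    """
    if not subjects:
        raise ValidationError("need at least one subject")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    root = np.random.default_rng(seed)
    manifest: dict = {"seed": seed, "fs_hz": fs, "subjects": []}
    for si, subj in enumerate(subjects):
        rng = np.random.default_rng(root.integers(2**63))
        entry: dict = {"id": si, "paradigms": {}}
        for paradigm, train in sequences.items():
            spec = subj.templates.get(paradigm, subj.templates.get("default"))
            if spec is None:
                raise ValidationError(f"subject {si}: no template for {paradigm!r}")
            template = make_template(spec)
            trains = train if isinstance(train, list) else [train]
            paths = []
            for ri, tr in enumerate(trains):
                sweeps = simulate_sweeps(
                    template, tr, subj.n_sweeps, subj.noise, rng,
                    artifact_rate=subj.artifact_rate, paradigm=paradigm)
                suffix = f"_rate{ri}" if len(trains) > 1 else ""
                path = out_dir / f"subject{si:02d}_{paradigm}{suffix}.tsv"
                save_sweeps(path, sweeps, subject=si)
                paths.append(path.name)
            entry["paradigms"][paradigm] = {
                "files": paths,
                "template": {
                    "components": [vars(c) for c in spec.components],
                    "duration_ms": spec.duration_ms,
                },
            }
        manifest["subjects"].append(entry)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
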