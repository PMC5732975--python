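"""End-to-end study orchestration on synthetic EEG.

simulate → preprocess → deconvolve (three transient templates) →
synthesize steady-state responses → compare with the recorded control in
time and frequency domains → report.  All randomness flows through one
seeded generator, so a fixed seed gives a fully deterministic report.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .core import SteadyStateRecord, TransientAEP, save_waveform
from .deconv_clad import clad_deconvolve
from .deconv_msad import build_fold_system, msad_deconvolve
from .preprocess import average_sweeps, build_multi_rate_assr, build_rassr, reject_artifacts
from .sequences import (
    CLAD_ISIS_MS,
    CONTROL_ISI_MS,
    TRADITIONAL_EPOCH_MS,
    StimulusSequence,
    isi_to_samples,
    make_clad_sequence,
    to_impulse_train,
)
from .sequences import ImpulseTrain
from .spectrum_stats import harmonic_set, hotelling_one_sample, outlier_policy, pointwise_ttest
from .synthdata import NoiseSpec, TemplateSpec, make_template, simulate_sweeps
from .synthesis import contribution_table, synthesize_assr

logger = logging.getLogger(__name__)

PARADIGMS = ("traditional", "clad", "msad", "rassr")
SYNTH_KEYS = ("tASSR", "cASSR", "mASSR")
AEP_KEYS = {"tASSR": "tAEP", "cASSR": "cAEP", "mASSR": "mAEP"}


@dataclass(frozen=True)
class StudyConfig:
    fs: float = 20000.0
    clad_isis: tuple = CLAD_ISIS_MS
    control_isi_ms: float = CONTROL_ISI_MS
    traditional_epoch_ms: float = TRADITIONAL_EPOCH_MS
    n_subjects: int = 19
    n_sweeps: int = 1500
    n_cycles: int = 4
    noise: NoiseSpec = NoiseSpec(rms_uv=1.0)
    templates: dict = field(default_factory=dict)  # paradigm -> TemplateSpec
    artifact_rate: float = 0.0
    artifact_threshold_uv: float = 40.0
    clad_ridge: float = 0.0
    msad_method: str = "tikhonov"
    msad_parameter: float | str = "auto"
    msad_support_ms: float | None = None  # default: template duration
    remove_outliers: bool = False
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        templates = dict(self.templates)
        if "default" not in templates:
            templates["default"] = TemplateSpec(fs=self.fs)
        # keep template sampling consistent with the study grid
        templates = {k: replace(v, fs=self.fs) for k, v in templates.items()}
        object.__setattr__(self, "templates", templates)

    def template_for(self, paradigm: str) -> TemplateSpec:
        return self.templates.get(paradigm, self.templates["default"])


def fast_config(seed: int = 0, **overrides) -> StudyConfig:
    """CI-scale profile: coarse grid, few subjects, short blocks."""
    defaults = dict(fs=2500.0, n_subjects=5, n_sweeps=200, seed=seed)
    defaults.update(overrides)
    return StudyConfig(**defaults)


def _single_click_train(n_samples: int, fs: float) -> ImpulseTrain:
    samples = np.zeros(n_samples)
    samples[0] = 1.0
    return ImpulseTrain(samples=samples, fs=fs, onsets=(0,))


def _process_subject(config: StudyConfig, rng: np.random.Generator,
                     clad_train, msad_trains, fold_system) -> dict:
    fs = config.fs
    out: dict = {}

    def acquire(template_spec, train, paradigm):
        sweeps = simulate_sweeps(
            make_template(template_spec), train, config.n_sweeps, config.noise,
            rng, artifact_rate=config.artifact_rate, paradigm=paradigm)
        kept, report = reject_artifacts(sweeps, config.artifact_threshold_uv)
        mean, consistency = average_sweeps(kept)
        return mean, report, consistency

    # traditional: one click per long epoch, average is the template estimate
    epoch_n = isi_to_samples(config.traditional_epoch_ms, fs)
    mean, rep, cons = acquire(config.template_for("traditional"),
                              _single_click_train(epoch_n, fs), "traditional")
    out["tAEP"] = TransientAEP(waveform=mean, fs=fs)
    out["qc"] = {"traditional": {"rejected": rep.n_rejected, "consistency": cons}}

    # clad: averaged quasi-periodic record, then inverse filtering
    mean, rep, cons = acquire(config.template_for("clad"), clad_train, "clad")
    multi_isi = SteadyStateRecord(waveform=mean, fs=fs)
    out["cAEP"] = clad_deconvolve(multi_isi, clad_train, ridge=config.clad_ridge)
    out["multi_isi_assr"] = multi_isi
    out["qc"]["clad"] = {"rejected": rep.n_rejected, "consistency": cons}

    # msad: eight per-rate one-cycle averages, spliced, then regularized solve
    per_rate = {}
    msad_qc = {}
    for isi, train in zip(config.clad_isis, msad_trains):
        mean, rep, cons = acquire(config.template_for("msad"), train, "msad")
        per_rate[float(isi)] = mean
        msad_qc[f"isi_{isi}"] = {"rejected": rep.n_rejected, "consistency": cons}
    multi_rate = build_multi_rate_assr(per_rate, list(config.clad_isis), fs)
    noise_level = config.noise.rms_uv / np.sqrt(max(config.n_sweeps, 1))
    solution = msad_deconvolve(
        multi_rate, fold_system, method=config.msad_method,
        parameter=config.msad_parameter, noise_level=noise_level)
    out["mAEP"] = solution.estimate
    out["msad_solution"] = solution
    out["multi_rate_assr"] = multi_rate
    out["qc"]["msad"] = msad_qc

    # classical control: four-cycle epoch
    period = isi_to_samples(config.control_isi_ms, fs)
    control_seq = StimulusSequence(isis=(config.control_isi_ms,) * config.n_cycles,
                                   kind="isochronic")
    control_train = to_impulse_train(control_seq, fs)
    mean, rep, cons = acquire(config.template_for("rassr"), control_train, "rassr")
    out["rASSR"] = build_rassr(mean, config.control_isi_ms, fs, config.n_cycles)
    out["qc"]["rassr"] = {"rejected": rep.n_rejected, "consistency": cons}

    # synthesis from the three templates
    for key in SYNTH_KEYS:
        aep = out[AEP_KEYS[key]]
        out[key] = synthesize_assr(aep, config.control_isi_ms, config.n_cycles)
    return out


def run_study(config: StudyConfig, out_dir: str | Path | None = None) -> dict:
    """Run the full synthetic study; returns the in-memory report bundle."""
    t0 = time.perf_counter()
    fs = config.fs
    clad_train = to_impulse_train(make_clad_sequence(config.clad_isis), fs)
    msad_trains = [
        _single_click_train(isi_to_samples(isi, fs), fs) for isi in config.clad_isis
    ]
    support_ms = config.msad_support_ms
    if support_ms is None:
        support_ms = config.template_for("msad").duration_ms
    n_support = int(round(support_ms * fs / 1000.0))
    fold_system = build_fold_system(
        [isi_to_samples(i, fs) for i in config.clad_isis], n_support, fs)

    root = np.random.default_rng(config.seed)
    subjects = []
    for si in range(config.n_subjects):
        rng = np.random.default_rng(root.integers(2**63))
        try:
            subjects.append(_process_subject(config, rng, clad_train, msad_trains,
                                             fold_system))
        except Exception as err:  # annotate with stage context
            raise RuntimeError(f"subject {si} failed: {err}") from err
        logger.info("subject %d done (%.1f s)", si, time.perf_counter() - t0)

    report: dict = {"config": config, "subjects": subjects}

    # grand averages
    grand = {}
    for key in ("tAEP", "cAEP", "mAEP"):
        stack = np.array([s[key].waveform for s in subjects])
        grand[key] = TransientAEP(waveform=stack.mean(axis=0), fs=fs)
    for key in ("rASSR",) + tuple(SYNTH_KEYS):
        stack = np.array([s[key].waveform for s in subjects])
        grand[key] = stack.mean(axis=0)
    report["grand"] = grand

    # time-domain comparison: synthetic minus recorded, pointwise t-test
    time_domain = {}
    for key in SYNTH_KEYS:
        diff = np.array([s[key].waveform - s["rASSR"].waveform for s in subjects])
        if len(subjects) >= 3 and np.any(diff.std(axis=0) > 0):
            trace = pointwise_ttest(diff, alpha=config.alpha)
            time_domain[key] = {
                "mean_difference": trace.mean,
                "significant_fraction_pct": trace.significant_fraction_pct,
                "p_values": trace.p_values,
            }
        else:
            time_domain[key] = {
                "mean_difference": diff.mean(axis=0),
                "significant_fraction_pct": 0.0 if np.allclose(diff, 0) else None,
                "p_values": None,
                "degenerate": True,
            }
    report["time_domain"] = time_domain

    # frequency domain: six-element harmonic difference vectors, Hotelling T²
    freq_domain = {}
    for key in SYNTH_KEYS:
        vectors = []
        for s in subjects:
            h_synth = harmonic_set(s[key])
            h_rec = harmonic_set(s["rASSR"])
            vectors.append(h_synth.as_vector() - h_rec.as_vector())
        vectors = np.array(vectors)
        entry: dict = {"difference_vectors": vectors}
        kept = np.arange(vectors.shape[0])
        if config.remove_outliers and vectors.shape[0] >= 5:
            kept = outlier_policy(vectors)
        entry["kept_subjects"] = kept
        sub = vectors[kept]
        if sub.shape[0] > sub.shape[1] and np.linalg.matrix_rank(np.cov(sub, rowvar=False)) == sub.shape[1]:
            entry["hotelling"] = hotelling_one_sample(sub, alpha=config.alpha)
        else:
            entry["hotelling"] = None
            entry["degenerate"] = True
        freq_domain[key] = entry
    report["frequency_domain"] = freq_domain

    # component contributions from the grand-average templates
    contributions = {}
    for key in SYNTH_KEYS:
        aep = grand[AEP_KEYS[key]]
        try:
            contributions[key] = contribution_table(
                aep, isi_ms=config.control_isi_ms, n_cycles=config.n_cycles)
        except Exception as err:
            logger.warning("contribution table for %s skipped: %s", key, err)
    report["contributions"] = contributions

    if out_dir is not None:
        _write_report(report, Path(out_dir))
    logger.info("study complete in %.1f s", time.perf_counter() - t0)
    return report


def _write_report(report: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    config = report["config"]
    fs = config.fs
    for key, aep in (("tAEP", None), ("cAEP", None), ("mAEP", None)):
        save_waveform(out_dir / f"grand_{key}.tsv", report["grand"][key].waveform, fs)
    for key in ("rASSR",) + tuple(SYNTH_KEYS):
        save_waveform(out_dir / f"grand_{key}.tsv", np.asarray(report["grand"][key]), fs)
    summary: dict = {"seed": config.seed, "fs_hz": fs,
                     "n_subjects": config.n_subjects, "time_domain": {},
                     "frequency_domain": {}, "contributions": report["contributions"]}
    for key, entry in report["time_domain"].items():
        summary["time_domain"][key] = {
            "significant_fraction_pct": entry["significant_fraction_pct"]}
        save_waveform(out_dir / f"diff_{key}.tsv", entry["mean_difference"], fs)
    for key, entry in report["frequency_domain"].items():
        h = entry["hotelling"]
        summary["frequency_domain"][key] = None if h is None else {
            "t2": h.t2, "f": h.f, "p_value": h.p_value, "n": h.n, "p": h.p}
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2, default=float))


def make_figures(report: dict, out_dir: str | Path) -> list[Path]:
    """Render the standard figure set from a report bundle; returns paths."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not report or "grand" not in report:
        logger.warning("empty report: no figures produced")
        return []
    config = report["config"]
    fs = config.fs
    paths: list[Path] = []

    def finish(fig, name):
        path = out_dir / name
        fig.savefig(path, dpi=110)
        plt.close(fig)
        paths.append(path)

    grand = report["grand"]

    def t_axis(w):
        return np.arange(np.asarray(w).size) * 1000.0 / fs

    fig, ax = plt.subplots(figsize=(7, 4))
    for key, color in (("tAEP", "tab:blue"), ("cAEP", "tab:green"), ("mAEP", "tab:red")):
        ax.plot(t_axis(grand[key].waveform), grand[key].waveform,
                color=color, label=key, lw=1)
    ax.set_xlabel("time (ms)"); ax.set_ylabel("µV"); ax.legend()
    ax.set_title("grand-average transient templates")
    finish(fig, "fig1_templates.png")

    fig, axes = plt.subplots(3, 1, figsize=(7, 7), sharex=True)
    for ax, (a, b) in zip(axes, (("tAEP", "cAEP"), ("cAEP", "mAEP"), ("tAEP", "mAEP"))):
        wa, wb = grand[a].waveform, grand[b].waveform
        n = min(wa.size, wb.size)
        ax.plot(t_axis(wa), wa, "b-", lw=1, label=a)
        ax.plot(t_axis(wa[:n]), wa[:n] - wb[:n], "r--", lw=1, label=f"{a}−{b}")
        ax.legend(fontsize=8)
    axes[-1].set_xlabel("time (ms)")
    finish(fig, "fig2_template_differences.png")

    t_assr = np.arange(np.asarray(grand["rASSR"]).size) * 1000.0 / fs
    fig, axes = plt.subplots(3, 1, figsize=(7, 7), sharex=True)
    for ax, key in zip(axes, SYNTH_KEYS):
        ax.plot(t_assr, np.asarray(grand["rASSR"]), "b-", lw=1, label="rASSR")
        ax.plot(t_assr, np.asarray(grand[key]), "r-", lw=1, label=key)
        entry = report["time_domain"][key]
        diff = np.asarray(entry["mean_difference"])
        ax.plot(t_assr, diff, "k-", lw=0.8)
        if entry.get("p_values") is not None:
            mask = np.asarray(entry["p_values"]) < config.alpha
            shown = np.where(mask, diff, np.nan)
            ax.plot(t_assr, shown, "r-", lw=2.5)
        ax.legend(fontsize=8)
    axes[-1].set_xlabel("time (ms)")
    finish(fig, "fig3_assr_comparison.png")

    fig, ax = plt.subplots(figsize=(6, 4))
    contrib = report.get("contributions", {})
    names = list(next(iter(contrib.values()))["normalized_pct"]) if contrib else []
    width = 0.25
    for i, key in enumerate(k for k in SYNTH_KEYS if k in contrib):
        vals = [contrib[key]["normalized_pct"][n] for n in names]
        ax.bar(np.arange(len(names)) + i * width, vals, width, label=key)
    ax.set_xticks(np.arange(len(names)) + width, names)
    ax.set_ylabel("normalized contribution (%)"); ax.legend()
    finish(fig, "fig4_contributions.png")

    # harmonic decomposition of the grand recorded control
    rec = SteadyStateRecord(
        waveform=np.asarray(grand["rASSR"]), fs=fs, n_cycles=config.n_cycles)
    from .spectrum_stats import harmonic_set as _hs, reconstruct as _rc
    hset = _hs(rec)
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    axes[0].plot(t_assr, rec.waveform, "r-", lw=1)
    axes[0].set_title("recorded control")
    axes[1].plot(t_assr, rec.waveform, "r-", lw=1, label="record")
    axes[1].plot(t_assr, _rc(hset), "k-", lw=1, label="first 3 harmonics")
    axes[1].legend(fontsize=8)
    finish(fig, "fig5_harmonics.png")

    fig, axes = plt.subplots(1, 3, figsize=(10, 3.5))
    colors = {"tASSR": "k", "cASSR": "g", "mASSR": "b"}
    for hi in range(3):
        ax = axes[hi]
        for key in SYNTH_KEYS:
            vecs = report["frequency_domain"][key]["difference_vectors"]
            ax.scatter(vecs[:, 2 * hi], vecs[:, 2 * hi + 1], s=8,
                       color=colors[key], label=key if hi == 0 else None)
        ax.axhline(0, color="0.7", lw=0.5); ax.axvline(0, color="0.7", lw=0.5)
        ax.set_title(f"harmonic {hi + 1}")
    axes[0].legend(fontsize=8)
    finish(fig, "fig6_difference_vectors.png")

    fig, ax = plt.subplots(figsize=(6, 3.5))
    fracs = {k: report["time_domain"][k]["significant_fraction_pct"]
             for k in SYNTH_KEYS}
    keys = [k for k, v in fracs.items() if v is not None]
    ax.bar(keys, [fracs[k] for k in keys], color="tab:red")
    ax.set_ylabel("significant fraction (%)")
    finish(fig, "fig7_significant_fractions.png")

    return paths
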