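"""End-to-end orchestration: simulate -> preprocess -> ERP + ITPC -> stats -> figures.

Stages are pure functions of (config, seed); each stage checkpoints its
outputs in the run directory together with a hash of the configuration, so
re-running skips clean stages and reproduces downstream results exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import erp as erp_mod
from . import itpc as itpc_mod
from . import preprocess as pre
from . import stats as stats_mod
from . import synth
from .stimulus import ErpProtocol, InvalidParameterError

__all__ = ["RunConfig", "run_all", "STAGES"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "erp", "itpc", "stats", "figures")


@dataclass
class RunConfig:
    """Everything a run depends on; serialized alongside the results."""

    design: dict[tuple[str, str, str], int] = field(
        default_factory=synth.default_female_design
    )
    seed: int = 0
    sessions: str = "both"
    n_trials_per_pair: int = 101
    erp_n_repetitions: int = 120
    erp_repetition_rate_hz: float = 0.25
    sim_rate_hz: float = 4096.0
    analysis_rate_hz: float = 1024.0
    erp_window_ms: tuple[float, float] = (-250.0, 750.0)
    baseline_ms: tuple[float, float] = (-250.0, 0.0)
    assr_window_ms: tuple[float, float] = (-100.0, 350.0)
    summary_window_ms: tuple[float, float] = (50.0, 250.0)
    freq_grid: tuple[float, float, int] = (10.0, 100.0, 31)
    peak_windows_ms: dict = field(
        default_factory=lambda: dict(erp_mod.DEFAULT_PEAK_WINDOWS_MS)
    )
    noise_rms_uv: float = 15.0
    assr_amplitude_uv: float = 8.0
    strict_artifacts: bool = False

    # ------------------------------------------------------------- serde
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["design"] = [
            {"genotype": g, "sex": s, "age": a, "n": n}
            for (g, s, a), n in sorted(self.design.items())
        ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["design"] = {
            (c["genotype"], c["sex"], c["age"]): c["n"] for c in d["design"]
        }
        for key in ("erp_window_ms", "baseline_ms", "assr_window_ms",
                    "summary_window_ms", "freq_grid"):
            if key in d:
                d[key] = tuple(d[key])
        d["peak_windows_ms"] = {
            k: tuple(v) for k, v in d.get("peak_windows_ms", {}).items()
        }
        return cls(**d)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    def erp_protocol(self) -> ErpProtocol:
        return ErpProtocol(
            n_repetitions=self.erp_n_repetitions,
            repetition_rate_hz=self.erp_repetition_rate_hz,
        )

    def morlet_params(self) -> itpc_mod.MorletParams:
        lo, hi, n = self.freq_grid
        return itpc_mod.MorletParams(freqs_hz=itpc_mod.default_freq_grid(int(n), lo, hi))


# --------------------------------------------------------------------------
# checkpoint helpers


def _marker_path(outdir: Path, stage: str) -> Path:
    return outdir / "stages" / f"{stage}.json"


def _stage_clean(outdir: Path, stage: str, cfg_hash: str) -> bool:
    marker = _marker_path(outdir, stage)
    if not marker.exists():
        return False
    try:
        payload = json.loads(marker.read_text())
    except json.JSONDecodeError:
        return False
    if payload.get("config_hash") != cfg_hash:
        return False
    return all(Path(f).exists() for f in payload.get("outputs", []))


def _mark_stage(outdir: Path, stage: str, cfg_hash: str, outputs: list,
                elapsed_s: float) -> None:
    marker = _marker_path(outdir, stage)
    marker.parent.mkdir(parents=True, exist_ok=True)
    marker.write_text(json.dumps(
        {"config_hash": cfg_hash, "outputs": [str(o) for o in outputs],
         "elapsed_s": round(elapsed_s, 3)}, indent=1))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


# --------------------------------------------------------------------------
# stages


def _stage_simulate(config: RunConfig, outdir: Path) -> list[Path]:
    subjects = synth.simulate_cohort(
        config.design,
        seed=config.seed,
        presets=synth.cohort_presets(
            noise_rms_uv=config.noise_rms_uv,
            assr_amplitude_uv=config.assr_amplitude_uv,
        ),
        sessions=config.sessions,
        n_trials_per_pair=config.n_trials_per_pair,
        erp_protocol=config.erp_protocol(),
        sample_rate_hz=config.sim_rate_hz,
    )
    rec_path = outdir / "recordings.h5"
    with h5py.File(rec_path, "w") as h:
        for s in subjects:
            grp = h.create_group(s.subject.subject_id)
            if s.erp is not None:
                s.erp.to_hdf5(grp.create_group("erp"))
            if s.assr is not None:
                s.assr.to_hdf5(grp.create_group("assr"))
    manifest_path = outdir / "cohort_manifest.csv"
    synth.write_cohort_manifest(
        subjects, {s.subject.subject_id: "recordings.h5" for s in subjects},
        manifest_path,
    )
    return [rec_path, manifest_path]


def _load_recordings(outdir: Path, session: str) -> list[synth.Recording]:
    out = []
    with h5py.File(outdir / "recordings.h5", "r") as h:
        for sid in sorted(h):
            if session in h[sid]:
                out.append(synth.Recording.from_hdf5(h[sid][session]))
    return out


def _preprocess_one(recording: synth.Recording, config: RunConfig,
                    window_ms: tuple[float, float], labels) -> pre.EpochSet:
    rec = pre.downsample(recording, config.analysis_rate_hz)
    epochs = pre.extract_epochs(rec, window_ms=window_ms)
    epochs = epochs.select(labels)
    epochs = pre.baseline_correct(epochs, config.baseline_ms)
    epochs = pre.detrend_epochs(epochs)
    return pre.screen_artifacts(epochs)


def _stage_preprocess(config: RunConfig, outdir: Path) -> list[Path]:
    epoch_dir = outdir / "epochs"
    epoch_dir.mkdir(exist_ok=True)
    outputs = []
    if config.sessions in ("both", "erp"):
        for rec in _load_recordings(outdir, "erp"):
            ep = _preprocess_one(rec, config, config.erp_window_ms, "erp")
            path = epoch_dir / f"{rec.subject.subject_id}_erp.h5"
            ep.to_hdf5(path)
            outputs.append(path)
    if config.sessions in ("both", "assr"):
        for rec in _load_recordings(outdir, "assr"):
            rec_ds = pre.downsample(rec, config.analysis_rate_hz)
            epochs = pre.extract_epochs(rec_ds, window_ms=config.assr_window_ms)
            gap_labels = [l for l in set(epochs.event_labels) if l.startswith("gap")]
            epochs = epochs.select(gap_labels)
            epochs = pre.screen_artifacts(epochs)
            path = epoch_dir / f"{rec.subject.subject_id}_assr.h5"
            epochs.to_hdf5(path)
            outputs.append(path)
    return outputs


def _subject_specs(outdir: Path) -> dict[str, synth.SubjectSpec]:
    manifest = pd.read_csv(outdir / "cohort_manifest.csv")
    return {
        row.subject_id: synth.SubjectSpec(
            row.subject_id, row.genotype, row.sex, row.age_group
        )
        for row in manifest.itertuples()
    }


def _stage_erp(config: RunConfig, outdir: Path) -> list[Path]:
    specs = _subject_specs(outdir)
    results = []
    waveforms_path = outdir / "erp_waveforms.h5"
    with h5py.File(waveforms_path, "w") as h:
        for sid, spec in specs.items():
            path = outdir / "epochs" / f"{sid}_erp.h5"
            if not path.exists():
                continue
            epochs = pre.EpochSet.from_hdf5(path)
            by_channel = {}
            for ch in epochs.channels:
                wf = erp_mod.average_erp(
                    epochs, ch, strict=config.strict_artifacts, subject_id=sid
                )
                by_channel[ch] = erp_mod.detect_peaks(wf, config.peak_windows_ms)
                grp = h.require_group(f"{sid}/{ch}")
                grp.create_dataset("mean_uv", data=wf.mean_uv)
                grp.create_dataset("times_ms", data=wf.times_ms)
                grp.attrs["n_trials"] = wf.n_trials
            results.append((spec, by_channel))
    table = erp_mod.erp_group_table(results)
    table_path = outdir / "erp_table.csv"
    table.to_csv(table_path, index=False)
    return [table_path, waveforms_path]


def _stage_itpc(config: RunConfig, outdir: Path) -> list[Path]:
    specs = _subject_specs(outdir)
    params = config.morlet_params()
    results = []
    example_path = outdir / "itpc_example_surface.h5"
    example_written = False
    for sid, spec in specs.items():
        path = outdir / "epochs" / f"{sid}_assr.h5"
        if not path.exists():
            continue
        epochs = pre.EpochSet.from_hdf5(path)
        by_channel = {}
        for ch in epochs.channels:
            keep = (not example_written) and ch == "FC"
            summaries, surfaces = itpc_mod.itpc_by_pair(
                epochs, ch, params,
                window_ms=config.summary_window_ms,
                strict=config.strict_artifacts,
                keep_surfaces=keep,
                min_trials_warn=min(100, config.n_trials_per_pair),
            )
            by_channel[ch] = summaries
            if keep and surfaces:
                pair = max(surfaces, key=lambda p: (p.mod_depth_pct, p.gap_width_ms))
                surf = surfaces[pair]
                with h5py.File(example_path, "w") as h:
                    h.attrs.update(subject=sid, channel=ch, pair=pair.label,
                                   n_trials=surf.n_trials)
                    h.create_dataset("itpc", data=surf.values)
                    h.create_dataset("freqs_hz", data=surf.freqs_hz)
                    h.create_dataset("times_ms", data=surf.times_ms)
                example_written = True
        results.append((spec, by_channel))
    table = itpc_mod.itpc_group_table(results)
    table_path = outdir / "itpc_table.csv"
    table.to_csv(table_path, index=False)
    collapsed_path = outdir / "itpc_collapsed.csv"
    itpc_mod.collapse_gap_widths(table).to_csv(collapsed_path, index=False)
    outputs = [table_path, collapsed_path]
    if example_written:
        outputs.append(example_path)
    return outputs


def _stage_stats(config: RunConfig, outdir: Path) -> list[Path]:
    erp_path = outdir / "erp_table.csv"
    itpc_path = outdir / "itpc_table.csv"
    erp_table = pd.read_csv(erp_path) if erp_path.exists() else None
    itpc_table = pd.read_csv(itpc_path) if itpc_path.exists() else None
    report = stats_mod.run_paper_contrasts(erp_table, itpc_table)
    paths = [outdir / "stats_report.json", outdir / "stats_anova.csv",
             outdir / "stats_contrasts.csv"]
    report.to_json(paths[0])
    report.to_csv(paths[1], paths[2])
    return paths


def _stage_figures(config: RunConfig, outdir: Path) -> list[Path]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig_dir = outdir / "figures"
    fig_dir.mkdir(exist_ok=True)
    outputs = []
    ages = synth.AGE_GROUPS

    wf_path = outdir / "erp_waveforms.h5"
    if wf_path.exists():
        specs = _subject_specs(outdir)
        fig, axes = plt.subplots(2, 3, figsize=(11, 6), sharex=True, sharey=True)
        with h5py.File(wf_path, "r") as h:
            for i, ch in enumerate(("AC", "FC")):
                for j, age in enumerate(ages):
                    ax = axes[i, j]
                    for geno, color in (("WT", "k"), ("KO", "r")):
                        traces = [
                            h[f"{sid}/{ch}/mean_uv"][...]
                            for sid, spec in specs.items()
                            if spec.age_group == age and spec.genotype == geno
                            and f"{sid}/{ch}" in h
                        ]
                        if traces:
                            t = h[f"{next(iter(specs))}/{ch}/times_ms"][...]
                            ax.plot(t, np.mean(traces, axis=0), color, label=geno)
                    ax.set_title(f"{ch} {age}")
                    ax.axvline(0, ls=":", lw=0.5)
        axes[0, 0].legend()
        fig.supxlabel("time (ms)")
        fig.supylabel("amplitude (uV)")
        path = fig_dir / "grand_average_erps.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        outputs.append(path)

    itpc_path = outdir / "itpc_table.csv"
    if itpc_path.exists():
        table = pd.read_csv(itpc_path)
        depths = sorted(table["mod_depth_pct"].unique())
        fig, axes = plt.subplots(
            len(ages), 2 * len(depths), figsize=(3.2 * 2 * len(depths), 7),
            sharex=True, sharey=True, squeeze=False,
        )
        for i, age in enumerate(ages):
            for j, (depth, ch) in enumerate(
                [(d, c) for d in depths for c in ("AC", "FC")]
            ):
                ax = axes[i, j]
                sub = table[
                    (table["age"] == age)
                    & (table["mod_depth_pct"] == depth)
                    & (table["channel"] == ch)
                ]
                for geno, color in (("WT", "k"), ("KO", "r")):
                    g = sub[sub["genotype"] == geno]
                    if len(g):
                        curve = g.groupby("gap_width_ms")["itpc"].mean()
                        ax.plot(curve.index, curve.values, f"{color}o-",
                                ms=3, label=geno)
                ax.set_title(f"{ch} {depth:g}% {age}", fontsize=8)
        axes[0, 0].legend(fontsize=7)
        fig.supxlabel("gap width (ms)")
        fig.supylabel("mean 40 Hz ITPC")
        path = fig_dir / "itpc_vs_gap.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        outputs.append(path)

        collapsed = itpc_mod.collapse_gap_widths(table)
        fig, axes = plt.subplots(2, len(depths), figsize=(4 * len(depths), 6),
                                 sharey=True, squeeze=False)
        for i, ch in enumerate(("AC", "FC")):
            for j, depth in enumerate(depths):
                ax = axes[i, j]
                sub = collapsed[
                    (collapsed["channel"] == ch)
                    & (collapsed["mod_depth_pct"] == depth)
                ]
                width = 0.35
                xs = np.arange(len(ages))
                for off, (geno, color) in ((-width / 2, ("WT", "0.3")),
                                           (width / 2, ("KO", "r"))):
                    means = [
                        sub[(sub["age"] == a) & (sub["genotype"] == geno)][
                            "itpc_collapsed"
                        ].mean()
                        for a in ages
                    ]
                    ax.bar(xs + off, means, width, color=color, label=geno)
                ax.set_xticks(xs, ages)
                ax.set_title(f"{ch} {depth:g}%")
        axes[0, 0].legend()
        fig.supylabel("gap-collapsed mean 40 Hz ITPC")
        path = fig_dir / "itpc_collapsed_bars.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        outputs.append(path)

    example = outdir / "itpc_example_surface.h5"
    if example.exists():
        with h5py.File(example, "r") as h:
            fig, ax = plt.subplots(figsize=(5, 4))
            mesh = ax.pcolormesh(
                h["times_ms"][...], h["freqs_hz"][...], h["itpc"][...],
                shading="auto", cmap="turbo", vmin=0, vmax=1,
            )
            ax.axvline(0, color="w", ls="--", lw=0.7)
            ax.set_xlabel("time (ms)")
            ax.set_ylabel("frequency (Hz)")
            ax.set_title(
                f"ITPC {h.attrs['channel']} {h.attrs['pair']} "
                f"(n={h.attrs['n_trials']})", fontsize=9,
            )
            fig.colorbar(mesh, label="ITPC")
            path = fig_dir / "itpc_heatmap_example.png"
            fig.savefig(path, dpi=120)
            plt.close(fig)
            outputs.append(path)
    return outputs


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "erp": _stage_erp,
    "itpc": _stage_itpc,
    "stats": _stage_stats,
    "figures": _stage_figures,
}


def run_all(config: RunConfig, outdir, stages=STAGES, force: bool = False) -> dict:
    """Run the pipeline; returns the run manifest (also written to disk).

    Clean stages (same config hash, outputs present) are skipped unless
    ``force``.  The manifest lists every output file with a sha256 hash.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    config.to_json(outdir / "config.json")

    unknown = set(stages) - set(STAGES)
    if unknown:
        raise InvalidParameterError(f"unknown stages: {sorted(unknown)}")
    stage_status = {}
    all_outputs: list[Path] = [outdir / "config.json"]
    for stage in STAGES:
        if stage not in stages:
            stage_status[stage] = "not-requested"
            continue
        if not force and _stage_clean(outdir, stage, cfg_hash):
            stage_status[stage] = "cached"
            payload = json.loads(_marker_path(outdir, stage).read_text())
            all_outputs += [Path(p) for p in payload["outputs"]]
            logger.info("stage %-10s cached", stage)
            continue
        t0 = time.perf_counter()
        outputs = _STAGE_FUNCS[stage](config, outdir)
        elapsed = time.perf_counter() - t0
        _mark_stage(outdir, stage, cfg_hash, outputs, elapsed)
        stage_status[stage] = "ran"
        all_outputs += outputs
        logger.info("stage %-10s finished in %.2f s (%d outputs)",
                    stage, elapsed, len(outputs))

    manifest = {
        "seed": config.seed,
        "config_hash": cfg_hash,
        "stages": stage_status,
        "files": {
            str(p.relative_to(outdir)): _sha256(p)
            for p in sorted(set(all_outputs)) if p.exists()
        },
    }
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
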