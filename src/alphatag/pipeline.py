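"""End-to-end orchestration: simulate -> spectral -> statistics -> report.

The analysis order mirrors the sensor-level study design: induced alpha
contrast (auditory vs visual cue), evoked tag-envelope contrasts (36/40 Hz
and the 4 Hz intermodulation component) over the pre-target window, the
44 Hz bleed-over control, seed-based trial-by-trial correlation maps with
group cluster tests, condition interaction and median-split / t / Bayes
factor follow-ups, and the behavioural summaries.  A single master seed
deterministically derives every stage seed, so ``(config, seed)`` maps to an
identical report.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as beh
from .cluster import ClusterResult, permutation_cluster_test
from .core import (
    EpochSet,
    band_preset,
    build_neighbor_graph,
    posterior_channels,
    read_epochs,
    standard_layout_64,
    write_epochs,
)
from .simulate import SimulationConfig, generate_participant, participant_seeds
from .spectral import baseline_relative_change, compute_band_envelopes
from .trialcorr import (
    SeedSpec,
    exclude_outliers,
    group_corr_cluster_test,
    interaction_test,
    jzs_bf10,
    median_split_contrast,
    one_sample_t,
    seed_correlation_map,
)

__all__ = ["PipelineConfig", "AnalysisReport", "run_simulate", "run_analysis", "run_report"]


@dataclass
class PipelineConfig:
    """Configuration of the full analysis run."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    # analysis windows, seconds relative to cue onset (cue at 0, target at
    # tag_offset); presets follow the 500/400/150 ms pre-target conventions
    baseline_window: tuple[float, float] = (-0.7, -0.2)
    alpha_window: tuple[float, float] | None = None  # default: last 2 s before target
    pretarget_window: tuple[float, float] | None = None  # default: last 500 ms
    seed_window: tuple[float, float] | None = None  # default: last 1 s before target

    # cluster settings
    n_perm: int = 1000
    criterion: float = 95.0
    alpha_pointwise: float = 0.05
    neighbor_max_dist: float = 0.33
    stat_step: float = 0.05  # s between samples entering the cluster test

    # correlation settings
    seed_channels: tuple | None = None  # default: posterior channels
    corr_conditions: tuple = ("visual_cue", "auditory_cue")

    seed: int = 0

    def resolve_windows(self) -> dict:
        t1 = self.simulation.tag_offset
        return {
            "alpha": self.alpha_window or (t1 - 2.0, t1),
            "pretarget": self.pretarget_window or (t1 - 0.5, t1),
            "seed": self.seed_window or (t1 - 1.0, t1),
        }

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class AnalysisReport:
    """All numeric outputs of one analysis run plus provenance."""

    cluster_tables: dict  # analysis name -> DataFrame
    correlation_summary: pd.DataFrame
    behavior_summary: pd.DataFrame
    behavior_effects: pd.DataFrame
    significant: dict  # analysis name -> bool
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "cluster_tables": {
                k: v.to_dict(orient="list") for k, v in self.cluster_tables.items()
            },
            "correlation_summary": self.correlation_summary.to_dict(orient="list"),
            "behavior_summary": self.behavior_summary.to_dict(orient="list"),
            "behavior_effects": self.behavior_effects.to_dict(orient="list"),
            "significant": dict(self.significant),
            "provenance": dict(self.provenance),
        }

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stage_seeds(master: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


# ---------------------------------------------------------------------------
# simulate stage
# ---------------------------------------------------------------------------

def run_simulate(config: PipelineConfig, outdir) -> list[Path]:
    """Write the synthetic cohort and ground-truth sidecars to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = config.simulation
    sim.validate()
    layout = standard_layout_64()
    layout.to_tsv(outdir / "layout.tsv")
    sim.to_file(outdir / "simulation.yaml")
    paths = []
    for p, seed in enumerate(participant_seeds(sim)):
        pid = f"p{p:02d}"
        epochs, truth = generate_participant(sim, seed, participant_id=pid, layout=layout)
        path = outdir / f"{pid}.epochs.zip"
        write_epochs(epochs, path)
        truth.to_tsv(outdir / f"{pid}.truth.tsv")
        paths.append(path)
    return paths


def load_cohort(indir) -> list[EpochSet]:
    """Read every participant container from a simulation output directory."""
    paths = sorted(Path(indir).glob("*.epochs.zip"))
    if not paths:
        raise FileNotFoundError(f"no participant files under {indir}")
    return [read_epochs(p) for p in paths]


# ---------------------------------------------------------------------------
# analysis stage
# ---------------------------------------------------------------------------

def _window_map(env_values, times, window, step_samples, valid_mask):
    mask = (times >= window[0]) & (times <= window[1]) & valid_mask
    idx = np.flatnonzero(mask)[::step_samples]
    if idx.size == 0:
        raise ValueError(f"analysis window {window} has no valid samples")
    return env_values[..., idx]


def _stage(name):
    """Wrap stage failures with the stage name for diagnosable aborts."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"analysis stage '{name}' failed: {exc}") from exc
            return False

    return _Ctx()


def run_analysis(config: PipelineConfig, cohort: list[EpochSet]) -> AnalysisReport:
    """Run the full sensor-level analysis on a cohort of EpochSets."""
    sim = config.simulation
    windows = config.resolve_windows()
    layout = standard_layout_64().subset(cohort[0].channels)
    graph = build_neighbor_graph(layout, config.neighbor_max_dist)
    step = max(int(round(config.stat_step * cohort[0].sfreq)), 1)
    stat_seed, *corr_seeds = _stage_seeds(config.seed, 8)

    conds = ("auditory_cue", "visual_cue")
    contrast_bands = [
        ("alpha", "induced"),
        ("visual_tag", "evoked"),
        ("auditory_tag", "evoked"),
        ("intermodulation", "evoked"),
        ("control_44", "evoked"),
    ]
    alpha_band = band_preset("alpha")
    seed_channels = tuple(config.seed_channels or posterior_channels(layout))
    seed_spec = SeedSpec(
        channels=seed_channels, window=windows["seed"], band=alpha_band
    )
    target_bands = [band_preset("visual_tag"), band_preset("auditory_tag")]

    # ---- per-participant feature extraction --------------------------------
    with _stage("feature extraction"):
        maps: dict[tuple[str, str], list] = {(b, c): [] for b, _ in contrast_bands for c in conds}
        corr_maps: dict[tuple[str, str], list] = {
            (b.name, c): [] for b in target_bands for c in config.corr_conditions
        }
        split_rows = []
        for epochs in cohort:
            times = epochs.times
            for band_name, path in contrast_bands:
                band = band_preset(band_name)
                for cond in conds:
                    sub = epochs.select(cond)
                    evoked, induced = compute_band_envelopes(
                        sub, band, config.baseline_window
                    )
                    if path == "induced":
                        vals = baseline_relative_change(
                            induced.values, times, config.baseline_window
                        )
                        window = windows["alpha"]
                        valid = induced.valid_mask()
                    else:
                        vals = evoked.values
                        window = windows["pretarget"]
                        valid = evoked.valid_mask()
                    maps[(band_name, cond)].append(
                        _window_map(vals, times, window, step, valid)
                    )
            for cond in config.corr_conditions:
                sub = epochs.select(cond)
                for band in target_bands:
                    cm = seed_correlation_map(
                        sub, seed_spec, band, windows["pretarget"]
                    )
                    cm.participant_id = epochs.participant_id
                    cm.condition = cond
                    corr_maps[(band.name, cond)].append(cm)
                    high, low = median_split_contrast(
                        sub, seed_spec, band, windows["pretarget"],
                        target_channels=seed_channels,
                    )
                    split_rows.append(
                        {
                            "participant": epochs.participant_id,
                            "condition": cond,
                            "band": band.name,
                            "high_mean": high,
                            "low_mean": low,
                        }
                    )

    # ---- condition contrasts ----------------------------------------------
    cluster_tables = {}
    significant = {}
    with _stage("condition contrasts"):
        rng = np.random.default_rng(stat_seed)
        for band_name, _ in contrast_bands:
            a = np.stack(maps[(band_name, "auditory_cue")])
            b = np.stack(maps[(band_name, "visual_cue")])
            res = permutation_cluster_test(
                a, b, graph, channels=list(layout.channels),
                n_perm=config.n_perm, criterion=config.criterion,
                alpha_pointwise=config.alpha_pointwise, rng=rng,
            )
            name = f"{band_name}_contrast"
            cluster_tables[name] = res.to_table()
            significant[name] = bool(res.significant)

    # ---- seed correlations and follow-ups ----------------------------------
    corr_rows = []
    with _stage("seed correlations"):
        splits = pd.DataFrame(split_rows)
        k = 0
        for band in target_bands:
            for cond in config.corr_conditions:
                cms = corr_maps[(band.name, cond)]
                res = group_corr_cluster_test(
                    cms, graph, n_perm=config.n_perm, criterion=config.criterion,
                    alpha_pointwise=config.alpha_pointwise, rng=np.random.default_rng(corr_seeds[k % len(corr_seeds)]),
                )
                k += 1
                name = f"corr_{band.name}_{cond}"
                cluster_tables[name] = res.to_table()
                significant[name] = bool(res.significant)
                # participant-level follow-ups over the cluster channels
                # (seed/posterior set when no significant cluster exists)
                if res.significant:
                    ch_idx = sorted(res.significant[0].channel_indices)
                else:
                    ch_idx = [layout.channels.index(c) for c in seed_channels]
                zmat = np.stack([m.z for m in cms])
                mean_z = np.nanmean(zmat[:, ch_idx], axis=1)
                mean_z = exclude_outliers(mean_z, k=2.0)
                t, df, p = one_sample_t(mean_z)
                bf = jzs_bf10(t, len(mean_z))
                sp = splits[(splits["band"] == band.name) & (splits["condition"] == cond)]
                split_diff = (sp["high_mean"] - sp["low_mean"]).to_numpy()
                split_diff = exclude_outliers(split_diff, k=2.0)
                ts, dfs, ps = one_sample_t(split_diff)
                bfs = jzs_bf10(ts, len(split_diff))
                corr_rows.append(
                    {
                        "band": band.name,
                        "condition": cond,
                        "cluster_p": res.clusters[0].p if res.clusters else np.nan,
                        "cluster_significant": bool(res.significant),
                        "mean_z": float(np.mean(mean_z)),
                        "t": t, "df": df, "p": p, "bf10": bf,
                        "split_t": ts, "split_df": dfs, "split_p": ps,
                        "split_bf10": bfs,
                        "n_participants": len(mean_z),
                    }
                )
        # interaction between the two correlation conditions, per band
        if len(config.corr_conditions) == 2:
            ca, cb = config.corr_conditions
            for band in target_bands:
                res = interaction_test(
                    corr_maps[(band.name, ca)], corr_maps[(band.name, cb)],
                    graph, n_perm=config.n_perm, criterion=config.criterion,
                    alpha_pointwise=config.alpha_pointwise,
                    rng=np.random.default_rng(corr_seeds[-1]),
                )
                name = f"corr_interaction_{band.name}"
                cluster_tables[name] = res.to_table()
                significant[name] = bool(res.significant)

    # ---- behaviour ---------------------------------------------------------
    with _stage("behaviour"):
        tables = []
        for epochs in cohort:
            if epochs.behavior is None:
                continue
            t = epochs.behavior.copy()
            t["condition"] = epochs.condition
            t["participant"] = epochs.participant_id
            tables.append(t)
        if tables:
            big = pd.concat(tables, ignore_index=True)
            behavior_summary = beh.condition_summary(big)
            eff_rows = []
            for modality in ("auditory", "visual"):
                row = {"modality": modality}
                try:
                    row["attentional_benefit_ms"] = beh.attentional_benefit(big, modality)
                except ValueError:
                    row["attentional_benefit_ms"] = np.nan
                try:
                    d_acc, d_rt = beh.distractor_cost(big, modality)
                except ValueError:
                    d_acc = d_rt = np.nan
                row["distractor_cost_acc_pct"] = d_acc
                row["distractor_cost_rt_ms"] = d_rt
                eff_rows.append(row)
            behavior_effects = pd.DataFrame(eff_rows)
        else:
            behavior_summary = pd.DataFrame()
            behavior_effects = pd.DataFrame()

    provenance = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_participants": len(cohort),
        "n_perm": config.n_perm,
        "windows": {k: list(v) for k, v in windows.items()},
        "version": 1,
    }
    return AnalysisReport(
        cluster_tables=cluster_tables,
        correlation_summary=pd.DataFrame(corr_rows),
        behavior_summary=behavior_summary,
        behavior_effects=behavior_effects,
        significant=significant,
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# report stage
# ---------------------------------------------------------------------------

def run_report(report: AnalysisReport, outdir) -> Path:
    """Render the report: machine-readable JSON + TSV tables + text summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=1, default=str)
    for name, table in report.cluster_tables.items():
        table.to_csv(outdir / f"clusters_{name}.tsv", sep="\t", index=False)
    report.correlation_summary.to_csv(outdir / "correlations.tsv", sep="\t", index=False)
    report.behavior_summary.to_csv(outdir / "behavior.tsv", sep="\t", index=False)
    report.behavior_effects.to_csv(outdir / "behavior_effects.tsv", sep="\t", index=False)

    lines = [f"analysis report (config {report.provenance['config_hash']}, "
             f"seed {report.provenance['seed']})", ""]
    for name, table in report.cluster_tables.items():
        sig = table[table["significant"]] if len(table) else table
        if len(sig):
            for _, row in sig.iterrows():
                lines.append(
                    f"{name}: significant {row['sign']} cluster, mass {row['mass']:.1f}, "
                    f"p = {row['p']:.4f}, {row['n_points']} points"
                )
        else:
            lines.append(f"{name}: no significant clusters")
    lines.append("")
    for _, row in report.correlation_summary.iterrows():
        lines.append(
            f"corr {row['band']} / {row['condition']}: mean z = {row['mean_z']:.3f}, "
            f"t({row['df']}) = {row['t']:.2f}, p = {row['p']:.4f}, BF10 = {row['bf10']:.2f}"
        )
    path = outdir / "summary.txt"
    path.write_text("\n".join(lines) + "\n")
    return path


def read_report(path) -> dict:
    """Read back the machine-readable report (inverse of :func:`run_report`)."""
    with open(Path(path) / "report.json") as fh:
        return json.load(fh)
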