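"""Monte-Carlo calibration and power/recovery studies.

This module is the package's "calibrate" harness.  It answers three
questions about the statistical machinery:

* **Null calibration** -- does the cluster permutation test control the
  family-wise error rate at its nominal 5% when there is no effect?  The
  paired-test calibration draws participant-level condition maps from a
  spatio-temporally smoothed Gaussian null (the error rate of the sign-flip
  permutation scheme is a property of the map-level exchangeability, so no
  waveform synthesis is needed); the correlation-map calibration draws
  per-trial amplitudes from the generator's copula layer at zero coupling
  plus envelope measurement noise.
* **Power / recovery** -- with the generator's default effect sizes
  (posterior alpha gain 1.3 and pre-target tag gain 1.2 for auditory cues),
  how often does the full waveform pipeline (synthesis -> filtering ->
  envelopes -> cluster test) detect each injected contrast, and does the
  44 Hz control band stay silent?
* **Coupling recovery** -- does the seed-correlation pipeline recover an
  increasing Fisher-z with increasing injected alpha-tag coupling, and
  detect the coupling cluster reliably at rho >= 0.4?

Study sizes (reduced sampling rate 160 Hz, epochs -1.2..3.5 s, trial counts
below) keep a full run in the tens of minutes on one core; they are part of
the package's fixed study design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cluster import one_sample_cluster_test, permutation_cluster_test
from .core import band_preset, build_neighbor_graph, posterior_channels, standard_layout_64
from .simulate import SimulationConfig, component_topographies, draw_trial_latents, generate_participant
from .spectral import baseline_relative_change, design_blackman_sinc_bandpass, multiband_analytic
from .trialcorr import spearman_z_columns

__all__ = [
    "NullCalibrationResult",
    "paired_null_calibration",
    "correlation_null_calibration",
    "power_study",
    "coupling_study",
    "mc_simulation_config",
]

# fixed study-design constants
MC_SFREQ = 160.0
MC_EPOCH = (-1.2, 3.5)
MC_BASELINE = (-0.7, -0.2)
MC_ALPHA_WINDOW = (1.0, 3.0)  # last 2 s before target
MC_PRETARGET_WINDOW = (2.5, 3.0)  # last 500 ms
MC_SEED_WINDOW = (2.0, 3.0)
MC_NEIGHBOR_DIST = 0.33
MC_STAT_STEP_S = 0.05


def _seeds(master: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def mc_simulation_config(
    seed: int,
    coupling_rho: float = 0.4,
    conditions=("auditory_cue", "visual_cue"),
    n_trials_per_condition: int = 16,
) -> SimulationConfig:
    """Reduced-size simulation config used by the Monte-Carlo studies."""
    return SimulationConfig(
        n_participants=20,
        n_trials_per_condition=n_trials_per_condition,
        conditions=conditions,
        sfreq=MC_SFREQ,
        epoch_span=MC_EPOCH,
        coupling_rho=coupling_rho,
        seed=seed,
    )


@dataclass
class NullCalibrationResult:
    """Family-wise error of a cluster test over simulated null datasets."""

    n_datasets: int
    n_false_positives: int
    flags: list = field(default_factory=list)

    @property
    def fwer(self) -> float:
        return self.n_false_positives / self.n_datasets


# ---------------------------------------------------------------------------
# null calibrations
# ---------------------------------------------------------------------------

def _smooth_maps(maps: np.ndarray, adj: np.ndarray) -> np.ndarray:
    """Mild spatial (neighbour average) and temporal (3-sample) smoothing."""
    deg = adj.sum(axis=1, keepdims=True)
    spatial = maps + 0.5 * np.einsum("pct,cd->pdt", maps, adj.T / np.maximum(deg, 1))
    out = spatial.copy()
    out[..., 1:] += spatial[..., :-1]
    out[..., :-1] += spatial[..., 1:]
    return out / 3.0


def paired_null_calibration(
    seed: int,
    n_datasets: int = 200,
    n_participants: int = 20,
    n_times: int = 20,
    n_trials_per_condition: int = 100,
    n_perm: int = 200,
) -> NullCalibrationResult:
    """FWER of the paired cluster permutation test under the null.

    Each dataset holds two condition maps per participant, drawn as
    trial-averaged Gaussian noise (variance 1/n_trials) with smooth spatial
    and temporal correlation, and no condition effect.
    """
    layout = standard_layout_64()
    graph = build_neighbor_graph(layout, MC_NEIGHBOR_DIST)
    adj = graph.adjacency_matrix(layout.channels).astype(float)
    n_ch = len(layout.channels)
    sd = 1.0 / np.sqrt(n_trials_per_condition)
    hits = 0
    for s in _seeds(seed, n_datasets):
        rng = np.random.default_rng(s)
        a = _smooth_maps(rng.standard_normal((n_participants, n_ch, n_times)) * sd, adj)
        b = _smooth_maps(rng.standard_normal((n_participants, n_ch, n_times)) * sd, adj)
        res = permutation_cluster_test(
            a, b, graph, channels=layout.channels, n_perm=n_perm, rng=rng
        )
        hits += bool(res.significant)
    return NullCalibrationResult(n_datasets, hits)


def correlation_null_calibration(
    seed: int,
    n_datasets: int = 200,
    n_participants: int = 20,
    n_trials: int = 100,
    n_perm: int = 200,
    measurement_noise: float = 0.3,
) -> NullCalibrationResult:
    """FWER of the one-sample correlation-cluster test at zero coupling.

    Per participant, per-trial amplitude latents are drawn from the
    generator's copula at ``coupling_rho = 0``; the seed read-out and the
    per-channel target read-outs add independent envelope measurement noise
    on top of the component topographies, mimicking what the envelope
    pipeline would deliver, at a fraction of its cost.
    """
    layout = standard_layout_64()
    graph = build_neighbor_graph(layout, MC_NEIGHBOR_DIST)
    topo = component_topographies(layout)
    cfg = mc_simulation_config(0, coupling_rho=0.0)
    n_ch = len(layout.channels)
    hits = 0
    for s in _seeds(seed, n_datasets):
        rng = np.random.default_rng(s)
        zmaps = np.empty((n_participants, n_ch))
        for p in range(n_participants):
            lat = draw_trial_latents(cfg, n_trials, rng)
            seed_vals = lat["amp_alpha"].to_numpy() + measurement_noise * rng.standard_normal(n_trials)
            targets = (
                lat["amp_visual"].to_numpy()[:, None] * topo.visual[None, :]
                + measurement_noise * rng.standard_normal((n_trials, n_ch))
            )
            zmaps[p], _ = spearman_z_columns(seed_vals, targets)
        res = one_sample_cluster_test(
            zmaps, graph, channels=layout.channels, n_perm=n_perm, rng=rng
        )
        hits += bool(res.significant)
    return NullCalibrationResult(n_datasets, hits)


# ---------------------------------------------------------------------------
# power / recovery with the full waveform pipeline
# ---------------------------------------------------------------------------

def _window_idx(times: np.ndarray, window, step: int) -> np.ndarray:
    mask = (times >= window[0]) & (times <= window[1])
    return np.flatnonzero(mask)[::step]


@dataclass
class PowerStudyResult:
    n_sims: int
    alpha_detections: int
    tag36_detections: int
    tag40_detections: int
    control44_positives: int

    def rates(self) -> dict:
        n = self.n_sims
        return {
            "alpha": self.alpha_detections / n,
            "tag36": self.tag36_detections / n,
            "tag40": self.tag40_detections / n,
            "control44": self.control44_positives / n,
        }


def power_study(seed: int, n_sims: int = 50, n_perm: int = 200) -> PowerStudyResult:
    """Detection rate of the injected condition effects, full pipeline.

    Each simulation draws a 20-participant cohort at the generator defaults
    (auditory-cue alpha gain 1.3 over posterior channels, pre-target tag
    gain 1.2), runs the induced-alpha and evoked 36/40 Hz contrasts, and
    counts a detection when a significant positive cluster (auditory >
    visual) emerges.  The 44 Hz band, which contains no injected component,
    is analysed identically as the bleed-over control.
    """
    layout = standard_layout_64()
    graph = build_neighbor_graph(layout, MC_NEIGHBOR_DIST)
    step = max(int(round(MC_STAT_STEP_S * MC_SFREQ)), 1)
    bands = [
        ("alpha", band_preset("alpha"), "induced", MC_ALPHA_WINDOW),
        ("tag36", band_preset("visual_tag"), "evoked", MC_PRETARGET_WINDOW),
        ("tag40", band_preset("auditory_tag"), "evoked", MC_PRETARGET_WINDOW),
        ("control44", band_preset("control_44"), "evoked", MC_PRETARGET_WINDOW),
    ]
    kernels = [design_blackman_sinc_bandpass(b, MC_SFREQ) for _, b, _, _ in bands]
    counts = {name: 0 for name, *_ in bands}
    for s in _seeds(seed, n_sims):
        cfg = mc_simulation_config(s)
        maps = {name: {"auditory_cue": [], "visual_cue": []} for name, *_ in bands}
        for p, pseed in enumerate(_seeds(cfg.seed, cfg.n_participants)):
            epochs, _ = generate_participant(cfg, pseed, participant_id=f"p{p:02d}", layout=layout)
            times = epochs.times
            bmask = epochs.time_mask(*MC_BASELINE)
            analytic = multiband_analytic(epochs.data, kernels)
            cond_arr = np.asarray(epochs.condition)
            for (name, band, path, window), kern in zip(bands, kernels):
                y = analytic[band.name]
                idx = _window_idx(times, window, step)
                for cond in ("auditory_cue", "visual_cue"):
                    yc = y[cond_arr == cond]
                    if path == "induced":
                        env = np.abs(yc).mean(axis=0)
                        vals = baseline_relative_change(env, times, MC_BASELINE)
                    else:
                        base = yc.real[..., bmask].mean(axis=-1, keepdims=True)
                        vals = np.abs((yc - base).mean(axis=0))
                    maps[name][cond].append(vals[:, idx])
        rng = np.random.default_rng(s)
        for name, *_ in bands:
            res = permutation_cluster_test(
                np.stack(maps[name]["auditory_cue"]),
                np.stack(maps[name]["visual_cue"]),
                graph, channels=layout.channels, n_perm=n_perm, rng=rng,
            )
            if name == "control44":
                counts[name] += bool(res.significant)  # any cluster is a false positive
            else:
                counts[name] += any(c.sign > 0 for c in res.significant)
    return PowerStudyResult(
        n_sims=n_sims,
        alpha_detections=counts["alpha"],
        tag36_detections=counts["tag36"],
        tag40_detections=counts["tag40"],
        control44_positives=counts["control44"],
    )


@dataclass
class CouplingStudyResult:
    rhos: list
    mean_z: dict  # rho -> mean recovered Fisher-z over posterior channels
    detection_rate_at: dict  # rho -> fraction of sims with significant + cluster
    n_sims: dict


def _coupling_sim(cohort_seed: int, rho: float, layout, graph, seed_channels, n_perm: int):
    """One coupling cohort: returns (mean posterior z, significant positive?)."""
    cfg = mc_simulation_config(
        cohort_seed, coupling_rho=rho, conditions=("visual_cue",),
        n_trials_per_condition=40,
    )
    kernels = [
        design_blackman_sinc_bandpass(band_preset("alpha"), MC_SFREQ),
        design_blackman_sinc_bandpass(band_preset("visual_tag"), MC_SFREQ),
    ]
    post_idx = [layout.channels.index(c) for c in seed_channels]
    zmaps = []
    for p, pseed in enumerate(_seeds(cfg.seed, cfg.n_participants)):
        epochs, _ = generate_participant(cfg, pseed, participant_id=f"p{p:02d}", layout=layout)
        times = epochs.times
        analytic = multiband_analytic(epochs.data, kernels)
        seed_idx = _window_idx(times, MC_SEED_WINDOW, 1)
        targ_idx = _window_idx(times, MC_PRETARGET_WINDOW, 1)
        seed_vals = (
            np.abs(analytic["alpha"][:, post_idx][..., seed_idx]).mean(axis=(1, 2))
        )
        targets = np.abs(analytic["visual_tag"][..., targ_idx]).mean(axis=-1)
        z, _ = spearman_z_columns(seed_vals, targets)
        zmaps.append(z)
    zmaps = np.nan_to_num(np.stack(zmaps), nan=0.0)
    rng = np.random.default_rng(cohort_seed)
    res = one_sample_cluster_test(
        zmaps, graph, channels=layout.channels, n_perm=n_perm, rng=rng
    )
    mean_post_z = float(zmaps[:, post_idx].mean())
    detected = any(c.sign > 0 for c in res.significant)
    return mean_post_z, detected


def coupling_study(
    seed: int,
    rhos=(0.0, 0.2, 0.4, 0.6),
    n_sims_primary: int = 50,
    primary_rho: float = 0.4,
    n_sims_grid: int = 12,
    n_perm: int = 200,
) -> CouplingStudyResult:
    """Coupling recovery across injected rank correlations.

    ``primary_rho`` gets ``n_sims_primary`` simulations (detection-rate
    estimate); the remaining grid points get ``n_sims_grid`` each, enough to
    order the recovered mean Fisher-z across rho values.
    """
    layout = standard_layout_64()
    graph = build_neighbor_graph(layout, MC_NEIGHBOR_DIST)
    seed_channels = posterior_channels(layout)
    mean_z: dict = {}
    detect: dict = {}
    n_used: dict = {}
    master = _seeds(seed, len(rhos))
    for rho, rho_seed in zip(rhos, master):
        n = n_sims_primary if rho == primary_rho else n_sims_grid
        zs, dets = [], []
        for s in _seeds(rho_seed, n):
            z, d = _coupling_sim(s, rho, layout, graph, seed_channels, n_perm)
            zs.append(z)
            dets.append(d)
        mean_z[rho] = float(np.mean(zs))
        detect[rho] = float(np.mean(dets))
        n_used[rho] = n
    return CouplingStudyResult(
        rhos=list(rhos), mean_z=mean_z, detection_rate_at=detect, n_sims=n_used
    )
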