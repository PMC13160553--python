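"""Synthetic multi-participant cohorts with known ground truth.

The generator emulates the statistical structure the sensor-level analysis
assumes, without any forward head modelling:

* 1/f ("pink") background noise, independent per channel;
* a posterior alpha oscillation whose amplitude is larger when an auditory
  target is cued, phase-randomised per trial (induced activity);
* 36 Hz (visual) and 40 Hz (auditory) steady-state components active during
  the cue-to-target interval with raised-cosine on/off ramps, phase-locked
  across trials (evoked activity), with a condition-dependent amplitude gain
  over the final pre-target window;
* a 4 Hz intermodulation component with its own topography, also phase-locked
  and pre-target modulated;
* per-trial latent amplitudes coupled through a Gaussian copula so the
  Spearman correlation between alpha and tag amplitudes equals
  ``coupling_rho`` in expectation, whatever the (log-normal) marginals;
* reaction times negatively coupled to the pre-target latent, plus
  per-condition offsets (cued faster than non-specific) and a distractor cost.

Every output is a pure function of ``(config, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .core import CONDITIONS, EpochSet, SensorLayout, standard_layout_64

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_pink_noise",
    "draw_trial_latents",
    "synthesize_trial",
    "generate_participant",
    "generate_cohort",
    "spearman_to_pearson",
]


def spearman_to_pearson(rho_s: float) -> float:
    """Pearson correlation of a bivariate Gaussian with Spearman ``rho_s``.

    Inverts ``rho_s = (6 / pi) * arcsin(r / 2)``.
    """
    return 2.0 * np.sin(np.pi * rho_s / 6.0)


def _cond_map(value, default: float) -> dict:
    out = {c: default for c in CONDITIONS}
    if value:
        out.update(value)
    return out


@dataclass
class SimulationConfig:
    """All generative parameters of the synthetic cohort.

    Amplitudes are in units of the background-noise standard deviation
    (``noise_scale=1`` gives unit broadband noise per channel).  Defaults
    realise the qualitative effect pattern the analysis is designed to
    detect at n=20 participants: higher posterior alpha and higher pre-target
    tag envelopes under auditory cues, and a positive trial-by-trial
    alpha-tag coupling.
    """

    n_participants: int = 20
    n_trials_per_condition: int = 50
    conditions: Sequence[str] = CONDITIONS
    sfreq: float = 500.0
    epoch_span: tuple[float, float] = (-1.5, 4.5)

    # tagged components
    tag_visual_hz: float = 36.0
    tag_auditory_hz: float = 40.0
    intermod_hz: float = 4.0
    tag_onset: float = 0.0
    tag_offset: float = 3.0
    tag_ramp: float = 0.4  # raised-cosine on/off ramp (s); off-ramp starts at tag_offset
    pretarget_window: float = 0.5  # final pre-target gain window (s)

    # oscillation amplitudes (units of noise sd) and topography widths
    alpha_center_hz: float = 10.0
    alpha_bandwidth: float = 2.0
    alpha_amp: float = 1.5
    tag_visual_amp: float = 0.7
    tag_auditory_amp: float = 0.7
    intermod_amp: float = 0.45

    # per-condition gains
    alpha_gain: dict = field(default_factory=dict)
    tag_pretarget_gain: dict = field(default_factory=dict)
    alpha_mod_onset: float = 0.5  # s after cue: condition gain ramps in
    alpha_mod_rise: float = 0.5  # s: smoothstep duration

    # latent structure
    coupling_rho: float = 0.4
    latent_sigma: float = 0.35  # log-normal sigma of amplitude latents
    im_tag_corr: float = 0.5  # Pearson corr of intermod latent with tag latent

    # noise
    noise_exponent: float = 1.0
    noise_scale: float = 1.0

    # behaviour
    rt_base_ms: float = 550.0
    rt_slope_ms: float = 40.0  # ms per unit of the standardised latent
    rt_sd_ms: float = 80.0
    rt_condition_offset: dict = field(default_factory=dict)
    accuracy: dict = field(default_factory=dict)
    distractor_rt_cost_ms: float = 35.0
    distractor_accuracy_drop: float = 0.08

    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self) -> None:
        self.conditions = tuple(self.conditions)
        self.alpha_gain = _cond_map(
            self.alpha_gain or {"auditory_cue": 1.3, "visual_cue": 1.0, "nonspecific_cue": 1.15},
            1.0,
        )
        self.tag_pretarget_gain = _cond_map(
            self.tag_pretarget_gain
            or {"auditory_cue": 1.2, "visual_cue": 1.0, "nonspecific_cue": 1.1},
            1.0,
        )
        self.rt_condition_offset = _cond_map(
            self.rt_condition_offset
            or {"auditory_cue": -30.0, "visual_cue": -45.0, "nonspecific_cue": 0.0},
            0.0,
        )
        self.accuracy = _cond_map(
            self.accuracy
            or {"auditory_cue": 0.75, "visual_cue": 0.90, "nonspecific_cue": 0.82},
            0.85,
        )

    def validate(self) -> None:
        if self.n_participants <= 0 or self.n_trials_per_condition <= 0:
            raise ValueError("participant and trial counts must be positive")
        if not (0 <= abs(self.coupling_rho) < 1):
            raise ValueError("coupling_rho must satisfy 0 <= |rho| < 1")
        nyq = self.sfreq / 2.0
        for f in (self.tag_visual_hz, self.tag_auditory_hz, self.alpha_center_hz):
            if f >= nyq:
                raise ValueError(f"component frequency {f} Hz at/above Nyquist {nyq}")
        t0, t1 = self.epoch_span
        if not (t0 < self.tag_onset < self.tag_offset <= t1 - self.tag_ramp):
            raise ValueError("tag window (including the off-ramp) must lie inside the epoch span")
        unknown = set(self.conditions) - set(CONDITIONS)
        if unknown:
            raise ValueError(f"unknown condition labels: {sorted(unknown)}")
        for name, m in (
            ("alpha_gain", self.alpha_gain),
            ("tag_pretarget_gain", self.tag_pretarget_gain),
            ("accuracy", self.accuracy),
        ):
            missing = set(self.conditions) - set(m)
            if missing:
                raise ValueError(f"{name} missing conditions: {sorted(missing)}")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")

    @property
    def times(self) -> np.ndarray:
        t0, t1 = self.epoch_span
        n = int(round((t1 - t0) * self.sfreq))
        return t0 + np.arange(n) / self.sfreq

    # -- plain-text key=value configuration file ---------------------
    @classmethod
    def from_file(cls, path) -> "SimulationConfig":
        """Read a config from a YAML/key-value file; unknown keys are errors."""
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise KeyError(f"unknown simulation config keys: {sorted(unknown)}")
        if "epoch_span" in raw:
            raw["epoch_span"] = tuple(raw["epoch_span"])
        return cls(**raw)

    def to_file(self, path) -> None:
        import yaml

        d = asdict(self)
        d["conditions"] = list(self.conditions)
        d["epoch_span"] = list(self.epoch_span)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


@dataclass
class GroundTruth:
    """Injected truth for one participant: per-trial latents and behaviour.

    ``table`` has one row per generated trial with the latent amplitude draws
    (alpha, visual tag, auditory tag, intermodulation), the condition and the
    behavioural outcome.  ``coupling_rho_realised`` is the sample Spearman
    correlation between the alpha and tag latents actually drawn.
    """

    table: pd.DataFrame
    alpha_gain: dict
    tag_pretarget_gain: dict
    coupling_rho_target: float
    coupling_rho_realised: float
    participant_id: str = "p00"

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# component generators
# ---------------------------------------------------------------------------

def generate_pink_noise(
    n_samples: int,
    exponent: float = 1.0,
    scale: float = 1.0,
    rng: np.random.Generator | None = None,
    shape: tuple = (),
) -> np.ndarray:
    """Zero-mean noise with power spectrum ~ 1/f**exponent.

    Shaped in the frequency domain from white Gaussian noise; each output
    series is rescaled to standard deviation ``scale``.  ``shape`` prepends
    extra axes (e.g. ``(n_trials, n_channels)``).
    """
    if n_samples <= 1:
        raise ValueError("n_samples must be > 1")
    if exponent < 0:
        raise ValueError("exponent must be >= 0")
    if scale < 0:
        raise ValueError("scale must be >= 0")
    rng = rng or np.random.default_rng()
    white = rng.standard_normal(tuple(shape) + (n_samples,))
    if scale == 0:
        return np.zeros_like(white)
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n_samples)
    gain = np.zeros_like(f)
    gain[1:] = f[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * gain, n=n_samples, axis=-1)
    x -= x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x * (scale / sd)


def _gauss_topography(layout: SensorLayout, center: tuple[float, float], width: float) -> np.ndarray:
    d2 = ((layout.pos2d - np.asarray(center)) ** 2).sum(axis=1)
    w = np.exp(-d2 / (2.0 * width**2))
    return w / w.max()


@dataclass
class _Topographies:
    alpha: np.ndarray
    visual: np.ndarray
    auditory: np.ndarray
    intermod: np.ndarray


def component_topographies(layout: SensorLayout) -> _Topographies:
    """Smooth parametric spatial weight maps for each injected component.

    Alpha and the visual tag are occipital, the auditory tag fronto-central,
    the intermodulation component broad and centro-posterior.
    """
    return _Topographies(
        alpha=_gauss_topography(layout, (0.0, -0.82), 0.38),
        visual=_gauss_topography(layout, (0.0, -0.85), 0.35),
        auditory=_gauss_topography(layout, (0.0, 0.18), 0.45),
        intermod=_gauss_topography(layout, (0.1, -0.30), 0.60),
    )


def _smoothstep(t: np.ndarray, t0: float, t1: float) -> np.ndarray:
    """Raised-cosine step from 0 (t<=t0) to 1 (t>=t1)."""
    if t1 <= t0:
        return (t >= t0).astype(float)
    u = np.clip((t - t0) / (t1 - t0), 0.0, 1.0)
    return 0.5 * (1.0 - np.cos(np.pi * u))


def _tag_window(times: np.ndarray, cfg: SimulationConfig) -> np.ndarray:
    # tagging runs at full amplitude until target onset (tag_offset) and
    # ramps out just after it; a sharp offset would smear phase-locked
    # broadband splatter into neighbouring analysis bands inside the
    # pre-target window
    on = _smoothstep(times, cfg.tag_onset, cfg.tag_onset + cfg.tag_ramp)
    off = 1.0 - _smoothstep(times, cfg.tag_offset, cfg.tag_offset + cfg.tag_ramp)
    return on * off


def _pretarget_profile(times: np.ndarray, cfg: SimulationConfig, gain: float) -> np.ndarray:
    """1 outside, ``gain`` inside the final pre-target window.

    The transition is a 300 ms raised cosine ending at the window start,
    slow enough that its amplitude-modulation sidebands stay well below the
    4 Hz separation of the tagged frequencies.
    """
    t0 = cfg.tag_offset - cfg.pretarget_window
    return 1.0 + (gain - 1.0) * _smoothstep(times, t0 - 0.3, t0)


def _alpha_profile(times: np.ndarray, cfg: SimulationConfig, gain: float) -> np.ndarray:
    """Condition gain ramping in during the cue-to-target interval."""
    rise = _smoothstep(times, cfg.alpha_mod_onset, cfg.alpha_mod_onset + cfg.alpha_mod_rise)
    fall = 1.0 - _smoothstep(times, cfg.tag_offset, cfg.tag_offset + 0.3)
    return 1.0 + (gain - 1.0) * rise * fall


def draw_trial_latents(
    cfg: SimulationConfig, n_trials: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Per-trial latent amplitudes from the rank-coupled (copula) model.

    ``z_alpha`` and ``z_tag`` are bivariate standard normal with Pearson
    correlation chosen so their Spearman correlation is ``coupling_rho``;
    both tag components share ``z_tag``; the intermodulation latent is
    correlated with ``z_tag`` at ``im_tag_corr``.  Amplitude latents are
    ``exp(latent_sigma * z)`` (unit median, log-normal), so any monotone
    envelope read-out preserves the injected rank correlation.
    """
    r = spearman_to_pearson(cfg.coupling_rho)
    z_alpha = rng.standard_normal(n_trials)
    z_tag = r * z_alpha + np.sqrt(max(1.0 - r * r, 0.0)) * rng.standard_normal(n_trials)
    c = cfg.im_tag_corr
    z_im = c * z_tag + np.sqrt(max(1.0 - c * c, 0.0)) * rng.standard_normal(n_trials)
    s = cfg.latent_sigma
    return pd.DataFrame(
        {
            "z_alpha": z_alpha,
            "z_tag": z_tag,
            "z_im": z_im,
            "amp_alpha": np.exp(s * z_alpha),
            "amp_visual": np.exp(s * z_tag),
            "amp_auditory": np.exp(s * z_tag),
            "amp_im": np.exp(s * z_im),
        }
    )


def synthesize_trial(
    cfg: SimulationConfig,
    condition: str,
    latents: dict,
    rng: np.random.Generator,
    layout: SensorLayout | None = None,
    topo: _Topographies | None = None,
) -> np.ndarray:
    """One trial as a ``channels x samples`` array.

    ``latents`` supplies the per-trial amplitude draws (keys ``amp_alpha``,
    ``amp_visual``, ``amp_auditory``, ``amp_im``) and the trial-invariant tag
    phases (``phase_visual``, ``phase_auditory``, ``phase_im``; default 0 =
    phase-locked across trials).  Alpha phase and frequency jitter are drawn
    from ``rng`` per trial.
    """
    if condition not in cfg.conditions:
        raise ValueError(f"condition {condition!r} not in configured set {cfg.conditions}")
    if not (cfg.epoch_span[0] < cfg.tag_onset < cfg.tag_offset <= cfg.epoch_span[1]):
        raise ValueError("tag window outside epoch span")
    layout = layout or standard_layout_64()
    topo = topo or component_topographies(layout)
    times = cfg.times
    n_ch = len(layout.channels)

    noise = generate_pink_noise(
        len(times), cfg.noise_exponent, cfg.noise_scale, rng, shape=(n_ch,)
    )
    x = noise

    # induced alpha: common phase across channels, random per trial
    f_alpha = cfg.alpha_center_hz + cfg.alpha_bandwidth * (rng.uniform() - 0.5)
    phase = rng.uniform(0, 2 * np.pi)
    gain = cfg.alpha_gain[condition]
    alpha_wave = np.sin(2 * np.pi * f_alpha * times + phase)
    alpha_env = cfg.alpha_amp * latents["amp_alpha"] * _alpha_profile(times, cfg, gain)
    x = x + topo.alpha[:, None] * (alpha_env * alpha_wave)[None, :]

    # phase-locked tagged components, active in the cue-to-target interval
    window = _tag_window(times, cfg)
    pre = _pretarget_profile(times, cfg, cfg.tag_pretarget_gain[condition])
    for freq, amp, key, topo_w, ph_key in (
        (cfg.tag_visual_hz, cfg.tag_visual_amp, "amp_visual", topo.visual, "phase_visual"),
        (cfg.tag_auditory_hz, cfg.tag_auditory_amp, "amp_auditory", topo.auditory, "phase_auditory"),
        (cfg.intermod_hz, cfg.intermod_amp, "amp_im", topo.intermod, "phase_im"),
    ):
        wave = np.sin(2 * np.pi * freq * times + latents.get(ph_key, 0.0))
        env = amp * latents[key] * window * pre
        x = x + topo_w[:, None] * (env * wave)[None, :]
    return x.astype(cfg.dtype)


def _behaviour_row(
    cfg: SimulationConfig, condition: str, z_im: float, rng: np.random.Generator
) -> tuple[float, bool, bool]:
    distractor = bool(rng.uniform() < 0.5) if condition != "nonspecific_cue" else False
    rt = (
        cfg.rt_base_ms
        + cfg.rt_condition_offset[condition]
        - cfg.rt_slope_ms * z_im
        + cfg.rt_sd_ms * rng.standard_normal()
        + (cfg.distractor_rt_cost_ms if distractor else 0.0)
    )
    p_correct = cfg.accuracy[condition] - (cfg.distractor_accuracy_drop if distractor else 0.0)
    correct = bool(rng.uniform() < p_correct)
    return max(rt, 120.0), correct, distractor


def generate_participant(
    cfg: SimulationConfig,
    participant_seed: int,
    participant_id: str = "p00",
    layout: SensorLayout | None = None,
) -> tuple[EpochSet, GroundTruth]:
    """Generate one participant's :class:`EpochSet` and its ground truth."""
    cfg.validate()
    rng = np.random.default_rng(participant_seed)
    layout = layout or standard_layout_64()
    topo = component_topographies(layout)
    times = cfg.times
    n_ch = len(layout.channels)
    n_cond = len(cfg.conditions)
    n_trials = cfg.n_trials_per_condition * n_cond

    # tag phases are fixed across trials (phase-locked); one draw per participant
    phases = {
        "phase_visual": rng.uniform(0, 2 * np.pi),
        "phase_auditory": rng.uniform(0, 2 * np.pi),
        "phase_im": rng.uniform(0, 2 * np.pi),
    }

    rows = []
    data = np.empty((n_trials, n_ch, len(times)), dtype=cfg.dtype)
    conditions: list[str] = []
    i = 0
    for cond in cfg.conditions:
        lat = draw_trial_latents(cfg, cfg.n_trials_per_condition, rng)
        for k in range(cfg.n_trials_per_condition):
            trial_lat = dict(lat.iloc[k]) | phases
            data[i] = synthesize_trial(cfg, cond, trial_lat, rng, layout, topo)
            rt, correct, distractor = _behaviour_row(cfg, cond, lat["z_im"].iloc[k], rng)
            rows.append(
                {
                    "trial": i,
                    "condition": cond,
                    **{c: lat[c].iloc[k] for c in lat.columns},
                    "rt_ms": rt,
                    "correct": correct,
                    "distractor_present": distractor,
                }
            )
            conditions.append(cond)
            i += 1

    truth_table = pd.DataFrame(rows)
    # realised rank coupling between the alpha and tag latents
    realised = float(
        truth_table[["amp_alpha", "amp_visual"]].corr(method="spearman").iloc[0, 1]
    )
    behavior = truth_table[["rt_ms", "correct", "distractor_present"]].copy()
    epochs = EpochSet(
        data=data,
        sfreq=cfg.sfreq,
        times=times,
        channels=list(layout.channels),
        condition=conditions,
        participant_id=participant_id,
        behavior=behavior,
    )
    truth = GroundTruth(
        table=truth_table,
        alpha_gain=dict(cfg.alpha_gain),
        tag_pretarget_gain=dict(cfg.tag_pretarget_gain),
        coupling_rho_target=cfg.coupling_rho,
        coupling_rho_realised=realised,
        participant_id=participant_id,
    )
    return epochs, truth


def participant_seeds(cfg: SimulationConfig) -> list[int]:
    """Deterministic per-participant seeds derived from the master seed."""
    ss = np.random.SeedSequence(cfg.seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(cfg.n_participants)]


def generate_cohort(
    cfg: SimulationConfig, layout: SensorLayout | None = None
) -> list[tuple[EpochSet, GroundTruth]]:
    """Generate ``n_participants`` independent participants (deterministic)."""
    cfg.validate()
    layout = layout or standard_layout_64()
    out = []
    for p, seed in enumerate(participant_seeds(cfg)):
        out.append(generate_participant(cfg, seed, participant_id=f"p{p:02d}", layout=layout))
    return out
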