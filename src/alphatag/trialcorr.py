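"""Trial-by-trial seed correlation mapping and its follow-up tests.

For each participant and condition a per-trial *seed* value (mean band
envelope over a seed channel set and time window, typically the previously
identified alpha cluster) is Spearman-correlated with the per-trial target
band envelope at every channel; the Fisher-z transformed coefficients form a
``participants x channels`` matrix that is tested against a zero-correlation
model with the one-sample cluster permutation test.  Follow-ups: a paired
cluster test on z-differences between conditions (interaction), a median
split of trials into high/low seed halves, participant-level one-sample
t-tests with a 2-SD outlier exclusion, and a default-prior (JZS) Bayes
factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, special
from scipy import stats as sst

from .core import AnalysisBand, EpochSet, NeighborGraph
from .cluster import ClusterResult, one_sample_cluster_test, permutation_cluster_test
from .spectral import EnvelopeResult, compute_induced_envelope

__all__ = [
    "SeedSpec",
    "CorrelationMap",
    "spearman_rho",
    "spearman_z_columns",
    "fisher_z",
    "seed_values",
    "trial_band_values",
    "seed_correlation_map",
    "group_corr_cluster_test",
    "interaction_test",
    "median_split_contrast",
    "exclude_outliers",
    "one_sample_t",
    "jzs_bf10",
]

#: |rho| = 1 is clipped to this before atanh (flagged on the result).
RHO_CLIP = 1.0 - 1e-12


@dataclass(frozen=True)
class SeedSpec:
    """Seed definition: channel subset, time window (s) and band."""

    channels: tuple
    window: tuple[float, float]
    band: AnalysisBand
    path: str = "induced"

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("seed channel set must be nonempty")
        if self.window[1] <= self.window[0]:
            raise ValueError("seed window must have positive length")


@dataclass
class CorrelationMap:
    """Fisher-z Spearman correlations per channel, one participant/condition."""

    z: np.ndarray  # (n_channels,), NaN where rho undefined
    channels: list[str]
    n_trials: int
    participant_id: str = "p00"
    condition: str = ""
    clipped: np.ndarray | None = None  # mask: |rho| was 1 and got clipped

    @property
    def missing(self) -> np.ndarray:
        return ~np.isfinite(self.z)


# ---------------------------------------------------------------------------
# elementary statistics
# ---------------------------------------------------------------------------

def _midranks(x: np.ndarray) -> np.ndarray:
    return sst.rankdata(x, method="average")


def spearman_rho(x, y) -> float:
    """Spearman rank correlation (Pearson correlation of mid-ranks).

    Returns NaN ("missing") when either ranked vector has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if len(x) < 5:
        raise ValueError("need at least 5 paired observations")
    rx, ry = _midranks(x), _midranks(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        return float("nan")
    rho = float(np.mean((rx - rx.mean()) * (ry - ry.mean())) / (sx * sy))
    return float(np.clip(rho, -1.0, 1.0))


def fisher_z(rho: float) -> float:
    """Variance-stabilising z-transform ``atanh(rho)``; odd in rho.

    ``|rho| = 1`` is clipped to ``1 - 1e-12`` (z of about 13.9) rather than
    returning infinity.
    """
    if np.isnan(rho):
        return float("nan")
    if abs(rho) > 1:
        raise ValueError("|rho| must be <= 1")
    return float(np.arctanh(np.clip(rho, -RHO_CLIP, RHO_CLIP)))


def spearman_z_columns(s: np.ndarray, targets: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fisher-z Spearman correlation of ``s`` with every column of ``targets``.

    Vectorised over columns; returns ``(z, clipped)`` with NaN where a
    column's ranks have zero variance.
    """
    s = np.asarray(s, dtype=float)
    targets = np.asarray(targets, dtype=float)
    rs = _midranks(s)
    rs_c = rs - rs.mean()
    denom_s = rs_c.std()
    rt = sst.rankdata(targets, method="average", axis=0)
    rt_c = rt - rt.mean(axis=0)
    denom_t = rt_c.std(axis=0)
    n_ch = targets.shape[1]
    z = np.full(n_ch, np.nan)
    clipped = np.zeros(n_ch, dtype=bool)
    if denom_s == 0:
        return z, clipped
    ok = denom_t > 0
    rho = np.clip((rs_c @ rt_c[:, ok]) / len(s) / (denom_s * denom_t[ok]), -1.0, 1.0)
    clipped[ok] = np.abs(rho) >= 1.0
    z[ok] = np.arctanh(np.clip(rho, -RHO_CLIP, RHO_CLIP))
    return z, clipped


# ---------------------------------------------------------------------------
# seed values and correlation maps
# ---------------------------------------------------------------------------

def _per_trial_envelope(epochs: EpochSet, band: AnalysisBand) -> EnvelopeResult:
    env = compute_induced_envelope(epochs, band)
    return env


def trial_band_values(
    epochs: EpochSet,
    band: AnalysisBand,
    window: tuple[float, float],
    channels=None,
    env: EnvelopeResult | None = None,
) -> np.ndarray:
    """Per-trial band envelope averaged over ``window`` (and channels if given).

    Returns ``(n_trials, n_channels)`` or ``(n_trials,)`` when ``channels``
    selects a subset to average over.
    """
    env = env or _per_trial_envelope(epochs, band)
    mask = (env.times >= window[0]) & (env.times <= window[1])
    if not mask.any():
        raise ValueError(f"window {window} outside epoch span")
    valid = env.valid_mask()
    if not (mask & valid).any():
        raise ValueError(
            f"window {window} lies entirely inside the filter-transient region"
        )
    vals = env.per_trial[:, :, mask & valid].mean(axis=-1)
    if channels is not None:
        idx = [env.channels.index(c) for c in channels]
        return vals[:, idx].mean(axis=1)
    return vals


def seed_values(epochs: EpochSet, seed: SeedSpec) -> np.ndarray:
    """Per-trial scalar: mean band envelope over the seed channels x window."""
    return trial_band_values(epochs, seed.band, seed.window, channels=seed.channels)


def seed_correlation_map(
    epochs: EpochSet,
    seed: SeedSpec,
    target_band: AnalysisBand,
    target_window: tuple[float, float],
    condition: str | None = None,
) -> CorrelationMap:
    """Fisher-z Spearman correlation of seed values with every channel's
    per-trial target-band envelope (within one condition)."""
    if condition is not None:
        epochs = epochs.select(condition)
    if epochs.n_trials < 5:
        raise ValueError("need at least 5 trials in the selected condition")
    s = seed_values(epochs, seed)
    targets = trial_band_values(epochs, target_band, target_window)
    z, clipped = spearman_z_columns(s, targets)
    return CorrelationMap(
        z=z,
        channels=list(epochs.channels),
        n_trials=epochs.n_trials,
        participant_id=epochs.participant_id,
        condition=condition or "",
        clipped=clipped,
    )


def _stack_maps(maps) -> tuple[np.ndarray, list[str]]:
    channels = maps[0].channels
    for m in maps:
        if m.channels != channels:
            raise ValueError("correlation maps have mismatched channel sets")
    z = np.stack([m.z for m in maps])
    return np.nan_to_num(z, nan=0.0), channels


def group_corr_cluster_test(
    maps,
    neighbors: NeighborGraph,
    n_perm: int = 1000,
    criterion: float = 95.0,
    alpha_pointwise: float = 0.05,
    rng=None,
) -> ClusterResult:
    """Channel-only cluster inference of z-maps against a zero-correlation
    model (missing channels contribute z=0, i.e. no evidence)."""
    if len(maps) < 3:
        raise ValueError("need at least 3 participants")
    z, channels = _stack_maps(maps)
    return one_sample_cluster_test(
        z, neighbors, channels=channels, n_perm=n_perm,
        criterion=criterion, alpha_pointwise=alpha_pointwise, rng=rng,
    )


def interaction_test(
    maps_a,
    maps_b,
    neighbors: NeighborGraph,
    n_perm: int = 1000,
    criterion: float = 95.0,
    alpha_pointwise: float = 0.05,
    rng=None,
) -> ClusterResult:
    """Condition interaction: paired cluster test on per-participant z
    differences (a - b) over channels."""
    ids_a = [m.participant_id for m in maps_a]
    ids_b = [m.participant_id for m in maps_b]
    if ids_a != ids_b:
        raise ValueError("participant sets differ between conditions")
    za, channels = _stack_maps(maps_a)
    zb, _ = _stack_maps(maps_b)
    return permutation_cluster_test(
        za, zb, neighbors, channels=channels, n_perm=n_perm,
        criterion=criterion, alpha_pointwise=alpha_pointwise, rng=rng,
    )


# ---------------------------------------------------------------------------
# follow-ups
# ---------------------------------------------------------------------------

def median_split_contrast(
    epochs: EpochSet,
    seed: SeedSpec,
    target_band: AnalysisBand,
    target_window: tuple[float, float],
    target_channels=None,
    condition: str | None = None,
) -> tuple[float, float]:
    """Mean target activity in high- vs low-seed trial halves.

    Trials at or below the median seed value go to the low half (odd counts
    leave the middle trial in the low half).  Returns ``(high_mean,
    low_mean)``; raises if all seed values are identical.
    """
    if condition is not None:
        epochs = epochs.select(condition)
    if epochs.n_trials < 6:
        raise ValueError("need at least 6 trials for a median split")
    s = seed_values(epochs, seed)
    if np.all(s == s[0]):
        raise ValueError("all seed values identical; median split undefined")
    t = trial_band_values(epochs, target_band, target_window, channels=target_channels)
    if t.ndim > 1:
        t = t.mean(axis=1)
    # trials at or below the median go to the low half: median-tied trials
    # are assigned low, and odd counts leave the middle trial in the low half
    low = s <= np.median(s)
    return float(t[~low].mean()), float(t[low].mean())


def exclude_outliers(values, k: float = 2.0) -> np.ndarray:
    """Single-pass exclusion of values beyond ``k`` SD from the mean.

    The mean and SD come from the full input; there is no re-iteration.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 3:
        raise ValueError("need at least 3 values")
    if np.isinf(k):
        return values.copy()
    sd = values.std(ddof=0)
    if sd == 0:
        return values.copy()
    keep = np.abs(values - values.mean()) <= k * sd
    return values[keep]


def one_sample_t(values) -> tuple[float, int, float]:
    """Classical one-sample t-test against zero: ``(t, df, p_two_sided)``."""
    values = np.asarray(values, dtype=float)
    if len(values) < 3:
        raise ValueError("need at least 3 values")
    sd = values.std(ddof=1)
    if sd == 0:
        raise ValueError("zero standard deviation; t undefined")
    n = len(values)
    t = values.mean() / (sd / np.sqrt(n))
    df = n - 1
    p = 2.0 * sst.t.sf(abs(t), df)
    return float(t), df, float(p)


def jzs_bf10(t: float, n: int, scale: float = np.sqrt(2) / 2) -> float:
    """Default-prior (JZS) Bayes factor BF10 for a one-sample t-test.

    The alternative places a Cauchy prior with ``scale`` r on the
    standardised effect size (equivalently a Zellner-Siow inverse-gamma
    mixture on g); the Bayes factor is

        BF10 = [ integral over g of (1+ng)^{-1/2}
                 (1 + t^2 / ((1+ng) nu))^{-(nu+1)/2} pi_r(g) dg ]
               / (1 + t^2/nu)^{-(nu+1)/2},

    with nu = n - 1 and pi_r an InverseGamma(1/2, r^2/2) density, computed
    by adaptive quadrature.  Strictly increasing in |t| at fixed n.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if scale <= 0:
        raise ValueError("scale must be > 0")
    nu = n - 1.0
    t2 = float(t) * float(t)
    r2 = scale * scale
    log_null = -(nu + 1.0) / 2.0 * np.log1p(t2 / nu)

    def integrand(g: float) -> float:
        if g <= 0:
            return 0.0
        log_lik = -0.5 * np.log1p(n * g) - (nu + 1.0) / 2.0 * np.log1p(
            t2 / ((1.0 + n * g) * nu)
        )
        log_prior = (
            0.5 * np.log(r2 / 2.0)
            - special.gammaln(0.5)
            - 1.5 * np.log(g)
            - r2 / (2.0 * g)
        )
        return float(np.exp(log_lik + log_prior - log_null))

    # substitute g = r2 * u / (1 - u) to map (0, inf) to (0, 1)
    def sub(u: float) -> float:
        g = r2 * u / (1.0 - u)
        jac = r2 / (1.0 - u) ** 2
        return integrand(g) * jac

    bf, err = integrate.quad(sub, 0.0, 1.0, limit=200, epsabs=0.0, epsrel=1e-10)
    if not np.isfinite(bf) or bf <= 0 or (err / bf) > 1e-6:
        raise RuntimeError(
            f"JZS quadrature did not converge (bf={bf}, abs err={err})"
        )
    return float(bf)
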