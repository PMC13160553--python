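"""Group-level spatio-temporal cluster-based permutation inference.

Pointwise paired (or one-sample) t-tests over participants are thresholded
at an uncorrected alpha; supra-threshold points of equal sign are grouped by
connectivity (same channel at adjacent time indices, or neighbouring channels
at the same time index); a cluster is retained only if at some time index it
contains at least two channels that are graph neighbours.  Family-wise error
is controlled by comparing each real cluster's t-mass against the extreme
cluster masses of label-shuffled (paired: per-participant condition swap;
one-sample: per-participant sign flip) surrogate data: a cluster is deemed
significant when its |mass| exceeds the criterion percentile (default 95)
of the per-permutation extreme |mass| over both tails (a two-sided
max-statistic; per-tail extremes are available via ``tails='per_tail'``),
and a per-cluster permutation p-value is reported with the add-one
estimator ``(1 + k) / (1 + n_perm)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sst
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .core import NeighborGraph

__all__ = [
    "StatMap",
    "Cluster",
    "ClusterResult",
    "paired_t_map",
    "one_sample_t_map",
    "form_clusters",
    "permutation_cluster_test",
    "one_sample_cluster_test",
]


@dataclass
class StatMap:
    """Pointwise t-statistics: ``channels x time`` (time may be length 1)."""

    t: np.ndarray
    df: int
    p_pointwise: np.ndarray
    channels: list[str]
    zero_variance: np.ndarray | None = None  # mask of points flagged t=0

    def __post_init__(self) -> None:
        if self.t.shape != self.p_pointwise.shape:
            raise ValueError("t and p_pointwise shapes must agree")


@dataclass
class Cluster:
    """A sign-homogeneous set of supra-threshold (channel, time) points."""

    members: list  # list of (channel_index, time_index)
    sign: int  # +1 or -1
    mass: float  # sum of member t-values
    p: float = np.nan

    @property
    def channel_indices(self) -> set:
        return {c for c, _ in self.members}

    @property
    def time_span(self) -> tuple[int, int]:
        ts = [t for _, t in self.members]
        return min(ts), max(ts)


@dataclass
class ClusterResult:
    """Clusters with per-cluster p-values and the surrogate distributions."""

    clusters: list
    surrogate_max_pos: np.ndarray
    surrogate_min_neg: np.ndarray
    n_permutations: int
    criterion_percentile: float
    stat: StatMap | None = None
    tails: str = "combined"
    pos_threshold: float = np.nan
    neg_threshold: float = np.nan
    abs_threshold: float = np.nan

    @property
    def surrogate_max_abs(self) -> np.ndarray:
        """Per-permutation extreme |mass| over both tails (max statistic)."""
        return np.maximum(self.surrogate_max_pos, -self.surrogate_min_neg)

    @property
    def significant(self) -> list:
        """Clusters whose mass exceeds the criterion percentile of the
        surrogate distribution (two-sided max-|mass| by default; per-tail
        extremes when ``tails='per_tail'``)."""
        out = []
        for c in self.clusters:
            if self.tails == "combined":
                if abs(c.mass) > self.abs_threshold:
                    out.append(c)
            elif c.sign > 0 and c.mass > self.pos_threshold:
                out.append(c)
            elif c.sign < 0 and c.mass < self.neg_threshold:
                out.append(c)
        return out

    def to_table(self):
        import pandas as pd

        rows = []
        for k, c in enumerate(self.clusters):
            ch = sorted(c.channel_indices)
            names = [self.stat.channels[i] for i in ch] if self.stat else ch
            rows.append(
                {
                    "id": k,
                    "sign": "+" if c.sign > 0 else "-",
                    "mass": c.mass,
                    "p": c.p,
                    "significant": c in self.significant,
                    "n_points": len(c.members),
                    "channels": ",".join(map(str, names)),
                    "t_start": c.time_span[0],
                    "t_end": c.time_span[1],
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "id", "sign", "mass", "p", "significant",
                "n_points", "channels", "t_start", "t_end",
            ],
        )


# ---------------------------------------------------------------------------
# pointwise statistics
# ---------------------------------------------------------------------------

#: Finite stand-in for the t-value of a zero-variance, nonzero-mean point.
T_CAP = 100.0


def _t_from_diffs(diffs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One-sample t of ``diffs`` (participants on axis 0) against zero.

    Zero-variance points are flagged; they get t=0 when the mean is also
    zero, and a capped ``sign(mean) * T_CAP`` otherwise (a degenerate point
    where every participant shows the identical nonzero value is maximally,
    not minimally, significant -- an infinity is avoided so cluster masses
    stay finite and comparable).
    """
    n = diffs.shape[0]
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    zero = sd == 0
    sd_safe = np.where(zero, 1.0, sd)
    t = mean / (sd_safe / np.sqrt(n))
    t = np.where(zero, np.sign(mean) * T_CAP, t)
    return t, zero


def one_sample_t_map(maps: np.ndarray, channels=None) -> StatMap:
    """Pointwise one-sample t-test of ``participants x channels [x time]``."""
    maps = np.asarray(maps, dtype=float)
    if maps.ndim == 2:
        maps = maps[:, :, None]
    if maps.shape[0] < 3:
        raise ValueError("need at least 3 participants")
    t, zero = _t_from_diffs(maps)
    df = maps.shape[0] - 1
    p = 2.0 * sst.t.sf(np.abs(t), df)
    channels = list(channels) if channels is not None else [str(i) for i in range(t.shape[0])]
    return StatMap(t=t, df=df, p_pointwise=p, channels=channels, zero_variance=zero)


def paired_t_map(cond_a: np.ndarray, cond_b: np.ndarray, channels=None) -> StatMap:
    """Pointwise paired t-test (``participants x channels [x time]`` each)."""
    cond_a = np.asarray(cond_a, dtype=float)
    cond_b = np.asarray(cond_b, dtype=float)
    if cond_a.shape != cond_b.shape:
        raise ValueError("condition arrays must have equal shapes")
    return one_sample_t_map(cond_a - cond_b, channels=channels)


# ---------------------------------------------------------------------------
# cluster formation
# ---------------------------------------------------------------------------

def _neighbor_pairs(graph: NeighborGraph, channels) -> np.ndarray:
    idx = {c: i for i, c in enumerate(channels)}
    missing = [c for c in channels if c not in set(graph.channels)]
    if missing:
        raise ValueError(f"neighbor graph does not cover channels: {missing}")
    pairs = []
    for e in graph.edges:
        a, b = tuple(e)
        if a in idx and b in idx:
            pairs.append((idx[a], idx[b]))
    return np.array(pairs, dtype=int).reshape(-1, 2)


def _clusters_from_mask(
    mask: np.ndarray, t: np.ndarray, pairs: np.ndarray, rule: str
) -> list[Cluster]:
    """Connected components of one sign's supra-threshold mask.

    ``rule='retention'`` keeps a cluster only if at some time index it has
    >= 2 member channels that are graph neighbours; ``rule='formation'``
    restricts supra-threshold points to those with a co-significant
    neighbouring channel at the same time index before clustering.
    """
    n_ch, n_t = mask.shape
    if rule == "formation" and len(pairs):
        support = np.zeros_like(mask)
        a, b = pairs[:, 0], pairs[:, 1]
        co = mask[a] & mask[b]  # (n_pairs, n_t)
        np.logical_or.at(support, a, co)
        np.logical_or.at(support, b, co)
        mask = mask & support
    pts = np.flatnonzero(mask.ravel())
    if pts.size == 0:
        return []
    pos_of = -np.ones(n_ch * n_t, dtype=int)
    pos_of[pts] = np.arange(pts.size)

    rows, cols = [], []
    # temporal adjacency: same channel, adjacent time index
    if n_t > 1:
        m = mask[:, :-1] & mask[:, 1:]
        ch_i, t_i = np.nonzero(m)
        rows.append(ch_i * n_t + t_i)
        cols.append(ch_i * n_t + t_i + 1)
    # spatial adjacency: neighbouring channels, same time index
    if len(pairs):
        a, b = pairs[:, 0], pairs[:, 1]
        co = mask[a] & mask[b]
        pi, t_i = np.nonzero(co)
        rows.append(a[pi] * n_t + t_i)
        cols.append(b[pi] * n_t + t_i)
    if rows:
        rows = pos_of[np.concatenate(rows)]
        cols = pos_of[np.concatenate(cols)]
    else:
        rows = cols = np.array([], dtype=int)
    adj = coo_matrix(
        (np.ones(len(rows), dtype=bool), (rows, cols)), shape=(pts.size, pts.size)
    )
    n_comp, labels = connected_components(adj, directed=False)

    tflat = t.ravel()
    clusters = []
    neighbor_set = {frozenset(p) for p in map(tuple, pairs)} if len(pairs) else set()
    for comp in range(n_comp):
        members_flat = pts[labels == comp]
        members = [(int(p // n_t), int(p % n_t)) for p in members_flat]
        if rule == "retention":
            by_time: dict[int, list[int]] = {}
            for c, ti in members:
                by_time.setdefault(ti, []).append(c)
            ok = any(
                len(chs) >= 2
                and any(
                    frozenset((x, y)) in neighbor_set
                    for i, x in enumerate(chs)
                    for y in chs[i + 1 :]
                )
                for chs in by_time.values()
            )
            if not ok:
                continue
        elif rule == "formation":
            pass  # already enforced point-wise
        else:
            raise ValueError(f"unknown rule {rule!r}")
        mass = float(tflat[members_flat].sum())
        clusters.append(Cluster(members=members, sign=1 if mass >= 0 else -1, mass=mass))
    return clusters


def form_clusters(
    stat: StatMap,
    neighbors: NeighborGraph,
    alpha_pointwise: float = 0.05,
    rule: str = "retention",
) -> list[Cluster]:
    """Group supra-threshold points into sign-homogeneous clusters.

    Points with ``p_pointwise < alpha_pointwise`` connect iff they share a
    channel at adjacent time indices or are neighbouring channels at the same
    time index and have the same t-sign; clusters failing the two-neighbouring-
    channels rule are dropped (``rule='retention'``, default).
    """
    pairs = _neighbor_pairs(neighbors, stat.channels)
    supra = stat.p_pointwise < alpha_pointwise
    out = []
    for sign in (1, -1):
        mask = supra & ((stat.t > 0) if sign > 0 else (stat.t < 0))
        out.extend(_clusters_from_mask(mask, stat.t, pairs, rule))
    return sorted(out, key=lambda c: -abs(c.mass))


# ---------------------------------------------------------------------------
# permutation tests
# ---------------------------------------------------------------------------

def _perm_t_maps(diffs: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """t-maps for every sign pattern at once: ``(n_perm, channels, time)``."""
    n, n_ch, n_t = diffs.shape
    flat = diffs.reshape(n, -1)
    means = (signs @ flat) / n
    msq = (flat**2).mean(axis=0)[None, :]
    var = (msq - means**2) * (n / (n - 1.0))
    var = np.maximum(var, 0.0)
    zero = var <= 1e-300
    t = means / np.sqrt(np.where(zero, 1.0, var) / n)
    t = np.where(zero, np.sign(means) * T_CAP, t)
    return t.reshape(-1, n_ch, n_t)


def _cluster_permutation(
    diffs: np.ndarray,
    channels,
    neighbors: NeighborGraph,
    n_perm: int,
    criterion: float,
    alpha_pointwise: float,
    rule: str,
    tails: str,
    rng: np.random.Generator,
) -> ClusterResult:
    n = diffs.shape[0]
    if n < 3:
        raise ValueError("need at least 3 participants")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if n_perm > 2**n:
        warnings.warn(
            f"n_perm={n_perm} exceeds the 2^{n} distinct sign patterns; "
            "permutations are sampled with replacement",
            stacklevel=3,
        )
    stat = one_sample_t_map(diffs, channels=channels)
    real = form_clusters(stat, neighbors, alpha_pointwise, rule)
    pairs = _neighbor_pairs(neighbors, stat.channels)
    df = n - 1
    tcrit = sst.t.isf(alpha_pointwise / 2.0, df)

    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    tmaps = _perm_t_maps(diffs, signs)
    max_pos = np.zeros(n_perm)
    min_neg = np.zeros(n_perm)
    for k in range(n_perm):
        t = tmaps[k]
        for sign in (1, -1):
            mask = (t > tcrit) if sign > 0 else (t < -tcrit)
            if not mask.any():
                continue
            cl = _clusters_from_mask(mask, t, pairs, rule)
            if not cl:
                continue
            masses = [c.mass for c in cl]
            if sign > 0:
                max_pos[k] = max(masses)
            else:
                min_neg[k] = min(masses)

    pos_thr = float(np.quantile(max_pos, criterion / 100.0))
    neg_thr = float(np.quantile(min_neg, 1.0 - criterion / 100.0))
    max_abs = np.maximum(max_pos, -min_neg)
    abs_thr = float(np.quantile(max_abs, criterion / 100.0))
    for c in real:
        if tails == "combined":
            k = int(np.sum(max_abs >= abs(c.mass)))
        elif c.sign > 0:
            k = int(np.sum(max_pos >= c.mass))
        else:
            k = int(np.sum(min_neg <= c.mass))
        c.p = (1.0 + k) / (1.0 + n_perm)
    return ClusterResult(
        clusters=real,
        surrogate_max_pos=max_pos,
        surrogate_min_neg=min_neg,
        n_permutations=n_perm,
        criterion_percentile=criterion,
        stat=stat,
        tails=tails,
        pos_threshold=pos_thr,
        neg_threshold=neg_thr,
        abs_threshold=abs_thr,
    )


def permutation_cluster_test(
    cond_a: np.ndarray,
    cond_b: np.ndarray,
    neighbors: NeighborGraph,
    channels=None,
    n_perm: int = 1000,
    criterion: float = 95.0,
    alpha_pointwise: float = 0.05,
    rule: str = "retention",
    tails: str = "combined",
    rng: np.random.Generator | int | None = None,
) -> ClusterResult:
    """Paired cluster permutation test between two conditions.

    Surrogates independently swap or keep each participant's condition pair
    (a fair coin per participant), equivalent to flipping the sign of that
    participant's difference map.
    """
    cond_a = np.asarray(cond_a, dtype=float)
    cond_b = np.asarray(cond_b, dtype=float)
    if cond_a.shape != cond_b.shape:
        raise ValueError("condition arrays must have equal shapes")
    diffs = cond_a - cond_b
    if diffs.ndim == 2:
        diffs = diffs[:, :, None]
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    return _cluster_permutation(
        diffs, channels, neighbors, n_perm, criterion, alpha_pointwise, rule, tails, rng
    )


def one_sample_cluster_test(
    maps: np.ndarray,
    neighbors: NeighborGraph,
    channels=None,
    n_perm: int = 1000,
    criterion: float = 95.0,
    alpha_pointwise: float = 0.05,
    rule: str = "retention",
    tails: str = "combined",
    rng: np.random.Generator | int | None = None,
) -> ClusterResult:
    """Cluster permutation test of ``participants x channels [x time]`` maps
    against zero; surrogates flip the sign of whole participant maps
    (null hypothesis: maps symmetric about zero)."""
    maps = np.asarray(maps, dtype=float)
    if maps.ndim == 2:
        maps = maps[:, :, None]
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    return _cluster_permutation(
        maps, channels, neighbors, n_perm, criterion, alpha_pointwise, rule, tails, rng
    )
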