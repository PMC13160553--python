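"""Core data containers, sensor geometry and on-disk round-tripping.

The central object is the :class:`EpochSet`: a ``trials x channels x samples``
tensor of epoched multichannel data with its time axis expressed in seconds
relative to cue onset (cue onset = 0 s; in the default paradigm the target
appears at +3 s).  Sensor geometry lives in a :class:`SensorLayout` (2-D
positions in a normalised head-circle frame) from which a distance-thresholded
:class:`NeighborGraph` is built; the graph feeds the "at least two neighbouring
channels" retention rule of the cluster statistics.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "CONDITIONS",
    "EpochSet",
    "SensorLayout",
    "NeighborGraph",
    "AnalysisBand",
    "ValidationReport",
    "band_preset",
    "build_neighbor_graph",
    "validate_epochs",
    "write_epochs",
    "read_epochs",
    "standard_layout_64",
    "posterior_channels",
]

#: Cue condition labels used throughout the package.
CONDITIONS = ("auditory_cue", "visual_cue", "nonspecific_cue")

#: Columns of the per-trial behaviour table.
BEHAVIOR_COLUMNS = ("rt_ms", "correct", "distractor_present")


class ValidationError(ValueError):
    """Raised when a container violates one of its invariants."""


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_epochs`: ``ok`` plus named violations."""

    issues: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    def __bool__(self) -> bool:  # truthiness == validity
        return self.ok


@dataclass
class EpochSet:
    """Epoched multichannel trial data.

    Parameters
    ----------
    data
        ``(n_trials, n_channels, n_samples)`` real array, arbitrary amplitude
        units.
    sfreq
        Sampling rate in Hz.
    times
        ``(n_samples,)`` seconds relative to cue onset, uniform grid with step
        ``1/sfreq``.
    channels
        Ordered channel labels, unique.
    condition
        Per-trial condition label, one of :data:`CONDITIONS`.
    participant_id
        Identifier for the participant the epochs belong to.
    behavior
        Optional per-trial table with columns ``rt_ms`` (float, ms),
        ``correct`` (bool) and ``distractor_present`` (bool).
    """

    data: np.ndarray
    sfreq: float
    times: np.ndarray
    channels: list[str]
    condition: list[str]
    participant_id: str = "p00"
    behavior: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.times = np.asarray(self.times, dtype=float)
        self.channels = list(self.channels)
        self.condition = list(self.condition)

    # -- convenience -------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def channel_index(self, names) -> np.ndarray:
        """Indices of ``names`` in the channel axis (order preserved)."""
        lookup = {c: i for i, c in enumerate(self.channels)}
        try:
            return np.array([lookup[n] for n in names], dtype=int)
        except KeyError as err:  # pragma: no cover - message path
            raise KeyError(f"unknown channel {err.args[0]!r}") from None

    def time_mask(self, start: float, end: float) -> np.ndarray:
        """Boolean mask over the sample axis for ``start <= t <= end``."""
        return (self.times >= start) & (self.times <= end)

    def select(self, condition: str) -> "EpochSet":
        """Sub-EpochSet containing only trials of one condition."""
        keep = [i for i, c in enumerate(self.condition) if c == condition]
        beh = None
        if self.behavior is not None:
            beh = self.behavior.iloc[keep].reset_index(drop=True)
        return replace(
            self,
            data=self.data[keep],
            condition=[self.condition[i] for i in keep],
            behavior=beh,
        )


@dataclass
class SensorLayout:
    """Channel identities and 2-D positions in a normalised head circle."""

    channels: list[str]
    pos2d: np.ndarray  # (n_channels, 2)

    def __post_init__(self) -> None:
        self.channels = list(self.channels)
        self.pos2d = np.asarray(self.pos2d, dtype=float)
        if self.pos2d.shape != (len(self.channels), 2):
            raise ValidationError("pos2d must be (n_channels, 2)")
        if len(set(self.channels)) != len(self.channels):
            raise ValidationError("duplicate channel labels in layout")
        if not np.all(np.isfinite(self.pos2d)):
            raise ValidationError("layout positions must be finite")

    def position(self, name: str) -> np.ndarray:
        return self.pos2d[self.channels.index(name)]

    def subset(self, names) -> "SensorLayout":
        idx = [self.channels.index(n) for n in names]
        return SensorLayout(list(names), self.pos2d[idx])

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            {"channel": self.channels, "x": self.pos2d[:, 0], "y": self.pos2d[:, 1]}
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SensorLayout":
        df = pd.read_csv(path, sep="\t")
        return cls(df["channel"].tolist(), df[["x", "y"]].to_numpy())


@dataclass
class NeighborGraph:
    """Symmetric channel adjacency (no self-edges)."""

    channels: list[str]
    edges: set = field(default_factory=set)  # set of frozenset({a, b})

    def __post_init__(self) -> None:
        self.channels = list(self.channels)
        known = set(self.channels)
        clean = set()
        for e in self.edges:
            pair = frozenset(e)
            if len(pair) != 2:
                raise ValidationError(f"self-edge or malformed edge: {e}")
            if not pair <= known:
                raise ValidationError(f"edge endpoint outside channel set: {e}")
            clean.add(pair)
        self.edges = clean

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def are_neighbors(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self.edges

    def adjacency_matrix(self, order=None) -> np.ndarray:
        """Boolean (n, n) adjacency in ``order`` (default: graph order)."""
        order = list(order) if order is not None else self.channels
        idx = {c: i for i, c in enumerate(order)}
        mat = np.zeros((len(order), len(order)), dtype=bool)
        for e in self.edges:
            a, b = tuple(e)
            if a in idx and b in idx:
                mat[idx[a], idx[b]] = mat[idx[b], idx[a]] = True
        return mat

    def degree(self, name: str) -> int:
        return sum(1 for e in self.edges if name in e)


@dataclass(frozen=True)
class AnalysisBand:
    """A named frequency band with its FIR design parameters.

    ``filter_order`` is the number of kernel taps minus one, quoted at the
    reference sampling rate ``order_sfreq`` (500 Hz, the rate the preset
    orders were defined for); kernel design scales it proportionally to the
    actual rate, keeping it even so the kernel stays symmetric.
    """

    name: str
    f_lo: float
    f_hi: float
    filter_order: int
    order_sfreq: float = 500.0

    def __post_init__(self) -> None:
        if not (0 < self.f_lo < self.f_hi):
            raise ValidationError(f"band edges must satisfy 0 < f_lo < f_hi: {self}")
        if self.filter_order <= 0 or self.filter_order % 2:
            raise ValidationError("filter_order must be a positive even integer")

    @property
    def center(self) -> float:
        return 0.5 * (self.f_lo + self.f_hi)

    def order_at(self, sfreq: float) -> int:
        """Filter order rescaled to ``sfreq`` (rounded to the nearest even)."""
        m = int(round(self.filter_order * sfreq / self.order_sfreq / 2.0)) * 2
        return max(m, 2)


# Default presets.  The narrow tag/control bands use 0.8 s kernels
# (order 400 @ 500 Hz) so that components 4 Hz apart are isolated
# (first spectral null at 3.75 Hz; leakage at +-4 Hz < 1e-2).  The slower
# bands keep the shorter kernels appropriate to their frequencies.
_BAND_DEFS = {
    "visual_tag": (35.5, 36.5, 400),
    "auditory_tag": (39.5, 40.5, 400),
    "control_44": (43.5, 44.5, 400),
    "intermodulation": (3.5, 4.5, 344),
    "alpha": (7.5, 12.5, 276),
}

#: Short-kernel orders favouring temporal over frequency resolution
#: (116 for the tag bands, 344 at 4 Hz, 276 for alpha).
SHORT_KERNEL_ORDERS = {
    "visual_tag": 116,
    "auditory_tag": 116,
    "control_44": 116,
    "intermodulation": 344,
    "alpha": 276,
}


def band_preset(name: str, short_kernels: bool = False) -> AnalysisBand:
    """Return a preset :class:`AnalysisBand` by name.

    ``short_kernels=True`` selects the short high-temporal-resolution kernel
    orders instead of the frequency-selective defaults.
    """
    try:
        f_lo, f_hi, order = _BAND_DEFS[name]
    except KeyError:
        raise KeyError(
            f"unknown band {name!r}; presets: {sorted(_BAND_DEFS)}"
        ) from None
    if short_kernels:
        order = SHORT_KERNEL_ORDERS[name]
    return AnalysisBand(name, f_lo, f_hi, order)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def build_neighbor_graph(layout: SensorLayout, max_dist: float) -> NeighborGraph:
    """Channel adjacency by Euclidean distance threshold in layout coordinates.

    Two channels are neighbours iff the distance between their 2-D positions
    is ``<= max_dist``.  The default packaged layout gives a median degree of
    4-8 at ``max_dist=0.33``.
    """
    if max_dist <= 0:
        raise ValueError("max_dist must be > 0")
    if len(set(layout.channels)) != len(layout.channels):
        raise ValidationError("duplicate channel labels")
    pos = layout.pos2d
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    edges = set()
    n = len(layout.channels)
    for i in range(n):
        for j in range(i + 1, n):
            if d[i, j] <= max_dist:
                edges.add(frozenset((layout.channels[i], layout.channels[j])))
    return NeighborGraph(layout.channels, edges)


def validate_epochs(epochs: EpochSet) -> ValidationReport:
    """Check every :class:`EpochSet` invariant; report all violations."""
    issues: list[str] = []
    d = epochs.data
    if d.ndim != 3:
        issues.append(f"data must be 3-D (trials x channels x samples), got {d.ndim}-D")
        return ValidationReport(issues)
    if epochs.sfreq <= 0:
        issues.append("sfreq must be > 0")
    if len(epochs.times) != d.shape[2]:
        issues.append("times length does not match sample axis")
    else:
        dt = np.diff(epochs.times)
        if len(dt) and not np.all(dt > 0):
            issues.append("times must be strictly increasing")
        elif len(dt) and epochs.sfreq > 0:
            if not np.allclose(dt, 1.0 / epochs.sfreq, rtol=1e-6, atol=1e-9):
                issues.append("times must have constant step 1/sfreq")
    if not np.all(np.isfinite(d)):
        issues.append("data contains non-finite values")
    if len(epochs.condition) != d.shape[0]:
        issues.append("condition length does not match trial count")
    unknown = sorted(set(epochs.condition) - set(CONDITIONS))
    if unknown:
        issues.append(f"unknown condition labels: {unknown}")
    if len(epochs.channels) != d.shape[1]:
        issues.append("channel list length does not match channel axis")
    if len(set(epochs.channels)) != len(epochs.channels):
        issues.append("channel labels are not unique")
    if epochs.behavior is not None:
        if len(epochs.behavior) != d.shape[0]:
            issues.append("behavior table length does not match trial count")
        missing = set(BEHAVIOR_COLUMNS) - set(epochs.behavior.columns)
        if missing:
            issues.append(f"behavior table missing columns: {sorted(missing)}")
    return ValidationReport(issues)


# ---------------------------------------------------------------------------
# on-disk container: zip with a raw little-endian float payload and a JSON
# metadata header.  Round trips are bit exact.
# ---------------------------------------------------------------------------

_MAGIC = "alphatag-epochs-v1"


class EpochFileError(IOError):
    """Malformed epoch container file."""


def write_epochs(epochs: EpochSet, path) -> None:
    """Write an :class:`EpochSet` to its self-describing container file."""
    meta = {
        "magic": _MAGIC,
        "sfreq": float(epochs.sfreq),
        "channels": list(epochs.channels),
        "condition": list(epochs.condition),
        "participant_id": str(epochs.participant_id),
        "dtype": str(epochs.data.dtype),
        "shape": list(epochs.data.shape),
        "has_behavior": epochs.behavior is not None,
    }
    def entry(name):  # fixed timestamp so identical content is byte-identical
        info = zipfile.ZipInfo(name, date_time=(1980, 1, 1, 0, 0, 0))
        info.compress_type = zipfile.ZIP_DEFLATED
        return info

    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        zf.writestr(entry("meta.json"), json.dumps(meta, indent=1))
        zf.writestr(entry("times.bin"), np.ascontiguousarray(epochs.times, dtype="<f8").tobytes())
        zf.writestr(
            entry("data.bin"),
            np.ascontiguousarray(epochs.data).astype(epochs.data.dtype, copy=False).tobytes(),
        )
        if epochs.behavior is not None:
            buf = io.StringIO()
            epochs.behavior.to_csv(buf, sep="\t", index=False)
            zf.writestr(entry("behavior.tsv"), buf.getvalue())


def read_epochs(path) -> EpochSet:
    """Read a container written by :func:`write_epochs` (bit-exact inverse)."""
    try:
        with zipfile.ZipFile(path) as zf:
            names = set(zf.namelist())
            if "meta.json" not in names:
                raise EpochFileError(f"{path}: missing meta.json section")
            meta = json.loads(zf.read("meta.json"))
            if meta.get("magic") != _MAGIC:
                raise EpochFileError(f"{path}: bad magic in meta.json")
            for section in ("times.bin", "data.bin"):
                if section not in names:
                    raise EpochFileError(f"{path}: missing {section} section")
            times = np.frombuffer(zf.read("times.bin"), dtype="<f8")
            shape = tuple(meta["shape"])
            raw = zf.read("data.bin")
            expected = int(np.prod(shape)) * np.dtype(meta["dtype"]).itemsize
            if len(raw) != expected:
                raise EpochFileError(
                    f"{path}: data.bin has {len(raw)} bytes, expected {expected}"
                )
            data = np.frombuffer(raw, dtype=meta["dtype"]).reshape(shape).copy()
            behavior = None
            if meta.get("has_behavior"):
                if "behavior.tsv" not in names:
                    raise EpochFileError(f"{path}: missing behavior.tsv section")
                behavior = pd.read_csv(
                    io.StringIO(zf.read("behavior.tsv").decode()), sep="\t"
                )
                behavior["correct"] = behavior["correct"].astype(bool)
                behavior["distractor_present"] = behavior["distractor_present"].astype(bool)
    except zipfile.BadZipFile as err:
        raise EpochFileError(f"{path}: not a valid epoch container ({err})") from err
    return EpochSet(
        data=data,
        sfreq=float(meta["sfreq"]),
        times=times.copy(),
        channels=list(meta["channels"]),
        condition=list(meta["condition"]),
        participant_id=meta["participant_id"],
        behavior=behavior,
    )


# ---------------------------------------------------------------------------
# packaged 64-channel 10-10 style layout
# ---------------------------------------------------------------------------

_LAYOUT_64 = [
    "Fp1", "Fpz", "Fp2",
    "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2", "Iz",
    "F9", "F10",
]


def standard_layout_64() -> SensorLayout:
    """64-channel 10-10 style layout on the normalised head circle.

    Positions come from the standard idealised 10-05 montage (via MNE) and
    are flattened with an azimuthal-equidistant projection: Cz at the origin,
    the equatorial ring at radius 1, +y towards the nose.
    """
    import warnings

    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        try:
            montage = mne.channels.make_standard_montage("colin27_1005")
        except ValueError:  # older naming
            montage = mne.channels.make_standard_montage("standard_1005")
    pos3d = montage.get_positions()["ch_pos"]
    out = []
    for ch in _LAYOUT_64:
        x, y, z = pos3d[ch]
        r = np.sqrt(x * x + y * y + z * z)
        theta = np.arccos(np.clip(z / r, -1, 1))  # polar angle from vertex
        phi = np.arctan2(x, y)  # azimuth from nose, clockwise to the right
        rho = theta / (np.pi / 2.0)
        out.append((rho * np.sin(phi), rho * np.cos(phi)))
    return SensorLayout(list(_LAYOUT_64), np.array(out))


def posterior_channels(layout: SensorLayout, y_max: float = -0.45) -> list[str]:
    """Channels in the posterior part of the layout (``y <= y_max``)."""
    return [c for c, (x, y) in zip(layout.channels, layout.pos2d) if y <= y_max]
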