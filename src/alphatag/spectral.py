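"""Narrow-band filtering, Hilbert envelopes and sliding-window power.

Two envelope paths are distinguished throughout:

* the **evoked** path averages baseline-corrected, band-filtered waveforms
  over trials before taking the analytic envelope, so only phase-locked
  activity (the steady-state responses) survives;
* the **induced** path takes the analytic envelope per trial and averages the
  envelopes, so phase-random activity (ongoing alpha) is retained.

Band-pass kernels are linear-phase FIRs built as the difference of two
Blackman-windowed sinc low-pass kernels and normalised to unit gain at band
centre; they are applied with full group-delay compensation (zero phase) and
mirror padding at the epoch edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import AnalysisBand, EpochSet

__all__ = [
    "FilterKernel",
    "EnvelopeResult",
    "TFRResult",
    "design_blackman_sinc_bandpass",
    "apply_zero_phase",
    "band_analytic",
    "multiband_analytic",
    "analytic_envelope",
    "compute_band_envelopes",
    "compute_evoked_ssep",
    "compute_induced_envelope",
    "compute_tfr",
    "baseline_relative_change",
    "normalized_difference",
    "intermodulation_frequency",
]

#: Default baseline window (s relative to cue onset): 700-200 ms before cue.
DEFAULT_BASELINE = (-0.7, -0.2)


@dataclass(frozen=True)
class FilterKernel:
    """Symmetric (linear-phase) FIR taps for one analysis band."""

    taps: np.ndarray
    band: AnalysisBand
    sfreq: float

    def __post_init__(self) -> None:
        taps = np.asarray(self.taps, dtype=float)
        object.__setattr__(self, "taps", taps)
        if not np.all(np.isfinite(taps)):
            raise ValueError("kernel taps must be finite")
        if not np.allclose(taps, taps[::-1], atol=1e-12):
            raise ValueError("kernel taps must be symmetric (linear phase)")

    @property
    def order(self) -> int:
        return len(self.taps) - 1

    @property
    def half(self) -> int:
        """Half length in samples (group delay / transient extent)."""
        return self.order // 2

    def response(self, freqs) -> np.ndarray:
        """Magnitude response evaluated at ``freqs`` (Hz)."""
        freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
        n = np.arange(len(self.taps))
        ph = np.exp(-2j * np.pi * freqs[:, None] * n / self.sfreq)
        return np.abs(ph @ self.taps)


def _blackman_sinc_lowpass(fc: float, order: int, sfreq: float) -> np.ndarray:
    n = np.arange(order + 1) - order / 2.0
    h = (2.0 * fc / sfreq) * np.sinc(2.0 * fc * n / sfreq) * np.blackman(order + 1)
    return h / h.sum()  # unit DC gain


def design_blackman_sinc_bandpass(band: AnalysisBand, sfreq: float) -> FilterKernel:
    """Blackman-windowed sinc band-pass for ``band`` at sampling rate ``sfreq``.

    Built as the difference of two unit-DC low-pass kernels with cutoffs at
    the band edges, then scaled to unit magnitude response at the band centre.
    DC gain is exactly zero by construction.  The quoted ``filter_order`` is
    rescaled to ``sfreq`` (orders are defined at the band's reference rate).
    """
    if band.f_hi >= sfreq / 2.0:
        raise ValueError(
            f"band {band.name}: f_hi={band.f_hi} must be below Nyquist ({sfreq / 2})"
        )
    order = band.order_at(sfreq)
    if order % 2:
        raise ValueError("filter order must be even (symmetric kernel)")
    h = _blackman_sinc_lowpass(band.f_hi, order, sfreq) - _blackman_sinc_lowpass(
        band.f_lo, order, sfreq
    )
    kernel = FilterKernel(h, band, sfreq)
    center_gain = kernel.response(band.center)[0]
    if center_gain <= 0:
        raise ValueError(f"degenerate kernel for band {band.name}")
    return FilterKernel(h / center_gain, band, sfreq)


def _mirror_pad(x: np.ndarray, pad: int) -> np.ndarray:
    """Reflect-pad the last axis by ``pad`` samples on each side."""
    if pad >= x.shape[-1]:
        raise ValueError("epoch shorter than filter kernel")
    left = x[..., 1 : pad + 1][..., ::-1]
    right = x[..., -pad - 1 : -1][..., ::-1]
    return np.concatenate([left, x, right], axis=-1)


def filter_array(kernel: FilterKernel, x: np.ndarray) -> np.ndarray:
    """Zero-phase filter an array along its last axis (mirror-padded edges)."""
    x = np.asarray(x)
    half = kernel.half
    padded = _mirror_pad(x, half)
    out = sps.fftconvolve(padded, kernel.taps[(None,) * (x.ndim - 1)], mode="valid", axes=-1)
    # 'valid' on a signal padded by half on each side returns exactly len(x)
    return out


def band_analytic(kernel: FilterKernel, x: np.ndarray) -> np.ndarray:
    """Zero-phase band filtering and analytic signal in one FFT pass.

    Returns the complex analytic signal of the band-filtered input along the
    last axis: real part = zero-phase filtered waveform, magnitude = Hilbert
    envelope.  The input is mirror-padded by half a kernel on each side and
    the FFT is zero-padded past the kernel length, so the result equals
    linear (not circular) convolution; computed in single precision for
    speed.
    """
    return multiband_analytic(x, [kernel])[kernel.band.name]


def apply_zero_phase(kernel: FilterKernel, epochs: EpochSet) -> EpochSet:
    """Filter every trial/channel of ``epochs`` with zero net delay."""
    if epochs.n_samples <= len(kernel.taps):
        raise ValueError(
            f"epoch length {epochs.n_samples} must exceed kernel length "
            f"{len(kernel.taps)}"
        )
    from dataclasses import replace

    return replace(epochs, data=filter_array(kernel, epochs.data))


def multiband_analytic(x: np.ndarray, kernels) -> dict:
    """Analytic band signals for several kernels from one forward FFT.

    Equivalent to :func:`band_analytic` per kernel (same mirror padding and
    linear-convolution guarantees, with the pad width set by the longest
    kernel) but amortises the forward transform, which dominates when many
    bands are extracted from the same epochs.  Returns ``{band name:
    complex array}``.
    """
    from scipy import fft as sfft

    kernels = list(kernels)
    if not kernels:
        return {}
    sfreq = kernels[0].sfreq
    if any(k.sfreq != sfreq for k in kernels):
        raise ValueError("all kernels must share one sampling rate")
    x = np.asarray(x, dtype=np.float32)
    n = x.shape[-1]
    max_half = max(k.half for k in kernels)
    padded = _mirror_pad(x, max_half)
    nfft = sfft.next_fast_len(padded.shape[-1] + 2 * max_half)
    freqs = np.fft.rfftfreq(nfft, d=1.0 / sfreq)
    spec = sfft.rfft(padded, n=nfft, axis=-1)
    half_n = nfft // 2
    out = {}
    for k in kernels:
        resp = (
            np.exp(-2j * np.pi * freqs[:, None] * np.arange(len(k.taps)) / sfreq)
            @ k.taps.astype(np.float32)
        ).astype(np.complex64)
        bs = spec * resp
        full = np.zeros(x.shape[:-1] + (nfft,), dtype=np.complex64)
        full[..., 0] = bs[..., 0]
        full[..., 1:half_n] = 2.0 * bs[..., 1:half_n]
        full[..., half_n] = bs[..., half_n] if nfft % 2 == 0 else 2.0 * bs[..., half_n]
        y = sfft.ifft(full, axis=-1)
        lo = max_half + k.half
        out[k.band.name] = y[..., lo : lo + n]
    return out


def analytic_envelope(series: np.ndarray, axis: int = -1) -> np.ndarray:
    """Magnitude of the analytic (Hilbert) signal along ``axis``."""
    series = np.asarray(series)
    if not np.all(np.isfinite(series)):
        raise ValueError("input to analytic_envelope must be finite")
    return np.abs(sps.hilbert(series, axis=axis))


@dataclass
class EnvelopeResult:
    """Band-limited amplitude envelope, evoked or induced path.

    ``values`` is ``channels x samples`` for the trial-collapsed result;
    the induced path additionally retains ``per_trial``
    (``trials x channels x samples``) for trial-by-trial analyses.
    """

    values: np.ndarray
    times: np.ndarray
    channels: list[str]
    band: AnalysisBand
    path: str  # {"evoked", "induced"}
    baseline_state: str = "raw"  # {"raw", "relative_change"}
    per_trial: np.ndarray | None = None
    transient_samples: int = 0

    def valid_mask(self) -> np.ndarray:
        """Samples outside the filter-transient edge regions."""
        mask = np.ones(len(self.times), dtype=bool)
        k = self.transient_samples
        if k:
            mask[:k] = False
            mask[-k:] = False
        return mask

    def to_long_table(self, participant_id: str = "", condition: str = ""):
        """Long-format table (participant, condition, channel, time, value)."""
        import pandas as pd

        n_ch, n_t = self.values.shape
        return pd.DataFrame(
            {
                "participant": participant_id,
                "condition": condition,
                "channel": np.repeat(self.channels, n_t),
                "time": np.tile(self.times, n_ch),
                "value": self.values.ravel(),
            }
        )


def compute_evoked_ssep(
    epochs: EpochSet,
    band: AnalysisBand,
    baseline_window: tuple[float, float] = DEFAULT_BASELINE,
) -> EnvelopeResult:
    """Trial-averaged steady-state response envelope (evoked path).

    Per trial the data are zero-phase band-filtered and the scalar mean over
    ``baseline_window`` is subtracted from each channel's waveform; the
    corrected waveforms are averaged over trials and the Hilbert envelope of
    the average is returned.  Phase-random components cancel in the average.
    """
    evoked, _ = compute_band_envelopes(epochs, band, baseline_window, induced=False)
    return evoked


def compute_induced_envelope(epochs: EpochSet, band: AnalysisBand) -> EnvelopeResult:
    """Per-trial Hilbert envelope averaged over trials (induced path).

    The per-trial envelopes are retained on the result for trial-by-trial
    correlation analyses.
    """
    _, induced = compute_band_envelopes(epochs, band, evoked=False)
    return induced


def compute_band_envelopes(
    epochs: EpochSet,
    band: AnalysisBand,
    baseline_window: tuple[float, float] = DEFAULT_BASELINE,
    evoked: bool = True,
    induced: bool = True,
) -> tuple[EnvelopeResult | None, EnvelopeResult | None]:
    """Evoked and induced envelopes of one band from a single filtering pass.

    The analytic band signal is computed once per trial; the induced result
    is the trial-average (and per-trial) envelope, the evoked result is the
    envelope of the trial-averaged baseline-corrected waveform (averaging
    the analytic signal commutes with averaging the waveform, and baseline
    correction subtracts the trial's scalar baseline-window mean).
    """
    if epochs.n_trials == 0:
        raise ValueError("no trials selected")
    kernel = design_blackman_sinc_bandpass(band, epochs.sfreq)
    analytic = band_analytic(kernel, epochs.data)
    transient = min(2 * kernel.half, epochs.n_samples // 2)
    common = dict(
        times=epochs.times,
        channels=list(epochs.channels),
        band=band,
        transient_samples=transient,
    )
    evoked_res = induced_res = None
    if evoked:
        bmask = epochs.time_mask(*baseline_window)
        if not bmask.any():
            raise ValueError(f"baseline window {baseline_window} outside epoch span")
        # the baseline is the scalar mean of the *waveform* (real part); the
        # analytic signal of (x - c) is analytic(x) - c for a real constant
        baseline = analytic.real[..., bmask].mean(axis=-1, keepdims=True)
        avg = (analytic - baseline).mean(axis=0)
        evoked_res = EnvelopeResult(values=np.abs(avg), path="evoked", **common)
    if induced:
        env = np.abs(analytic)
        induced_res = EnvelopeResult(
            values=env.mean(axis=0), path="induced", per_trial=env, **common
        )
    return evoked_res, induced_res


@dataclass
class TFRResult:
    """Sliding-window power: ``channels x freqs x times``."""

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    channels: list[str]
    normalisation: str = "raw"  # {"raw", "relative_change", "delta_sum"}

    def to_long_table(self, participant_id: str = "", condition: str = ""):
        """Long-format table (participant, condition, channel, freq, time, value)."""
        import pandas as pd

        n_ch, n_f, n_t = self.power.shape
        return pd.DataFrame(
            {
                "participant": participant_id,
                "condition": condition,
                "channel": np.repeat(self.channels, n_f * n_t),
                "freq": np.tile(np.repeat(self.freqs, n_t), n_ch),
                "time": np.tile(self.times, n_ch * n_f),
                "value": self.power.ravel(),
            }
        )


def compute_tfr(
    epochs: EpochSet,
    freqs=None,
    cycles: float = 3.0,
    tstep: float = 0.010,
) -> TFRResult:
    """Hanning-tapered sliding-window power, trial averaged.

    For each frequency the window length is ``cycles / f`` seconds; power is
    the squared magnitude of the tapered windowed Fourier coefficient at the
    target frequency, normalised so a stationary sinusoid of amplitude ``A``
    yields power ``A**2 / 4`` (i.e. power scales with amplitude squared).
    Output times advance in steps of ``tstep`` seconds.
    """
    if freqs is None:
        freqs = np.arange(5.0, 20.0 + 1e-9, 0.5)
    freqs = np.asarray(freqs, dtype=float)
    sf = epochs.sfreq
    n = epochs.n_samples
    too_long = [f for f in freqs if int(round(cycles / f * sf)) > n]
    if too_long:
        raise ValueError(
            f"window of {cycles} cycles exceeds the epoch for frequencies {too_long}"
        )
    step = max(int(round(tstep * sf)), 1)
    out_idx = np.arange(0, n, step)
    power = np.zeros((epochs.n_channels, len(freqs), len(out_idx)))
    x = epochs.data
    for fi, f in enumerate(freqs):
        wlen = int(round(cycles / f * sf))
        win = np.hanning(wlen)
        t = np.arange(wlen) / sf
        kern = win * np.exp(-2j * np.pi * f * t)
        scale = 2.0 / win.sum()  # amplitude-A tone -> coefficient magnitude A
        half = wlen // 2
        padded = _mirror_pad(x, half)
        coef = sps.fftconvolve(padded, kern[None, None, :], mode="valid", axes=-1)
        coef = coef[..., : n] * scale
        p = (np.abs(coef) ** 2) / 4.0
        power[:, fi, :] = p.mean(axis=0)[:, out_idx]
    return TFRResult(
        power=power,
        freqs=freqs,
        times=epochs.times[out_idx],
        channels=list(epochs.channels),
    )


def baseline_relative_change(
    x: np.ndarray, times: np.ndarray, baseline_window: tuple[float, float]
) -> np.ndarray:
    """Relative change from baseline: ``(x - b) / b`` along the last axis.

    ``b`` is the mean of ``x`` over ``baseline_window`` computed separately
    for every leading index (channel, and frequency for TFRs).
    """
    x = np.asarray(x, dtype=float)
    times = np.asarray(times)
    mask = (times >= baseline_window[0]) & (times <= baseline_window[1])
    if not mask.any():
        raise ValueError(f"baseline window {baseline_window} outside time axis")
    b = x[..., mask].mean(axis=-1, keepdims=True)
    if np.any(b == 0):
        raise ZeroDivisionError("baseline mean is zero for at least one series")
    return (x - b) / b


def normalized_difference(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Bounded condition contrast ``(a - b) / (a + b)`` (antisymmetric)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    s = a + b
    if np.any(s == 0):
        raise ZeroDivisionError("a + b is zero somewhere; contrast undefined")
    return (a - b) / s


def intermodulation_frequency(f_auditory: float, f_visual: float) -> float:
    """Difference frequency ``f_auditory - f_visual`` of two simultaneous tags."""
    out = f_auditory - f_visual
    if out < 0:
        raise ValueError("f_auditory must be >= f_visual")
    return out
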