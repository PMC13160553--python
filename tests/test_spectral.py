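"""Filter design, envelope paths, TFR and normalisation formulas."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alphatag.core import AnalysisBand, band_preset
from alphatag.spectral import (
    analytic_envelope,
    apply_zero_phase,
    band_analytic,
    baseline_relative_change,
    compute_band_envelopes,
    compute_evoked_ssep,
    compute_induced_envelope,
    compute_tfr,
    design_blackman_sinc_bandpass,
    intermodulation_frequency,
    normalized_difference,
)

from conftest import make_epochs


def tone(freq, sfreq, n, amp=1.0, phase=0.0):
    t = np.arange(n) / sfreq
    return amp * np.sin(2 * np.pi * freq * t + phase)


class TestFilterDesign:
    def test_dc_gain_is_negligible(self):
        for name in ("visual_tag", "intermodulation", "alpha"):
            k = design_blackman_sinc_bandpass(band_preset(name), 500.0)
            assert abs(k.taps.sum()) < 0.01

    def test_unit_gain_at_band_centre_for_quoted_order(self):
        """Order 116 at 500 Hz, 35.5-36.5 Hz: |H(36)| within 5% of 1."""
        band = AnalysisBand("tag", 35.5, 36.5, 116)
        k = design_blackman_sinc_bandpass(band, 500.0)
        assert 0.95 <= k.response(36.0)[0] <= 1.05

    def test_kernel_is_symmetric(self):
        k = design_blackman_sinc_bandpass(band_preset("alpha"), 250.0)
        np.testing.assert_allclose(k.taps, k.taps[::-1])

    def test_default_tag_kernels_isolate_neighbouring_tags(self):
        """36/40/44 Hz components 4 Hz apart must not leak into each other."""
        for sf in (160.0, 500.0):
            k36 = design_blackman_sinc_bandpass(band_preset("visual_tag"), sf)
            assert k36.response(36.0)[0] == pytest.approx(1.0, abs=1e-6)
            assert k36.response(40.0)[0] < 0.01
            k44 = design_blackman_sinc_bandpass(band_preset("control_44"), sf)
            assert k44.response(40.0)[0] < 0.01

    def test_odd_order_rejected(self):
        with pytest.raises(Exception):
            AnalysisBand("bad", 35.5, 36.5, 117)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            design_blackman_sinc_bandpass(band_preset("control_44"), 80.0)


class TestZeroPhase:
    def test_in_band_tone_keeps_peak_positions(self):
        sf, n = 500.0, 2000
        x = tone(36.0, sf, n)
        ep = make_epochs(data=x[None, None, :], sfreq=sf, n_samples=n)
        k = design_blackman_sinc_bandpass(band_preset("visual_tag"), sf)
        out = apply_zero_phase(k, ep).data[0, 0]
        inner = slice(400, -400)
        lags = np.arange(-5, 6)
        xc = [np.dot(out[inner], np.roll(x, l)[inner]) for l in lags]
        assert lags[int(np.argmax(xc))] == 0

    def test_out_of_band_tone_suppressed(self):
        sf, n = 500.0, 3000
        x = tone(10.0, sf, n)
        ep = make_epochs(data=x[None, None, :], sfreq=sf, n_samples=n)
        k = design_blackman_sinc_bandpass(band_preset("visual_tag"), sf)
        out = apply_zero_phase(k, ep).data[0, 0]
        assert np.sqrt(np.mean(out[500:-500] ** 2)) < 0.02 * np.sqrt(np.mean(x**2))

    def test_zeros_stay_zero(self):
        ep = make_epochs(n_trials=2, n_channels=2, sfreq=500.0, n_samples=1500)
        k = design_blackman_sinc_bandpass(band_preset("alpha"), 500.0)
        assert np.all(apply_zero_phase(k, ep).data == 0)

    def test_epoch_shorter_than_kernel_rejected(self):
        ep = make_epochs(n_samples=100, sfreq=500.0)
        k = design_blackman_sinc_bandpass(band_preset("visual_tag"), 500.0)
        with pytest.raises(ValueError):
            apply_zero_phase(k, ep)

    def test_fused_analytic_matches_convolution_path(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(3, 2, 900)).astype(np.float32)
        ep = make_epochs(data=x, sfreq=250.0, n_samples=900, n_trials=3)
        k = design_blackman_sinc_bandpass(band_preset("alpha"), 250.0)
        exact = apply_zero_phase(k, ep).data
        fused = band_analytic(k, x).real
        assert np.abs(exact - fused).max() < 1e-4 * np.abs(exact).max() + 1e-5


class TestEnvelope:
    def test_pure_tone_envelope_equals_amplitude(self):
        x = tone(36.0, 500.0, 2500, amp=3.0)
        env = analytic_envelope(x)
        assert np.abs(env[200:-200] - 3.0).max() < 0.03

    def test_zeros_give_zeros(self):
        assert np.all(analytic_envelope(np.zeros(256)) == 0)

    def test_am_envelope_recovered(self):
        """(1 + 0.5 cos 2pi 2t) sin(2pi 40 t): envelope RMSE < 2% of mean."""
        sf, n = 500.0, 5000
        t = np.arange(n) / sf
        am = 1 + 0.5 * np.cos(2 * np.pi * 2 * t)
        x = am * np.sin(2 * np.pi * 40 * t)
        env = analytic_envelope(x)
        inner = slice(250, -250)
        rmse = np.sqrt(np.mean((env[inner] - am[inner]) ** 2))
        assert rmse < 0.02 * am[inner].mean()


class TestEvokedInducedPaths:
    sf = 250.0

    def _tag_epochs(self, n_trials, phase_locked=True, amp=1.0, seed=0):
        rng = np.random.default_rng(seed)
        n = 1500
        t = np.arange(n) / self.sf - 1.0
        data = np.empty((n_trials, 1, n))
        for i in range(n_trials):
            ph = 0.5 if phase_locked else rng.uniform(0, 2 * np.pi)
            data[i, 0] = amp * np.sin(2 * np.pi * 36.0 * (t + 1.0) + ph)
        return make_epochs(data=data, sfreq=self.sf, t0=-1.0, n_samples=n)

    def test_phase_locked_evoked_envelope_recovers_amplitude(self):
        ep = self._tag_epochs(50, phase_locked=True, amp=2.0)
        res = compute_evoked_ssep(ep, band_preset("visual_tag"), (-0.7, -0.2))
        mid = (ep.times > 1.0) & (ep.times < 3.0)
        assert np.abs(res.values[0, mid] / 2.0 - 1).max() < 0.05

    def test_random_phase_evoked_envelope_collapses(self):
        """|mean of 200 random phasors| is far below the single-trial amp."""
        ep = self._tag_epochs(200, phase_locked=False)
        res = compute_evoked_ssep(ep, band_preset("visual_tag"), (-0.7, -0.2))
        mid = (ep.times > 1.0) & (ep.times < 3.0)
        assert res.values[0, mid].mean() < 0.15

    def test_random_phase_induced_envelope_survives(self):
        ep = self._tag_epochs(30, phase_locked=False, amp=1.5)
        res = compute_induced_envelope(ep, band_preset("visual_tag"))
        mid = (ep.times > 1.0) & (ep.times < 3.0)
        assert np.abs(res.values[0, mid] / 1.5 - 1).max() < 0.05

    def test_single_trial_evoked_equals_that_trials_envelope(self):
        ep = self._tag_epochs(1, phase_locked=True)
        ev = compute_evoked_ssep(ep, band_preset("visual_tag"), (-0.7, -0.2))
        ind = compute_induced_envelope(ep, band_preset("visual_tag"))
        mid = (ep.times > 0.5) & (ep.times < 3.5)
        np.testing.assert_allclose(ev.values[0, mid], ind.values[0, mid], rtol=0.02)

    def test_evoked_below_induced_pointwise(self):
        ep = self._tag_epochs(40, phase_locked=False, seed=3)
        ev = compute_evoked_ssep(ep, band_preset("visual_tag"), (-0.7, -0.2))
        ind = compute_induced_envelope(ep, band_preset("visual_tag"))
        mid = (ep.times > 0.5) & (ep.times < 3.5)
        assert (ev.values[0, mid] <= ind.values[0, mid] + 1e-3).all()

    def test_induced_homogeneity_under_amplitude_scaling(self):
        ep = self._tag_epochs(10, phase_locked=False, seed=5)
        ep2 = make_epochs(data=ep.data * 2, sfreq=self.sf, t0=-1.0, n_samples=ep.n_samples)
        r1 = compute_induced_envelope(ep, band_preset("visual_tag"))
        r2 = compute_induced_envelope(ep2, band_preset("visual_tag"))
        np.testing.assert_allclose(r2.values, 2 * r1.values, rtol=1e-4, atol=1e-6)

    def test_empty_selection_rejected(self):
        ep = self._tag_epochs(3)
        with pytest.raises(ValueError):
            compute_band_envelopes(ep.select("auditory_cue"), band_preset("alpha"))


class TestTFR:
    def test_stationary_tone_peaks_at_its_frequency(self):
        sf, n = 250.0, 1250
        data = np.tile(tone(10.0, sf, n), (3, 2, 1))
        ep = make_epochs(data=data, sfreq=sf, n_samples=n, n_trials=3, n_channels=2)
        res = compute_tfr(ep)
        peak = res.freqs[np.argmax(res.power[0], axis=0)]
        inner = (res.times > ep.times[0] + 0.4) & (res.times < ep.times[-1] - 0.4)
        assert np.all(peak[inner] == 10.0)

    def test_power_scales_with_amplitude_squared(self):
        sf, n = 250.0, 1250
        e1 = make_epochs(data=tone(10.0, sf, n)[None, None], sfreq=sf, n_samples=n, n_trials=1, n_channels=1)
        e2 = make_epochs(data=2 * tone(10.0, sf, n)[None, None], sfreq=sf, n_samples=n, n_trials=1, n_channels=1)
        f = np.array([10.0])
        p1 = compute_tfr(e1, freqs=f).power
        p2 = compute_tfr(e2, freqs=f).power
        mid = slice(40, -40)
        ratio = p2[0, 0, mid] / p1[0, 0, mid]
        assert np.abs(ratio - 4.0).max() < 0.2

    def test_window_lengths_follow_three_cycles(self):
        # 3 cycles: 0.6 s at 5 Hz, 0.15 s at 20 Hz
        assert int(round(3 / 5 * 500)) == 300  # samples at 500 Hz
        sf, n = 500.0, 400  # 0.8 s epoch: 5 Hz window fits, 2 Hz would not
        ep = make_epochs(data=np.zeros((1, 1, n)), sfreq=sf, n_samples=n, n_trials=1, n_channels=1)
        compute_tfr(ep, freqs=np.array([5.0]))
        with pytest.raises(ValueError, match="2"):
            compute_tfr(ep, freqs=np.array([2.0]))

    def test_separated_components_add_without_crossterms(self):
        """At each component's own frequency bin the summed-signal power
        matches the sum of component powers within 5%, provided the 3-cycle
        window resolves the other component (separation beyond the Hann
        mainlobe, half-width ~2f/3 Hz); at bins in between, short windows
        cannot separate the pair and cross-terms are unavoidable."""
        sf, n = 250.0, 2500
        a = tone(6.0, sf, n)
        b = tone(18.0, sf, n)
        f = np.array([6.0, 18.0])
        def pw(sig):
            ep = make_epochs(data=sig[None, None], sfreq=sf, n_samples=n, n_trials=1, n_channels=1)
            return compute_tfr(ep, freqs=f).power[0]
        mid = slice(60, -60)
        combined = pw(a + b)[:, mid]
        summed = (pw(a) + pw(b))[:, mid]
        for fi in range(2):
            denom = summed[fi].max()
            assert np.abs(combined[fi] - summed[fi]).max() / denom < 0.05


class TestNormalisations:
    def test_constant_series_normalises_to_zero(self):
        x = np.full((2, 10), 7.0)
        t = np.arange(10) / 10.0
        out = baseline_relative_change(x, t, (0.0, 0.4))
        np.testing.assert_allclose(out, 0.0)

    def test_double_baseline_gives_one(self):
        t = np.arange(10) / 10.0
        x = np.where(t < 0.5, 2.0, 4.0)[None, :]
        out = baseline_relative_change(x, t, (0.0, 0.4))
        np.testing.assert_allclose(out[0, t >= 0.5], 1.0)

    def test_arithmetic_example(self):
        x = np.array([[4.0, 4.0, 4.0, 4.0, 6.0]])
        t = np.arange(5.0)
        out = baseline_relative_change(x, t, (0.0, 3.0))
        assert out[0, -1] == pytest.approx(0.5)

    def test_zero_baseline_guarded(self):
        with pytest.raises(ZeroDivisionError):
            baseline_relative_change(np.zeros((1, 5)), np.arange(5.0), (0.0, 3.0))

    def test_delta_sum_examples(self):
        a = np.array([1.0, 2.0])
        assert np.all(normalized_difference(a, a) == 0)
        np.testing.assert_allclose(normalized_difference(a, np.zeros(2) + 1e-12), 1.0, atol=1e-9)

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(0.1, 10), min_size=1, max_size=5),
           st.lists(st.floats(0.1, 10), min_size=1, max_size=5))
    def test_delta_sum_antisymmetric(self, a, b):
        n = min(len(a), len(b))
        a, b = np.array(a[:n]), np.array(b[:n])
        np.testing.assert_allclose(
            normalized_difference(a, b), -normalized_difference(b, a)
        )

    def test_long_table_exports_are_faithful(self):
        sf, n = 250.0, 1250
        data = np.tile(tone(10.0, sf, n), (2, 2, 1))
        ep = make_epochs(data=data, sfreq=sf, n_samples=n, n_trials=2, n_channels=2)
        env = compute_induced_envelope(ep, band_preset("alpha"))
        tab = env.to_long_table(participant_id="p00", condition="visual_cue")
        assert len(tab) == 2 * n
        row = tab[(tab.channel == "ch1") & (tab.time == ep.times[5])]
        assert row["value"].iloc[0] == env.values[1, 5]
        tfr = compute_tfr(ep, freqs=np.array([10.0, 12.0]))
        ttab = tfr.to_long_table()
        assert len(ttab) == 2 * 2 * len(tfr.times)
        assert set(ttab.columns) == {"participant", "condition", "channel", "freq", "time", "value"}

    def test_intermodulation_frequency(self):
        assert intermodulation_frequency(40.0, 36.0) == 4.0
        assert intermodulation_frequency(5.0, 5.0) == 0.0
        assert intermodulation_frequency(44.0, 36.0) == 8.0
        with pytest.raises(ValueError):
            intermodulation_frequency(36.0, 40.0)
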