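"""Seed correlations, median splits, t-tests and Bayes factors."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alphatag.core import band_preset, posterior_channels
from alphatag.trialcorr import (
    SeedSpec,
    exclude_outliers,
    fisher_z,
    group_corr_cluster_test,
    interaction_test,
    jzs_bf10,
    median_split_contrast,
    one_sample_t,
    seed_correlation_map,
    seed_values,
    spearman_rho,
    spearman_z_columns,
)


def brute_force_spearman(x, y):
    """1 - 6 sum d^2 / (n(n^2-1)) with mid-rank correction via Pearson."""
    from scipy import stats as sst

    rx = sst.rankdata(x)
    ry = sst.rankdata(y)
    return np.corrcoef(rx, ry)[0, 1]


class TestSpearman:
    def test_monotone_relations(self):
        x = np.arange(10.0)
        assert spearman_rho(x, 3 * x + 1) == 1.0
        assert spearman_rho(x, -x) == -1.0

    def test_worked_example(self):
        assert spearman_rho([1, 2, 3, 4, 5], [3, 1, 2, 5, 4]) == pytest.approx(0.6)

    def test_matches_brute_force_on_random_short_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            n = rng.integers(5, 9)
            x = rng.integers(0, 5, n).astype(float)  # ties likely
            y = rng.integers(0, 5, n).astype(float)
            mine = spearman_rho(x, y)
            ref = brute_force_spearman(x, y)
            if np.isnan(ref):
                assert np.isnan(mine)
            else:
                assert mine == pytest.approx(ref, abs=1e-12)

    def test_zero_variance_is_missing(self):
        assert np.isnan(spearman_rho([1, 1, 1, 1, 1], [1, 2, 3, 4, 5]))

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10_000))
    def test_invariant_under_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        base = spearman_rho(x, y)
        assert spearman_rho(np.exp(x), y**3) == pytest.approx(base, abs=1e-12)


class TestFisherZ:
    def test_zero_maps_to_zero(self):
        assert fisher_z(0.0) == 0.0

    def test_odd_function(self):
        for r in (0.1, 0.5, 0.99):
            assert fisher_z(-r) == -fisher_z(r)

    def test_half_maps_to_known_value(self):
        assert fisher_z(0.5) == pytest.approx(0.5493, abs=1e-4)

    def test_unit_correlation_clipped_finite(self):
        z = fisher_z(1.0)
        assert np.isfinite(z) and z > 10


class TestSeedValues:
    def _coupled_epochs(self, layout, rho=0.6, n_trials=60, seed=0):
        from alphatag.montecarlo import mc_simulation_config
        from alphatag.simulate import generate_participant

        cfg = mc_simulation_config(
            seed, coupling_rho=rho, conditions=("visual_cue",),
            n_trials_per_condition=n_trials,
        )
        ep, truth = generate_participant(cfg, seed + 1, layout=layout)
        return ep, truth

    def test_single_channel_single_sample_window(self):
        from conftest import make_epochs

        rng = np.random.default_rng(0)
        data = rng.normal(size=(6, 2, 600))
        ep = make_epochs(data=data, sfreq=200.0, t0=-0.5, n_samples=600)
        band = band_preset("alpha")
        spec = SeedSpec(channels=("ch0",), window=(1.0, 1.004), band=band)
        vals = seed_values(ep, spec)
        assert vals.shape == (6,)
        # doubling one trial's amplitude doubles its seed value
        data2 = data.copy()
        data2[2] *= 2
        ep2 = make_epochs(data=data2, sfreq=200.0, t0=-0.5, n_samples=600)
        vals2 = seed_values(ep2, spec)
        assert vals2[2] == pytest.approx(2 * vals[2], rel=1e-5)
        assert vals2[0] == pytest.approx(vals[0], rel=1e-6)

    def test_noise_free_seed_values_rank_match_latents(self, layout64):
        from alphatag.montecarlo import mc_simulation_config
        from alphatag.simulate import generate_participant

        cfg = mc_simulation_config(3, conditions=("visual_cue",), n_trials_per_condition=30)
        cfg.noise_scale = 0.0
        cfg.alpha_bandwidth = 0.0  # frequency jitter would perturb filter gain per trial
        ep, truth = generate_participant(cfg, 11, layout=layout64)
        spec = SeedSpec(
            channels=tuple(posterior_channels(layout64)), window=(1.0, 2.0),
            band=band_preset("alpha"),
        )
        vals = seed_values(ep, spec)
        rho = spearman_rho(vals, truth.table["amp_alpha"].to_numpy())
        assert rho > 0.999

    def test_window_in_transient_region_rejected(self, layout64):
        from conftest import make_epochs

        ep = make_epochs(data=np.random.default_rng(0).normal(size=(6, 2, 600)),
                         sfreq=200.0, t0=-0.5, n_samples=600)
        spec = SeedSpec(channels=("ch0",), window=(-0.5, -0.45), band=band_preset("alpha"))
        with pytest.raises(ValueError, match="transient"):
            seed_values(ep, spec)


class TestCorrelationPipeline:
    def test_map_is_deterministic(self, layout64):
        from alphatag.montecarlo import mc_simulation_config
        from alphatag.simulate import generate_participant

        cfg = mc_simulation_config(5, conditions=("visual_cue",), n_trials_per_condition=20)
        ep, _ = generate_participant(cfg, 21, layout=layout64)
        spec = SeedSpec(channels=("Oz", "POz"), window=(2.0, 3.0), band=band_preset("alpha"))
        m1 = seed_correlation_map(ep, spec, band_preset("visual_tag"), (2.5, 3.0))
        m2 = seed_correlation_map(ep, spec, band_preset("visual_tag"), (2.5, 3.0))
        np.testing.assert_array_equal(m1.z, m2.z)

    def test_coupled_latents_give_positive_posterior_z(self):
        """Latent-level check: rho=0.6 over 300 trials yields mean z > 0.4
        on channels carrying the tag topography."""
        rng = np.random.default_rng(0)
        from alphatag.montecarlo import mc_simulation_config
        from alphatag.simulate import draw_trial_latents

        cfg = mc_simulation_config(0, coupling_rho=0.6)
        lat = draw_trial_latents(cfg, 300, rng)
        s = lat["amp_alpha"].to_numpy()
        targets = lat["amp_visual"].to_numpy()[:, None] + 0.1 * rng.standard_normal((300, 4))
        z, _ = spearman_z_columns(s, targets)
        assert z.mean() > 0.4

    def test_null_latents_give_small_z(self):
        rng = np.random.default_rng(1)
        from alphatag.montecarlo import mc_simulation_config
        from alphatag.simulate import draw_trial_latents

        cfg = mc_simulation_config(0, coupling_rho=0.0)
        hits = 0
        for _ in range(20):
            lat = draw_trial_latents(cfg, 300, rng)
            z, _ = spearman_z_columns(
                lat["amp_alpha"].to_numpy(),
                lat["amp_visual"].to_numpy()[:, None] * 0
                + rng.standard_normal((300, 1)),
            )
            hits += abs(z[0]) < 0.12
        assert hits >= 18  # ~95% of null z inside +-0.12 at n=300

    def test_group_test_and_interaction_on_synthetic_maps(self, layout64, graph64):
        from alphatag.trialcorr import CorrelationMap

        rng = np.random.default_rng(2)
        chans = layout64.channels
        post = [chans.index(c) for c in posterior_channels(layout64)]

        def make_maps(effect):
            maps = []
            for p in range(12):
                z = rng.normal(0, 0.15, len(chans))
                z[post] += effect
                maps.append(CorrelationMap(z=z, channels=chans, n_trials=50,
                                           participant_id=f"p{p:02d}"))
            return maps

        maps_pos = make_maps(0.5)
        maps_null = make_maps(0.0)
        res = group_corr_cluster_test(maps_pos, graph64, n_perm=150,
                                      rng=np.random.default_rng(0))
        assert any(c.sign > 0 for c in res.significant)
        inter = interaction_test(maps_pos, maps_null, graph64, n_perm=150,
                                 rng=np.random.default_rng(0))
        assert any(c.sign > 0 for c in inter.significant)
        # swapping the conditions flips cluster signs
        inter_swapped = interaction_test(maps_null, maps_pos, graph64, n_perm=150,
                                         rng=np.random.default_rng(0))
        assert sorted(c.mass for c in inter_swapped.clusters) == pytest.approx(
            sorted(-c.mass for c in inter.clusters)
        )

    def test_identical_map_sets_give_no_interaction(self, layout64, graph64):
        from alphatag.trialcorr import CorrelationMap

        rng = np.random.default_rng(3)
        chans = layout64.channels
        maps = [CorrelationMap(z=rng.normal(size=len(chans)), channels=chans,
                               n_trials=40, participant_id=f"p{p}") for p in range(8)]
        res = interaction_test(maps, maps, graph64, n_perm=120)
        assert res.clusters == []

    def test_participant_mismatch_rejected(self, layout64, graph64):
        from alphatag.trialcorr import CorrelationMap

        chans = layout64.channels
        a = [CorrelationMap(z=np.zeros(len(chans)), channels=chans, n_trials=10,
                            participant_id=f"p{p}") for p in range(4)]
        b = [CorrelationMap(z=np.zeros(len(chans)), channels=chans, n_trials=10,
                            participant_id=f"q{p}") for p in range(4)]
        with pytest.raises(ValueError):
            interaction_test(a, b, graph64, n_perm=120)


class TestMedianSplit:
    def test_six_trials_split_rule(self):
        from conftest import make_epochs

        # seed values proportional to trial amplitude 1..6 at a posterior band
        sf, n = 200.0, 800
        t = np.arange(n) / sf - 0.5
        data = np.stack([
            (i + 1) * np.sin(2 * np.pi * 10 * t)[None, :].repeat(1, axis=0)
            for i in range(6)
        ])
        ep = make_epochs(data=data, sfreq=sf, t0=-0.5, n_samples=n, n_channels=1)
        band = band_preset("alpha")
        spec = SeedSpec(channels=("ch0",), window=(1.0, 2.0), band=band)
        high, low = median_split_contrast(ep, spec, band, (1.0, 2.0),
                                          target_channels=("ch0",))
        # high half = trials {4,5,6} -> mean amp 5; low half = {1,2,3} -> 2
        assert high == pytest.approx(5.0, rel=0.02)
        assert low == pytest.approx(2.0, rel=0.02)

    def test_identical_seed_values_flagged(self):
        from conftest import make_epochs

        data = np.tile(np.sin(2 * np.pi * 10 * (np.arange(800) / 200.0)), (6, 1, 1))
        ep = make_epochs(data=data, sfreq=200.0, t0=-0.5, n_samples=800, n_channels=1)
        band = band_preset("alpha")
        spec = SeedSpec(channels=("ch0",), window=(1.0, 2.0), band=band)
        with pytest.raises(ValueError, match="identical"):
            median_split_contrast(ep, spec, band, (1.0, 2.0), target_channels=("ch0",))


class TestOutliersAndT:
    def test_all_equal_none_removed(self):
        out = exclude_outliers([2.0, 2.0, 2.0, 2.0])
        assert len(out) == 4

    def test_single_deviant_removed(self):
        # note: with only 5 values no point can exceed 2 SD (max possible
        # z-score is (n-1)/sqrt(n) ~ 1.79), so a 7-value set is used
        vals = [0.0, 0.1, -0.1, 0.05, -0.05, 0.02, 6.0]
        out = exclude_outliers(vals)
        assert 6.0 not in out
        assert len(out) == 6

    def test_infinite_k_is_identity(self):
        vals = np.array([1.0, -3.0, 10.0])
        np.testing.assert_array_equal(exclude_outliers(vals, k=np.inf), vals)

    def test_single_pass_not_iterated(self):
        # after removing 10, the value 3 would deviate > 2 SD of the rest,
        # but a single pass keeps it
        vals = np.array([0.0, 0.1, -0.1, 0.05, -0.05, 3.0, 10.0])
        out = exclude_outliers(vals)
        assert 10.0 not in out and 3.0 in out

    def test_t_symmetric_values_give_zero(self):
        t, df, p = one_sample_t([-1.0, 1.0, -2.0, 2.0])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_t_hand_example(self):
        t, df, p = one_sample_t([1.0, 2.0, 3.0])
        assert t == pytest.approx(2 * np.sqrt(3))
        assert df == 2

    def test_t_scale_invariant(self):
        t1, *_ = one_sample_t([1.0, 2.0, 3.0])
        t2, *_ = one_sample_t([10.0, 20.0, 30.0])
        assert t1 == pytest.approx(t2)

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError):
            one_sample_t([1.0, 1.0, 1.0])


class TestBayesFactor:
    def test_null_point_data_favours_null(self):
        assert jzs_bf10(0.0, 20) < 1.0

    def test_monotone_in_t(self):
        assert jzs_bf10(3.0, 20) > jzs_bf10(2.0, 20)
        assert jzs_bf10(-3.0, 20) == pytest.approx(jzs_bf10(3.0, 20))

    def test_matches_independent_quadrature_oracle(self):
        """Cauchy-prior BF via the noncentral-t integral over effect size."""
        from scipy import integrate, stats

        def oracle(t, n, r=np.sqrt(2) / 2):
            nu = n - 1
            num, _ = integrate.quad(
                lambda d: stats.nct.pdf(t, nu, d * np.sqrt(n)) * stats.cauchy.pdf(d, 0, r),
                -np.inf, np.inf, limit=400,
            )
            return num / stats.t.pdf(t, nu)

        for t, n in [(2.29, 20), (0.5, 10), (4.0, 25), (-1.7, 15)]:
            assert jzs_bf10(t, n) == pytest.approx(oracle(t, n), rel=1e-6)

    def test_reproduces_published_scale_of_evidence(self):
        # one-sample t of 2.29 with n=20 sits just below the substantial-
        # evidence threshold; strong t values give BF >> 10
        assert jzs_bf10(2.29, 20) == pytest.approx(1.90, abs=0.02)
        assert jzs_bf10(4.95, 20) > 100

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            jzs_bf10(1.0, 1)
        with pytest.raises(ValueError):
            jzs_bf10(1.0, 10, scale=-1.0)
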