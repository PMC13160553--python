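"""Trial-by-trial alpha-tag correlation mapping with follow-up tests.

Simulates eight participants whose per-trial alpha and 36 Hz tag amplitudes
are rank-coupled at rho = 0.5, maps the seed correlation over all channels,
tests the Fisher-z maps against a zero-correlation model with the cluster
permutation approach, and runs the median-split and Bayes-factor follow-ups.
"""

import numpy as np

from alphatag.core import band_preset, build_neighbor_graph, posterior_channels, standard_layout_64
from alphatag.montecarlo import mc_simulation_config
from alphatag.simulate import generate_participant
from alphatag.trialcorr import (
    SeedSpec,
    group_corr_cluster_test,
    jzs_bf10,
    median_split_contrast,
    one_sample_t,
    seed_correlation_map,
)

layout = standard_layout_64()
graph = build_neighbor_graph(layout, 0.33)
seed_spec = SeedSpec(
    channels=tuple(posterior_channels(layout)),
    window=(2.0, 3.0),
    band=band_preset("alpha"),
)
target = band_preset("visual_tag")

cfg = mc_simulation_config(9, coupling_rho=0.5, conditions=("visual_cue",),
                           n_trials_per_condition=40)
cfg.n_participants = 8
maps, split_diffs = [], []
for p in range(cfg.n_participants):
    epochs, _ = generate_participant(cfg, 300 + p, layout=layout)
    maps.append(seed_correlation_map(epochs, seed_spec, target, (2.5, 3.0)))
    high, low = median_split_contrast(
        epochs, seed_spec, target, (2.5, 3.0),
        target_channels=seed_spec.channels,
    )
    split_diffs.append(high - low)

res = group_corr_cluster_test(maps, graph, n_perm=500, rng=np.random.default_rng(1))
print("group cluster test:", len(res.significant), "significant cluster(s)")
if res.significant:
    c = res.significant[0]
    names = sorted(layout.channels[i] for i in c.channel_indices)
    print(f"  mass {c.mass:.1f}, p = {c.p:.4f}, channels: {', '.join(names[:8])} ...")

mean_z = np.array([np.nanmean(m.z[[layout.channels.index(c) for c in seed_spec.channels]])
                   for m in maps])
t, df, p = one_sample_t(mean_z)
print(f"mean posterior Fisher-z = {mean_z.mean():.3f}; t({df}) = {t:.2f}, p = {p:.4f}, "
      f"BF10 = {jzs_bf10(t, len(mean_z)):.1f}")
t2, df2, p2 = one_sample_t(split_diffs)
print(f"median split high-low = {np.mean(split_diffs):+.3f}; t({df2}) = {t2:.2f}, "
      f"p = {p2:.4f}")
print("\npositive z, a positive split difference and BF10 > 3 all reflect the")
print("injected rank coupling between alpha and the 36 Hz envelope")
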