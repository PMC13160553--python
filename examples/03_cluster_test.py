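"""Spatio-temporal cluster permutation test on a simulated alpha contrast.

Simulates six participants with a posterior alpha gain of 1.3 for auditory
cues, computes per-condition induced alpha maps (relative change from
baseline) over the last two seconds before the target, and tests the
condition difference with the paired cluster permutation test.
"""

import numpy as np

from alphatag.core import band_preset, build_neighbor_graph, standard_layout_64
from alphatag.cluster import permutation_cluster_test
from alphatag.montecarlo import mc_simulation_config
from alphatag.simulate import generate_participant
from alphatag.spectral import baseline_relative_change, compute_band_envelopes

layout = standard_layout_64()
graph = build_neighbor_graph(layout, 0.33)
band = band_preset("alpha")

cfg = mc_simulation_config(5)
cfg.n_participants = 6
maps = {"auditory_cue": [], "visual_cue": []}
for p in range(cfg.n_participants):
    epochs, _ = generate_participant(cfg, 100 + p, layout=layout)
    for cond in maps:
        sub = epochs.select(cond)
        _, induced = compute_band_envelopes(sub, band)
        rel = baseline_relative_change(induced.values, sub.times, (-0.7, -0.2))
        idx = np.flatnonzero(sub.time_mask(1.0, 3.0))[::8]  # 50 ms steps
        maps[cond].append(rel[:, idx])

result = permutation_cluster_test(
    np.stack(maps["auditory_cue"]), np.stack(maps["visual_cue"]),
    graph, channels=layout.channels, n_perm=500, rng=np.random.default_rng(0),
)
print(result.to_table().to_string(index=False, max_colwidth=40))
print("\nsignificant clusters:", len(result.significant))
print("a positive cluster over posterior channels reflects the injected")
print("auditory > visual alpha gain; p-values come from 500 sign-flip")
print("permutations of the participant-level difference maps")
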