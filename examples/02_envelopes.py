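"""Evoked vs induced envelope paths on one synthetic participant.

The 36 Hz steady-state response is phase-locked across trials, so it
survives trial averaging (evoked path); ongoing alpha has random phase, so
it only shows in the per-trial envelope average (induced path).  The
printed numbers make that dissociation concrete.
"""

import numpy as np

from alphatag.core import band_preset, standard_layout_64
from alphatag.montecarlo import mc_simulation_config
from alphatag.simulate import generate_participant
from alphatag.spectral import compute_band_envelopes

layout = standard_layout_64()
cfg = mc_simulation_config(0, conditions=("visual_cue",), n_trials_per_condition=24)
epochs, _ = generate_participant(cfg, 7, layout=layout)
oz = layout.channels.index("Oz")
window = epochs.time_mask(2.0, 3.0)  # within the cue-to-target interval

for band_name in ("visual_tag", "alpha"):
    band = band_preset(band_name)
    evoked, induced = compute_band_envelopes(epochs, band)
    ev = evoked.values[oz, window].mean()
    ind = induced.values[oz, window].mean()
    print(f"{band_name:11s} @Oz: evoked envelope {ev:5.2f}   induced envelope {ind:5.2f}"
          f"   ratio {ev / ind:.2f}")

print("\nthe phase-locked tag keeps most of its amplitude in the evoked path")
print("(ratio near 1), while phase-random alpha collapses there (ratio << 1)")
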