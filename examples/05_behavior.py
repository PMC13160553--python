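"""Behavioural filtering, summaries, attentional benefit and distractor cost.

Builds a one-participant behaviour table from the generator (three cue
conditions), applies the reaction-time trimming (drop incorrect trials and
RTs faster than 100 ms or above 1500 ms) and prints the derived measures.
"""

from alphatag.behavior import (
    attentional_benefit,
    chance_level,
    condition_summary,
    distractor_cost,
    filter_trials,
)
from alphatag.montecarlo import mc_simulation_config
from alphatag.simulate import generate_participant
from alphatag.core import standard_layout_64

cfg = mc_simulation_config(
    3, conditions=("auditory_cue", "visual_cue", "nonspecific_cue"),
    n_trials_per_condition=60,
)
# one channel is enough: this example only uses the behaviour table
epochs, _ = generate_participant(cfg, 17, layout=standard_layout_64().subset(["Cz"]))
table = epochs.behavior.copy()
table["condition"] = epochs.condition

kept, report = filter_trials(table)
print(f"retained {report.n_retained}/{report.n_input} trials "
      f"({report.n_incorrect} incorrect, {report.n_too_fast} too fast, "
      f"{report.n_too_slow} too slow)")
print(f"chance level of the 3-alternative task: {100 * chance_level(3):.1f}%\n")

print(condition_summary(table).to_string(index=False))
print()
for modality in ("auditory", "visual"):
    ben = attentional_benefit(table, modality)
    d_acc, d_rt = distractor_cost(table, modality)
    print(f"{modality:8s}: attentional benefit {ben:+6.1f} ms "
          f"(negative = cue speeds responses); distractor cost "
          f"{d_rt:+5.1f} ms, {d_acc:+.1f} %-points accuracy")
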