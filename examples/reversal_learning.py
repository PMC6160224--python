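"""Differential conditioning with mid-experiment reward reversal.

Free-flying model bees choose between arms showing stimuli A and B. For
the first 15 trials choosing A is rewarded; from trial 16 the reward
moves to B. The per-trial population preference tracks the contingency:
it rises toward A during acquisition, then collapses and reverses. This
is stimulus-specific associative learning carried by the KC->EN pathway.
"""

from beemb import ExperimentConfig, run_reversal_experiment

result = run_reversal_experiment(
    ExperimentConfig(n_bees=100, master_seed=1))

print("trial  %choosing A   (reward: A on trials 1-15, B afterwards)")
for _, row in result.blocks.iterrows():
    t = int(row.trial_index) + 1
    bar = "#" * int(row.percent_a / 4)
    marker = "  <- reversal" if t == 16 else ""
    print(f"{t:5d}  {row.percent_a:6.1f}  {bar}{marker}")
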