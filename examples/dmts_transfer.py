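"""Sameness learning in the Y-maze and its transfer to novel stimuli.

Runs a small population of model bees through the delayed
match-to-sample protocol (pretraining, 60 rewarded training trials on the
A/B pair) and then tests them, without reward and with frozen weights, on
two stimulus pairs they have never seen. Above-chance transfer shows the
population learned the abstract matching rule, not the training stimuli.
A larger population (the published setup uses 360) tightens the numbers.
"""

from beemb import ExperimentConfig, run_dmts_experiment

config = ExperimentConfig(task="DMTS", n_bees=60, master_seed=1)
result = run_dmts_experiment(config)

print("DMTS acquisition, percent correct per block of 10 trials:")
for _, row in result.blocks.iterrows():
    print(f"  block {int(row['block']) + 1}: {row['mean']:5.1f}%  "
          f"(SEM {row['sem']:.1f})")

print("\nunrewarded transfer to novel pairs (weights frozen):")
for pair, pct in result.transfer_percent.items():
    print(f"  {'/'.join(pair)}: {pct:5.1f}% correct")
print(f"  overall: {result.transfer_overall:.1f}% "
      "(50% would mean no concept transfer)")
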