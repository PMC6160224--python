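"""Negative patterning: a nonlinear discrimination the sparse KC code solves.

Restrained model bees are rewarded on the single odours (A+, B+) but not
on their mixture (AB-). A linear associator cannot respond to A and to B
yet withhold the response to AB; the model manages because some Kenyon
cells need coincident input from both odour groups to cross threshold
and therefore fire for the compound only — their synapses can be
depressed without touching the single-odour response.
"""

from beemb import BeeModel, ExperimentConfig, ModelParams
from beemb.protocols import patterning_curves, run_patterning

params = ModelParams().calibrated()
bee = BeeModel(params, seed=1)
bee.state.start_trial()
ab = bee.present(frozenset({"A", "B"}), at_entrance=True).y > 0
bee.state.start_trial()
a = bee.present(frozenset({"A"}), at_entrance=True).y > 0
bee.state.start_trial()
b = bee.present(frozenset({"B"}), at_entrance=True).y > 0
print(f"KCs active for A: {a.sum()}, for B: {b.sum()}, for AB: {ab.sum()} "
      f"of which compound-only: {(ab & ~a & ~b).sum()}")

records = run_patterning(
    ExperimentConfig(n_bees=60, master_seed=1), "negative")
curves = patterning_curves(records).pivot(
    index="block", columns="stimulus", values="percent_responding")

print("\nnegative patterning (A+, B+, AB-), percent responding per block:")
print(curves.round(1).to_string())
final = curves.iloc[-1]
print(f"\nfinal block: elements {final['A']:.0f}%/{final['B']:.0f}% vs "
      f"compound {final['A+B']:.0f}% — the population withholds its "
      "response to the unrewarded mixture while responding to its parts.")
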