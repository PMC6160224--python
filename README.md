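# beemb — mushroom-body circuit models of abstract concept learning

Honey bees can learn the abstract concepts *sameness* and *difference*:
trained in a Y-maze to approach (or avoid) whichever arm repeats the
sample shown at the entrance, they transfer the rule to stimuli they have
never seen. `beemb` is a research package for simulating a neural-circuit
account of this ability that needs nothing beyond known insect
neuroanatomy — no working-memory buffer, no top-down control. It is
aimed at computational neuroscientists and students of invertebrate
learning who want a compact, fully testable model of the mushroom body
that handles both abstract-rule tasks and the classical conditioning
battery with one set of parameters.

## The model in brief

A three-layer linear-threshold network with an inhibitory side loop:

```
 IN (144) --fixed sparse c_ij--> KC (5000) --plastic w_jk--> EN (4 GO + 4 NOGO)
                                   |  \                          ^
                                   |   '--> PCT (6) --plastic w_lk (inhibitory)
                                   '<------ delayed feedback
```

- KC: `y_j = g·M_j·[Σ_i c_ij x_i − b − Σ_l s*_l]_+`, with sensory
  accommodation `M_j = 0.7` for KCs active at the maze entrance of the
  current trial (1 otherwise) — a decaying trace of the sample.
- PCT: `s_l = [Σ_j y_j − b_s(l)]_+` with thresholds 120/150 and an upper
  cut-off; tuned so the whole population fires for novel stimuli and
  stays silent for repeated ones — a stimulus-unspecific novelty signal.
- EN: `z_k = [Σ_j w_jk y_j − 0.5 Σ_l w_lk s_l]_+`; behaviour is GO when
  `Σz_GO > Σz_NOGO + R·d` (R ~ U[−0.5, 0.5], d escalating with NOGOs).
- Learning is a reward-modulated three-factor rule on both plastic
  matrices, `Δw ∝ ±λ (R − R_b)·pre·post` with R ∈ {0, 1}, R_b = 2/3,
  λ_e = 0.06 = 2λ_i.

Because the PCT novelty signal carries no stimulus identity, whatever
the PCT→EN synapses learn about novelty transfers unchanged to novel
stimuli — that is the proposed mechanism of sameness/difference
learning. The stimulus-specific KC→EN pathway handles ordinary
conditioning (single-odour PER, differential/reversal, positive and
negative patterning) in the same circuit. A two-node reduction of the
same principle is included (`beemb.reduced`).

## Worked example

```
$ python examples/dmts_transfer.py
DMTS acquisition, percent correct per block of 10 trials:
  block 1:  45.5%  (SEM 1.8)
  block 2:  66.5%  (SEM 1.7)
  block 3:  70.5%  (SEM 1.9)
  block 4:  75.0%  (SEM 1.7)
  block 5:  73.0%  (SEM 1.5)
  block 6:  74.0%  (SEM 1.4)

unrewarded transfer to novel pairs (weights frozen):
  C/D:  82.9% correct
  E/F:  86.2% correct
  overall: 84.6% (50% would mean no concept transfer)
```

Block 1 sits *below* chance: pretraining with a familiarisation stimulus
releases PCT→GO inhibition, biasing naive bees toward novel (here:
wrong) arms. Training then drives percent correct into the seventies,
and the population prefers the matching arm of stimulus pairs it has
never seen, with all weights frozen — the signature of rule rather than
stimulus learning. `examples/` holds similar narrative scripts for
novelty detection, reversal learning, patterning and the reduced model;
the `beemb` command-line tool runs the same experiments with CSV/JSON
output (`beemb dmts --n-bees 360`, `beemb lesion-matrix`, `beemb sweep`,
…).

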