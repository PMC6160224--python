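# Methods

## The circuit model

`beemb` implements a rate-based model of the insect mushroom body in which
abstract sameness/difference learning and ordinary associative conditioning
coexist in one circuit. The network is linear-threshold with no membrane
dynamics; an *iteration* is one synchronous evaluation of three layers:

- **Input neurons (IN)**, 144 units. A stimulus is a fixed, disjoint group
  of 8 units (labels Z, A–F); an active unit carries 1 − U[−0.05, 0.05],
  drawn once per bee and frozen, so stimulus codes are consistent within a
  bee but differ between bees.
- **Kenyon cells (KC)**, 5000 units, each connected to every IN
  independently with probability 0.02 (fixed binary wiring per bee; the
  wiring seed defines the bee). KC j computes
  `y_j = g · M_j · [Σ_i c_ij x_i − b − Σ_l s*_l]_+` with threshold
  b = 1.2, a global output gain g (calibrated, below), accommodation
  factor M_j, and the delayed inhibitory feedback s\* of the PCT loop.
- **Protocerebral-tract neurons (PCT)**, 6 inhibitory units driven by the
  summed KC output, threshold-linear with per-unit thresholds
  b_s = 120 (unit 0) and 150 (units 1–5) and an upper cut-off (below).
- **Extrinsic neurons (EN)**, 8 output units split into GO and NOGO
  subpopulations of 4: `z_k = [Σ_j w_jk y_j − 0.5 Σ_l w_lk s_l]_+` with
  plastic KC→EN weights `w_jk` and plastic PCT→EN weights `w_lk`, all
  clipped to [0, 1] and initialised at 0.5.

**Sensory accommodation** is the working-memory trace: KCs that were
active when the trial's entrance (sample) stimulus was shown are
attenuated multiplicatively (M = 0.7) for the remainder of the trial.
A repeated stimulus therefore arrives with 70% of its KC drive, which
drops the summed KC output below every PCT threshold: the PCT population
responds to novel stimuli only. That stimulus-unspecific novelty signal,
routed through the plastic PCT→EN synapses, is what carries the abstract
rule; everything stimulus-specific lives in KC→EN.

**Decision readout.** Behaviour is GO when
`Σ z_GO > Σ z_NOGO + R·d`, with R ~ U[−0.5, 0.5] and a bias d that grows
by 10 with every NOGO choice of the trial (reset at trial start); ties go
to NOGO, and no decision is read while total EN activity is at or below
0.1. The widening noise guarantees the bee eventually commits, with
P(GO) approaching 1/2 from below for arbitrarily unattractive options.

**Three-factor plasticity.** On a learning event with binary reward R and
baseline R_b = 2/3:

    Δw_jk = +λ_e (R − R_b) · pre · post      λ_e = 0.06   (KC→EN)
    Δw_lk = −λ_i (R − R_b) · pre · post      λ_i = 0.03   (PCT→EN)

Pre-activity is binarised at > 0. λ_e = 2λ_i (excitatory learning twice
as fast) and the binary reward with R_b = 2/3 makes extinction (R = 0)
twice as fast as acquisition (R = 1).

## Calibration of the KC output gain

The circuit only works if the PCT thresholds bracket the novel/repeated
summed KC outputs. Nothing in the architecture fixes the absolute scale
of KC output, so the package calibrates one global output gain `g` in
closed form. With unit-strength connections a KC needs at least two of
the 8 active inputs to cross b = 1.2 (one input, at most 1.05, never
does; two, at least 1.9, always do — so the binomial expectation below is
exact, not approximate). The expected raw summed output per novel
stimulus is

    E[T_raw] = n_kc · Σ_k P(Bin(8, 0.02) = k) · (k − b) ≈ 43.5

and g is set so that `g · E[T_raw]` hits a target inside the **novelty
window** `(b_s_high, b_s_low / 0.7) = (150, 171.4)` — the range in which
every PCT unit fires for a novel stimulus and none for an accommodated
repetition. The default target sits a quarter of the way into the window
(≈155) rather than at its midpoint: random wiring spreads per-stimulus
totals with a relative standard deviation of ≈14% (a handful of
two-connection KCs dominate each stimulus's total), and the two tails
fail asymmetrically. A stimulus below the window merely loses its
high-threshold novelty response (the 120-threshold unit still signals
novelty down to T = 120), while a stimulus above it leaks a PCT response
to its own repetition, actively mislabelling a matching arm as novel —
the costlier error. Unit-strength wiring (rather than scaling the
connection weights up) is forced by the patterning tasks: compound
discrimination needs KCs that fire for AB but for neither element, which
exist only while single connections stay subthreshold, and it keeps the
KC code sparse (~1% of KCs per stimulus).

The ≈14% spread is irreducible within the published architecture
(8 active inputs × Bin(8, 0.02) wiring), so roughly a third of stimuli
fall outside the window for any target. This population heterogeneity is
deliberate — it is the model's "individual bees" — and it is the main
source of the ~15–30% error mass in the transfer results. A variant with
per-stimulus divisive gain normalisation was evaluated and rejected: it
drives matching-task transfer to ~98%, well above the ~75% population
average the task is known for.

## PCT saturation

The PCT units are threshold-linear with an upper cut-off, saturating at
the drive `b_l / 0.7`, i.e. `s_max,l = b_l · 3/7` (≈51 for the low unit,
≈64 for the high ones) — the top of each unit's novelty-coding range.
The reduced model's inhibitory node is explicitly a threshold-linear
unit with a high-activity cut-off; the full model needs the same bound
because a two-odour compound roughly triples the summed KC drive and an
unbounded PCT response would then exceed the entire EN excitation,
deadlocking the patterning protocols before any learning could begin.
Saturation leaves single stimuli in the calibrated range untouched. It
can be disabled (`ModelParams(pct_saturates=False)`) for inspecting the
pure rectified-linear response.

## Credit assignment

Learning is action-credited. Only the GO subpopulation's afferent
weights ever change: the NOGO subpopulation is the fixed comparison level
against which GO drive is read out, and choices credit the channel that
produced them. Postsynaptic eligibility is binarised on the
**pre-inhibition** associative drive `Σ_j w_jk y_j` of each GO unit
rather than on the final rectified z: inhibition shapes the readout, not
the Hebbian eligibility. (With post-inhibition eligibility, an EN whose
inhibition exceeds its excitation freezes permanently — rewarded
compounds in positive patterning could never acquire, and an
over-inhibited bee could never recover.)

Where learning events happen:

- **Maze tasks** — at the arm the bee GOes into, with R = 1 if that arm
  is rewarded and R = 0 otherwise ("no reward" and "punishment" are the
  same R = 0 event under the binary rule). Entering the maze during a
  training trial carries no outcome and is not a learning event; the
  rewarded entrance repetitions of pretraining are.
- **Restrained (PER) protocols** — the sucrose reward is delivered per
  schedule regardless of behaviour. On rewarded presentations the
  excitatory CS–US update applies whether or not the model responded
  (the unconditioned stimulus elicits the response and reinforces the
  associative pathway), while the inhibitory PCT→EN update applies only
  after a self-initiated GO: it is a choice-pathway rule, and a
  restrained bee that failed to respond made no choice. Unrewarded
  presentations extinguish (R = 0, both pathways) only when the model
  responded. This split is what lets single-odour acquisition start from
  zero responders while leaving a KC→EN-lesioned model unable to acquire
  it through the PCT pathway.
- **Transfer tests** — no reward is given and all weights are frozen
  (`freeze_transfer=True`), so nothing learned after training can
  contribute to transfer performance.

## Maze state machine

A trial is: entrance (sample shown, accommodation mask recorded, GO
forced), then face an arm drawn uniformly; each NOGO sends the bee to
the *other* arm (with two arms, "choose another arm" is a deterministic
switch) and increments the bias counter; the first GO ends the trial in
that arm. If the EN floor is never cleared within 100 iterations at a
position the position resolves as NOGO; a trial exceeding 1000 NOGOs
raises `CalibrationError`. Differential/reversal trials show no entrance
stimulus (neither arm is a sample, so nothing should be accommodated)
and counterbalance arm sides across trials.

Pretraining familiarisation: 10 rewarded entries with the pretraining
stimulus Z at the entrance, then 10 rewarded forced visits to each arm.
The arms display no stimulus during familiarisation — the bee is being
habituated to the apparatus, not trained on a discrimination — so arm
visits reward travel without stimulus-evoked plasticity.

## Reduced model constants

The two-stimulus reduction uses the published sigmoid gain c = 80 and
bias constant d₀ = 1, with k (consecutive NOGOs) capped at c/d₀ − 1 so
the sigmoid gain stays positive. Open constants: novelty threshold
θ = 0.85 (anywhere in (0.7, 1.0) works — it must separate the
accommodated from the full stimulus drive), activity bounds
x_min = 0 / x_max = 10 (never binding in practice), inhibitory ceiling
w_max = 1 with initialisation at w_max/2, excitatory weight w_e = 1, and
5 rewarded pretraining presentations (the reduction needs fewer than the
full model; its bias is directly proportional to the count).

## Synthetic stimuli: what they do and do not emulate

All inputs are generated internally; there is no external data. The
stimulus model captures: distinct, consistent, non-overlapping sensory
codes per stimulus; per-bee idiosyncrasy (wiring seed and input jitter);
and within-trial repetition structure. It does not capture: realistic
olfactory/visual tuning curves or overlap between similar stimuli,
noise between repeated presentations of the same stimulus within a bee,
temporal dynamics of perception, or any navigation. Passing tests
therefore show that the *circuit computations* produce the behavioural
patterns under idealised coding assumptions — not that real sensory
statistics would support them.

## Numerical choices and problem sizes

- Determinism: every experiment is reproducible from `master_seed`;
  per-bee wiring seeds are drawn from it, and each bee's jitter and
  decision streams are independent generators keyed on its wiring seed.
- Weight updates are exact rank-one additions followed by clipping to
  [0, 1]; ties in the decision rule resolve to NOGO; KC "active" means
  strictly positive.
- The accommodation ratio test is exact to 1e−9 (it is a single
  multiplicative factor; only rounding in the two sums intervenes).
- Population sizes: the matching experiments default to 360 bees
  (60 training trials, blocks of 10, 8 transfer trials), reversal to
  200 bees × 30 trials, PER protocols to 100 bees (12 single-odour
  trials; 10 patterning blocks). The test suite runs the matching tasks
  at full scale once and uses 60–120 bees for replications, lesions and
  sweeps, sizes at which every asserted contrast is several standard
  errors wide.

## Known limitations

- **DNMTS training curve.** Transfer of difference learning lands near
  the published ~70%, but the full model's DNMTS *training* curve sits
  near chance rather than rising: bees whose training-pair stimuli fall
  outside the novelty window drift into a matched-stimulus preference
  (associative punishment of the chosen matching arm depresses that
  stimulus's weights; the weaker, accommodated stimulus then always
  looks least aversive) that the slower inhibitory pathway cannot always
  overcome. Transfer survives because it probes fresh stimuli whose
  associative weights are untouched. This is the flip side of the
  heterogeneity discussed under calibration.
- **Positive patterning suppresses nothing.** The rewarded compound is
  acquired, but responding to the elements persists: with extinction
  exactly twice acquisition and the compound presented twice per block,
  an element's KC weights gain `2 × λ_e/3` per block from the compound
  rewards and can lose at most `2λ_e/3` from its own single unrewarded
  presentation — the flux can never go negative. Element suppression
  would need a different acquisition:extinction ratio or schedule.
  Negative patterning, whose discrimination rests on the
  compound-selective KCs, is reproduced in full.
- **Single-bee behaviour is nearly deterministic** once margins exceed
  the decision noise; population spread comes almost entirely from
  wiring heterogeneity rather than from trial-to-trial stochasticity of
  individual bees.
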