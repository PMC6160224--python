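"""The reduced two-stimulus abstraction of the circuit.

Stimulus nodes S1/S2 (plus extra transfer nodes T_i with identical wiring)
drive a single novelty node I and linear GO/NOGO output nodes. I is a hard
gate: I = S * [S > theta], so with theta between the accommodated (0.7) and
full (1.0) stimulus drives it fires only for non-repeated stimuli. The
plastic inhibitory weights I->GO carry all of the sameness/difference
learning; because I is stimulus-unspecific, whatever is learned transfers
unchanged to stimuli never seen in training.

Choice is probabilistic: P(GO) = 1 / (1 + exp(-(c - k*d0) * (GO - NOGO))),
where k counts consecutive NOGO selections, so the sigmoid flattens toward
a coin flip the longer the model dithers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .maze import TrialRecord
from .params import ModelParams
from .plasticity import RewardEvent, delta_inhibitory

__all__ = ["ReducedState", "reduced_forward", "p_go", "reduced_trial",
           "pretrain_reduced"]


@dataclass
class ReducedState:
    """Weights and per-trial bookkeeping of the reduced model.

    ``w_inh`` maps node name ("GO"/"NOGO") to the plastic I->node inhibitory
    weight, clipped to [0, w_max] and initialised to half the ceiling.
    """

    params: ModelParams
    w_inh: dict = field(default_factory=dict)
    k: int = 0                     # consecutive NOGO counter
    entrance_stimulus: int | None = None

    def __post_init__(self) -> None:
        if not self.w_inh:
            half = self.params.w_max / 2.0
            self.w_inh = {"GO": half, "NOGO": half}


def reduced_forward(stimulus_index: int, repeated: bool,
                    state: ReducedState) -> tuple[float, float, float]:
    """Evaluate (I, GO, NOGO) for one stimulus presentation.

    The repeated (sample-matching) stimulus is attenuated to 0.7, which
    falls below the novelty threshold theta, silencing I and bypassing the
    plastic inhibitory pathway entirely.
    """
    p = state.params
    if stimulus_index < 1:
        raise ValueError("stimulus_index must be a positive stimulus id")
    s = p.accommodation_factor if repeated else 1.0
    i_act = s if s > p.theta else 0.0
    go = p.w_exc * s - state.w_inh["GO"] * i_act
    nogo = p.w_exc * s - state.w_inh["NOGO"] * i_act
    clip = lambda v: min(max(v, p.x_min), p.x_max)  # noqa: E731
    return clip(i_act), clip(go), clip(nogo)


def p_go(go: float, nogo: float, k: int, c: float, d0: float) -> float:
    """Probability that GO wins the behavioural readout.

    Requires c - k*d0 > 0; the factor shrinks with every consecutive NOGO,
    flattening the sigmoid so that P(GO) rises toward 1/2 even when
    GO < NOGO — the model cannot refuse forever.
    """
    gain = c - k * d0
    if gain <= 0:
        raise ValueError("c - k*d0 must be positive")
    return 1.0 / (1.0 + math.exp(-gain * (go - nogo)))


def _sample_arm(rng: np.random.Generator) -> str:
    return "left" if rng.random() < 0.5 else "right"


def reduced_trial(task: str, entrance_stimulus: int, arm_stimuli: dict,
                  state: ReducedState, rng: np.random.Generator, *,
                  rewarded_stimulus: int | None = None,
                  correct_stimulus: int | None = None,
                  learn: bool = True, bee_id: int = 0,
                  trial_index: int = 0) -> TrialRecord:
    """One reduced-model Y-maze trial.

    ``arm_stimuli`` maps "left"/"right" to stimulus ids; the arm showing
    ``entrance_stimulus`` is the repeated one. On the first GO in an arm the
    trial ends; if that arm's stimulus is the rewarded one the inhibitory
    weights onto GO depress (R = 1), otherwise they potentiate (R = 0).
    Only the chosen GO channel learns, and only when I is active, so
    matching-arm choices never move the weights.
    """
    p = state.params
    state.entrance_stimulus = entrance_stimulus
    state.k = 0
    max_k = int(p.c / p.d0) - 1

    while True:
        arm = _sample_arm(rng)
        stim = arm_stimuli[arm]
        repeated = stim == entrance_stimulus
        i_act, go, nogo = reduced_forward(stim, repeated, state)
        if rng.random() < p_go(go, nogo, state.k, p.c, p.d0):
            break
        state.k = min(state.k + 1, max_k)

    rewarded = rewarded_stimulus is not None and stim == rewarded_stimulus
    if learn and rewarded_stimulus is not None:
        reward = RewardEvent(1 if rewarded else 0, p.r_b)
        pre = 1.0 if i_act > 0 else 0.0
        dw = delta_inhibitory(pre, 1.0, reward, p.lambda_i)
        state.w_inh["GO"] = min(max(state.w_inh["GO"] + dw, 0.0), p.w_max)

    correct_stim = correct_stimulus if correct_stimulus is not None \
        else rewarded_stimulus
    return TrialRecord(
        bee_id=bee_id, trial_index=trial_index, task=task,
        entrance_stimulus=str(entrance_stimulus), first_go_arm=arm,
        first_go_stimulus=str(stim), nogo_count_total=state.k,
        correct=(stim == correct_stim) if correct_stim is not None else None,
        rewarded=rewarded,
    )


def pretrain_reduced(state: ReducedState, reps: int) -> ReducedState:
    """Familiarisation for the reduced model: ``reps`` rewarded GO
    presentations of a novel stimulus, each depressing the I->GO weight.
    The resulting attraction to novelty is proportional to ``reps``."""
    p = state.params
    reward = RewardEvent(1, p.r_b)
    for _ in range(reps):
        dw = delta_inhibitory(1.0, 1.0, reward, p.lambda_i)
        state.w_inh["GO"] = min(max(state.w_inh["GO"] + dw, 0.0), p.w_max)
    return state
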