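"""Y-maze environment: stimulus encoding and the trial state machine.

The maze has three positions — entrance, facing the left arm, facing the
right arm. The bee always enters at the entrance (GO is forced there; a bee
that refuses to enter leaves the experiment), then faces an arm drawn
uniformly at random. At each arm-facing the network reads out GO or NOGO;
NOGO sends the bee to the other arm and increments the escalating GO bias,
GO ends the trial in that arm where the trial's reward contingency applies.

Stimuli are disjoint groups of 8 input neurons. An active neuron carries a
value 1 - U[-0.05, 0.05] drawn once per bee and frozen for the whole
experiment, so stimulus representations are consistent within a bee but
differ between bees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import CalibrationError, Decision
from .params import ModelParams
from .plasticity import RewardEvent, apply_learning

__all__ = ["STIMULUS_LABELS", "StimulusLibrary", "encode_stimulus",
           "TrialSpec", "TrialRecord", "run_maze_trial"]

#: Z is the pretraining stimulus, A/B the training pair, C/D and E/F the two
#: transfer-test pairs.
STIMULUS_LABELS = ("Z", "A", "B", "C", "D", "E", "F")


@dataclass(frozen=True)
class StimulusLibrary:
    """Per-bee mapping from stimulus labels to jittered IN activity."""

    indices: dict
    values: np.ndarray
    n_in: int

    @classmethod
    def generate(cls, params: ModelParams,
                 rng: np.random.Generator) -> "StimulusLibrary":
        needed = len(STIMULUS_LABELS) * params.group_size
        if needed > params.n_in:
            raise ValueError("not enough input neurons for disjoint groups")
        indices = {
            label: np.arange(i * params.group_size,
                             (i + 1) * params.group_size)
            for i, label in enumerate(STIMULUS_LABELS)
        }
        jitter = rng.uniform(-params.jitter_half_width,
                             params.jitter_half_width, params.n_in)
        return cls(indices=indices, values=1.0 - jitter, n_in=params.n_in)


def encode_stimulus(labels, library: StimulusLibrary) -> np.ndarray:
    """IN activity vector for a set of stimulus labels.

    Compound stimuli (e.g. {"A", "B"} in patterning) activate the union of
    their groups; the groups are disjoint so activities never sum.
    """
    x = np.zeros(library.n_in)
    for label in labels:
        if label not in library.indices:
            raise KeyError(f"unknown stimulus label: {label!r}")
        idx = library.indices[label]
        x[idx] = library.values[idx]
    return x


@dataclass(frozen=True)
class TrialSpec:
    """One maze trial: what is shown where, and what pays off.

    ``rewarded_arm`` is None for unrewarded (transfer) trials;
    ``correct_arm`` defines correctness even then (match arm for DMTS,
    non-match for DNMTS). ``learn`` disables plasticity for the trial
    (transfer tests run with frozen weights). ``unrewarded_choice_learns``
    controls whether a chosen-but-unrewarded arm is an R = 0 learning event.
    """

    task: str
    entrance_stimulus: str | None
    left_arm: str
    right_arm: str
    rewarded_arm: str | None
    correct_arm: str | None = None
    learn: bool = True
    unrewarded_choice_learns: bool = True

    def arm_stimulus(self, arm: str) -> str:
        return self.left_arm if arm == "left" else self.right_arm


@dataclass
class TrialRecord:
    """Outcome of one maze trial."""

    bee_id: int
    trial_index: int
    task: str
    entrance_stimulus: str | None
    first_go_arm: str
    first_go_stimulus: str
    nogo_count_total: int
    correct: bool | None
    rewarded: bool


def run_maze_trial(model, spec: TrialSpec, rng: np.random.Generator, *,
                   bee_id: int = 0, trial_index: int = 0) -> TrialRecord:
    """Run one Y-maze trial on a full-model bee.

    Sequence: present the entrance stimulus (recording the accommodation
    mask; GO forced, no outcome, no learning), then repeatedly face a
    uniformly drawn arm and read out the decision until the first GO. The
    chosen arm's reward contingency is applied as a learning event when
    ``spec.learn`` allows it.
    """
    params = model.params
    model.state.start_trial()
    if spec.entrance_stimulus is not None:
        model.present(frozenset({spec.entrance_stimulus}), at_entrance=True)

    nogo_count = 0
    arm = "left" if rng.random() < 0.5 else "right"
    while True:
        stimulus = spec.arm_stimulus(arm)
        decision = model.run_position(frozenset({stimulus}), nogo_count, rng)
        if decision is Decision.GO:
            break
        nogo_count += 1
        if nogo_count > params.max_nogo_per_trial:
            raise CalibrationError(
                "trial exceeded the NOGO cap; the network never chose GO")
        # NOGO sends the bee to the other arm (with two arms, "choose
        # another arm" is a deterministic switch)
        arm = "right" if arm == "left" else "left"

    rewarded = spec.rewarded_arm is not None and arm == spec.rewarded_arm
    if spec.learn and spec.rewarded_arm is not None:
        if rewarded:
            apply_learning(model.weights, model.state,
                           RewardEvent(1, params.r_b), params)
        elif spec.unrewarded_choice_learns:
            apply_learning(model.weights, model.state,
                           RewardEvent(0, params.r_b), params)

    correct_arm = spec.correct_arm or spec.rewarded_arm
    return TrialRecord(
        bee_id=bee_id,
        trial_index=trial_index,
        task=spec.task,
        entrance_stimulus=spec.entrance_stimulus,
        first_go_arm=arm,
        first_go_stimulus=stimulus,
        nogo_count_total=nogo_count,
        correct=(arm == correct_arm) if correct_arm is not None else None,
        rewarded=rewarded,
    )
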