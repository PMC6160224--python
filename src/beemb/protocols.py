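"""The behavioural experiment suite.

Implements the published protocols around the circuit model: pretraining
familiarisation, DMTS/DNMTS training with unrewarded transfer tests, lesion
variants, the pretraining-repetition sweep, differential/reversal learning
in the maze, and the restrained classical-conditioning protocols (single
odour and positive/negative patterning, with GO read out as proboscis
extension).

"Models as animals": each bee is an independent :class:`~beemb.model.BeeModel`
whose IN->KC wiring seed and stimulus jitter differ, and experiments report
population statistics over many bees.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .analysis import block_performance
from .maze import TrialSpec, run_maze_trial
from .model import BeeModel
from .network import Decision, decide
from .params import ModelParams
from .plasticity import RewardEvent, apply_learning

__all__ = [
    "ExperimentConfig", "ExperimentResult", "pretrain_familiarise",
    "run_dmts_experiment", "run_transfer_test", "run_reversal_experiment",
    "run_per_single", "run_patterning", "run_pretraining_sweep",
    "run_lesion_matrix", "run_reduced_experiment",
]

#: lesion condition -> (lesion_kc_en, lesion_pct_en)
CONDITIONS = {
    "full": (False, False),
    "kc_only": (False, True),   # only KC->EN learning remains
    "pct_only": (True, False),  # only PCT->EN learning remains
    "none_learning": (True, True),
}


@dataclass(frozen=True)
class ExperimentConfig:
    """Shared knobs for the population experiments."""

    task: str = "DMTS"
    n_bees: int = 360
    n_training_trials: int = 60
    block_size: int = 10
    pretraining_reps: int = 10       # entrance reps; also reps per arm
    condition: str = "full"
    transfer_sets: tuple = (("C", "D"), ("E", "F"))
    master_seed: int = 0
    freeze_transfer: bool = True
    shuffle_trial_sets: bool = False
    unrewarded_choice_learns: bool = True
    params: ModelParams = field(default_factory=ModelParams)

    def __post_init__(self) -> None:
        if self.n_training_trials % self.block_size:
            raise ValueError("training trials must fill whole blocks")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")


@dataclass
class ExperimentResult:
    """Population curves plus the raw per-trial records."""

    task: str
    condition: str
    blocks: pd.DataFrame                 # block, mean, sem (percent correct)
    transfer_percent: dict               # per transfer set
    transfer_overall: float | None
    records: pd.DataFrame                # training trials
    transfer_records: pd.DataFrame | None
    metadata: dict

    def summary(self) -> dict:
        return {
            "task": self.task,
            "condition": self.condition,
            "block_percent": self.blocks["mean"].round(2).tolist(),
            "block_sem": self.blocks["sem"].round(3).tolist(),
            "transfer_percent": {"/".join(k): round(v, 2)
                                 for k, v in self.transfer_percent.items()},
            "transfer_overall": None if self.transfer_overall is None
            else round(self.transfer_overall, 2),
            **self.metadata,
        }


def _bee_seeds(master_seed: int, n_bees: int) -> np.ndarray:
    rng = np.random.default_rng(master_seed)
    return rng.integers(0, 2**31 - 1, size=n_bees)


def _make_bee(config: ExperimentConfig, seed: int) -> BeeModel:
    kc, pct = CONDITIONS[config.condition]
    return BeeModel(config.params, int(seed),
                    lesion_kc_en=kc, lesion_pct_en=pct)


def _decision_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), 3])


# ---------------------------------------------------------------------------
# pretraining
# ---------------------------------------------------------------------------

def pretrain_familiarise(model: BeeModel, *, reps_entrance: int = 10,
                         reps_per_arm: int = 10) -> BeeModel:
    """Familiarisation with the apparatus using the pretraining stimulus Z.

    First ``reps_entrance`` rewarded entries of the maze with Z shown at
    the entrance (GO forced — the first visit stands for the bee finding
    the feeder), then ``reps_per_arm`` rewarded forced visits to each arm.
    The arms display no stimulus during familiarisation (the bee is being
    habituated to the apparatus, not trained on a discrimination), so the
    arm visits reward travel without driving stimulus-evoked plasticity.
    Every rewarded forced GO is a learning event.
    """
    p = model.params
    reward = RewardEvent(1, p.r_b)
    for _ in range(reps_entrance):
        model.state.start_trial()
        model.present(frozenset({"Z"}), at_entrance=True)
        apply_learning(model.weights, model.state, reward, p)
    for _arm in ("left", "right"):
        for _ in range(reps_per_arm):
            model.state.start_trial()
            model.present(frozenset({"Z"}), at_entrance=True)
            model.state.start_presentation()
            model.present(frozenset(), at_entrance=False)
            apply_learning(model.weights, model.state, reward, p)
    return model


# ---------------------------------------------------------------------------
# DMTS / DNMTS
# ---------------------------------------------------------------------------

def _matching_specs(task: str, pair: tuple, *, learn: bool,
                    unrewarded_learns: bool) -> list[TrialSpec]:
    """The repeated 4-trial set: each stimulus twice at the entrance, with
    its matching arm once on each side. DMTS rewards the matching arm,
    DNMTS the other; in unrewarded transfer the same rule defines
    correctness only."""
    s1, s2 = pair
    specs = []
    for entrance, match_side in ((s1, "left"), (s1, "right"),
                                 (s2, "left"), (s2, "right")):
        other = s2 if entrance == s1 else s1
        left = entrance if match_side == "left" else other
        right = entrance if match_side == "right" else other
        target = match_side if task == "DMTS" else \
            ("right" if match_side == "left" else "left")
        specs.append(TrialSpec(
            task=task, entrance_stimulus=entrance, left_arm=left,
            right_arm=right,
            rewarded_arm=target if learn else None,
            correct_arm=target, learn=learn,
            unrewarded_choice_learns=unrewarded_learns))
    return specs


def run_transfer_test(model: BeeModel, transfer_sets, rng, *,
                      task: str, bee_id: int = 0,
                      freeze: bool = True) -> pd.DataFrame:
    """Unrewarded transfer trials on novel stimulus pairs.

    Four repetitions per set (each stimulus at the entrance, matching arm on
    each side). No reward or punishment is delivered and, by default, all
    weights stay frozen so no learning can contribute to the outcome.
    """
    records = []
    idx = 0
    for pair in transfer_sets:
        for spec in _matching_specs(task, tuple(pair), learn=not freeze,
                                    unrewarded_learns=False):
            rec = run_maze_trial(model, spec, rng, bee_id=bee_id,
                                 trial_index=idx)
            records.append({**rec.__dict__, "transfer_set": "/".join(pair)})
            idx += 1
    return pd.DataFrame(records)


def run_dmts_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Full DMTS or DNMTS population experiment.

    Per bee: pretraining familiarisation, 60 rewarded training trials
    cycling the 4-trial set on the A/B pair, then unrewarded transfer on
    each novel pair. Population curves are percent correct per 10-trial
    block with SEM over bees.
    """
    if config.task not in ("DMTS", "DNMTS"):
        raise ValueError("task must be DMTS or DNMTS")
    specs = _matching_specs(
        config.task, ("A", "B"), learn=True,
        unrewarded_learns=config.unrewarded_choice_learns)
    train_rows, transfer_rows = [], []
    for bee_id, seed in enumerate(_bee_seeds(config.master_seed,
                                             config.n_bees)):
        model = _make_bee(config, seed)
        rng = _decision_rng(seed)
        pretrain_familiarise(model, reps_entrance=config.pretraining_reps,
                             reps_per_arm=config.pretraining_reps)
        order = list(range(4))
        for t in range(config.n_training_trials):
            if config.shuffle_trial_sets and t % 4 == 0:
                rng.shuffle(order)
            spec = specs[order[t % 4]]
            rec = run_maze_trial(model, spec, rng, bee_id=bee_id,
                                 trial_index=t)
            train_rows.append(rec.__dict__)
        transfer_rows.append(run_transfer_test(
            model, config.transfer_sets, rng, task=config.task,
            bee_id=bee_id, freeze=config.freeze_transfer))

    records = pd.DataFrame(train_rows)
    transfer = pd.concat(transfer_rows, ignore_index=True)
    per_set = transfer.groupby("transfer_set")["correct"].mean() * 100.0
    return ExperimentResult(
        task=config.task,
        condition=config.condition,
        blocks=block_performance(records, config.block_size),
        transfer_percent={tuple(k.split("/")): float(v)
                          for k, v in per_set.items()},
        transfer_overall=float(transfer["correct"].mean() * 100.0),
        records=records,
        transfer_records=transfer,
        metadata={"n_bees": config.n_bees, "seed": config.master_seed,
                  "pretraining_reps": config.pretraining_reps},
    )


# ---------------------------------------------------------------------------
# differential / reversal learning
# ---------------------------------------------------------------------------

def run_reversal_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Free-flying differential conditioning with mid-experiment reversal.

    30 trials, no pretraining, no entrance stimulus (neither arm stimulus
    is a sample, so nothing is accommodated). For the first 15 trials
    choosing the arm with stimulus A is rewarded; from trial 16 the reward
    moves to B. Analysed per trial over the population, as the fraction
    choosing the currently rewarded stimulus.
    """
    n_trials = 30
    rows = []
    for bee_id, seed in enumerate(_bee_seeds(config.master_seed,
                                             config.n_bees)):
        model = _make_bee(config, seed)
        rng = _decision_rng(seed)
        for t in range(n_trials):
            rewarded_stim = "A" if t < 15 else "B"
            left, right = ("A", "B") if t % 2 == 0 else ("B", "A")
            spec = TrialSpec(
                task="DIFFERENTIAL", entrance_stimulus=None,
                left_arm=left, right_arm=right,
                rewarded_arm="left" if left == rewarded_stim else "right",
                learn=True,
                unrewarded_choice_learns=config.unrewarded_choice_learns)
            rec = run_maze_trial(model, spec, rng, bee_id=bee_id,
                                 trial_index=t)
            rows.append(rec.__dict__)
    records = pd.DataFrame(rows)
    per_trial = (records.assign(chose_a=records.first_go_stimulus == "A")
                 .groupby("trial_index")
                 .agg(percent_a=("chose_a", lambda v: 100.0 * v.mean()),
                      percent_correct=("correct",
                                       lambda v: 100.0 * v.mean()))
                 .reset_index())
    return ExperimentResult(
        task="DIFFERENTIAL", condition=config.condition, blocks=per_trial,
        transfer_percent={}, transfer_overall=None, records=records,
        transfer_records=None,
        metadata={"n_bees": config.n_bees, "seed": config.master_seed,
                  "reversal_trial": 15},
    )


# ---------------------------------------------------------------------------
# restrained (PER) protocols
# ---------------------------------------------------------------------------

def _per_presentation(model: BeeModel, labels: frozenset, rewarded: bool,
                      rng: np.random.Generator) -> bool:
    """One restrained presentation; returns True when the model responds.

    The readout is a single GO/NOGO decision (no maze, no escalating bias).
    On rewarded presentations the sucrose reward arrives regardless of the
    response: the excitatory CS-US association is driven either way, while
    the inhibitory choice pathway updates only after a self-initiated GO.
    Unrewarded presentations extinguish (R = 0, both pathways) only when
    the model actually responded.
    """
    p = model.params
    model.state.start_trial()
    model.present(labels, at_entrance=True)
    decision = decide(model.state, 0, rng, p)
    responded = decision is Decision.GO
    if rewarded:
        pathways = ("kc_en", "pct_en") if responded else ("kc_en",)
        apply_learning(model.weights, model.state, RewardEvent(1, p.r_b), p,
                       pathways=pathways)
    elif responded:
        apply_learning(model.weights, model.state, RewardEvent(0, p.r_b), p)
    return responded


def run_per_single(config: ExperimentConfig,
                   n_trials: int = 12) -> pd.DataFrame:
    """Single-odour acquisition under the proboscis-extension paradigm.

    The odour is presented once per trial and rewarded every trial
    regardless of the response; NOGO counts as a failure to respond.
    Returns the per-trial percent of bees responding.
    """
    rows = []
    for bee_id, seed in enumerate(_bee_seeds(config.master_seed,
                                             config.n_bees)):
        model = _make_bee(config, seed)
        rng = _decision_rng(seed)
        for t in range(n_trials):
            responded = _per_presentation(model, frozenset({"A"}), True, rng)
            rows.append({"bee_id": bee_id, "trial_index": t,
                         "responded": responded})
    return pd.DataFrame(rows)


def per_single_curve(records: pd.DataFrame) -> pd.DataFrame:
    return (records.groupby("trial_index")["responded"].mean().mul(100.0)
            .rename("percent_responding").reset_index())


def run_patterning(config: ExperimentConfig, polarity: str,
                   n_blocks: int = 10) -> pd.DataFrame:
    """Positive or negative patterning under the PER paradigm.

    A block holds four presentations with the compound shown twice:
    positive [A-, AB+, B-, AB+], negative [A+, AB-, B+, AB-]. The compound
    activates both stimulus groups, recruiting coincidence KCs that fire
    for AB but for neither element alone — the substrate for the nonlinear
    discrimination. Returns per-presentation records (the two AB responses
    are averaged within a block downstream).
    """
    if polarity not in ("positive", "negative"):
        raise ValueError("polarity must be 'positive' or 'negative'")
    if polarity == "positive":
        block = [({"A"}, False), ({"A", "B"}, True),
                 ({"B"}, False), ({"A", "B"}, True)]
    else:
        block = [({"A"}, True), ({"A", "B"}, False),
                 ({"B"}, True), ({"A", "B"}, False)]
    rows = []
    for bee_id, seed in enumerate(_bee_seeds(config.master_seed,
                                             config.n_bees)):
        model = _make_bee(config, seed)
        rng = _decision_rng(seed)
        for b in range(n_blocks):
            for labels, rewarded in block:
                responded = _per_presentation(model, frozenset(labels),
                                              rewarded, rng)
                rows.append({
                    "bee_id": bee_id, "block": b,
                    "stimulus": "+".join(sorted(labels)),
                    "rewarded": rewarded, "responded": responded,
                    "correct": responded == rewarded,
                })
    return pd.DataFrame(rows)


def patterning_curves(records: pd.DataFrame) -> pd.DataFrame:
    """Per-block percent responding for A, B and AB (AB averaged within
    block)."""
    return (records.groupby(["block", "stimulus"])["responded"]
            .mean().mul(100.0).rename("percent_responding").reset_index())


# ---------------------------------------------------------------------------
# pretraining sweep
# ---------------------------------------------------------------------------

def run_pretraining_sweep(config: ExperimentConfig,
                          reps_list=(0, 2, 5, 10, 20)) -> pd.DataFrame:
    """First-block bias toward the non-matching arm vs pretraining amount.

    For each pretraining count, runs pretraining plus one 10-trial block of
    the configured task under (a) full learning and (b) PCT->EN learning
    alone, and reports the first-block percent of first GOs on the
    non-matching (novel) arm. With PCT learning alone the pretraining bias
    keeps growing with repetitions; the associative pathway of the full
    model counteracts it within the block.
    """
    rows = []
    for reps in reps_list:
        for condition in ("full", "pct_only"):
            cfg = replace(config, condition=condition,
                          pretraining_reps=int(reps))
            specs = _matching_specs(cfg.task, ("A", "B"), learn=True,
                                    unrewarded_learns=True)
            novel, correct, total = 0, 0, 0
            for bee_id, seed in enumerate(_bee_seeds(cfg.master_seed,
                                                     cfg.n_bees)):
                model = _make_bee(cfg, seed)
                rng = _decision_rng(seed)
                if reps:
                    pretrain_familiarise(model, reps_entrance=int(reps),
                                         reps_per_arm=int(reps))
                for t in range(cfg.block_size):
                    rec = run_maze_trial(model, specs[t % 4], rng,
                                         bee_id=bee_id, trial_index=t)
                    novel += rec.first_go_stimulus != rec.entrance_stimulus
                    correct += bool(rec.correct)
                    total += 1
            rows.append({"pretraining_reps": int(reps),
                         "condition": condition,
                         "percent_novel_choice": 100.0 * novel / total,
                         "percent_correct": 100.0 * correct / total})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# lesion matrix for the pathway-requirement table
# ---------------------------------------------------------------------------

def run_lesion_matrix(master_seed: int = 0, *, params: ModelParams | None
                      = None, n_bees_maze: int = 360,
                      n_bees_per: int = 100,
                      n_bees_differential: int = 200) -> dict:
    """Run every task under each single-pathway condition and collect the
    success counts that feed :func:`beemb.analysis.sufficiency_report`.

    Success metrics per task: DMTS/DNMTS — transfer-trial correctness vs
    chance; single PER — final-trial vs first-trial response counts;
    patterning — final-block vs first-block responses to the rewarded
    presentations (acquisition of the contingency); differential — choices
    of the newly rewarded stimulus over the post-reversal plateau (last
    five trials), the phenomenon the protocol exists to test.
    """
    params = params or ModelParams()
    out = {}
    for pathway, condition in (("kc_en", "kc_only"), ("pct_en", "pct_only")):
        for task in ("DMTS", "DNMTS"):
            cfg = ExperimentConfig(task=task, n_bees=n_bees_maze,
                                   condition=condition,
                                   master_seed=master_seed, params=params)
            res = run_dmts_experiment(cfg)
            t = res.transfer_records
            out[(task, pathway)] = {
                "successes": int(t["correct"].sum()), "total": len(t)}

        per_cfg = ExperimentConfig(task="PER", n_bees=n_bees_per,
                                   condition=condition,
                                   master_seed=master_seed, params=params)
        rec = run_per_single(per_cfg)
        first = rec[rec.trial_index == 0]["responded"]
        last = rec[rec.trial_index == rec.trial_index.max()]["responded"]
        out[("single_per", pathway)] = {
            "successes": int(last.sum()), "total": len(last),
            "baseline_successes": int(first.sum()),
            "baseline_total": len(first)}

        for polarity in ("positive", "negative"):
            rec = run_patterning(per_cfg, polarity)
            final = rec[(rec.block == rec.block.max()) & rec.rewarded]
            first = rec[(rec.block == 0) & rec.rewarded]
            out[(f"{polarity}_patterning", pathway)] = {
                "successes": int(final["responded"].sum()),
                "total": len(final),
                "baseline_successes": int(first["responded"].sum()),
                "baseline_total": len(first)}

        diff_cfg = ExperimentConfig(task="DIFFERENTIAL",
                                    n_bees=n_bees_differential,
                                    condition=condition,
                                    master_seed=master_seed, params=params)
        res = run_reversal_experiment(diff_cfg)
        window = res.records.query("trial_index >= 25")
        out[("differential", pathway)] = {
            "successes": int(window["correct"].sum()),
            "total": len(window)}
    return out


# ---------------------------------------------------------------------------
# reduced-model population experiment
# ---------------------------------------------------------------------------

def run_reduced_experiment(config: ExperimentConfig,
                           pretraining_reps: int = 5) -> ExperimentResult:
    """DMTS/DNMTS with the reduced model, mirroring the full-model layout.

    Stimuli are abstract ids: 1/2 train, (3,4) and (5,6) are the transfer
    pairs (extra inputs with wiring identical to S1/S2). Transfer runs with
    learning disabled.
    """
    from .reduced import ReducedState, pretrain_reduced, reduced_trial

    if config.task not in ("DMTS", "DNMTS"):
        raise ValueError("task must be DMTS or DNMTS")
    p = config.params
    train_rows, transfer_rows = [], []
    schedule = [(1, "left"), (1, "right"), (2, "left"), (2, "right")]
    for bee_id, seed in enumerate(_bee_seeds(config.master_seed,
                                             config.n_bees)):
        rng = _decision_rng(seed)
        state = ReducedState(params=p)
        pretrain_reduced(state, pretraining_reps)
        for t in range(config.n_training_trials):
            entrance, match_side = schedule[t % 4]
            other = 2 if entrance == 1 else 1
            arms = {"left": entrance, "right": other} \
                if match_side == "left" else \
                {"left": other, "right": entrance}
            novel = other
            rewarded = entrance if config.task == "DMTS" else novel
            rec = reduced_trial(config.task, entrance, arms, state, rng,
                                rewarded_stimulus=rewarded,
                                bee_id=bee_id, trial_index=t)
            train_rows.append(rec.__dict__)
        idx = 0
        for pair in ((3, 4), (5, 6)):
            for entrance, match_side in [(pair[0], "left"),
                                         (pair[0], "right"),
                                         (pair[1], "left"),
                                         (pair[1], "right")]:
                other = pair[1] if entrance == pair[0] else pair[0]
                arms = {"left": entrance, "right": other} \
                    if match_side == "left" else \
                    {"left": other, "right": entrance}
                correct = entrance if config.task == "DMTS" else other
                rec = reduced_trial(config.task, entrance, arms, state, rng,
                                    correct_stimulus=correct, learn=False,
                                    bee_id=bee_id, trial_index=idx)
                transfer_rows.append(
                    {**rec.__dict__, "transfer_set": f"{pair[0]}/{pair[1]}"})
                idx += 1

    records = pd.DataFrame(train_rows)
    transfer = pd.DataFrame(transfer_rows)
    per_set = transfer.groupby("transfer_set")["correct"].mean() * 100.0
    return ExperimentResult(
        task=config.task, condition="reduced",
        blocks=block_performance(records, config.block_size),
        transfer_percent={tuple(k.split("/")): float(v)
                          for k, v in per_set.items()},
        transfer_overall=float(transfer["correct"].mean() * 100.0),
        records=records, transfer_records=transfer,
        metadata={"n_bees": config.n_bees, "model": "reduced",
                  "pretraining_reps": pretraining_reps},
    )
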