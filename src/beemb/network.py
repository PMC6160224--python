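"""Feedforward/feedback dynamics of the full mushroom-body model.

The network is a linear-threshold rate model with no membrane dynamics: each
"iteration" is one synchronous evaluation of

    y_j = gain * M_j * [sum_i c_ij x_i - b - sum_l s*_l]_+        (KC layer)
    s_l = [sum_j y_j - b_s(l)]_+                                  (PCT layer)
    z_k = [sum_j w_jk y_j - 0.5 * sum_l w_lk s_l]_+               (EN layer)

where [.]_+ is a rectifier, M_j is the sensory-accommodation factor (0.7 for
KCs that were active at the maze entrance of the current trial, 1 otherwise)
and s*_l is the PCT activity delayed by ``pct_delay`` iterations through the
KC->PCT->KC loop (zero until that many iterations have elapsed within the
current stimulus presentation).

Behavioural readout compares the summed GO and NOGO EN subpopulations: GO is
selected when sum(z_GO) > sum(z_NOGO) + R*d with R ~ U[-0.5, 0.5] and a bias
d that grows by 10 with every NOGO decision, provided total EN activity
exceeds the 0.1 decision floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .params import ModelParams

__all__ = [
    "Decision",
    "Connectivity",
    "SynapticWeights",
    "NetworkState",
    "build_connectivity",
    "kc_forward",
    "pct_forward",
    "en_forward",
    "decide",
]


class Decision(str, Enum):
    GO = "GO"
    NOGO = "NOGO"
    NONE = "NONE"  # EN activity below the decision floor: no decision yet


class CalibrationError(RuntimeError):
    """The network could not produce a decision within the iteration caps."""


@dataclass(frozen=True)
class Connectivity:
    """Fixed binary IN->KC wiring for one model bee.

    ``c`` has shape (n_in, n_kc) with entries in {0, 1}; ``seed`` identifies
    the bee variant that generated it.
    """

    c: np.ndarray
    seed: int

    @property
    def density(self) -> float:
        return float(self.c.mean())


def build_connectivity(params: ModelParams, seed: int) -> Connectivity:
    """Draw the random IN->KC wiring: each of the n_in x n_kc possible
    connections is present independently with probability ``p_in_kc``.

    The same seed always yields the same matrix; distinct seeds define the
    distinct model bees of the "models as animals" population.
    """
    if seed < 0:
        raise ValueError("seed must be non-negative")
    rng = np.random.default_rng(seed)
    c = (rng.random((params.n_in, params.n_kc)) < params.p_in_kc)
    return Connectivity(c=c.astype(np.float64), seed=seed)


@dataclass
class SynapticWeights:
    """Plastic synapses of the full model.

    ``w_kc_en`` (n_kc, n_en) are the excitatory KC->EN weights; ``w_pct_en``
    (n_pct, n_en) the inhibitory PCT->EN weights. Every entry lives in
    [0, 1]. A lesion flag freezes its matrix bit-identically for the whole
    run (the pathway stays active; only plasticity is suppressed).
    """

    w_kc_en: np.ndarray
    w_pct_en: np.ndarray
    lesion_kc_en: bool = False
    lesion_pct_en: bool = False

    @classmethod
    def initial(cls, params: ModelParams, *, lesion_kc_en: bool = False,
                lesion_pct_en: bool = False) -> "SynapticWeights":
        return cls(
            w_kc_en=np.full((params.n_kc, params.n_en), params.w_init),
            w_pct_en=np.full((params.n_pct, params.n_en), params.w_init),
            lesion_kc_en=lesion_kc_en,
            lesion_pct_en=lesion_pct_en,
        )


@dataclass
class NetworkState:
    """Instantaneous activities plus per-trial bookkeeping.

    ``entrance_mask`` marks KCs that were active (y > 0) when the entrance
    stimulus of the current trial was presented; those KCs are attenuated by
    the accommodation factor for the rest of the trial. ``s_history`` holds
    the PCT activities of the current stimulus presentation so the delayed
    KC<-PCT feedback can be read off.
    """

    x: np.ndarray
    y: np.ndarray
    s: np.ndarray
    z: np.ndarray
    entrance_mask: np.ndarray
    s_history: list = field(default_factory=list)
    iteration: int = 0

    @classmethod
    def empty(cls, params: ModelParams) -> "NetworkState":
        return cls(
            x=np.zeros(params.n_in),
            y=np.zeros(params.n_kc),
            s=np.zeros(params.n_pct),
            z=np.zeros(params.n_en),
            entrance_mask=np.zeros(params.n_kc, dtype=bool),
        )

    def start_trial(self) -> None:
        self.entrance_mask[:] = False
        self.start_presentation()

    def start_presentation(self) -> None:
        self.s_history = []
        self.iteration = 0

    def delayed_pct_sum(self, params: ModelParams) -> float:
        """Summed PCT activity ``pct_delay`` iterations ago, or 0 if the
        presentation is younger than the loop delay."""
        idx = len(self.s_history) - params.pct_delay
        if idx < 0:
            return 0.0
        return float(self.s_history[idx].sum())


def _relu(v: np.ndarray) -> np.ndarray:
    return np.maximum(v, 0.0)


def kc_forward(state: NetworkState, conn: Connectivity, params: ModelParams,
               at_entrance: bool, *, kc_drive: np.ndarray | None = None,
               pct_feedback: bool = True) -> np.ndarray:
    """One KC-layer evaluation for the stimulus in ``state.x``.

    At the maze entrance the accommodation factor M is 1 for every KC and
    the set of active KCs is recorded in ``entrance_mask``; at the arms,
    KCs flagged in the mask are attenuated by ``accommodation_factor``.
    ``kc_drive`` may carry a precomputed ``x @ c`` to avoid the matvec.
    ``pct_feedback=False`` disables the delayed inhibitory KC<-PCT term
    (used to isolate the accommodation pathway).
    """
    if np.any(state.x < 0):
        raise ValueError("IN activities must be non-negative")
    if kc_drive is None:
        kc_drive = state.x @ conn.c
    inhibition = state.delayed_pct_sum(params) if pct_feedback else 0.0
    y = _relu(kc_drive - params.b - inhibition)
    if at_entrance:
        state.entrance_mask = y > 0
    else:
        y = np.where(state.entrance_mask,
                     params.accommodation_factor * y, y)
    y = params.gain * y
    state.y = y
    return y


def pct_forward(state: NetworkState, params: ModelParams) -> np.ndarray:
    """One PCT-layer evaluation from the current KC activity.

    Each unit is threshold-linear with an upper cut-off (as the inhibitory
    node of the reduced model is described): unit l responds above its
    threshold b_l and saturates at the drive b_l / accommodation_factor —
    the top of its novelty-coding range, beyond which an accommodated
    repetition would start to leak through. The cap is what keeps compound
    stimuli (with roughly summed KC totals) from producing runaway
    inhibition at the EN layer. Unit 0 carries the low threshold (120),
    units l > 0 the high one (150); with the calibrated KC gain all units
    respond to novel but not repeated stimuli, making the population a
    novelty detector. The result is pushed onto the presentation's delay
    buffer.
    """
    total = float(state.y.sum())
    thresholds = params.pct_thresholds()
    s = _relu(total - thresholds)
    if params.pct_saturates:
        caps = thresholds / params.accommodation_factor - thresholds
        s = np.minimum(s, caps)
    state.s = s
    state.s_history.append(s)
    state.iteration += 1
    return s


def en_forward(state: NetworkState, weights: SynapticWeights,
               params: ModelParams) -> np.ndarray:
    """One EN-layer evaluation: plastic KC excitation minus 0.5-scaled
    plastic PCT inhibition, rectified. Uses the current-episode PCT
    activity (the loop delay applies only to the KC<-PCT term)."""
    if weights.w_kc_en.shape != (state.y.size, params.n_en):
        raise ValueError("KC->EN weight matrix does not match populations")
    if weights.w_pct_en.shape != (state.s.size, params.n_en):
        raise ValueError("PCT->EN weight matrix does not match populations")
    drive = state.y @ weights.w_kc_en
    inhibition = params.pct_en_scale * (state.s @ weights.w_pct_en)
    z = _relu(drive - inhibition)
    state.z = z
    return z


def go_nogo_sums(z: np.ndarray, params: ModelParams) -> tuple[float, float]:
    n_go = params.n_go
    return float(z[:n_go].sum()), float(z[n_go:].sum())


def decide(state: NetworkState, nogo_count: int, rng: np.random.Generator,
           params: ModelParams) -> Decision:
    """GO/NOGO readout with the escalating NOGO bias.

    Returns NONE while total EN activity is at or below the decision floor.
    Otherwise GO iff sum(z_GO) > sum(z_NOGO) + R*d, with d = 10 * nogo_count
    and R ~ U[-0.5, 0.5]; ties resolve to NOGO. The widening noise term
    makes P(GO) approach 1/2 from below as NOGOs accumulate, so the bee
    cannot dither forever.
    """
    if nogo_count < 0:
        raise ValueError("nogo_count must be non-negative")
    z_total = float(state.z.sum())
    if z_total <= params.decision_floor:
        return Decision.NONE
    go_sum, nogo_sum = go_nogo_sums(state.z, params)
    bias = (rng.uniform(-0.5, 0.5) * params.nogo_bias_step * nogo_count
            if nogo_count > 0 else 0.0)
    return Decision.GO if go_sum > nogo_sum + bias else Decision.NOGO
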