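"""Reward-modulated three-factor learning rules.

Both plastic pathways use the same Hebbian kernel, pre * post * (R - R_b),
with opposite signs: excitatory KC->EN synapses potentiate on reward
(dw = +lambda_e * (R - R_b) * pre * post) while inhibitory PCT->EN synapses
depress on reward (dw = -lambda_i * (R - R_b) * pre * post). With R binary
and R_b = 2/3, the unrewarded change is twice the rewarded one — extinction
twice as fast as acquisition — and lambda_e = 2 * lambda_i makes the
excitatory pathway learn twice as fast as the inhibitory one.

Credit assignment: weight changes occur when the GO action is taken (or,
in classical-conditioning protocols, when the reward itself elicits the
response). The post-active units are then the GO-subpopulation ENs whose
pre-inhibition associative drive (sum of w_jk * y_j) is positive — the
inhibitory input modulates the readout, not the Hebbian eligibility, so a
transiently silenced EN can still unlearn and recover. The NOGO
subpopulation provides the fixed comparison level and its afferent weights
are never modified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import NetworkState, SynapticWeights
from .params import ModelParams

__all__ = ["RewardEvent", "delta_excitatory", "delta_inhibitory",
           "apply_learning"]


@dataclass(frozen=True)
class RewardEvent:
    """Binary reward outcome with its baseline. r = 1 when reward is given
    and 0 in all other cases (a chosen-but-unrewarded option is r = 0)."""

    r: int
    r_b: float = 2.0 / 3.0

    def __post_init__(self) -> None:
        if self.r not in (0, 1):
            raise ValueError("reward r must be 0 or 1")
        if not 0.0 < self.r_b < 1.0:
            raise ValueError("r_b must lie in (0, 1)")


def delta_excitatory(pre_active: float, post_active: float,
                     reward: RewardEvent, lambda_e: float) -> float:
    """Excitatory weight change: +lambda_e * (R - R_b) * pre * post.

    The caller clips the updated weight to [0, 1].
    """
    return lambda_e * (reward.r - reward.r_b) * pre_active * post_active


def delta_inhibitory(pre_active: float, post_active: float,
                     reward: RewardEvent, lambda_i: float) -> float:
    """Inhibitory weight change: -lambda_i * (R - R_b) * pre * post
    (sign-flipped relative to the excitatory rule)."""
    return -lambda_i * (reward.r - reward.r_b) * pre_active * post_active


def apply_learning(weights: SynapticWeights, state: NetworkState,
                   reward: RewardEvent, params: ModelParams, *,
                   pathways: tuple[str, ...] = ("kc_en", "pct_en"),
                   ) -> SynapticWeights:
    """Apply one learning event in place and return the weights.

    Presynaptic activity is binarised at strictly > 0 (KCs for the
    excitatory matrix, PCT units for the inhibitory one). Postsynaptic
    activity is binarised on the pre-inhibition associative drive of the
    GO subpopulation — the action channel being credited. Matrices with
    their lesion flag set are left bit-identical; all updated entries are
    clipped to [0, 1]. ``pathways`` selects which rules fire
    (classical-conditioning protocols drive the excitatory pathway without
    a self-initiated GO).
    """
    post = np.zeros(params.n_en)
    go_drive = state.y @ weights.w_kc_en[:, :params.n_go]
    post[:params.n_go] = (go_drive > 0).astype(float)

    if "kc_en" in pathways and not weights.lesion_kc_en:
        pre = (state.y > 0).astype(float)
        dw = params.lambda_e * (reward.r - reward.r_b) * np.outer(pre, post)
        np.clip(weights.w_kc_en + dw, 0.0, 1.0, out=weights.w_kc_en)

    if "pct_en" in pathways and not weights.lesion_pct_en:
        pre = (state.s > 0).astype(float)
        dw = -params.lambda_i * (reward.r - reward.r_b) * np.outer(pre, post)
        np.clip(weights.w_pct_en + dw, 0.0, 1.0, out=weights.w_pct_en)

    return weights
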