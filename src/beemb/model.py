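"""One model bee: wiring, stimulus library, plastic weights and state.

A :class:`BeeModel` owns everything that is frozen per bee (random IN->KC
wiring, jittered stimulus values) and everything that evolves (synaptic
weights, trial state). Stimulus drive vectors onto the KC layer are cached
per stimulus set, since the wiring and the input values never change within
an experiment.
"""

from __future__ import annotations

import numpy as np

from .maze import StimulusLibrary, encode_stimulus
from .network import (Decision, NetworkState, SynapticWeights,
                      build_connectivity, decide, en_forward, kc_forward,
                      pct_forward)
from .params import ModelParams

__all__ = ["BeeModel"]


class BeeModel:
    """A single full-model bee identified by its connectivity seed."""

    def __init__(self, params: ModelParams, seed: int, *,
                 lesion_kc_en: bool = False, lesion_pct_en: bool = False):
        self.params = params.calibrated()
        self.seed = int(seed)
        self.conn = build_connectivity(self.params, self.seed)
        # Independent per-bee streams: stimulus jitter is frozen at
        # construction, decisions consume the run-time stream.
        self.library = StimulusLibrary.generate(
            self.params, np.random.default_rng([self.seed, 1]))
        self.weights = SynapticWeights.initial(
            self.params, lesion_kc_en=lesion_kc_en,
            lesion_pct_en=lesion_pct_en)
        self.state = NetworkState.empty(self.params)
        self._drive_cache: dict = {}
        self._x_cache: dict = {}

    # -- forward passes ----------------------------------------------------

    def _stimulus_arrays(self, labels: frozenset):
        key = labels
        if key not in self._drive_cache:
            x = encode_stimulus(labels, self.library)
            self._x_cache[key] = x
            self._drive_cache[key] = x @ self.conn.c
        return self._x_cache[key], self._drive_cache[key]

    def present(self, labels: frozenset, *, at_entrance: bool,
                pct_feedback: bool = True) -> NetworkState:
        """One synchronous network evaluation of a stimulus set."""
        x, drive = self._stimulus_arrays(frozenset(labels))
        self.state.x = x
        kc_forward(self.state, self.conn, self.params, at_entrance,
                   kc_drive=drive, pct_feedback=pct_feedback)
        pct_forward(self.state, self.params)
        en_forward(self.state, self.weights, self.params)
        return self.state

    def run_position(self, labels: frozenset, nogo_count: int,
                     rng: np.random.Generator) -> Decision:
        """Iterate the network at one maze position until it commits.

        Each iteration re-evaluates the layers (the delayed KC<-PCT loop
        term can change the picture after ``pct_delay`` iterations) and
        attempts a readout. If the EN floor is never cleared within the
        per-position iteration cap the position resolves as NOGO.
        """
        self.state.start_presentation()
        for _ in range(self.params.max_iter_per_position):
            self.present(labels, at_entrance=False)
            decision = decide(self.state, nogo_count, rng, self.params)
            if decision is not Decision.NONE:
                return decision
        return Decision.NOGO

    # -- measurements ------------------------------------------------------

    def summed_kc_output(self, labels: frozenset, *, at_entrance: bool,
                         pct_feedback: bool = True) -> float:
        self.state.start_presentation()
        x, drive = self._stimulus_arrays(frozenset(labels))
        self.state.x = x
        y = kc_forward(self.state, self.conn, self.params, at_entrance,
                       kc_drive=drive, pct_feedback=pct_feedback)
        return float(y.sum())

    def active_kc_count(self, labels: frozenset) -> int:
        self.state.start_trial()
        self.present(frozenset(labels), at_entrance=True)
        return int((self.state.y > 0).sum())
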