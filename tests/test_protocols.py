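"""Experiment protocols: pretraining, maze populations, PER battery."""

import numpy as np
import pytest

from beemb import BeeModel, ExperimentConfig, pretrain_familiarise
from beemb.protocols import (per_single_curve, patterning_curves,
                             run_dmts_experiment, run_patterning,
                             run_per_single, run_reduced_experiment,
                             run_reversal_experiment)


class TestPretraining:
    def test_potentiation_arithmetic_on_pretraining_stimulus(self, params):
        """Ten rewarded entrance repetitions move each Z-driven KC's GO
        weights by +0.02 apiece; arm visits (no stimulus) add nothing."""
        model = BeeModel(params, 6)
        model.state.start_trial()
        z_active = model.present(frozenset({"Z"}), at_entrance=True).y > 0
        pretrain_familiarise(model)
        w = model.weights.w_kc_en
        assert np.allclose(w[z_active][:, :params.n_go], 0.5 + 10 * 0.02)
        assert np.allclose(w[~z_active], 0.5)
        assert np.allclose(w[:, params.n_go:], 0.5)

    def test_pct_bias_from_entrance_novelty(self, params):
        """Each rewarded entry with the novel pretraining stimulus releases
        PCT->GO inhibition by 0.01 for the PCT units it drives."""
        model = BeeModel(params, 8)
        model.state.start_trial()
        s = model.present(frozenset({"Z"}), at_entrance=True).s
        pretrain_familiarise(model)
        w = model.weights.w_pct_en
        for l in range(params.n_pct):
            expect = 0.5 - 0.1 if s[l] > 0 else 0.5
            assert w[l, :params.n_go] == pytest.approx(expect)
        assert np.all(w[:, params.n_go:] == 0.5)

    def test_fully_lesioned_pretraining_is_a_no_op(self, params):
        model = BeeModel(params, 6, lesion_kc_en=True, lesion_pct_en=True)
        pretrain_familiarise(model)
        assert np.all(model.weights.w_kc_en == 0.5)
        assert np.all(model.weights.w_pct_en == 0.5)


@pytest.fixture(scope="module")
def small_dmts():
    return run_dmts_experiment(
        ExperimentConfig(task="DMTS", n_bees=20, master_seed=11))


@pytest.fixture(scope="module")
def reversal():
    return run_reversal_experiment(
        ExperimentConfig(n_bees=60, master_seed=13))


class TestMatchingExperiments:
    def test_result_shapes(self, small_dmts):
        assert len(small_dmts.blocks) == 6
        assert len(small_dmts.records) == 20 * 60
        assert len(small_dmts.transfer_records) == 20 * 8
        assert set(small_dmts.transfer_percent) == {("C", "D"), ("E", "F")}

    def test_acquisition_direction(self, small_dmts):
        """DMTS starts at or below chance (pretraining biases the bee
        toward the novel, i.e. wrong, arm) and improves with training."""
        means = small_dmts.blocks["mean"]
        assert means.iloc[0] < 60
        assert means.iloc[-1] > means.iloc[0]

    def test_reproducible_for_identical_seed(self, small_dmts):
        again = run_dmts_experiment(
            ExperimentConfig(task="DMTS", n_bees=20, master_seed=11))
        assert again.transfer_overall == small_dmts.transfer_overall
        assert list(again.blocks["mean"]) == list(small_dmts.blocks["mean"])

    def test_reduced_and_full_agree_on_direction(self, small_dmts):
        """The reduced abstraction shows the same qualitative behaviour:
        above-chance transfer for both task rules."""
        for task in ("DMTS", "DNMTS"):
            res = run_reduced_experiment(
                ExperimentConfig(task=task, n_bees=40, master_seed=11))
            assert res.transfer_overall > 55
        assert small_dmts.transfer_overall > 55


class TestReversal:
    def test_preference_rises_then_reverses(self, reversal):
        pa = reversal.blocks["percent_a"]
        early = pa.iloc[:3].mean()
        pre = pa.iloc[11:15].mean()
        post = pa.iloc[26:30].mean()
        assert pre > early + 15          # acquisition of the A preference
        assert post < 50 < pre           # collapse and reversal to B

    def test_lesioned_population_stays_at_chance(self):
        res = run_reversal_experiment(ExperimentConfig(
            n_bees=60, master_seed=13, condition="none_learning"))
        pa = res.blocks["percent_a"]
        assert abs(pa.iloc[11:15].mean() - 50) < 15
        assert abs(pa.iloc[26:30].mean() - 50) < 15


class TestPER:
    def test_single_odour_acquisition_is_rapid_and_monotone(self):
        rec = run_per_single(ExperimentConfig(n_bees=40, master_seed=7))
        curve = per_single_curve(rec)["percent_responding"]
        assert curve.iloc[0] < 20            # naive bees rarely respond
        assert curve.iloc[3] > 80            # acquisition within few trials
        assert all(b >= a - 5 for a, b in zip(curve, curve[1:]))

    def test_negative_patterning_discriminates_compound(self):
        """Trained on A+, B+, AB-: responses to the elements stay high
        while the compound response is suppressed."""
        rec = run_patterning(
            ExperimentConfig(n_bees=40, master_seed=7), "negative")
        last = patterning_curves(rec)
        final = last[last.block == last.block.max()].set_index("stimulus")
        assert final.loc["A", "percent_responding"] > 80
        assert final.loc["B", "percent_responding"] > 80
        assert final.loc["A+B", "percent_responding"] < 50

    def test_positive_patterning_acquires_the_compound(self):
        rec = run_patterning(
            ExperimentConfig(n_bees=40, master_seed=7), "positive")
        last = patterning_curves(rec)
        final = last[last.block == last.block.max()].set_index("stimulus")
        assert final.loc["A+B", "percent_responding"] > 80

    def test_block_layout_presents_compound_twice(self):
        rec = run_patterning(
            ExperimentConfig(n_bees=2, master_seed=7), "positive",
            n_blocks=3)
        per_block = rec[rec.bee_id == 0].groupby(["block", "stimulus"])
        counts = per_block.size().unstack()
        assert (counts["A+B"] == 2).all()
        assert (counts["A"] == 1).all() and (counts["B"] == 1).all()
        assert not rec[rec.stimulus != "A+B"].rewarded.any()
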