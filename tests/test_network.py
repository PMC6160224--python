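"""Layer arithmetic, connectivity statistics and the decision readout."""

import math

import numpy as np
import pytest
from scipy import stats

from beemb import (BeeModel, Decision, ModelParams, NetworkState,
                   SynapticWeights, build_connectivity, decide, en_forward,
                   kc_forward, pct_forward)


# ---------------------------------------------------------------------------
# connectivity
# ---------------------------------------------------------------------------

class TestConnectivity:
    def test_density_matches_binomial_expectation(self, params):
        """Non-zero count within 3 sigma of n_in * n_kc * p."""
        n = params.n_in * params.n_kc
        expect = n * params.p_in_kc
        sigma = math.sqrt(n * params.p_in_kc * (1 - params.p_in_kc))
        counts = [build_connectivity(params, seed).c.sum()
                  for seed in range(5)]
        assert abs(np.mean(counts) - expect) < 3 * sigma / math.sqrt(5)
        for c in counts:
            assert abs(c - expect) < 3 * sigma

    def test_zero_probability_gives_empty_matrix(self):
        p = ModelParams(p_in_kc=0.0, kc_gain=1.0)
        assert build_connectivity(p, 3).c.sum() == 0

    def test_seed_determinism_and_bee_individuality(self, params):
        a = build_connectivity(params, 11)
        b = build_connectivity(params, 11)
        c = build_connectivity(params, 12)
        assert np.array_equal(a.c, b.c)
        assert not np.array_equal(a.c, c.c)

    def test_negative_seed_rejected(self, params):
        with pytest.raises(ValueError):
            build_connectivity(params, -1)


# ---------------------------------------------------------------------------
# KC layer
# ---------------------------------------------------------------------------

def _state_for(params):
    return NetworkState.empty(params)


def _single_kc_setup(unit_params, drive_inputs):
    """One KC wired to len(drive_inputs) input neurons carrying them."""
    p = unit_params
    conn = np.zeros((p.n_in, p.n_kc))
    state = _state_for(p)
    for i, v in enumerate(drive_inputs):
        conn[i, 0] = 1.0
        state.x[i] = v
    from beemb.network import Connectivity
    return state, Connectivity(c=conn, seed=0)


class TestKCForward:
    def test_single_connection_below_threshold(self, unit_params):
        state, conn = _single_kc_setup(unit_params, [1.0])
        y = kc_forward(state, conn, unit_params, at_entrance=True)
        assert y[0] == 0.0

    def test_two_connections_give_rectified_drive(self, unit_params):
        state, conn = _single_kc_setup(unit_params, [1.0, 1.0])
        y = kc_forward(state, conn, unit_params, at_entrance=True)
        assert y[0] == pytest.approx(2.0 - unit_params.b)  # 0.8

    def test_accommodation_scales_entrance_active_kcs(self, unit_params):
        state, conn = _single_kc_setup(unit_params, [1.0, 1.0])
        y_ent = kc_forward(state, conn, unit_params, at_entrance=True)
        y_arm = kc_forward(state, conn, unit_params, at_entrance=False)
        assert y_arm[0] == pytest.approx(0.7 * y_ent[0])  # 0.56
        assert y_arm[0] == pytest.approx(0.56)

    def test_kcs_inactive_at_entrance_not_accommodated(self, unit_params):
        state, conn = _single_kc_setup(unit_params, [1.0, 1.0])
        state.x[:] = 0.0
        kc_forward(state, conn, unit_params, at_entrance=True)
        state.x[0] = state.x[1] = 1.0
        y_arm = kc_forward(state, conn, unit_params, at_entrance=False)
        assert y_arm[0] == pytest.approx(0.8)

    def test_negative_input_rejected(self, unit_params):
        state, conn = _single_kc_setup(unit_params, [1.0])
        state.x[0] = -0.1
        with pytest.raises(ValueError):
            kc_forward(state, conn, unit_params, at_entrance=True)


class TestPCTForward:
    @pytest.mark.parametrize("total,expected", [
        (0.0, [0, 0, 0, 0, 0, 0]),
        (160.0, [40, 10, 10, 10, 10, 10]),
        (126.0, [6, 0, 0, 0, 0, 0]),     # only the low-threshold unit
    ])
    def test_threshold_arithmetic(self, unit_params, total, expected):
        state = _state_for(unit_params)
        state.y = np.zeros(unit_params.n_kc)
        state.y[0] = total
        s = pct_forward(state, unit_params)
        assert s == pytest.approx(expected)

    def test_saturation_caps_each_unit_at_its_novelty_range(self):
        """Above drive b_l / 0.7 a unit's response saturates; without the
        cut-off the response is the unbounded rectified drive."""
        p_sat = ModelParams(kc_gain=1.0)
        p_lin = ModelParams(kc_gain=1.0, pct_saturates=False)
        state = _state_for(p_sat)
        state.y = np.zeros(p_sat.n_kc)
        state.y[0] = 400.0
        s = pct_forward(state, p_sat)
        caps = [120 * 3 / 7] + [150 * 3 / 7] * 5
        assert s == pytest.approx(caps)
        state2 = _state_for(p_lin)
        state2.y = np.zeros(p_lin.n_kc)
        state2.y[0] = 180.0
        assert pct_forward(state2, p_lin) == pytest.approx(
            [60, 30, 30, 30, 30, 30])

    def test_novelty_detection_with_calibrated_gain(self, params):
        """High-threshold units respond to a novel stimulus but not to the
        same stimulus repeated (accommodated), for typical bees."""
        hits_novel, hits_repeated = 0, 0
        n = 30
        for seed in range(n):
            m = BeeModel(params, seed)
            m.state.start_trial()
            st = m.present(frozenset({"A"}), at_entrance=True)
            novel_high = st.s[1:].sum()
            st = m.present(frozenset({"A"}), at_entrance=False)
            rep_high = st.s[1:].sum()
            hits_novel += novel_high > 0
            hits_repeated += rep_high > 0
        # connectivity draws spread summed KC output around the calibration
        # target, so the property is statistical over bees, not per-bee
        assert hits_novel >= 0.45 * n
        assert hits_repeated <= 0.15 * n


class TestENForward:
    def test_zero_weights_silence_output(self, unit_params):
        p = unit_params
        state = _state_for(p)
        state.y = np.ones(p.n_kc)
        w = SynapticWeights.initial(p)
        w.w_kc_en[:] = 0.0
        z = en_forward(state, w, p)
        assert np.all(z == 0)

    def test_single_kc_drive(self, unit_params):
        p = unit_params
        state = _state_for(p)
        state.y[0] = 0.8
        w = SynapticWeights.initial(p)
        w.w_kc_en[:] = 0.0
        w.w_kc_en[0, 0] = 0.5
        w.w_pct_en[:] = 0.0
        z = en_forward(state, w, p)
        assert z[0] == pytest.approx(0.4)

    def test_pct_inhibition_with_half_scale(self, unit_params):
        p = unit_params
        state = _state_for(p)
        state.y[0] = 0.8
        state.s[0] = 30.0
        w = SynapticWeights.initial(p)
        w.w_kc_en[:] = 0.0
        w.w_kc_en[0, 0] = 0.5
        w.w_pct_en[:] = 0.0
        w.w_pct_en[0, 0] = 0.1
        z = en_forward(state, w, p)
        assert z[0] == pytest.approx(max(0.0, 0.4 - 0.5 * 3.0))
        assert z[0] == 0.0

    def test_dimension_mismatch_raises(self, unit_params):
        p = unit_params
        state = _state_for(p)
        w = SynapticWeights.initial(p)
        w.w_kc_en = w.w_kc_en[:-1]
        with pytest.raises(ValueError):
            en_forward(state, w, p)


# ---------------------------------------------------------------------------
# decision readout
# ---------------------------------------------------------------------------

class TestDecide:
    def _state(self, params, go, nogo):
        state = _state_for(params)
        n_go = params.n_go
        state.z[:n_go] = go / n_go
        state.z[n_go:] = nogo / n_go
        return state

    def test_below_floor_returns_none(self, unit_params, rng):
        state = self._state(unit_params, 0.05, 0.04)
        assert decide(state, 0, rng, unit_params) is Decision.NONE

    def test_zero_bias_strict_inequality(self, unit_params, rng):
        state = self._state(unit_params, 0.3, 0.2)
        for _ in range(20):
            assert decide(state, 0, rng, unit_params) is Decision.GO
        tie = self._state(unit_params, 0.3, 0.3)
        assert decide(tie, 0, rng, unit_params) is Decision.NOGO

    def test_go_probability_matches_uniform_cdf(self, unit_params):
        """P(GO) = P(R * 10 * n < margin) with R ~ U[-0.5, 0.5]:
        margin 2.0, one NOGO -> 0.7. Monte-Carlo against closed form."""
        state = self._state(unit_params, 2.2, 0.2)
        rng = np.random.default_rng(99)
        n = 100_000
        gos = sum(decide(state, 1, rng, unit_params) is Decision.GO
                  for _ in range(n))
        p_hat = gos / n
        sigma = math.sqrt(0.7 * 0.3 / n)
        assert abs(p_hat - 0.7) < 3 * sigma

    def test_go_probability_nondecreasing_in_nogo_count(self, unit_params):
        """When GO trails NOGO, escalating bias raises P(GO) toward 1/2."""
        state = self._state(unit_params, 0.2, 2.2)
        margin = -2.0
        p_theory = [0.0 if n == 0 else
                    min(1.0, max(0.0, 0.5 + margin /
                                 (unit_params.nogo_bias_step * n)))
                    for n in range(6)]
        assert all(b >= a for a, b in zip(p_theory, p_theory[1:]))
        rng = np.random.default_rng(5)
        for n, expect in [(1, 0.3), (2, 0.4)]:
            gos = sum(decide(state, n, rng, unit_params) is Decision.GO
                      for _ in range(40_000))
            assert abs(gos / 40_000 - expect) < 0.01


# ---------------------------------------------------------------------------
# sparse coding
# ---------------------------------------------------------------------------

def test_sparse_kc_activation_matches_binomial_oracle(params):
    """Expected active-KC count per stimulus equals
    n_kc * P(Bin(group_size, p) >= k_min) with k_min the least connection
    count whose drive clears the threshold; the fraction is order 1e-2."""
    g, p_conn = params.group_size, params.p_in_kc
    k_min = math.ceil(params.b)  # unit-strength inputs: k - b > 0 <=> k >= 2
    expect = params.n_kc * (1.0 - stats.binom.cdf(k_min - 1, g, p_conn))
    per_kc = 1.0 - stats.binom.cdf(k_min - 1, g, p_conn)
    sigma = math.sqrt(params.n_kc * per_kc * (1 - per_kc))
    n_bees = 20
    counts = [BeeModel(params, seed).active_kc_count({"A"})
              for seed in range(n_bees)]
    assert abs(np.mean(counts) - expect) < 3 * sigma / math.sqrt(n_bees)
    assert expect / params.n_kc < 0.05


def test_compound_stimulus_recruits_coincidence_kcs(params):
    """Some KCs fire for the AB compound but for neither element alone:
    count matches n_kc * P(one connection to each group)."""
    g, pc = params.group_size, params.p_in_kc
    p1 = g * pc * (1 - pc) ** (g - 1)
    expect = params.n_kc * p1 * p1
    sigma = math.sqrt(params.n_kc * p1 * p1 * (1 - p1 * p1))
    counts = []
    for seed in range(20):
        m = BeeModel(params, seed)
        m.state.start_trial()
        ab = m.present(frozenset({"A", "B"}), at_entrance=True).y > 0
        m.state.start_trial()
        a = m.present(frozenset({"A"}), at_entrance=True).y > 0
        m.state.start_trial()
        b = m.present(frozenset({"B"}), at_entrance=True).y > 0
        counts.append(int((ab & ~a & ~b).sum()))
    assert all(c > 0 for c in counts)
    assert abs(np.mean(counts) - expect) < 3 * sigma / math.sqrt(20)
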