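"""Unit and property tests of the three-pathway network and its plasticity."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bgopto import model as md
from bgopto.model import LearningParams, ModelState, PolicyParams


def zeroed(n_states=5, n_actions=4) -> ModelState:
    ms = ModelState.initial(n_states, n_actions)
    ms.w_d1[:] = 0
    ms.w_d2[:] = 0
    ms.beta_d1[:] = 0
    ms.beta_d2[:] = 0
    return ms


class TestPathwayInput:
    def test_zero_network_gives_zero_support(self):
        ms = zeroed()
        assert np.all(md.pathway_input(ms, "D1", 2) == 0)
        assert np.all(md.pathway_input(ms, "D2", 0) == 0)

    def test_direct_sum_of_weight_and_bias(self):
        ms = zeroed()
        ms.w_d1[1, 3] = 0.3
        ms.beta_d1[3] = -0.1
        s = md.pathway_input(ms, "D1", 1)
        assert s[3] == pytest.approx(0.2)
        assert np.all(s[:3] == 0)

    def test_matches_explicit_loop_oracle(self):
        rng = np.random.default_rng(0)
        ms = zeroed()
        ms.w_d1[:] = rng.normal(size=(5, 4))
        ms.beta_d1[:] = rng.normal(size=4)
        for state in range(5):
            o = np.eye(5)[state]
            expected = [
                ms.beta_d1[j] + sum(o[i] * ms.w_d1[i, j] for i in range(5))
                for j in range(4)
            ]
            np.testing.assert_allclose(md.pathway_input(ms, "D1", state), expected)

    def test_bad_state_raises(self, fresh_model):
        with pytest.raises(IndexError):
            md.pathway_input(fresh_model, "D1", 5)
        with pytest.raises(ValueError):
            md.pathway_input(fresh_model, "D3", 0)


class TestActionActivation:
    def test_equal_pathways_cancel(self):
        ms = zeroed()
        ms.w_d1[:] = ms.w_d2[:] = 0.7
        ms.beta_d1[:] = ms.beta_d2[:] = -0.2
        assert np.all(md.action_activation(ms, 0) == 0)

    def test_subtraction_oracle(self):
        rng = np.random.default_rng(1)
        ms = zeroed(2, 2)
        ms.w_d1[:] = rng.normal(size=(2, 2))
        ms.w_d2[:] = rng.normal(size=(2, 2))
        ms.beta_d1[:] = rng.normal(size=2)
        ms.beta_d2[:] = rng.normal(size=2)
        a = md.action_activation(ms, 1)
        expected = md.pathway_input(ms, "D1", 1) - md.pathway_input(ms, "D2", 1)
        np.testing.assert_array_equal(a, expected)
        # the (1, 0) vs (0, 1) pattern gives (1, -1)
        ms.w_d1[:] = [[0, 0], [1, 0]]
        ms.w_d2[:] = [[0, 0], [0, 1]]
        ms.beta_d1[:] = ms.beta_d2[:] = 0
        np.testing.assert_array_equal(md.action_activation(ms, 1), [1, -1])


class TestSoftmaxPolicy:
    def test_symmetry(self, pp):
        np.testing.assert_allclose(md.softmax_policy(np.zeros(2), pp), [0.5, 0.5])

    def test_closed_form_two_actions(self, pp):
        p = md.softmax_policy(np.array([1.0, 0.0]), pp)
        e2 = np.exp(2.0)
        np.testing.assert_allclose(p, [e2 / (1 + e2), 1 / (1 + e2)])

    def test_empty_eligible_rejected(self):
        with pytest.raises(ValueError):
            PolicyParams(eligible_actions=())

    def test_eligible_subset_only(self):
        pp = PolicyParams(eligible_actions=(0, 1))
        p = md.softmax_policy(np.array([0.0, 0.0, 99.0, 99.0]), pp)
        assert p.shape == (2,)
        np.testing.assert_allclose(p, [0.5, 0.5])

    @given(
        a=st.lists(st.floats(-50, 50), min_size=2, max_size=6),
        c=st.floats(-100, 100),
        gain=st.floats(0.1, 10),
    )
    def test_normalisation_and_shift_invariance(self, a, c, gain):
        a = np.asarray(a)
        pp = PolicyParams(gain=gain, eligible_actions=tuple(range(a.size)))
        p = md.softmax_policy(a, pp)
        assert abs(p.sum() - 1.0) < 1e-12
        assert np.all(p > 0) and np.all(p < 1 + 1e-12)
        np.testing.assert_allclose(p, md.softmax_policy(a + c, pp), atol=1e-12)

    @given(a=st.lists(st.floats(-5, 5), min_size=2, max_size=5), idx=st.integers(0, 4))
    def test_monotone_in_own_activation(self, a, idx):
        a = np.asarray(a)
        idx = idx % a.size
        pp = PolicyParams(eligible_actions=tuple(range(a.size)))
        p0 = md.softmax_policy(a, pp)
        a2 = a.copy()
        a2[idx] += 0.5
        p1 = md.softmax_policy(a2, pp)
        assert p1[idx] > p0[idx]


class TestSelectAction:
    def test_degenerate_distribution(self, rng):
        assert all(md.select_action(np.array([1.0, 0.0]), rng) == 0 for _ in range(100))

    def test_empirical_frequency(self, rng):
        draws = [md.select_action(np.array([0.5, 0.5]), rng) for _ in range(10_000)]
        freq0 = draws.count(0) / 10_000
        assert abs(freq0 - 0.5) < 0.015  # 3 sigma binomial bound

    def test_deterministic_under_seeding(self):
        p = np.array([0.3, 0.7])
        s1 = [md.select_action(p, np.random.default_rng(7)) for _ in range(1)]
        a = np.random.default_rng(7)
        b = np.random.default_rng(7)
        assert [md.select_action(p, a) for _ in range(50)] == [
            md.select_action(p, b) for _ in range(50)
        ]
        assert s1[0] in (0, 1)

    def test_malformed_p_rejected(self, rng):
        with pytest.raises(ValueError):
            md.select_action(np.array([0.5, 0.2]), rng)


class TestRewardPrediction:
    def test_fresh_model_predicts_zero(self, fresh_model):
        assert md.predict_reward(fresh_model, 0, 0) == 0.0

    def test_invalid_indices(self, fresh_model):
        with pytest.raises(IndexError):
            md.predict_reward(fresh_model, 0, 4)

    def test_converges_to_bernoulli_mean(self, fresh_model, lp, rng):
        # stochastic-approximation fixed point of the delta rule on Bernoulli(0.75)
        for _ in range(2000):
            r = 1.0 if rng.random() < 0.75 else 0.0
            delta = md.compute_rpe(md.predict_reward(fresh_model, 0, 1), r)
            md.update_rp(fresh_model, lp, 0, 1, delta)
        assert md.predict_reward(fresh_model, 0, 1) == pytest.approx(0.75, abs=0.05)

    def test_update_locality(self, fresh_model, lp):
        md.update_rp(fresh_model, lp, 2, 1, 1.0)
        expected = np.zeros((5, 4))
        expected[2, 1] = lp.alpha_rp
        np.testing.assert_array_equal(fresh_model.rp_pred, expected)


class TestRPE:
    @pytest.mark.parametrize(
        "predicted,actual,expected", [(0.0, 1.0, 1.0), (1.0, 1.0, 0.0), (0.8, 1.0, 0.2)]
    )
    def test_difference(self, predicted, actual, expected):
        assert md.compute_rpe(predicted, actual) == pytest.approx(expected)


class TestUpdateActor:
    def test_zero_rpe_is_a_no_op(self, fresh_model, lp):
        before = fresh_model.copy()
        md.update_actor(fresh_model, lp, 0, 1, 0.0, eligible=(0, 1))
        np.testing.assert_array_equal(fresh_model.w_d1, before.w_d1)
        np.testing.assert_array_equal(fresh_model.w_d2, before.w_d2)
        np.testing.assert_array_equal(fresh_model.traces_d1.p_joint, before.traces_d1.p_joint)

    def test_positive_rpe_strengthens_coactive_d1_weight(self, fresh_model, lp):
        ws = [fresh_model.w_d1[0, 1]]
        for _ in range(3):  # strictly increasing until trace saturation
            md.update_actor(fresh_model, lp, 0, 1, 1.0, eligible=(0, 1))
            ws.append(fresh_model.w_d1[0, 1])
        assert all(b > a for a, b in zip(ws, ws[1:]))

    def test_negative_rpe_sign_routing(self, fresh_model, lp):
        w1_before = fresh_model.w_d1[0, 1]
        w2_before = fresh_model.w_d2[0, 1]
        md.update_actor(fresh_model, lp, 0, 1, -1.0, eligible=(0, 1))
        assert fresh_model.w_d1[0, 1] < w1_before
        assert fresh_model.w_d2[0, 1] > w2_before

    def test_rpe_magnitude_scales_update(self, lp):
        big = ModelState.initial(2, 2)
        small = ModelState.initial(2, 2)
        md.update_actor(big, lp, 0, 0, 1.0, eligible=(0, 1))
        md.update_actor(small, lp, 0, 0, 0.1, eligible=(0, 1))
        assert big.w_d1[0, 0] > small.w_d1[0, 0] > 0

    @given(
        steps=st.lists(
            st.tuples(
                st.integers(0, 4),                    # state
                st.integers(0, 1),                    # selected among eligible
                st.floats(-2, 2, allow_nan=False),    # RPE
            ),
            min_size=1,
            max_size=30,
        )
    )
    def test_weights_always_derived_from_traces(self, steps):
        ms = ModelState.initial(5, 4)
        lp = LearningParams()
        for state, action, delta in steps:
            md.update_actor(ms, lp, state, action, delta, eligible=(0, 1))
        for tr, w, beta in (
            (ms.traces_d1, ms.w_d1, ms.beta_d1),
            (ms.traces_d2, ms.w_d2, ms.beta_d2),
        ):
            np.testing.assert_allclose(
                w, np.log(tr.p_joint / np.outer(tr.p_pre, tr.p_post)), atol=1e-12
            )
            np.testing.assert_allclose(beta, np.log(tr.p_post), atol=1e-12)
            assert np.all(tr.p_pre >= lp.epsilon) and np.all(tr.p_pre <= 1)
            assert np.all(tr.p_joint >= lp.epsilon) and np.all(tr.p_joint <= 1)


class TestUpdateRP:
    def test_one_step_delta_rule(self):
        lp = LearningParams(alpha_actor=0.2, alpha_rp=0.1)
        ms = ModelState.initial(1, 2)
        md.update_rp(ms, lp, 0, 0, 1.0)
        assert ms.rp_pred[0, 0] == pytest.approx(0.1)

    def test_floored_at_zero(self):
        lp = LearningParams(alpha_actor=0.2, alpha_rp=0.1)
        ms = ModelState.initial(1, 2)
        ms.rp_pred[0, 0] = 0.05
        md.update_rp(ms, lp, 0, 0, -1.0)
        assert ms.rp_pred[0, 0] == 0.0

    def test_slow_pathway_invariant_enforced(self):
        with pytest.raises(ValueError):
            LearningParams(alpha_actor=0.05, alpha_rp=0.05)


class TestSerialization:
    def test_roundtrip_preserves_state(self, fresh_model, lp, tmp_path):
        rng = np.random.default_rng(3)
        for _ in range(10):
            md.update_actor(fresh_model, lp, rng.integers(5), rng.integers(2),
                            rng.normal(), eligible=(0, 1))
            md.update_rp(fresh_model, lp, rng.integers(5), rng.integers(2), rng.normal())
        path = tmp_path / "ckpt.json"
        md.save_checkpoint(fresh_model, path, rng=rng)
        loaded, rng_state = md.load_checkpoint(path)
        np.testing.assert_allclose(loaded.w_d1, fresh_model.w_d1)
        np.testing.assert_allclose(loaded.rp_pred, fresh_model.rp_pred)
        np.testing.assert_allclose(loaded.traces_d2.p_joint, fresh_model.traces_d2.p_joint)
        assert rng_state is not None
        r2 = np.random.default_rng()
        r2.bit_generator.state = rng_state
        assert r2.random() == rng.random()
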