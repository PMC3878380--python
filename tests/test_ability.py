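"""Expertise-learning rules: judgments, conjugate updates, model family."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from expertrack import ability
from expertrack.ability import (
    AbilityBelief,
    WeightedUpdateParams,
    beta_posterior_update,
    judge_evidence,
    judge_simulation,
    rl_ability_update,
    run_learner,
)
from expertrack.task import AGENT_BET


def counting_oracle(judgment_weight_stream):
    """Brute-force pseudo-count replay: Beta(1+sum wg, 1+sum w(1-g)) means."""
    s, f = 1.0, 1.0
    means = []
    for g, w in judgment_weight_stream:
        s += w * g
        f += w * (1 - g)
        means.append(s / (s + f))
    return means


class TestJudgments:
    @pytest.mark.parametrize("c,expected", [(1, 1), (0, 0)])
    def test_evidence_judgment_equals_correctness(self, c, expected):
        j = judge_evidence(c)
        assert j.g == expected and j.slot == "feedback"

    @pytest.mark.parametrize(
        "a,q,expected", [(1, 0.7, 1), (0, 0.7, 0), (0, 0.3, 1), (1, 0.3, 0)]
    )
    def test_simulation_judgment_follows_belief_side(self, a, q, expected):
        j = judge_simulation(a, q)
        assert j.g == expected and j.slot == "mid_trial"

    def test_simulation_tie_yields_no_judgment(self):
        assert judge_simulation(1, 0.5) is None


class TestBetaUpdate:
    def test_single_success_from_uniform(self):
        b = beta_posterior_update(AbilityBelief(), 1)
        assert (b.s, b.f) == (2.0, 1.0) and b.mean == pytest.approx(2 / 3)

    def test_conjugate_counting(self):
        b = AbilityBelief()
        for g in [1] * 6 + [0] * 4:
            b = beta_posterior_update(b, g)
        assert (b.s, b.f) == (7.0, 5.0) and b.mean == pytest.approx(7 / 12)

    def test_zero_weight_is_null_update(self):
        b = beta_posterior_update(AbilityBelief(3, 2), 1, weight=0.0)
        assert (b.s, b.f) == (3.0, 2.0)

    @given(st.lists(st.tuples(st.integers(0, 1), st.floats(0.1, 2.0)), min_size=1, max_size=30))
    def test_final_belief_exchangeable_in_judgments(self, stream):
        # the posterior depends only on the multiset of (g, weight) pairs
        def final(seq):
            b = AbilityBelief()
            for g, w in seq:
                b = beta_posterior_update(b, g, w)
            return b.mean

        assert final(stream) == pytest.approx(final(list(reversed(stream))), abs=1e-12)


class TestModelTrajectories:
    def test_evidence_model_matches_counting_oracle(self, seq_subject, q_filter):
        traj = run_learner("evidence", {}, seq_subject, q=q_filter)
        agent = seq_subject[seq_subject.condition == AGENT_BET]
        for aid, grp in agent.groupby("agent_id"):
            idx = grp.index.to_numpy()
            expected = counting_oracle((int(c), 1.0) for c in grp.correctness)
            assert traj["m_post"][idx] == pytest.approx(expected, abs=0)

    def test_simulation_model_matches_counting_oracle(self, seq_subject, q_filter):
        traj = run_learner("simulation", {}, seq_subject, q=q_filter)
        agent = seq_subject[seq_subject.condition == AGENT_BET]
        for aid, grp in agent.groupby("agent_id"):
            idx = grp.index.to_numpy()
            stream = []
            for i in idx:
                j = judge_simulation(
                    int(seq_subject.agent_prediction[i]), float(q_filter[i])
                )
                stream.append((j.g, 1.0) if j is not None else (0, 0.0))
            assert traj["m_mid"][idx] == pytest.approx(counting_oracle(stream), abs=0)

    def test_sequential_model_matches_interleaved_oracle(self, seq_subject, q_filter):
        traj = run_learner("sequential", {}, seq_subject, q=q_filter)
        agent = seq_subject[seq_subject.condition == AGENT_BET]
        for aid, grp in agent.groupby("agent_id"):
            idx = grp.index.to_numpy()
            stream = []
            for i in idx:
                j = judge_simulation(
                    int(seq_subject.agent_prediction[i]), float(q_filter[i])
                )
                stream.append((j.g, 1.0) if j is not None else (0, 0.0))
                stream.append((int(seq_subject.correctness[i]), 1.0))
            oracle = counting_oracle(stream)
            assert traj["m_post"][idx] == pytest.approx(oracle[1::2], abs=0)

    def test_evidence_model_ignores_asset_beliefs(self, seq_subject, q_filter):
        permuted = np.random.default_rng(0).permutation(q_filter)
        t1 = run_learner("evidence", {}, seq_subject, q=q_filter)
        t2 = run_learner("evidence", {}, seq_subject, q=permuted)
        assert np.array_equal(t1["m_post"], t2["m_post"], equal_nan=True)

    def test_sequential_double_increment_on_agree_correct(self, seq_subject, q_filter):
        t_seq = run_learner("sequential", {}, seq_subject, q=q_filter)
        t_ev = run_learner("evidence", {}, seq_subject, q=q_filter)
        # on the first agent trial with agreement and a correct outcome the
        # sequential posterior (two successes) exceeds the evidence one
        agent_idx = np.flatnonzero(seq_subject.condition.to_numpy() == AGENT_BET)
        first = next(
            i for i in agent_idx if t_seq["g_sim"][i] == 1 and t_seq["g_ev"][i] == 1
        )
        assert t_seq["m_post"][first] > t_ev["m_post"][first]


class TestWeightedModel:
    def test_unit_weights_reproduce_sequential_bitwise(self, seq_subject, q_filter):
        tw = run_learner("weighted", {"rho": 1.0, "sigma": 1.0}, seq_subject, q=q_filter)
        ts = run_learner("sequential", {}, seq_subject, q=q_filter)
        for k in ("m_pre", "m_mid", "m_post"):
            assert np.array_equal(tw[k], ts[k], equal_nan=True)

    def test_zero_rho_reproduces_evidence_bitwise(self, seq_subject, q_filter):
        tw = run_learner("weighted", {"rho": 0.0, "sigma": 1.0}, seq_subject, q=q_filter)
        te = run_learner("evidence", {}, seq_subject, q=q_filter)
        for k in ("m_pre", "m_post"):
            assert np.array_equal(tw[k], te[k], equal_nan=True)

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            WeightedUpdateParams(-0.1, 1.0)
        with pytest.raises(ValueError):
            WeightedUpdateParams(0.0, 0.0)

    def test_relative_evidence_weight(self):
        assert WeightedUpdateParams(0.3, 1.0).relative_evidence_weight == pytest.approx(
            1.0 / 1.3
        )


class TestRLModels:
    def test_delta_rule_arithmetic_at_reported_mean_rate(self):
        st = ability.RLAbilityState(m_hat=0.5, rates={(None, None): 0.06})
        assert rl_ability_update(st, 1).m_hat == pytest.approx(0.53)

    def test_zero_rate_freezes(self):
        st = ability.RLAbilityState(m_hat=0.4, rates={(None, None): 0.0})
        assert rl_ability_update(st, 1).m_hat == 0.4

    def test_missing_rate_raises(self):
        st = ability.RLAbilityState(rates={("AC", "person"): 0.1})
        with pytest.raises(KeyError):
            rl_ability_update(st, 1, "DC", "algorithm")

    def test_long_run_estimate_approaches_ability(self):
        rng = np.random.default_rng(4)
        st = ability.RLAbilityState(rates={(None, None): 0.05})
        gs = (rng.random(3000) < 0.7).astype(int)
        for g in gs:
            st = rl_ability_update(st, int(g))
        assert abs(st.m_hat - 0.7) < 0.15

    def test_category_rates_route_by_agent(self, seq_subject, q_filter):
        traj = run_learner(
            "rl_evidence_3p", {"lambda_p": 0.3, "lambda_a": 0.0}, seq_subject, q=q_filter
        )
        mask_a = (seq_subject.condition == AGENT_BET) & (seq_subject.category == "algorithm")
        assert np.allclose(traj["m_post"][mask_a.to_numpy()], 0.5)
        mask_p = (seq_subject.condition == AGENT_BET) & (seq_subject.category == "person")
        assert not np.allclose(traj["m_post"][mask_p.to_numpy()], 0.5)


class TestFullModel:
    def test_uniform_prior_symmetry(self):
        jb = ability.JointBelief()
        assert jb.mean_alpha == pytest.approx(0.5, abs=1e-12)
        assert jb.mean_q == pytest.approx(0.5, abs=1e-12)

    def test_up_prediction_with_up_outcomes_raises_ability(self):
        # an agent repeatedly predicting up while the asset keeps going up is
        # judged able once the model believes up is the prevailing direction
        jb = ability.JointBelief()
        for _ in range(10):
            jb.observe_outcome(1)
        for _ in range(5):
            jb.observe_prediction(1, "direction")
            jb.observe_outcome(1)
        assert jb.mean_alpha > 0.55

    def test_outcome_coupling_factorizes_to_evidence_model(self, seq_subject, q_filter):
        t_full = run_learner("full", {"coupling": "outcome", "n_grid": 200}, seq_subject)
        t_ev = run_learner("evidence", {}, seq_subject, q=q_filter)
        mask = ~np.isnan(t_ev["m_post"])
        assert np.nanmax(np.abs(t_full["m_post"][mask] - t_ev["m_post"][mask])) < 1e-3
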