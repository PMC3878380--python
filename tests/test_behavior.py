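"""Lagged-regression behavioral analyses and the interaction contrast."""

import warnings

import numpy as np
import pandas as pd
import pytest

from expertrack import behavior, task
from expertrack.behavior import (
    build_lagged_design,
    interaction_contrast,
    lagged_outcome_regression,
    agreement_split_regression,
    post_outcome_choice_frequency,
)
from expertrack.task import ALGORITHM, PERSON


@pytest.fixture(scope="module")
def random_bettor(session, q_filter):
    """A subject whose bets ignore history entirely (beta = 0)."""
    return task.simulate_subject("sequential", {"beta": 0.0}, session, seed=77, q=q_filter)


class TestLaggedDesign:
    def test_design_matrix_shape(self, seq_subject, q_filter):
        design = build_lagged_design(seq_subject, n_lags=5, split=False, q=q_filter)
        lag_cols = [c for c in design.columns if "_lag" in c]
        assert len(lag_cols) == 10  # correct + incorrect at each of 5 lags

    def test_each_lag_has_exactly_one_event(self, seq_subject, q_filter):
        design = build_lagged_design(seq_subject, n_lags=5, split=False, q=q_filter)
        for j in range(1, 6):
            total = design[f"correct_lag{j}"] + design[f"incorrect_lag{j}"]
            assert (total == 1).all()

    def test_split_classes_partition_classified_lags(self, seq_subject, q_filter):
        design = build_lagged_design(seq_subject, n_lags=5, split=True, q=q_filter)
        for j in range(1, 6):
            total = sum(design[f"{cls}_lag{j}"] for cls in behavior.CLASSES)
            assert total.isin([0.0, 1.0]).all()  # 0 only for unclassifiable lags

    def test_histories_are_same_agent_only(self, seq_subject, q_filter):
        # shuffling OTHER agents' trials cannot change one agent's rows:
        # compare against a design built from that agent's trials alone
        design = build_lagged_design(seq_subject, n_lags=3, split=False, q=q_filter)
        one_agent = seq_subject[
            (seq_subject.condition != "agent_bet") | (seq_subject.agent_id == "P40")
        ]
        solo = build_lagged_design(one_agent, n_lags=3, split=False, q=q_filter[one_agent.index])
        merged = design.merge(solo, on="trial", suffixes=("", "_solo"))
        for j in range(1, 4):
            assert (merged[f"correct_lag{j}"] == merged[f"correct_lag{j}_solo"]).all()


class TestLagRegressions:
    def test_history_blind_bets_give_null_coefficients(self, random_bettor, q_filter):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = lagged_outcome_regression(random_bettor, by_category=False, q=q_filter)
        coefs = res.coefficients["all"].dropna()
        assert coefs.abs().max() < 2.0  # no systematic history effect

    def test_evidence_learner_shows_positive_recency(self):
        # pool a few evidence-model subjects: correct lags raise P(bet for),
        # most strongly at lag 1
        from conftest import simulate_cohort

        designs = []
        for done, q in simulate_cohort("evidence", {"beta": 6.0}, seed=51, n_subjects=6):
            designs.append(build_lagged_design(done, n_lags=5, split=False, q=q))
        pooled = pd.concat(designs, ignore_index=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            coef, _, _ = behavior._fit_logit(
                pooled["y"].to_numpy(), pooled[[c for c in pooled.columns if "_lag" in c]]
            )
        assert coef["correct_lag1"] > 0
        assert coef["correct_lag1"] > coef["correct_lag5"]

    def test_penalized_fallback_flagged(self, session, q_filter):
        # deterministic bets separate perfectly -> ridge fallback
        stubborn = session.copy()
        stubborn["bet"] = np.where(stubborn.condition == "agent_bet", "for", "up")
        stubborn["payoff"] = 1.0
        with pytest.warns(RuntimeWarning):
            res = lagged_outcome_regression(stubborn, by_category=False, q=q_filter)
        assert res.penalized["all"]


class TestInteractionContrast:
    def test_contrast_antisymmetric_under_category_swap(self, seq_subject, q_filter):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = agreement_split_regression(seq_subject, q=q_filter)
            swapped = behavior.LagRegressionResult(
                coefficients={
                    PERSON: res.coefficients[ALGORITHM],
                    ALGORITHM: res.coefficients[PERSON],
                },
                standard_errors={
                    PERSON: res.standard_errors[ALGORITHM],
                    ALGORITHM: res.standard_errors[PERSON],
                },
                penalized=res.penalized,
                n_lags=res.n_lags,
            )
            orig = interaction_contrast([res, res])
            flipped = interaction_contrast([swapped, swapped])
        assert orig.contrast_mean == pytest.approx(-flipped.contrast_mean, abs=1e-12)

    def test_needs_two_subjects(self, seq_subject, q_filter):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = agreement_split_regression(seq_subject, q=q_filter)
        with pytest.raises(ValueError):
            interaction_contrast([res])


class TestPostOutcomeFrequencies:
    def test_frequencies_bounded_and_partitioned(self, seq_subject, q_filter):
        freq = post_outcome_choice_frequency(seq_subject, q=q_filter)
        assert ((freq.p_bet_for >= 0) & (freq.p_bet_for <= 1)).all()
        assert set(freq.prev_class) <= set(behavior.CLASSES)

    def test_always_for_bettor_gives_unit_frequencies(self, session, q_filter):
        stubborn = session.copy()
        stubborn["bet"] = np.where(stubborn.condition == "agent_bet", "for", "up")
        stubborn["payoff"] = 1.0
        freq = post_outcome_choice_frequency(stubborn, q=q_filter)
        assert (freq.p_bet_for == 1.0).all()

    def test_evidence_learner_sorts_by_correctness_not_agreement(self):
        # under the evidence model agreement is irrelevant: P(for|AC) and
        # P(for|DC) sit together above P(for|AI) and P(for|DI)
        from conftest import simulate_cohort

        frames = [
            post_outcome_choice_frequency(done, q=q)
            for done, q in simulate_cohort("evidence", {"beta": 6.0}, seed=61, n_subjects=10)
        ]
        pooled = (
            pd.concat(frames)
            .groupby("prev_class")
            .apply(lambda g: np.average(g.p_bet_for, weights=g.n), include_groups=False)
        )
        assert min(pooled["AC"], pooled["DC"]) > max(pooled["AI"], pooled["DI"])
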