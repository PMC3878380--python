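"""Softmax choice rule, session likelihoods, latent regressors."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from expertrack import choice
from expertrack.choice import (
    asset_prediction_probability,
    bet_probability,
    compute_latent_regressors,
    regressor_correlations,
    session_loglik,
)


class TestSoftmax:
    def test_midpoint_is_indifferent(self):
        for beta in (0.0, 1.0, 4.45, 100.0):
            assert bet_probability(0.5, beta) == pytest.approx(0.5)

    def test_reported_mean_beta_value(self):
        # hand evaluation: 1/(1+exp(-4.45*0.2)) = 0.7089...
        assert bet_probability(0.7, 4.45) == pytest.approx(0.70889, abs=1e-4)

    def test_large_beta_saturates(self):
        assert bet_probability(0.6, 1000.0) > 0.999
        assert asset_prediction_probability(1.0 - 1e-9, 1000.0) > 0.999

    @given(st.floats(0.01, 0.99), st.floats(0.0, 50.0))
    def test_complementarity_and_monotonicity(self, m, beta):
        p = bet_probability(m, beta)
        assert 0 < p < 1
        assert p + bet_probability(1 - m, beta) == pytest.approx(1.0, abs=1e-12)
        assert bet_probability(min(m + 0.05, 0.999), beta) >= p

    def test_negative_beta_rejected(self):
        with pytest.raises(ValueError):
            bet_probability(0.6, -1.0)


class TestSessionLoglik:
    def test_beta_zero_closed_form(self, seq_subject, q_filter):
        ll = session_loglik("sequential", {"beta": 0.0}, seq_subject, q=q_filter)
        assert ll == pytest.approx(220 * np.log(0.5), abs=1e-9)

    def test_generating_model_beats_mismatched_model(self, seq_subject, q_filter):
        ll_seq = session_loglik("sequential", {"beta": 4.45}, seq_subject, q=q_filter)
        ll_sim = session_loglik("simulation", {"beta": 4.45}, seq_subject, q=q_filter)
        assert ll_seq > ll_sim

    def test_invariant_to_agent_relabeling(self, seq_subject, q_filter):
        relabeled = seq_subject.copy()
        mapping = {"P70": "X1", "P40": "X2", "A60": "X3", "P60": "X4",
                   "A30": "X5", "A40": "X6", "P30": "X7", "A70": "X8"}
        relabeled["agent_id"] = relabeled["agent_id"].map(lambda a: mapping.get(a, a))
        ll1 = session_loglik("sequential", {"beta": 4.45}, seq_subject, q=q_filter)
        ll2 = session_loglik("sequential", {"beta": 4.45}, relabeled, q=q_filter)
        assert ll1 == pytest.approx(ll2, abs=1e-12)


@pytest.fixture(scope="module")
def latents(seq_subject, q_filter):
    return compute_latent_regressors("sequential", {"beta": 4.45}, seq_subject, q=q_filter)


class TestLatentRegressors:
    def test_ev_and_rpe_arithmetic(self, latents, seq_subject):
        # EV folds the belief around 0.5: m=0.7 bet 'for' gives 0.4
        m = latents.mean_ability_pre.to_numpy()
        bet_for = seq_subject.bet.isin(["for", "up"]).to_numpy()
        agent = (seq_subject.condition == "agent_bet").to_numpy()
        expected_ev = np.where(bet_for, 2 * m - 1, 1 - 2 * m)
        assert latents.ev_chosen.to_numpy()[agent] == pytest.approx(expected_ev[agent])
        assert latents.rpe.to_numpy() == pytest.approx(
            seq_subject.payoff.to_numpy() - latents.ev_chosen.to_numpy()
        )
        assert latents.ev_chosen.abs().max() <= 1.0
        assert latents.rpe.abs().max() <= 2.0

    def test_unsigned_terms_are_absolute_values(self, latents):
        assert latents.ape_sim_unsigned.dropna().to_numpy() == pytest.approx(
            latents.ape_sim_signed.dropna().abs().to_numpy()
        )
        assert (latents.surprise_ev.dropna() >= 0).all()

    def test_rpe_range_partition(self, latents):
        rpe = latents.rpe.to_numpy()
        ev = latents.ev_chosen.to_numpy()
        assert np.all(np.isclose(rpe, 1 - ev) | np.isclose(rpe, -1 - ev))

    def test_unsigned_ape_maximal_near_indifferent_beliefs(self, latents):
        # |g - m| in {m, 1-m} has expectation peaking at m = 0.5
        sub = latents.dropna(subset=["ape_ev_unsigned"])
        near = sub[(sub.mean_ability_mid - 0.5).abs() < 0.1]
        far = sub[(sub.mean_ability_mid - 0.5).abs() > 0.25]
        if len(near) > 10 and len(far) > 10:
            assert near.ape_ev_unsigned.mean() > far.ape_ev_unsigned.mean()

    def test_unsigned_ape_tracks_surprisal(self, latents):
        sub = latents.dropna(subset=["ape_ev_unsigned", "surprise_ev"])
        r = np.corrcoef(sub.ape_ev_unsigned, sub.surprise_ev)[0, 1]
        assert r > 0.9


class TestRegressorCorrelations:
    def test_self_correlation_and_labels(self, seq_subject, q_filter):
        lat = compute_latent_regressors("sequential", {"beta": 4.45}, seq_subject, q=q_filter)
        corr = regressor_correlations(lat)
        assert np.allclose(np.diag(corr), 1.0)
        assert list(corr.columns) == list(corr.index)

    def test_constant_column_gives_na(self, seq_subject, q_filter):
        lat = compute_latent_regressors("sequential", {"beta": 4.45}, seq_subject, q=q_filter)
        lat["flat"] = 1.0
        corr = regressor_correlations(lat, columns=["ev_chosen", "flat"])
        assert np.isnan(corr.loc["ev_chosen", "flat"])

    def test_independent_noise_uncorrelated(self):
        import pandas as pd

        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(10_000, 2)), columns=["a", "b"])
        corr = regressor_correlations(df, columns=["a", "b"])
        assert abs(corr.loc["a", "b"]) < 0.1
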