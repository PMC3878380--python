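"""Softmax choice rules, session likelihoods, and latent trial variables.

Bets follow a logistic (softmax) rule in the distance of the relevant belief
from indifference: ``P(bet = for) = 1 / (1 + exp(-beta * (m - 0.5)))`` for
agent trials with ability-belief mean ``m``, and the same rule in ``q - 0.5``
for asset-prediction trials, with one inverse temperature ``beta`` per
subject shared across conditions.

The same belief trajectories define the trial-wise latent variables used as
parametric fMRI-style regressors: the chosen option's expected value, reward
prediction errors at feedback, signed and unsigned ability prediction errors
(aPEs) at the two update slots, and the surprisal of each judged event.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.special import expit

from . import ability as ability_mod
from .task import AGENT_BET, ASSET_PREDICT

__all__ = [
    "bet_probability",
    "asset_prediction_probability",
    "session_loglik",
    "compute_latent_regressors",
    "regressor_correlations",
    "LIKELIHOOD_FLOOR",
]

LIKELIHOOD_FLOOR = 1e-12


def bet_probability(mean_ability: float | np.ndarray, beta: float) -> float | np.ndarray:
    """P(bet 'for' the agent) under the softmax rule."""
    if beta < 0:
        raise ValueError("beta must be >= 0")
    return expit(beta * (np.asarray(mean_ability, dtype=float) - 0.5))


def asset_prediction_probability(q_t: float | np.ndarray, beta: float) -> float | np.ndarray:
    """P(predict 'up') on asset trials: the same softmax in q - 0.5."""
    if beta < 0:
        raise ValueError("beta must be >= 0")
    return expit(beta * (np.asarray(q_t, dtype=float) - 0.5))


def _choice_signed_distance(session: pd.DataFrame, traj: dict) -> np.ndarray:
    """Per-trial signed belief distance x_t such that P(observed bet) = expit(beta*x_t).

    x_t = (m - 0.5) for 'for'/'up' bets and -(m - 0.5) for 'against'/'down',
    with m the ability-belief mean on agent trials and q on asset trials.
    """
    cond = session["condition"].to_numpy()
    bets = session["bet"].to_numpy()
    is_asset = cond == ASSET_PREDICT
    belief = np.where(is_asset, traj["q_used"], traj["m_pre"])
    sign = np.where(np.isin(bets, ("for", "up")), 1.0, -1.0)
    if not np.all(np.isin(bets, ("for", "against", "up", "down"))):
        raise ValueError("session contains unfilled or unrecognized bets")
    return sign * (belief - 0.5)


def session_loglik(
    model: str,
    params: dict,
    session: pd.DataFrame,
    q: np.ndarray | None = None,
    traj: dict | None = None,
) -> float:
    """Total log-likelihood of a session's observed bets under a model.

    Beliefs are evolved online through the session; every trial (agent bets
    and asset predictions alike) contributes the log probability of the
    observed choice, floored at :data:`LIKELIHOOD_FLOOR`.
    """
    beta = float(params["beta"])
    if traj is None:
        traj = ability_mod.run_learner(model, params, session, q=q)
    x = _choice_signed_distance(session, traj)
    p = expit(beta * x)
    if np.any(p < LIKELIHOOD_FLOOR):
        warnings.warn("observed choices hit the likelihood floor", RuntimeWarning)
        p = np.maximum(p, LIKELIHOOD_FLOOR)
    return float(np.log(p).sum())


def compute_latent_regressors(
    model: str,
    params: dict,
    session: pd.DataFrame,
    q: np.ndarray | None = None,
) -> pd.DataFrame:
    """Model-derived trial-wise latent variables.

    Per trial: the chosen bet's expected value in dollars
    (``ev_chosen = 2 P(win|bet) - 1``), the reward prediction error
    (``rpe = payoff - ev_chosen``), signed and unsigned aPEs for the
    simulation slot (``g_sim - m_pre``) and the evidence slot
    (``g_ev - m_mid``; under models without a mid-trial update ``m_mid``
    equals ``m_pre``), and the surprisal ``-log2 P(g)`` of each judged event,
    where ``P(g)`` is the probability the current belief assigned to the
    observed judgment.
    """
    traj = ability_mod.run_learner(model, params, session, q=q)
    cond = session["condition"].to_numpy()
    bets = session["bet"].to_numpy()
    payoff = session["payoff"].to_numpy(dtype=float)
    is_asset = cond == ASSET_PREDICT

    belief = np.where(is_asset, traj["q_used"], traj["m_pre"])
    bet_pos = np.isin(bets, ("for", "up"))
    p_win = np.where(bet_pos, belief, 1.0 - belief)
    ev_chosen = 2.0 * p_win - 1.0
    rpe = payoff - ev_chosen

    g_sim, g_ev = traj["g_sim"], traj["g_ev"]
    m_pre, m_mid = traj["m_pre"], traj["m_mid"]
    ape_sim = g_sim - m_pre
    ape_ev = g_ev - m_mid

    with np.errstate(invalid="ignore"):
        p_gsim = np.where(g_sim == 1, m_pre, 1.0 - m_pre)
        p_gev = np.where(g_ev == 1, m_mid, 1.0 - m_mid)
        surprise_sim = -np.log2(np.maximum(p_gsim, LIKELIHOOD_FLOOR))
        surprise_ev = -np.log2(np.maximum(p_gev, LIKELIHOOD_FLOOR))
    surprise_sim[np.isnan(g_sim)] = np.nan
    surprise_ev[np.isnan(g_ev)] = np.nan

    return pd.DataFrame(
        {
            "trial": session["trial"].to_numpy(),
            "condition": cond,
            "q_t": traj["q_used"],
            "mean_ability_pre": m_pre,
            "mean_ability_mid": m_mid,
            "mean_ability_post": traj["m_post"],
            "ev_chosen": ev_chosen,
            "rpe": rpe,
            "ape_sim_signed": ape_sim,
            "ape_sim_unsigned": np.abs(ape_sim),
            "ape_ev_signed": ape_ev,
            "ape_ev_unsigned": np.abs(ape_ev),
            "surprise_sim": surprise_sim,
            "surprise_ev": surprise_ev,
        }
    )


def regressor_correlations(latents: pd.DataFrame, columns: list[str] | None = None) -> pd.DataFrame:
    """Pairwise Pearson correlations among latent regressors.

    Constant columns yield NA entries (their correlation is undefined).
    """
    if len(latents) < 2:
        raise ValueError("need at least two trials to correlate")
    cols = columns or [
        "ev_chosen",
        "rpe",
        "mean_ability_pre",
        "ape_sim_unsigned",
        "ape_ev_unsigned",
    ]
    return latents[cols].corr(method="pearson")
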