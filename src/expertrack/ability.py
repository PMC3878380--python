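"""Learning rules for beliefs about an agent's forecasting ability.

Every model maintains, per agent, a belief about the agent's fixed
probability ``alpha`` of predicting the asset correctly, and differs only in
*which* events it treats as informative and *when* within a trial it updates:

* **evidence model** — update once, at feedback, on the realized correctness
  ``c_t`` of the agent's prediction (the normatively optimal rule here,
  since ability is outcome-independent by construction);
* **simulation model** — update once, mid-trial, on whether the agent's
  prediction agrees with the subject's own asset belief ``q_t`` (the agent
  is judged good if it picked the side of 0.5 that ``q_t`` favors);
* **sequential model** — both updates in order: the simulation judgment when
  the prediction appears, then the correctness judgment at feedback, applied
  to the already-updated belief;
* **weighted model** — the sequential model with fractional pseudo-count
  weights ``rho`` (simulation update) and ``sigma`` (evidence update); it
  nests the sequential (rho=sigma=1) and evidence (rho=0) models exactly;
* **full model** — joint Bayesian inference on a 2-D grid over the asset's
  up-probability and the agent's ability, coupling the two unknowns;
* **RL variants** — delta-rule counterparts of the evidence / simulation /
  sequential models with one rate, category-specific rates, or (the
  "eight-rate" model) a rate per agreement-by-correctness trial class and
  agent category.

Bayesian beliefs are conjugate: with a uniform Beta(1,1) prior and binary
quality judgments ``g``, the posterior after any history is
``Beta(1 + sum(w*g), 1 + sum(w*(1-g)))``.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import asset as asset_mod
from .task import AGENT_BET, ALGORITHM, ASSET_PREDICT, PERSON

__all__ = [
    "AbilityBelief",
    "QualityJudgment",
    "WeightedUpdateParams",
    "RLAbilityState",
    "JointBelief",
    "judge_evidence",
    "judge_simulation",
    "beta_posterior_update",
    "rl_ability_update",
    "run_learner",
    "run_evidence_model",
    "run_simulation_model",
    "run_sequential_model",
    "run_weighted_model",
    "run_full_model",
    "MODEL_N_PARAMS",
    "BAYES_WEIGHTS",
    "RL_SCHEMES",
]

MID_TRIAL = "mid_trial"
FEEDBACK = "feedback"

#: per-subject free-parameter counts used in BIC penalties
MODEL_N_PARAMS = {
    "sequential": 1,
    "evidence": 1,
    "simulation": 1,
    "full": 1,
    "weighted": 3,
    "rl_sequential_2p": 2,
    "rl_evidence_2p": 2,
    "rl_simulation_2p": 2,
    "rl_sequential_3p": 3,
    "rl_evidence_3p": 3,
    "rl_simulation_3p": 3,
    "rl_evidence_4p": 4,
    "rl_eight_rate": 9,
}

#: (rho, sigma) pseudo-count weights of the fixed Bayesian variants
BAYES_WEIGHTS = {"sequential": (1.0, 1.0), "evidence": (0.0, 1.0), "simulation": (1.0, 0.0)}

#: (does_sim_update, does_ev_update, rate pooling) of the RL variants
RL_SCHEMES = {
    "rl_sequential_2p": (True, True, "pooled"),
    "rl_evidence_2p": (False, True, "pooled"),
    "rl_simulation_2p": (True, False, "pooled"),
    "rl_sequential_3p": (True, True, "category"),
    "rl_evidence_3p": (False, True, "category"),
    "rl_simulation_3p": (True, False, "category"),
    "rl_evidence_4p": (False, True, "category"),
    "rl_eight_rate": (False, True, "class_by_category"),
}


@dataclasses.dataclass
class AbilityBelief:
    """Beta pseudo-count posterior over an agent's ability."""

    s: float = 1.0
    f: float = 1.0

    @property
    def mean(self) -> float:
        return self.s / (self.s + self.f)


@dataclasses.dataclass(frozen=True)
class QualityJudgment:
    """A binary quality verdict ``g`` and the within-trial slot it occupies."""

    g: int
    slot: str  # MID_TRIAL or FEEDBACK


@dataclasses.dataclass(frozen=True)
class WeightedUpdateParams:
    """Weights of the semi-Bayesian weighted model."""

    rho: float  # simulation-update weight
    sigma: float  # evidence-update weight

    def __post_init__(self) -> None:
        if self.rho < 0 or self.sigma < 0:
            raise ValueError("weights must be non-negative")
        if self.rho + self.sigma == 0:
            raise ValueError("rho and sigma cannot both be zero")

    @property
    def relative_evidence_weight(self) -> float:
        """sigma / (rho + sigma), the between-subject covariate."""
        return self.sigma / (self.rho + self.sigma)


@dataclasses.dataclass
class RLAbilityState:
    """Delta-rule ability estimate with a lookup of learning rates."""

    m_hat: float = 0.5
    rates: dict = dataclasses.field(default_factory=dict)


def judge_evidence(c_t: int) -> QualityJudgment:
    """Feedback-slot judgment: the agent was good iff its prediction was correct."""
    if c_t is None or (isinstance(c_t, float) and np.isnan(c_t)):
        raise ValueError("evidence judgment requires an agent trial with feedback")
    return QualityJudgment(g=int(c_t), slot=FEEDBACK)


def judge_simulation(a_t: int, q_t: float) -> QualityJudgment | None:
    """Mid-trial judgment: good iff the prediction lies on q_t's side of 0.5.

    Returns ``None`` when ``q_t`` is exactly 0.5 (no judgment, no update) —
    under the continuous filter this is a measure-zero tie.
    """
    if not 0.0 < q_t < 1.0:
        raise ValueError("q_t must lie in (0,1)")
    if q_t == 0.5:
        return None
    g = int((a_t == 1 and q_t > 0.5) or (a_t == 0 and q_t < 0.5))
    return QualityJudgment(g=g, slot=MID_TRIAL)


def beta_posterior_update(
    belief: AbilityBelief, g: int, weight: float = 1.0
) -> AbilityBelief:
    """Conjugate update with a (possibly fractional) pseudo-count weight."""
    if weight < 0:
        raise ValueError("weight must be >= 0")
    return AbilityBelief(s=belief.s + weight * g, f=belief.f + weight * (1 - g))


def rl_ability_update(
    state: RLAbilityState,
    g: int,
    outcome_class: str | None = None,
    category: str | None = None,
) -> RLAbilityState:
    """Delta-rule update ``m_hat += rate * (g - m_hat)``.

    The applicable rate is looked up by (outcome_class, category) with
    fallbacks to (None, category) and (None, None), matching the pooled,
    per-category, and class-by-category schemes.
    """
    for key in ((outcome_class, category), (None, category), (None, None)):
        if key in state.rates:
            rate = state.rates[key]
            break
    else:
        raise KeyError(f"no learning rate for class={outcome_class!r}, category={category!r}")
    if not 0.0 <= rate <= 1.0:
        raise ValueError("learning rate must lie in [0,1]")
    return RLAbilityState(m_hat=state.m_hat + rate * (g - state.m_hat), rates=state.rates)


def _classify(g_sim: float, c: int) -> str | None:
    """AC/DC/AI/DI trial class from the agreement judgment and correctness."""
    if g_sim is None or (isinstance(g_sim, float) and np.isnan(g_sim)):
        return None
    return ("A" if g_sim else "D") + ("C" if c else "I")


def _rl_rate_table(model: str, params: dict) -> dict:
    scheme = RL_SCHEMES[model][2]
    if scheme == "pooled":
        return {(None, None): float(params["lambda_p"])}
    if scheme == "category":
        return {
            (None, PERSON): float(params["lambda_p"]),
            (None, ALGORITHM): float(params["lambda_a"]),
        }
    # class-by-category: gamma on AC, eta on DC, phi on AI, lambda on DI
    table = {}
    for cat, suffix in ((PERSON, "p"), (ALGORITHM, "a")):
        for cls, name in (("AC", "gamma"), ("DC", "eta"), ("AI", "phi"), ("DI", "lambda")):
            table[(cls, cat)] = float(params[f"{name}_{suffix}"])
    return table


def default_asset_beliefs(session: pd.DataFrame, **filter_kwargs) -> np.ndarray:
    """Volatility-filter q_t series for a session, cached on the DataFrame."""
    key = "q_filter" if not filter_kwargs else None
    if key and key in session.attrs:
        return session.attrs[key]
    q = asset_mod.asset_belief_series(session["outcome"].to_numpy(), **filter_kwargs)
    if key:
        session.attrs[key] = q
    return q


def run_learner(
    model: str,
    params: dict | None,
    session: pd.DataFrame,
    q: np.ndarray | None = None,
) -> dict:
    """Evolve a learner through a session and log its per-trial latent states.

    Parameters
    ----------
    model
        One of the Bayesian models (``"sequential"``, ``"evidence"``,
        ``"simulation"``, ``"weighted"``, ``"full"``) or RL variants (see
        :data:`RL_SCHEMES`).
    params
        Model parameters: ``rho``/``sigma`` for the weighted model, rates for
        RL models (``lambda_p``, ``lambda_a``, ``lambda_s``, or the eight
        ``gamma/eta/phi/lambda_{p,a}``), ``coupling`` for the full model.
        The choice parameter ``beta`` is ignored here (beliefs do not depend
        on it).
    q
        Per-trial asset beliefs; computed with the default volatility filter
        when omitted (the RL 4P variant instead derives them from its own
        delta-rule tracker with rate ``lambda_s``).

    Returns
    -------
    dict of per-trial arrays: ``q_used``, ``m_pre``, ``m_mid``, ``m_post``
    (ability-belief means before, after the mid-trial update, and after
    feedback; NaN on asset trials), ``g_sim``, ``g_ev`` (judgments; NaN when
    absent), and ``trial_class`` (AC/DC/AI/DI or None).
    """
    params = params or {}
    n = len(session)
    if model == "full":
        return _run_full_model(session, params)
    if model == "rl_evidence_4p":
        q = asset_mod.rl_asset_belief_series(
            session["outcome"].to_numpy(), float(params["lambda_s"])
        )
    elif q is None:
        q = default_asset_beliefs(session)

    if model in BAYES_WEIGHTS or model == "weighted":
        if model == "weighted":
            w = WeightedUpdateParams(float(params["rho"]), float(params["sigma"]))
            rho, sigma = w.rho, w.sigma
        else:
            rho, sigma = BAYES_WEIGHTS[model]
        bayes = True
        rates = None
    elif model in RL_SCHEMES:
        bayes = False
        sim_up, ev_up, _ = RL_SCHEMES[model]
        rates = _rl_rate_table(model, params)
    else:
        raise ValueError(f"unknown model {model!r}")

    beliefs: dict[str, object] = {}
    m_pre = np.full(n, np.nan)
    m_mid = np.full(n, np.nan)
    m_post = np.full(n, np.nan)
    g_sim_arr = np.full(n, np.nan)
    g_ev_arr = np.full(n, np.nan)
    classes = np.full(n, None, dtype=object)

    cond = session["condition"].to_numpy()
    agent_ids = session["agent_id"].to_numpy()
    preds = session["agent_prediction"].to_numpy()
    corr = session["correctness"].to_numpy()

    for i in range(n):
        if cond[i] == ASSET_PREDICT:
            continue
        aid = agent_ids[i]
        cat = session["category"].iat[i]
        if aid not in beliefs:
            beliefs[aid] = AbilityBelief() if bayes else RLAbilityState(rates=rates)
        bel = beliefs[aid]
        m_pre[i] = bel.mean if bayes else bel.m_hat

        # delta-rule asset beliefs can touch 0/1 at extreme rates; nudge
        # inside the open interval before judging
        sim = judge_simulation(int(preds[i]), float(np.clip(q[i], 1e-9, 1 - 1e-9)))
        if sim is not None:
            g_sim_arr[i] = sim.g
        cls = _classify(sim.g if sim is not None else None, int(corr[i]))
        classes[i] = cls

        # mid-trial (simulation-based) update
        if sim is not None:
            if bayes:
                if rho > 0:
                    bel = beta_posterior_update(bel, sim.g, rho)
            elif sim_up:
                bel = rl_ability_update(bel, sim.g, cls, cat)
        m_mid[i] = bel.mean if bayes else bel.m_hat

        # feedback (evidence-based) update
        ev = judge_evidence(int(corr[i]))
        g_ev_arr[i] = ev.g
        if bayes:
            if sigma > 0:
                bel = beta_posterior_update(bel, ev.g, sigma)
        elif ev_up:
            if RL_SCHEMES[model][2] == "class_by_category":
                if cls is not None:  # unclassifiable ties are not updated
                    bel = rl_ability_update(bel, ev.g, cls, cat)
            else:
                bel = rl_ability_update(bel, ev.g, cls, cat)
        m_post[i] = bel.mean if bayes else bel.m_hat
        beliefs[aid] = bel

    return {
        "q_used": np.asarray(q, dtype=float),
        "m_pre": m_pre,
        "m_mid": m_mid,
        "m_post": m_post,
        "g_sim": g_sim_arr,
        "g_ev": g_ev_arr,
        "trial_class": classes,
        "final_beliefs": beliefs,
    }


# ---------------------------------------------------------------------------
# full model: joint grid over (asset up-probability, agent ability)


@dataclasses.dataclass
class JointBelief:
    """2-D grid posterior over (q, alpha) for one agent."""

    n_q: int = 40
    n_alpha: int = 40

    def __post_init__(self) -> None:
        # even grid sizes keep 0.5 off the grid, so the direction indicator
        # q > 0.5 is always strict
        self.q_grid = (np.arange(self.n_q) + 0.5) / self.n_q
        self.alpha_grid = (np.arange(self.n_alpha) + 0.5) / self.n_alpha
        self.posterior = np.full((self.n_q, self.n_alpha), 1.0 / (self.n_q * self.n_alpha))

    def _renorm(self) -> None:
        s = self.posterior.sum()
        if s <= 0 or not np.isfinite(s):
            raise FloatingPointError("joint posterior degenerated")
        self.posterior /= s

    def observe_outcome(self, outcome: int) -> None:
        lik = self.q_grid if outcome == 1 else 1.0 - self.q_grid
        self.posterior *= lik[:, None]
        self._renorm()

    def observe_prediction(self, a_t: int, coupling: str = "direction", outcome: int | None = None) -> None:
        """Condition on the agent's prediction.

        ``direction`` coupling: the agent picks the currently more likely
        direction with probability alpha — P(a=1|q,alpha) = alpha if q>0.5
        else 1-alpha (0.5 exactly at q=0.5, unreachable on an even grid).
        ``outcome`` coupling: the agent matches the realized outcome with
        probability alpha, which factorizes the joint update into the
        evidence model times the asset model (used as a cross-check).
        """
        if coupling == "direction":
            up = (self.q_grid > 0.5)[:, None]
            p_up = np.where(up, self.alpha_grid[None, :], 1.0 - self.alpha_grid[None, :])
            lik = p_up if a_t == 1 else 1.0 - p_up
        elif coupling == "outcome":
            if outcome is None:
                raise ValueError("outcome coupling requires the realized outcome")
            match = 1 if a_t == outcome else 0
            la = self.alpha_grid if match else 1.0 - self.alpha_grid
            lik = np.broadcast_to(la[None, :], self.posterior.shape)
        else:
            raise ValueError(f"unknown coupling {coupling!r}")
        self.posterior = self.posterior * lik
        self._renorm()

    @property
    def mean_alpha(self) -> float:
        return float(self.posterior.sum(axis=0) @ self.alpha_grid)

    @property
    def mean_q(self) -> float:
        return float(self.posterior.sum(axis=1) @ self.q_grid)


def _run_full_model(session: pd.DataFrame, params: dict) -> dict:
    coupling = params.get("coupling", "direction")
    n_grid = int(params.get("n_grid", 40))
    n = len(session)
    grids: dict[str, JointBelief] = {}
    order: list[str] = []
    for aid in session.loc[session["condition"] == AGENT_BET, "agent_id"].unique():
        grids[aid] = JointBelief(n_q=n_grid, n_alpha=n_grid)
        order.append(aid)

    m_pre = np.full(n, np.nan)
    m_mid = np.full(n, np.nan)
    m_post = np.full(n, np.nan)
    g_sim_arr = np.full(n, np.nan)
    g_ev_arr = np.full(n, np.nan)
    classes = np.full(n, None, dtype=object)
    q_used = np.full(n, np.nan)

    cond = session["condition"].to_numpy()
    agent_ids = session["agent_id"].to_numpy()
    preds = session["agent_prediction"].to_numpy()
    outs = session["outcome"].to_numpy()
    corr = session["correctness"].to_numpy()

    for i in range(n):
        # the subject's overall asset belief: mean across agents' q-marginals
        q_used[i] = float(np.mean([grids[a].mean_q for a in order]))
        if cond[i] == AGENT_BET:
            g = grids[agent_ids[i]]
            m_pre[i] = g.mean_alpha
            if coupling == "direction" and q_used[i] != 0.5:
                sim = judge_simulation(int(preds[i]), q_used[i])
                if sim is not None:
                    g_sim_arr[i] = sim.g
                classes[i] = _classify(sim.g if sim else None, int(corr[i]))
            g.observe_prediction(int(preds[i]), coupling, outcome=int(outs[i]))
            m_mid[i] = g.mean_alpha
            g_ev_arr[i] = int(corr[i])
        # every trial reveals the asset's direction
        for a in order:
            grids[a].observe_outcome(int(outs[i]))
        if cond[i] == AGENT_BET:
            m_post[i] = grids[agent_ids[i]].mean_alpha

    return {
        "q_used": q_used,
        "m_pre": m_pre,
        "m_mid": m_mid,
        "m_post": m_post,
        "g_sim": g_sim_arr,
        "g_ev": g_ev_arr,
        "trial_class": classes,
        "final_beliefs": grids,
    }


# ---------------------------------------------------------------------------
# spec-surface wrappers


def run_evidence_model(session: pd.DataFrame, asset_beliefs: np.ndarray | None = None) -> dict:
    """Feedback-only conjugate learner (one update per agent trial, g = c_t)."""
    return run_learner("evidence", {}, session, q=asset_beliefs)


def run_simulation_model(session: pd.DataFrame, asset_beliefs: np.ndarray | None = None) -> dict:
    """Mid-trial-only conjugate learner (one update per agent trial, g from agreement)."""
    return run_learner("simulation", {}, session, q=asset_beliefs)


def run_sequential_model(session: pd.DataFrame, asset_beliefs: np.ndarray | None = None) -> dict:
    """Two conjugate updates per agent trial: agreement, then correctness."""
    return run_learner("sequential", {}, session, q=asset_beliefs)


def run_weighted_model(
    session: pd.DataFrame,
    asset_beliefs: np.ndarray | None = None,
    params: WeightedUpdateParams | None = None,
) -> dict:
    """Sequential learner with fractional pseudo-count weights (rho, sigma)."""
    p = params or WeightedUpdateParams(1.0, 1.0)
    return run_learner("weighted", {"rho": p.rho, "sigma": p.sigma}, session, q=asset_beliefs)


def run_full_model(session: pd.DataFrame, coupling: str = "direction", n_grid: int = 40) -> dict:
    """Joint-grid learner over (asset up-probability, agent ability)."""
    return run_learner("full", {"coupling": coupling, "n_grid": n_grid}, session)
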