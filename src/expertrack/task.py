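"""Generative model of the expertise-tracking experiment.

The task interleaves two kinds of trials. On *agent* trials the subject bets
for or against a forecaster (a "person" shown as a face, or an "algorithm"
shown as a fractal) who then predicts whether a hypothetical asset goes up or
down; the subject wins $1 if their bet about the forecaster's correctness is
right and loses $1 otherwise. On *asset* trials the subject predicts the
asset's direction themselves. The asset moves up with a slowly drifting
probability, and each forecaster has a fixed, outcome-independent probability
(its ability) of predicting the move correctly.

This module generates the full experiment — the drifting asset, the agents'
prediction streams, and the interleaved 4-block schedule — and simulates
subjects whose bets follow any learner defined in :mod:`expertrack.ability`.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TaskConfig",
    "AgentSpec",
    "SESSION_COLUMNS",
    "beta_drift_draw",
    "generate_asset_series",
    "generate_agent_predictions",
    "default_agent_roster",
    "generate_session",
    "simulate_subject",
]

#: Fixed column order of a session trial table.
SESSION_COLUMNS = [
    "block",
    "trial",
    "condition",
    "agent_id",
    "category",
    "ability_true",
    "agent_prediction",
    "outcome",
    "correctness",
    "bet",
    "payoff",
]

PERSON = "person"
ALGORITHM = "algorithm"
AGENT_BET = "agent_bet"
ASSET_PREDICT = "asset_predict"


@dataclasses.dataclass(frozen=True)
class AgentSpec:
    """One forecaster: an identity label, a category, and a fixed ability."""

    agent_id: str
    category: str  # "person" or "algorithm"
    ability: float

    def __post_init__(self) -> None:
        if not 0.0 < self.ability < 1.0:
            raise ValueError(f"ability must lie in (0,1), got {self.ability}")
        if self.category not in (PERSON, ALGORITHM):
            raise ValueError(f"unknown category {self.category!r}")


@dataclasses.dataclass
class TaskConfig:
    """Design parameters of one experimental session.

    Defaults reproduce the published design: four blocks of 55 trials, eleven
    asset-prediction trials per block, three agents per block (two of one
    category plus one of the other, alternating across blocks) drawn from a
    roster of four abilities per category, with the 0.4 and 0.6 agents
    repeated in a later block. The asset's up-probability drifts as
    successive beta draws with SD ``drift_sd``.
    """

    n_blocks: int = 4
    trials_per_block: int = 55
    asset_trials_per_block: int = 11
    agent_abilities: Sequence[float] = (0.3, 0.4, 0.6, 0.7)
    drift_sd: float = 0.07
    drift_clip: tuple[float, float] = (0.10, 0.90)
    p0: float = 0.5
    payoff_win: float = 1.0
    payoff_lose: float = -1.0
    first_block_majority: str = PERSON  # category with two agents in block 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.asset_trials_per_block >= self.trials_per_block:
            raise ValueError("asset trials must leave room for agent trials")
        if not 0.0 < self.drift_sd < 0.5:
            raise ValueError("drift_sd must lie in (0, 0.5)")
        lo, hi = self.drift_clip
        if not 0.0 < lo < hi < 1.0:
            raise ValueError("drift_clip bounds must satisfy 0 < lo < hi < 1")
        # beta moment matching needs sd^2 < m(1-m) for every admissible mean
        edge_var = min(lo * (1 - lo), hi * (1 - hi))
        if self.drift_sd**2 >= edge_var:
            raise ValueError(
                f"drift_sd={self.drift_sd} infeasible for clip bounds {self.drift_clip}: "
                f"requires sd^2 < {edge_var:.4f}"
            )

    @property
    def agent_trials_per_block(self) -> int:
        return self.trials_per_block - self.asset_trials_per_block

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block


def beta_drift_draw(
    mean: float | np.ndarray, sd: float, rng: np.random.Generator, size: int | None = None
) -> np.ndarray | float:
    """Draw from a beta distribution with the given mean and SD.

    Moment matching: with concentration ``nu = m(1-m)/sd^2 - 1`` the
    Beta(m*nu, (1-m)*nu) distribution has exactly this mean and SD. ``sd=0``
    degenerates to the mean itself.
    """
    m = np.asarray(mean, dtype=float)
    if np.any((m <= 0) | (m >= 1)):
        raise ValueError("mean must lie strictly inside (0,1)")
    if sd == 0.0:
        out = np.broadcast_to(m, np.shape(m) if size is None else size).copy()
        return float(out) if out.ndim == 0 else out
    var = sd * sd
    if np.any(var >= m * (1 - m)):
        raise ValueError(f"sd={sd} infeasible for mean {mean}: need sd^2 < m(1-m)")
    nu = m * (1 - m) / var - 1.0
    return rng.beta(m * nu, (1 - m) * nu, size=size)


def generate_asset_series(
    T: int,
    drift_sd: float = 0.07,
    p0: float = 0.5,
    clip: tuple[float, float] = (0.10, 0.90),
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Generate the asset's drifting up-probability and binary outcomes.

    Each trial's true probability is drawn from a beta distribution with SD
    ``drift_sd`` whose mean is the previous trial's probability, clipped into
    ``clip`` so the beta parameterization stays feasible. Outcomes are
    Bernoulli draws at the per-trial probability.

    Returns a DataFrame with columns ``p_true`` and ``outcome``.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    rng = np.random.default_rng(rng)
    p = np.empty(T)
    prev = p0
    for t in range(T):
        m = float(np.clip(prev, clip[0], clip[1]))
        p[t] = beta_drift_draw(m, drift_sd, rng)
        prev = p[t]
    outcome = (rng.random(T) < p).astype(int)
    return pd.DataFrame({"p_true": p, "outcome": outcome})


def generate_agent_predictions(
    ability: float,
    outcomes: Sequence[int],
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Predictions of an agent who is correct independently with probability ``ability``."""
    if not 0.0 < ability <= 1.0:
        raise ValueError("ability must lie in (0, 1]")
    rng = np.random.default_rng(rng)
    o = np.asarray(outcomes, dtype=int)
    if o.size == 0:
        return np.empty(0, dtype=int)
    correct = rng.random(o.size) < ability
    return np.where(correct, o, 1 - o)


def default_agent_roster(config: TaskConfig) -> list[AgentSpec]:
    """Eight agents: one per ability level per category."""
    roster = []
    for cat, prefix in ((PERSON, "P"), (ALGORITHM, "A")):
        for ab in config.agent_abilities:
            roster.append(AgentSpec(f"{prefix}{int(round(ab * 100)):02d}", cat, ab))
    return roster


def _block_assignments(config: TaskConfig) -> list[list[str]]:
    """Agents appearing in each block.

    Each block carries two agents of one category and one of the other,
    alternating which category is doubled. The middle-ability agents (second
    and third roster entries, 0.4 and 0.6 by default) recur in a later block;
    the extreme agents appear once.
    """
    a = [f"{int(round(ab * 100)):02d}" for ab in config.agent_abilities]
    if len(a) != 4:
        raise ValueError("default roster layout requires four ability levels")
    maj1 = "P" if config.first_block_majority == PERSON else "A"
    min1 = "A" if maj1 == "P" else "P"
    lo, mid_lo, mid_hi, hi = a
    layout = [
        [f"{maj1}{hi}", f"{maj1}{mid_lo}", f"{min1}{mid_hi}"],
        [f"{maj1}{mid_hi}", f"{min1}{lo}", f"{min1}{mid_lo}"],
        [f"{maj1}{lo}", f"{maj1}{mid_hi}", f"{min1}{mid_lo}"],
        [f"{maj1}{mid_lo}", f"{min1}{hi}", f"{min1}{mid_hi}"],
    ]
    if config.n_blocks != 4:
        raise ValueError("default block layout is defined for 4 blocks")
    return layout


def _interleave_block(
    labels_counts: dict[str, int],
    rng: np.random.Generator,
    max_tries: int = 1000,
    first_exclude: str | None = None,
) -> list[str]:
    """Random order of stimulus labels with no two adjacent labels equal.

    Sequential sampling with a forced-placement rule: at each position a
    label is drawn uniformly from those still available (excluding the
    previous label), except that when one label's remaining count exceeds
    half the remaining slots it must be placed immediately or the sequence
    becomes infeasible. Dead ends trigger a bounded retry.
    """
    labels = list(labels_counts)
    for _ in range(max_tries):
        counts = {lab: labels_counts[lab] for lab in labels}
        seq: list[str] = []
        prev = first_exclude  # no repeat across the block boundary either
        ok = True
        for slot in range(sum(labels_counts.values())):
            remaining = sum(counts.values())
            forced = [lab for lab, n in counts.items() if 2 * n > remaining]
            if forced:
                choicelist = [lab for lab in forced if lab != prev]
                if not choicelist:
                    ok = False
                    break
            else:
                choicelist = [lab for lab, n in counts.items() if n > 0 and lab != prev]
                if not choicelist:
                    ok = False
                    break
            lab = choicelist[rng.integers(len(choicelist))]
            seq.append(lab)
            counts[lab] -= 1
            prev = lab
        if ok:
            return seq
    raise RuntimeError("could not interleave block without adjacent repeats")


def generate_session(
    config: TaskConfig | None = None, seed: int | None = None
) -> pd.DataFrame:
    """Generate one session's trial table with bets left unfilled.

    The returned DataFrame has one row per trial in presentation order with
    the :data:`SESSION_COLUMNS` schema; ``bet`` and ``payoff`` are NA until a
    subject (real or simulated) is run through the session. The master seed
    is split into independent streams for the asset, the agents, and the
    schedule so each component is separately reproducible.
    """
    config = config or TaskConfig()
    if seed is None:
        seed = config.seed
    ss = np.random.SeedSequence(seed)
    rng_asset, rng_agents, rng_sched = (np.random.default_rng(s) for s in ss.spawn(3))

    asset = generate_asset_series(
        config.n_trials, config.drift_sd, config.p0, config.drift_clip, rng_asset
    )
    roster = {spec.agent_id: spec for spec in default_agent_roster(config)}
    blocks = _block_assignments(config)

    n_agent = config.agent_trials_per_block
    base, extra = divmod(n_agent, 3)

    rows: list[dict] = []
    t_global = 0
    for b, agent_ids in enumerate(blocks):
        # the doubled category's agents take the larger counts so that the
        # category totals come out equal across the session (88 and 88)
        cats = [roster[a].category for a in agent_ids]
        doubled = PERSON if cats.count(PERSON) == 2 else ALGORITHM
        order = sorted(agent_ids, key=lambda a: roster[a].category != doubled)
        counts = {}
        for i, a in enumerate(order):
            counts[a] = base + (1 if i < extra else 0)
        counts["__asset__"] = config.asset_trials_per_block
        last = rows[-1]["agent_id"] or "__asset__" if rows else None
        schedule = _interleave_block(counts, rng_sched, first_exclude=last)
        for lab in schedule:
            o = int(asset.outcome.iloc[t_global])
            if lab == "__asset__":
                rows.append(
                    dict(
                        block=b + 1,
                        trial=t_global + 1,
                        condition=ASSET_PREDICT,
                        agent_id=None,
                        category=None,
                        ability_true=np.nan,
                        agent_prediction=None,
                        outcome=o,
                        correctness=None,
                        bet=None,
                        payoff=np.nan,
                    )
                )
            else:
                spec = roster[lab]
                pred = int(generate_agent_predictions(spec.ability, [o], rng_agents)[0])
                rows.append(
                    dict(
                        block=b + 1,
                        trial=t_global + 1,
                        condition=AGENT_BET,
                        agent_id=spec.agent_id,
                        category=spec.category,
                        ability_true=spec.ability,
                        agent_prediction=pred,
                        outcome=o,
                        correctness=int(pred == o),
                        bet=None,
                        payoff=np.nan,
                    )
                )
            t_global += 1

    session = pd.DataFrame(rows, columns=SESSION_COLUMNS)
    session.attrs["p_true"] = asset["p_true"].to_numpy()
    return session


def simulate_subject(
    model: str,
    params: dict,
    session: pd.DataFrame,
    seed: int | None = None,
    q: np.ndarray | None = None,
) -> pd.DataFrame:
    """Fill a session's bets with softmax choices of a learner model.

    The learner (any model name accepted by
    :func:`expertrack.ability.run_learner`) is evolved online through the
    session; on each trial the bet is sampled from the softmax choice
    probability implied by the current belief, and the payoff follows the
    task rules (+$1 for a correct guess about the agent's correctness or the
    asset's direction, −$1 otherwise).

    Parameters
    ----------
    q
        Optional precomputed per-trial asset belief (saves re-running the
        volatility filter when simulating many subjects on related designs).

    Returns a completed copy of the session; per-trial latent states are
    attached via ``.attrs["latents"]``.
    """
    from . import ability
    from .choice import asset_prediction_probability, bet_probability

    rng = np.random.default_rng(seed)
    beta = float(params.get("beta", 0.0))
    if beta < 0:
        raise ValueError("beta must be >= 0")

    traj = ability.run_learner(model, params, session, q=q)
    out = session.copy()
    bets = np.empty(len(session), dtype=object)
    payoffs = np.empty(len(session))
    u = rng.random(len(session))
    for i, row in enumerate(session.itertuples(index=False)):
        if row.condition == ASSET_PREDICT:
            p_up = asset_prediction_probability(traj["q_used"][i], beta)
            bet_up = u[i] < p_up
            bets[i] = "up" if bet_up else "down"
            payoffs[i] = 1.0 if int(bet_up) == row.outcome else -1.0
        else:
            p_for = bet_probability(traj["m_pre"][i], beta)
            bet_for = u[i] < p_for
            bets[i] = "for" if bet_for else "against"
            guessed_right = int(bet_for) == row.correctness
            payoffs[i] = 1.0 if guessed_right else -1.0
    out["bet"] = bets
    out["payoff"] = payoffs
    out.attrs["latents"] = traj
    out.attrs["p_true"] = session.attrs.get("p_true")
    return out
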