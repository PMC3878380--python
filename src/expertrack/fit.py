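"""Maximum-likelihood fitting, BIC model comparison, and recovery experiments.

Per-subject fits use a deterministic two-stage scheme: a coarse parameter
grid (inverse temperature beta on [0, 20], learning rates on [0, 1]) followed
by bounded local refinement, so repeated fits of the same data give identical
estimates. Belief trajectories of the Bayesian models do not depend on beta,
and those of the RL models depend on the rates but not beta, which makes the
likelihood surface cheap to evaluate on the grid.

Model comparison follows the summed-BIC convention
``BIC = 2 * sum(NlogL) + k * n_subjects * ln(N_total)`` with ``N_total`` the
pooled number of trials across subjects (all conditions), and NlogL in
natural-log units.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import log_expit

from . import ability as ability_mod
from . import asset as asset_mod
from .ability import MODEL_N_PARAMS, RL_SCHEMES
from .choice import LIKELIHOOD_FLOOR, _choice_signed_distance
from .task import AGENT_BET, ALGORITHM, ASSET_PREDICT, PERSON

__all__ = [
    "FitResult",
    "RecoveryReport",
    "fit_subject_mle",
    "bic_total",
    "compare_models",
    "fit_fixed_effects_eight_rate",
    "recovery_experiment",
]

BETA_GRID = np.linspace(0.0, 20.0, 201)
RATE_GRID = np.linspace(0.0, 1.0, 101)


@dataclasses.dataclass
class FitResult:
    """Per-model fit summary across subjects."""

    model: str
    params_per_subject: int
    subject_params: list[dict]
    subject_nlogl: np.ndarray
    n_trials_total: int

    @property
    def nlogl_sum(self) -> float:
        return float(np.sum(self.subject_nlogl))

    @property
    def bic_sum(self) -> float:
        return bic_total(
            self.nlogl_sum,
            self.params_per_subject,
            len(self.subject_params),
            self.n_trials_total,
        )

    def mean_params(self) -> dict:
        keys = self.subject_params[0].keys()
        return {k: float(np.mean([p[k] for p in self.subject_params])) for k in keys}


def bic_total(
    sum_nlogl: float, params_per_subject: int, n_subjects: int, n_trials_total: int
) -> float:
    """Summed BIC: 2*sum(NlogL) + (k * n_subjects) * ln(N_total)."""
    if n_trials_total <= 0 or n_subjects <= 0:
        raise ValueError("counts must be positive")
    return 2.0 * sum_nlogl + params_per_subject * n_subjects * np.log(n_trials_total)


def _loglik_beta(x: np.ndarray, beta: float | np.ndarray) -> float | np.ndarray:
    """Sum of log P(observed choice) for signed distances x at given beta.

    With P = expit(beta*x), log P = log_expit(beta*x); the likelihood floor
    only matters for astronomically negative arguments, which log_expit
    handles without underflow, so the floor is applied on the final sum.
    """
    beta = np.asarray(beta, dtype=float)
    ll = log_expit(np.multiply.outer(beta, x)).sum(axis=-1)
    return np.maximum(ll, len(x) * np.log(LIKELIHOOD_FLOOR))


def _refine_beta(x: np.ndarray, beta0: float) -> tuple[float, float]:
    res = optimize.minimize_scalar(
        lambda b: -_loglik_beta(x, b),
        bounds=(max(0.0, beta0 - 0.25), min(20.0, beta0 + 0.25)),
        method="bounded",
        options={"xatol": 1e-6},
    )
    return float(res.x), float(-res.fun)


def _fit_beta(x: np.ndarray) -> tuple[float, float]:
    """Grid + bounded refinement of the single inverse temperature."""
    ll = _loglik_beta(x, BETA_GRID)
    b0 = float(BETA_GRID[int(np.argmax(ll))])
    b, llmax = _refine_beta(x, b0)
    if b <= 1e-6 or b >= 20.0 - 1e-6:
        warnings.warn(f"beta estimate at boundary ({b:.3g})", RuntimeWarning)
    return b, llmax


def _rl_signed_distances(
    session: pd.DataFrame, q: np.ndarray, model: str, rates: np.ndarray
) -> np.ndarray:
    """Signed belief distances for every trial under each pooled-rate value.

    Returns X of shape (n_trials, len(rates)). Because agents of the two
    categories are disjoint, running the pooled update with rate r yields,
    for category-c trials, exactly the trajectory of a category-specific
    model whose category-c rate is r; per-category likelihood slices of X
    therefore serve the 2P, 3P and 4P variants alike.
    """
    sim_up, ev_up, _ = RL_SCHEMES[model]
    G = rates.size
    n = len(session)
    X = np.empty((n, G))
    m_hat: dict[str, np.ndarray] = {}
    cond = session["condition"].to_numpy()
    aids = session["agent_id"].to_numpy()
    preds = session["agent_prediction"].to_numpy()
    corr = session["correctness"].to_numpy()
    bets = session["bet"].to_numpy()
    sign = np.where(np.isin(bets, ("for", "up")), 1.0, -1.0)
    for i in range(n):
        if cond[i] == ASSET_PREDICT:
            X[i] = sign[i] * (q[i] - 0.5)
            continue
        m = m_hat.setdefault(aids[i], np.full(G, 0.5))
        X[i] = sign[i] * (m - 0.5)
        if sim_up:
            sim = ability_mod.judge_simulation(
                int(preds[i]), float(np.clip(q[i], 1e-9, 1 - 1e-9))
            )
            if sim is not None:
                m += rates * (sim.g - m)
        if ev_up:
            m += rates * (int(corr[i]) - m)
    return X


def _fit_bayes_single_beta(model: str, params: dict, session: pd.DataFrame, q) -> tuple[dict, float]:
    traj = ability_mod.run_learner(model, params, session, q=q)
    x = _choice_signed_distance(session, traj)
    beta, ll = _fit_beta(x)
    return {"beta": beta, **params}, -ll


def _fit_weighted(session: pd.DataFrame, q) -> tuple[dict, float]:
    coarse = np.array([0.0, 0.1, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0])
    best = None
    for rho in coarse:
        for sigma in coarse:
            if rho + sigma == 0:
                continue
            traj = ability_mod.run_learner("weighted", {"rho": rho, "sigma": sigma}, session, q=q)
            x = _choice_signed_distance(session, traj)
            beta, ll = _fit_beta(x)
            if best is None or ll > best[0]:
                best = (ll, rho, sigma, beta)

    def neg(theta):
        rho, sigma, beta = theta
        # weights bounded at 5: beyond that only the rho/sigma ratio is
        # identifiable (the prior is already washed out within a few trials)
        if not (0 <= rho <= 5 and 0 <= sigma <= 5) or rho + sigma <= 1e-6 or beta < 0:
            return np.inf
        traj = ability_mod.run_learner("weighted", {"rho": rho, "sigma": sigma}, session, q=q)
        x = _choice_signed_distance(session, traj)
        return -_loglik_beta(x, beta)

    res = optimize.minimize(
        neg, x0=np.array(best[1:]), method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 400},
    )
    rho, sigma, beta = res.x
    return {"rho": float(rho), "sigma": float(sigma), "beta": float(beta)}, float(res.fun)


def _fit_rl(model: str, session: pd.DataFrame, q) -> tuple[dict, float]:
    scheme = RL_SCHEMES[model][2]
    cond = session["condition"].to_numpy()
    cats = session["category"].to_numpy()
    idx_p = (cond == AGENT_BET) & (cats == PERSON)
    idx_a = (cond == AGENT_BET) & (cats == ALGORITHM)
    idx_s = cond == ASSET_PREDICT

    X = _rl_signed_distances(session, q, model, RATE_GRID)
    # LL[category/asset] as (n_beta, n_rate) surfaces
    LLp = log_expit(BETA_GRID[:, None, None] * X[idx_p][None, :, :]).sum(axis=1)
    LLa = log_expit(BETA_GRID[:, None, None] * X[idx_a][None, :, :]).sum(axis=1)

    if model == "rl_evidence_4p":
        outcomes = session["outcome"].to_numpy()
        bets = session["bet"].to_numpy()
        sign_s = np.where(np.isin(bets[idx_s], ("for", "up")), 1.0, -1.0)
        Qs = np.stack(
            [asset_mod.rl_asset_belief_series(outcomes, ls)[idx_s] for ls in RATE_GRID], axis=1
        )
        Xs = sign_s[:, None] * (Qs - 0.5)
        LLs = log_expit(BETA_GRID[:, None, None] * Xs[None, :, :]).sum(axis=1)
    else:
        xs = X[idx_s][:, 0]
        LLs = log_expit(BETA_GRID[:, None] * xs[None, :]).sum(axis=1)[:, None]

    if scheme == "pooled":
        total = LLp + LLa + LLs[:, [0]] if LLs.shape[1] == 1 else None
        j, g = np.unravel_index(np.argmax(total), total.shape)
        start = {"lambda_p": RATE_GRID[g], "beta": BETA_GRID[j]}
        names = ["lambda_p"]
    else:
        # rates decouple given beta: optimize each rate's slice per beta
        best_p = LLp.max(axis=1)
        best_a = LLa.max(axis=1)
        if model == "rl_evidence_4p":
            best_s = LLs.max(axis=1)
            total_b = best_p + best_a + best_s
            j = int(np.argmax(total_b))
            start = {
                "lambda_p": RATE_GRID[int(np.argmax(LLp[j]))],
                "lambda_a": RATE_GRID[int(np.argmax(LLa[j]))],
                "lambda_s": RATE_GRID[int(np.argmax(LLs[j]))],
                "beta": BETA_GRID[j],
            }
            names = ["lambda_p", "lambda_a", "lambda_s"]
        else:
            total_b = best_p + best_a + LLs[:, 0]
            j = int(np.argmax(total_b))
            start = {
                "lambda_p": RATE_GRID[int(np.argmax(LLp[j]))],
                "lambda_a": RATE_GRID[int(np.argmax(LLa[j]))],
                "beta": BETA_GRID[j],
            }
            names = ["lambda_p", "lambda_a"]

    def neg(theta):
        p = dict(zip(names, np.clip(theta[:-1], 0.0, 1.0)))
        beta = theta[-1]
        if beta < 0 or beta > 20:
            return np.inf
        traj = ability_mod.run_learner(model, p, session, q=q)
        x = _choice_signed_distance(session, traj)
        return -_loglik_beta(x, beta)

    x0 = np.array([start[n] for n in names] + [start["beta"]])
    res = optimize.minimize(
        neg, x0, method="Nelder-Mead", options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 400}
    )
    theta = res.x
    params = {n: float(np.clip(v, 0.0, 1.0)) for n, v in zip(names, theta[:-1])}
    params["beta"] = float(theta[-1])
    return params, float(res.fun)


def fit_subject_mle(
    model: str, session: pd.DataFrame, q: np.ndarray | None = None
) -> tuple[dict, float]:
    """MLE of one subject's parameters; returns (params, NlogL).

    ``q`` is the precomputed asset-belief series; omitted, the default
    volatility filter is run on the session's outcomes (cached on the
    session). Fits are deterministic given the data.
    """
    if q is None and model != "full" and model != "rl_evidence_4p":
        q = ability_mod.default_asset_beliefs(session)
    if model in ("sequential", "evidence", "simulation"):
        return _fit_bayes_single_beta(model, {}, session, q)
    if model == "full":
        return _fit_bayes_single_beta(model, {}, session, None)
    if model == "weighted":
        return _fit_weighted(session, q)
    if model in RL_SCHEMES and model != "rl_eight_rate":
        return _fit_rl(model, session, q)
    raise ValueError(f"cannot fit model {model!r} per subject")


def compare_models(
    models: list[str],
    sessions: list[pd.DataFrame],
    q_list: list[np.ndarray] | None = None,
) -> pd.DataFrame:
    """Fit each model to every subject and tabulate summed NlogL and BIC.

    Rows are sorted by summed BIC ascending (best model first), with columns
    laid out as: model, params per subject, mean per-subject parameter
    values, summed NlogL, summed BIC.
    """
    if q_list is None:
        q_list = [ability_mod.default_asset_beliefs(s) for s in sessions]
    n_total = int(sum(len(s) for s in sessions))
    rows = []
    for model in models:
        try:
            fits = [fit_subject_mle(model, s, q) for s, q in zip(sessions, q_list)]
        except Exception as exc:  # record the failure, keep comparing
            rows.append({"model": model, "params_per_subject": MODEL_N_PARAMS.get(model),
                         "nlogl_sum": np.nan, "bic_sum": np.nan, "error": str(exc)})
            continue
        result = FitResult(
            model=model,
            params_per_subject=MODEL_N_PARAMS[model],
            subject_params=[p for p, _ in fits],
            subject_nlogl=np.array([nl for _, nl in fits]),
            n_trials_total=n_total,
        )
        row = {"model": model, "params_per_subject": result.params_per_subject}
        for k, v in result.mean_params().items():
            row[f"mean_{k}"] = v
        row["nlogl_sum"] = result.nlogl_sum
        row["bic_sum"] = result.bic_sum
        rows.append(row)
    table = pd.DataFrame(rows)
    return table.sort_values("bic_sum", na_position="last").reset_index(drop=True)


# ---------------------------------------------------------------------------
# fixed-effects eight-rate fit

_EIGHT_RATE_NAMES = [
    "gamma_p", "eta_p", "phi_p", "lambda_p",
    "gamma_a", "eta_a", "phi_a", "lambda_a",
]


def _session_events(session: pd.DataFrame, q: np.ndarray) -> dict:
    """Precompute the exogenous event streams one likelihood evaluation needs."""
    cond = session["condition"].to_numpy()
    bets = session["bet"].to_numpy()
    sign = np.where(np.isin(bets, ("for", "up")), 1.0, -1.0)
    idx_asset = cond == ASSET_PREDICT
    traj = ability_mod.run_learner("evidence", {}, session, q=q)  # classes/g only
    return {
        "agent_idx": np.flatnonzero(~idx_asset),
        "agent_ids": session["agent_id"].to_numpy(),
        "categories": session["category"].to_numpy(),
        "classes": traj["trial_class"],
        "g_ev": traj["g_ev"],
        "sign": sign,
        "x_asset": sign[idx_asset] * (q[idx_asset] - 0.5),
    }


def _eight_rate_nll(theta: np.ndarray, events: list[dict]) -> float:
    rates = {k: v for k, v in zip(_EIGHT_RATE_NAMES, theta[:8])}
    beta = theta[8]
    nll = 0.0
    cls_to_name = {"AC": "gamma", "DC": "eta", "AI": "phi", "DI": "lambda"}
    for ev in events:
        m_hat: dict[str, float] = {}
        x = []
        for i in ev["agent_idx"]:
            aid = ev["agent_ids"][i]
            m = m_hat.get(aid, 0.5)
            x.append(ev["sign"][i] * (m - 0.5))
            cls = ev["classes"][i]
            if cls is not None:
                suffix = "p" if ev["categories"][i] == PERSON else "a"
                rate = rates[f"{cls_to_name[cls]}_{suffix}"]
                m_hat[aid] = m + rate * (ev["g_ev"][i] - m)
        x = np.concatenate([np.asarray(x), ev["x_asset"]])
        nll -= _loglik_beta(x, beta)
    return float(nll)


def fit_fixed_effects_eight_rate(
    sessions: list[pd.DataFrame], q_list: list[np.ndarray] | None = None
) -> tuple[dict, float]:
    """Group-level MLE of the eight class-by-category rates plus shared beta.

    The model is not identifiable within single subjects (few trials per
    class), so the likelihood is pooled over all sessions and one parameter
    set is estimated for the group. Deterministic multi-start L-BFGS-B over
    bounded parameters.
    """
    if len(sessions) < 2:
        raise ValueError("fixed-effects fit needs at least two sessions")
    if q_list is None:
        q_list = [ability_mod.default_asset_beliefs(s) for s in sessions]
    events = [_session_events(s, q) for s, q in zip(sessions, q_list)]
    bounds = [(0.0, 1.0)] * 8 + [(0.0, 20.0)]
    starts = [
        np.array([0.10] * 8 + [5.0]),
        np.array([0.05] * 8 + [8.0]),
        np.array([0.30] * 8 + [3.0]),
    ]
    best = None
    for x0 in starts:
        res = optimize.minimize(
            _eight_rate_nll, x0, args=(events,), method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 300},
        )
        if best is None or res.fun < best.fun:
            best = res
    params = {k: float(v) for k, v in zip(_EIGHT_RATE_NAMES, best.x[:8])}
    params["beta"] = float(best.x[8])
    return params, float(best.fun)


# ---------------------------------------------------------------------------
# recovery experiments


@dataclasses.dataclass
class RecoveryReport:
    """Simulate-then-fit validation summary."""

    generator: str
    true_params: dict
    estimates: pd.DataFrame  # one row per simulated dataset/subject
    selection_counts: dict  # model -> times it won by summed BIC
    n_batches: int

    def bias(self, param: str) -> float:
        return float(self.estimates[param].mean() - self.true_params[param])

    def rmse(self, param: str) -> float:
        return float(np.sqrt(((self.estimates[param] - self.true_params[param]) ** 2).mean()))


def recovery_experiment(
    generator: str,
    gen_params: dict,
    fitted_models: list[str],
    n_subjects: int = 25,
    n_batches: int = 1,
    seed: int = 0,
    config=None,
) -> RecoveryReport:
    """Simulate cohorts under one model, refit candidate models, tabulate.

    Each batch simulates ``n_subjects`` fresh sessions and subjects from
    ``generator`` with ``gen_params``, fits every model in ``fitted_models``
    per subject, and records (a) the generator-model parameter estimates and
    (b) which model attains the lowest summed BIC. Fully seeded.
    """
    from .task import TaskConfig, generate_session, simulate_subject

    config = config or TaskConfig()
    ss = np.random.SeedSequence(seed)
    batch_seeds = ss.spawn(n_batches)
    est_rows = []
    selection: dict[str, int] = {m: 0 for m in fitted_models}
    for b, bs in enumerate(batch_seeds):
        subj_seeds = bs.spawn(n_subjects)
        sessions, q_list = [], []
        for s_seed in subj_seeds:
            child = s_seed.generate_state(2)
            sess = generate_session(config, seed=int(child[0] % (2**31)))
            q = ability_mod.default_asset_beliefs(sess)
            done = simulate_subject(generator, gen_params, sess, seed=int(child[1] % (2**31)), q=q)
            done.attrs["q_filter"] = q
            sessions.append(done)
            q_list.append(q)
        table = compare_models(fitted_models, sessions, q_list)
        winner = table.iloc[0]["model"]
        selection[winner] += 1
        for i, (sess, q) in enumerate(zip(sessions, q_list)):
            p, nll = fit_subject_mle(generator, sess, q)
            est_rows.append({"batch": b, "subject": i, "nlogl": nll, **p})
    return RecoveryReport(
        generator=generator,
        true_params=gen_params,
        estimates=pd.DataFrame(est_rows),
        selection_counts=selection,
        n_batches=n_batches,
    )
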