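"""Model-agnostic behavioral analyses of betting histories.

The central question: how do an agent's past correct and incorrect
predictions — and whether the subject likely *agreed* with them, as inferred
from the asset-tracking model — shape the subject's current bet on that
agent? The machinery is lagged logistic regression: the current bet (for=1)
is predicted from indicator regressors for the outcomes of the same agent's
previous ``n_lags`` trials, either split by correct/incorrect only, or by
the full agreement-by-correctness cross (AC, DC, AI, DI).

The headline statistic is the interaction contrast comparing the agreement
effect between people and algorithms. Following the display convention in
which incorrect-trial coefficients are sign-flipped (so positive values mean
"bets more after that event type" on a common axis), the per-category
agreement effect is ``(AC - DC) - (AI' - DI')`` with primed terms flipped,
and the group contrast is its people-minus-algorithms difference, tested
across subjects with a paired t test.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from . import ability as ability_mod
from .task import AGENT_BET, ALGORITHM, PERSON

__all__ = [
    "LagRegressionResult",
    "InteractionResult",
    "build_lagged_design",
    "lagged_outcome_regression",
    "agreement_split_regression",
    "interaction_contrast",
    "post_outcome_choice_frequency",
]

CLASSES = ("AC", "DC", "AI", "DI")
INCORRECT_CLASSES = ("AI", "DI")


@dataclasses.dataclass
class LagRegressionResult:
    """Per-category lagged-regression coefficients (and SEs where defined)."""

    coefficients: dict  # category -> pd.Series indexed by regressor name
    standard_errors: dict
    penalized: dict  # category -> bool (fell back to ridge)
    n_lags: int

    def display_coefficients(self, category: str) -> pd.Series:
        """Coefficients with incorrect-event terms sign-flipped (plot convention)."""
        coef = self.coefficients[category].copy()
        for name in coef.index:
            if name.startswith(("incorrect_", "AI_", "DI_")):
                coef[name] = -coef[name]
        return coef


@dataclasses.dataclass
class InteractionResult:
    """Group-level agreement-by-correctness-by-agent-type interaction."""

    per_subject: pd.DataFrame  # class means per category and the contrast, per subject
    contrast_mean: float
    t_stat: float
    f_stat: float
    p_value: float  # two-sided
    p_one_sided: float


def _agent_trial_classes(session: pd.DataFrame, q: np.ndarray | None = None) -> pd.Series:
    """AC/DC/AI/DI class of every agent trial (None where agreement undefined)."""
    if q is None:
        q = ability_mod.default_asset_beliefs(session)
    traj = ability_mod.run_learner("evidence", {}, session, q=q)
    mask = session["condition"].to_numpy() == AGENT_BET
    return pd.Series(traj["trial_class"][mask], index=session.index[mask])


def build_lagged_design(
    session: pd.DataFrame,
    n_lags: int = 5,
    split: bool = False,
    q: np.ndarray | None = None,
) -> pd.DataFrame:
    """Design table for the lagged regressions.

    One row per agent trial with at least ``n_lags`` previous trials of the
    *same* agent (histories run across block boundaries for agents that
    recur). Columns: ``y`` (bet for = 1), ``category``, ``block``, and per
    lag j either ``correct_lag{j}``/``incorrect_lag{j}`` indicators or the
    four class indicators ``AC_lag{j}`` ... ``DI_lag{j}`` (all zero for a
    lagged trial whose agreement was undefined).
    """
    agent_rows = session[session["condition"] == AGENT_BET]
    classes = _agent_trial_classes(session, q) if split else None
    names = (
        [f"{cls}_lag{j}" for j in range(1, n_lags + 1) for cls in CLASSES]
        if split
        else [f"{lab}_lag{j}" for j in range(1, n_lags + 1) for lab in ("correct", "incorrect")]
    )
    rows = []
    for _, grp in agent_rows.groupby("agent_id", sort=False):
        idx = grp.index.to_numpy()
        corr = grp["correctness"].to_numpy()
        for k in range(n_lags, len(idx)):
            bet = grp["bet"].iloc[k]
            if bet is None or (isinstance(bet, float) and np.isnan(bet)):
                raise ValueError("session bets must be filled before regression")
            row = {
                "trial": grp["trial"].iloc[k],
                "block": grp["block"].iloc[k],
                "category": grp["category"].iloc[k],
                "y": int(bet == "for"),
                **{nm: 0.0 for nm in names},
            }
            for j in range(1, n_lags + 1):
                if split:
                    cls = classes.loc[idx[k - j]]
                    if cls is not None:
                        row[f"{cls}_lag{j}"] = 1.0
                else:
                    lab = "correct" if corr[k - j] == 1 else "incorrect"
                    row[f"{lab}_lag{j}"] = 1.0
            rows.append(row)
    return pd.DataFrame(rows)


def _fit_logit(y: np.ndarray, X: pd.DataFrame) -> tuple[pd.Series, pd.Series, bool]:
    """Logistic fit with an L2-penalized fallback on separation/divergence."""
    import statsmodels.api as sm

    if len(np.unique(y)) < 2:
        warnings.warn("bets show no variation; coefficients set to zero", RuntimeWarning)
        zero = pd.Series(0.0, index=X.columns)
        return zero, pd.Series(np.nan, index=X.columns), True
    Xc = sm.add_constant(X, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        if res.mle_retvals.get("converged", False) and np.all(np.abs(res.params) < 15):
            return res.params.drop("const"), res.bse.drop("const"), False
    except Exception:
        pass
    warnings.warn("logistic regression separated; using ridge-penalized fit", RuntimeWarning)
    from sklearn.linear_model import LogisticRegression

    clf = LogisticRegression(C=1.0, solver="lbfgs", max_iter=1000)
    clf.fit(X.to_numpy(), y)
    coef = pd.Series(clf.coef_[0], index=X.columns)
    se = pd.Series(np.nan, index=X.columns)
    return coef, se, True


def lagged_outcome_regression(
    session: pd.DataFrame,
    n_lags: int = 5,
    by_category: bool = True,
    q: np.ndarray | None = None,
) -> LagRegressionResult:
    """Logistic regression of current bets on same-agent lagged outcomes."""
    design = build_lagged_design(session, n_lags=n_lags, split=False, q=q)
    return _run_lag_regression(design, n_lags, by_category)


def agreement_split_regression(
    session: pd.DataFrame,
    n_lags: int = 5,
    by_category: bool = True,
    q: np.ndarray | None = None,
) -> LagRegressionResult:
    """Lagged regression with outcomes split into AC/DC/AI/DI classes."""
    design = build_lagged_design(session, n_lags=n_lags, split=True, q=q)
    return _run_lag_regression(design, n_lags, by_category)


def _run_lag_regression(design: pd.DataFrame, n_lags: int, by_category: bool) -> LagRegressionResult:
    predictors = [c for c in design.columns if "_lag" in c]
    groups = design.groupby("category") if by_category else [("all", design)]
    coefs, ses, pen = {}, {}, {}
    for cat, sub in groups:
        X = sub[predictors]
        # drop all-zero columns (empty class at some lag): coefficient NA
        nonzero = [c for c in predictors if X[c].abs().sum() > 0]
        if len(nonzero) < len(predictors):
            warnings.warn(f"{cat}: empty predictor classes reported as NA", RuntimeWarning)
        coef, se, was_pen = _fit_logit(sub["y"].to_numpy(), X[nonzero])
        coefs[cat] = coef.reindex(predictors)
        ses[cat] = se.reindex(predictors)
        pen[cat] = was_pen
    return LagRegressionResult(coefficients=coefs, standard_errors=ses, penalized=pen, n_lags=n_lags)


def class_lag_means(result: LagRegressionResult, category: str, flip_incorrect: bool = True) -> dict:
    """Mean coefficient over lags 1..n for each AC/DC/AI/DI class."""
    coef = (
        result.display_coefficients(category)
        if flip_incorrect
        else result.coefficients[category]
    )
    out = {}
    for cls in CLASSES:
        vals = [coef[f"{cls}_lag{j}"] for j in range(1, result.n_lags + 1)]
        out[cls] = float(np.nanmean(vals))
    return out


def interaction_contrast(
    subject_results: list[LagRegressionResult], one_sided: bool = False
) -> InteractionResult:
    """Agreement-by-correctness-by-agent-type contrast across subjects.

    Per subject and category the lag-averaged class coefficients (incorrect
    classes sign-flipped to the display axis) enter
    ``(AC - DC) - (AI - DI)``; the subject's contrast is the
    people-minus-algorithms difference, tested against zero with a paired
    (one-sample) t test; F = t^2 with (1, n-1) degrees of freedom.
    """
    if len(subject_results) < 2:
        raise ValueError("need at least two subjects")
    rows = []
    for i, res in enumerate(subject_results):
        row = {"subject": i}
        cat_contrast = {}
        for cat in (PERSON, ALGORITHM):
            means = class_lag_means(res, cat, flip_incorrect=True)
            for cls, v in means.items():
                row[f"{cat}_{cls}"] = v
            cat_contrast[cat] = (means["AC"] - means["DC"]) - (means["AI"] - means["DI"])
            row[f"{cat}_contrast"] = cat_contrast[cat]
        row["contrast"] = cat_contrast[PERSON] - cat_contrast[ALGORITHM]
        rows.append(row)
    table = pd.DataFrame(rows)
    contrasts = table["contrast"].dropna().to_numpy()
    t_res = stats.ttest_1samp(contrasts, 0.0)
    t, p_two = float(t_res.statistic), float(t_res.pvalue)
    p_one = p_two / 2 if t > 0 else 1 - p_two / 2
    return InteractionResult(
        per_subject=table,
        contrast_mean=float(contrasts.mean()),
        t_stat=t,
        f_stat=t * t,
        p_value=p_one if one_sided else p_two,
        p_one_sided=p_one,
    )


def post_outcome_choice_frequency(
    session: pd.DataFrame, q: np.ndarray | None = None
) -> pd.DataFrame:
    """P(bet 'for' | same agent's previous trial class), by class and category."""
    agent_rows = session[session["condition"] == AGENT_BET]
    classes = _agent_trial_classes(session, q)
    recs = []
    for _, grp in agent_rows.groupby("agent_id", sort=False):
        idx = grp.index.to_numpy()
        for k in range(1, len(idx)):
            prev_cls = classes.loc[idx[k - 1]]
            if prev_cls is None:
                continue
            recs.append(
                {
                    "category": grp["category"].iloc[k],
                    "prev_class": prev_cls,
                    "bet_for": int(grp["bet"].iloc[k] == "for"),
                }
            )
    df = pd.DataFrame(recs)
    freq = (
        df.groupby(["category", "prev_class"])["bet_for"]
        .agg(["mean", "count"])
        .rename(columns={"mean": "p_bet_for", "count": "n"})
        .reset_index()
    )
    return freq
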