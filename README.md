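# expertrack

Model-based behavioral analysis of an **expertise-tracking task**: subjects
bet on whether forecasters — "people" (faces) or "algorithms" (fractals) —
will correctly predict a drifting binary asset, and occasionally predict the
asset themselves. Each forecaster has a fixed, outcome-independent
probability α of being right; the asset's up-probability drifts as
successive beta draws (SD 0.07). The scientific questions this tooling
serves: *how* do observers learn another agent's ability (from realized
correctness, from agreement with their own beliefs, or both), and do they
learn differently about people and algorithms?

The package is for computational-cognitive researchers who want a fully
simulated, ground-truth-known version of this paradigm: a task generator,
the complete family of learning models, likelihood-based fitting with BIC
comparison, the lagged-regression behavioral analyses, and construction of
the model-derived trial-wise regressors used in model-based neuroimaging.

## The models

Beliefs about an agent's ability are Beta pseudo-count posteriors: with a
uniform prior and binary quality judgments *g*,

    p(α | g_1:t) = Beta(1 + #[g=1], 1 + #[g=0])

Judgments come in two flavors — *simulation* (mid-trial: g = 1 iff the
agent's prediction lies on the subject's asset belief q_t's side of 0.5)
and *evidence* (feedback: g = correctness c_t). The **evidence**,
**simulation** and **sequential** (both, in order) models use one or both;
a **weighted** variant applies them with fractional weights ρ, σ; a **full
model** does joint grid inference over (q, α); and delta-rule
reinforcement-learning counterparts (1, 2, 3, or 8 learning rates) replace
the conjugate update with m̂ ← m̂ + λ(g − m̂). Bets follow a softmax

    P(bet = for) = 1 / (1 + exp(−β (mean(α_t) − 0.5)))

with one inverse temperature β per subject, and q_t comes from a Bayesian
volatility filter (a hierarchical grid learner over reward probability,
volatility, and volatility-of-volatility). Models are compared by summed
BIC = 2·ΣNlogL + k·n_subjects·ln(N_total).

## Worked example

```python
from expertrack import task, ability, fit

sess = task.generate_session(seed=1)          # 220 trials, 88/88/44 design
q = ability.default_asset_beliefs(sess)       # volatility-filter q_t
subj = task.simulate_subject("sequential", {"beta": 4.45}, sess, seed=2, q=q)

params, nlogl = fit.fit_subject_mle("sequential", subj, q)
print(params, nlogl)
table = fit.compare_models(["sequential", "evidence", "simulation"], [subj], [q])
print(table[["model", "nlogl_sum", "bic_sum"]])
```

prints (exactly, given these seeds)

```
{'beta': 4.460900744629941} 142.9266271475243
        model   nlogl_sum     bic_sum
0  sequential  142.926627  291.246882
1    evidence  145.364013  296.121653
2  simulation  147.691749  300.777125
```

— the fitted β ≈ 4.46 recovers the generating value 4.45 from one session's
220 bets, and the generating (sequential) model beats both single-update
models on BIC for this subject.

The numbered drivers under `analysis/` run the full study on a simulated
25-subject cohort and write their tables to `results/`:

```bash
cd analysis
python 01_simulate_cohort.py        # the cohort and task summary
python 02_model_comparison.py       # 11-model BIC table (sequential wins)
python 03_parameter_recovery.py     # beta, (rho,sigma), eight-rate recovery
python 04_behavioral_regressions.py # lagged regressions + interaction contrast
python 05_latent_regressors.py      # EV/rPE/aPE regressors + correlations
```

For shell use there is also a thin CLI: `expertrack simulate|fit|compare|
analyze|regressors|recover|all` (see `--help`).

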