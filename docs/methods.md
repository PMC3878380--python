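# Methods

This note documents the generative task model, the family of expertise
learners, the fitting and comparison machinery, and the behavioral analyses
implemented in `expertrack`, together with the numerical choices and known
limitations. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The task

A session is 4 blocks × 55 trials = 220 trials. A binary asset goes up on
trial *t* with probability *p*ᵗʳᵘᵉ_t; each successive probability is drawn
from a beta distribution with SD 0.07 whose mean is the previous value,
clipped into [0.10, 0.90] before the draw so the moment-matched
parameterization (ν = m(1−m)/σ² − 1, shapes mν and (1−m)ν) is always proper.
The clip bounds and the initial probability p₀ = 0.5 are not part of the
published design we emulate and are configurable; the defaults keep realized
probabilities fluctuating in roughly the 0.25–0.75 band.

Eight forecasting agents — four "people" and four "algorithms" — have fixed
abilities α ∈ {0.3, 0.4, 0.6, 0.7}: each predicts the asset's move correctly
with independent probability α. Each block presents three agents (two of one
category plus one of the other, alternating across blocks; the majority
category of block 1 is configurable) for 14–15 trials each, plus 11
asset-prediction trials, for session totals of 88 person, 88 algorithm and
44 asset trials. The 0.4 and 0.6 agents of each category recur in a later
block and their beliefs carry over. Stimuli are interleaved with no
immediate repeats, enforced across block boundaries as well; the scheduler
samples labels sequentially with a forced-placement rule (a label whose
remaining count exceeds half the remaining slots must be placed) and retries
on the rare dead end, which is cheaper and more reliable than rejection
sampling a full permutation.

On agent trials the subject bets *for* or *against* the agent's upcoming
prediction and earns +$1 if the bet about the agent's correctness is right,
−$1 otherwise; on asset trials the subject predicts the direction itself.
Payoffs never depend on the asset's own performance.

One master seed is split (`numpy.random.SeedSequence`) into independent
streams for the asset, the agents' predictions, the schedule, and the
simulated subject's choices, so each component is separately reproducible.

## Asset learning

The subject's belief q_t that the asset goes up is tracked by a grid-based
Bayesian volatility filter: the up-probability *r* drifts per trial through
a beta kernel whose SD is the current volatility *v*; log *v* follows a
Gaussian random walk with SD *k*; *k* is static. Default grids: 30 points
for *r* (cell midpoints of (0,1)), 30 log-spaced points for *v* on
[0.01, 0.25], 15 log-spaced points for *k* on [0.05, 2]. The joint posterior
is propagated through the two kernels and conditioned on each Bernoulli
outcome, renormalized after every step (normalization tolerance 1e-10).
Because every likelihood factor is bounded below by the smallest grid
midpoint, linear-space propagation with per-step renormalization cannot
underflow, so no log-space bookkeeping is needed. Near the grid edges the
kernel SD is capped at 0.9·√(m(1−m)) to keep the beta shapes proper; the
kernel mean is *not* clipped, so sustained evidence can drive q_t beyond the
generator's clip bounds (as it should — the filter models the subject, not
the generator). In the static limit (v pinned to ~0 the kernel becomes the
identity) the filter reduces exactly to a grid-discretized Beta–Bernoulli
learner, which the tests use as a conjugate oracle. q_t always denotes the
belief *before* trial t's outcome.

The exact grids and priors of the original filter formulation are not
recoverable; the implementation is a standard member of that family and its
hyperparameters are exposed in `VolatilityFilter`.

The reinforcement-learning alternative is a delta rule
q̂ ← q̂ + λ_s(o − q̂) with learning rate λ_s ∈ [0, 1].

## Expertise learners

All Bayesian variants share the conjugate core: with a uniform Beta(1,1)
prior over an agent's ability and binary quality judgments *g*, the
posterior is Beta(1 + Σwg, 1 + Σw(1−g)). Two judgment rules exist:

* simulation (mid-trial): g = 1 iff the agent's prediction lies on q_t's
  side of 0.5. At q_t = 0.5 exactly no judgment is made and no update
  occurs; under the continuous filter this is a measure-zero tie, and
  delta-rule asset beliefs that touch 0 or 1 exactly are nudged into the
  open interval before judging.
* evidence (feedback): g = c_t, the realized correctness.

The evidence model applies only the feedback update (the optimal rule here,
since ability is outcome-independent); the simulation model only the
mid-trial update; the sequential model both in order, the second applied to
the already-updated belief. The weighted semi-Bayesian model applies them
with fractional pseudo-count weights ρ (simulation) and σ (evidence); it
nests the sequential model at ρ=σ=1 and the evidence model at ρ=0
bit-for-bit, and the between-subject covariate is σ/(ρ+σ). Realizing the
weights as fractional pseudo-counts is a design choice: it shifts the
ability distributions up or down relative to the sequential model while
preserving the conjugate form.

The full model does joint inference on a per-agent 2-D grid (default 40×40;
even sizes keep 0.5 off the grid) over the asset up-probability and the
agent's ability, treating both as static unknowns. At the agent's
prediction the posterior is multiplied by the coupling likelihood
P(a=1|q,α) = α·1{q>0.5} + (1−α)·1{q<0.5}; at every observed outcome
(including other agents' trials and asset trials — the direction is always
shown) by the Bernoulli asset likelihood. The subject's overall asset
belief, used for condition-3 choices under this model, is the mean of the
active grids' q-marginal means. An alternative "outcome" coupling (agent
matches the realized outcome with probability α) is provided as a toggle;
it factorizes into evidence model × asset model and serves as a cross-check
oracle. The original joint formulation is not recoverable in detail; the
direction coupling is the declared reading, and its poor fit in the model
comparison (it judges good agents badly whenever the drifting probability
crosses 0.5) is itself a property the comparison is expected to show.

RL variants replace the conjugate update with m̂ ← m̂ + rate·(g − m̂),
initialized at 0.5: one pooled rate (2P), per-category rates (3P), a
4-parameter evidence variant whose asset beliefs come from the delta-rule
tracker (the only variant with λ_s), and the eight-rate model with one rate
per agreement-by-correctness class (AC, DC, AI, DI) and category, updating
at feedback only (the classes are feedback-defined); unclassifiable trials
(agreement tie) are not updated. For 2P/3P variants q_t comes from the same
volatility filter as the Bayesian models, consistent with their parameter
counts.

## Choice rule, likelihood, latent variables

P(bet for) = 1/(1 + exp(−β(m − 0.5))) with the pre-trial belief mean m, and
the same rule in q_t − 0.5 for asset predictions; a single β per subject is
shared across all three conditions, matching the one-parameter count of the
Bayesian models in the comparison table. Session log-likelihood sums over
all 220 trials with per-trial probabilities floored at 1e-12.

Latent trial variables (dollar units for value terms): EV_chosen =
2·P(win|bet) − 1 ∈ [−1, 1]; rPE = payoff − EV_chosen ∈ [−2, 2]; simulation
aPE = g − m_pre; evidence aPE = g − m_mid (m_mid is the mid-trial-updated
mean, which equals m_pre under models without a mid-trial update); unsigned
terms are absolute values; surprisal = −log₂ P(g) in bits, with P(g) the
probability the current belief assigned to the observed judgment. The
garbled printed form of the surprise expression is read as standard
surprisal. For binary events |g − m| = 1 − P(g), an almost-linear function
of −log₂P(g) over the belief range this task produces, which is why
unsigned aPEs and surprisal correlate near 0.98.

## Fitting and model comparison

Per-subject MLE is deterministic: a coarse grid (β on [0, 20] in 201 steps;
rates on [0, 1] in 101 steps) followed by bounded local refinement
(bounded scalar minimization for β; Nelder–Mead for multi-parameter models).
Two structural facts keep this cheap: Bayesian belief trajectories do not
depend on β, so the β likelihood is a 1-D problem over a fixed trajectory;
and RL trajectories for the two agent categories depend only on their own
category's rate, so per-category likelihood slices evaluated on the pooled
rate grid serve the 2P, 3P and 4P variants alike. The weighted model's
(ρ, σ) are bounded at 5 during refinement: beyond that the prior is washed
out within a few trials and only the ratio is identifiable. Degenerate data
(bets without variation) produce a boundary estimate with a warning.

The eight-rate model is fit as fixed effects — one parameter set maximizing
the likelihood pooled over all sessions — because single subjects provide
too few trials per class; the optimizer is multi-start L-BFGS-B over
bounded parameters (three fixed starts, best kept).

Comparison uses summed BIC = 2·ΣNlogL + k·n_subjects·ln(N_total) with
NlogL in natural-log units and N_total the pooled trial count across
subjects and conditions (5500 for 25 subjects × 220 trials). This
convention is pinned by the requirement that it reproduce the published
comparison table's printed (NlogL, BIC) pairs to within rounding, which it
does for both the one- and two-parameter rows; it is documented here as
derived rather than stated.

Recovery experiments (simulate → refit → tabulate bias/RMSE and BIC
selection counts) are fully seeded and deterministic.

## Behavioral regressions

Current bets (for = 1) are regressed on indicator regressors for the same
agent's previous five outcomes — correct/incorrect per lag, or the
agreement-by-correctness cross AC/DC/AI/DI per lag — via per-subject
logistic regression (logistic rather than linear is a choice; the link used
originally is unstated, and a linear fit of the same designs is a trivial
swap). Agreement is operationalized exactly as the simulation judgment:
agree iff the agent's prediction lies on the filter q_t's side of 0.5 — the
only symmetric threshold. Trials with fewer than five same-agent
predecessors are excluded; histories cross block boundaries for recurring
agents. On separation or non-convergence (common: ~21 predictors on ~65
trials of fairly deterministic choices) the fit falls back to an
L2-penalized logistic regression with a warning, and standard errors are
reported as NA; bets with no variation at all yield zero coefficients with
a warning.

The interaction contrast is computed on display-convention coefficients —
incorrect-class coefficients sign-flipped so that every class measures
"more betting after that event" on a common axis: per category
(AC − DC) − (AI − DI), and the group statistic is the
people-minus-algorithms difference tested with a one-sample t across
subjects (F = t²). The flip matters: with equal DC/DI rates and the
asymmetry γᵖ > γᵃ, φᵖ < φᵃ, the raw-coefficient contrast is zero by
algebra while the display-convention contrast isolates the agreement
asymmetry. A one-sided test option exists for directional replications.

## Synthetic cohorts: what they do and do not show

The synthetic generator reproduces the task's structure, payoffs, and
stochasticity and lets every analysis be validated against known ground
truth. It does not emulate real subjects' lapses, drifting attention,
response biases, block-order effects, or any individual variability beyond
what the generating model's parameters provide; passing tests therefore
demonstrate that the analyses recover what they claim from data of this
size and structure, not that any particular model describes human behavior.
Cohort sizes in the analyses (20–25 subjects, 220 trials) mirror the study
design they emulate.

## Numerical choices, degenerate inputs, limitations

* Filter posterior renormalized each step; degenerate (non-finite or
  non-positive) posteriors raise immediately rather than propagate.
* Likelihood floor 1e-12 per trial; β grid capped at 20 (a logistic in
  m − 0.5 is effectively a step function well before that).
* Exact agreement ties (q_t = 0.5) yield no judgment, no update, and are
  excluded from AC/DC/AI/DI classification.
* All fits are deterministic given data; no random restarts.
* The weighted model's ρ, σ are only jointly identifiable up to ~5; the
  reported covariate σ/(ρ+σ) is the stable quantity.
* The eight-rate fixed-effects fit assumes parameter homogeneity across
  subjects; it is a group-level description, not a hierarchical model.
* Quantities that require the original subject dataset (its NlogL values,
  mean β, asset-prediction hit rate, behavioral test statistics) are out of
  scope; the corresponding analyses are validated as qualitative patterns
  on synthetic cohorts instead.
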