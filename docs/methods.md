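# Methods

`habitlearn` is a simulate–analyze–fit package for two-step
outcome-devaluation experiments.  It exists to exercise, end to end and on
fully known ground truth, the claim that *model-based* reinforcement
learning during training protects against habit formation — i.e. predicts
sensitivity to a later devaluation of the learned outcome — while
*model-free* learning does not.  This note documents the models, the
choices that were genuinely open, and what the synthetic world does and
does not establish.

## The task

Two variants of a two-stage Markov decision task are generated.

**Two-game variant ("exp1").**  Two structurally identical games (gold and
silver coins, 25¢ each) are interleaved over 200 training trials (100 per
game, randomized with no run longer than 4).  A first-stage choice between
two options leads with probability .70 to that option's "common"
second-stage state and with probability .30 to the alternative; each
second-stage state pays a coin with a probability that follows an
independent Gaussian random walk (SD 0.025 per trial, reflected at .25 and
.75, initialized uniformly inside the bounds).  Responding costs 1¢ and
must occur within 2.5 s (the simulator models lapses as a configurable
omission rate, default 0).  After training come 4 no-feedback trials
(outcomes hidden; split 2/2 across games), the devaluation of one coin
type (counterbalanced across subjects), 20 test trials (10 per game,
random order) on which the agent may respond or withhold, and a
consumption display of 10 + 10 coins.

**Single-game variant ("exp2").**  One game whose two second-stage states
pay the two coin types.  150 drifting trials are followed by 50 trials
with reward probabilities pinned at .9 for the to-be-devalued state and .1
for the other — biasing every subject toward the action that is about to
be devalued — then 4 no-feedback trials, devaluation, and a 10-trial
forced-choice habit test (no withhold option, no response cost).

Reflection at a walk bound maps an overshoot p to 2·bound − p (repeatedly
if needed); this is the standard reading of a reflecting boundary and
preserves the stationary spread of the walk.

## The hybrid agent

Each simulated subject carries parameters (α, β, w, π) plus two
respond-rule parameters described below.  Two valuation systems run in
parallel:

* **Model-free.**  A cached first-stage value Q_MF(game, a) updated by a
  delta rule toward the terminal reward, Q ← Q + α(r − Q) (an eligibility
  parameter λ can blend the second-stage value into the target; λ = 1 by
  default because the task has no second-stage choice).  Second-stage
  values V2(s) are updated the same way.
* **Model-based.**  Q_MB(a) = P(common)·u(s_a)·V2(s_a) +
  P(rare)·u(s_a′)·V2(s_a′), where u(s) ∈ {1, 0} is the current incentive
  value of the coin paid by state s.  The transition model is fixed at the
  true .7/.3 mapping (participants are instructed and pre-trained on it).

Choice is a softmax over the mixture Q = w·Q_MB + (1 − w)·Q_MF with
inverse temperature β and a perseveration bonus π for repeating the
previous choice *in the same game*.  All cached values initialize at 0.5,
the midpoint of the reward-probability range.

Devaluation sets u(s) = 0 for the devalued coin's state(s) **and nothing
else** — the cached Q_MF is untouched.  That asymmetry is the entire
mechanism: a w = 1 agent re-evaluates instantly, a w = 0 agent cannot.

**Respond/withhold rule (two-game test phase).**  The engagement value of
a game is E = max_a Q(a) · 0.25 USD − 0.01 USD and
P(respond) = logistic(β_resp·E + b_resp).  This rule is a generative
assumption of this package, not an empirical estimate.  Defaults
β_resp = 50 /USD and b_resp = −1.7 were fixed a priori by solving the
logistic for P(respond | valued) ≈ .98 and P(respond | devalued, w = 1) ≈
.10, which reproduces the strongly bimodal devaluation-sensitivity
histogram (peaks near 0 and 10) that motivates the analysis; with the
response cost only 1¢, a flatter gain (e.g. β_resp ≈ 20) cannot separate
the two peaks.

**Default cohort.**  w ~ Uniform(0, 1) (the quantity under study),
α ~ Beta(5, 5), β ~ LogNormal(ln 5, 0.3), π ~ Normal(0.2, 0.15); the
devalued coin alternates across subjects.  A "null" cohort drives the
test phase with an independently drawn w, severing the true link between
training and devaluation behavior; it is the specificity control for
every between-subject analysis.  Consumption behavior is a generator
convention: each valued coin is collected with probability .55 and each
devalued coin with probability .06, making the in-silico manipulation
check (paired t-test on collected counts) meaningful.

## Behavioral metrics and filters

Devaluation sensitivity is valued-state minus devalued-state responses in
the two-game test (−10…10) or the proportion of still-valued choices in
the single-game test (0…1).  Consumption sensitivity is valued minus
devalued coins collected.  Exclusion rules (all strict): more than 10% of
training trials missed; the same key on more than 90% of responses; mean
reaction time beyond ±2 SD of the cohort mean (applied only when an RT
summary is supplied — the simulator does not generate RTs; the per-subject
*mean* RT is compared to the cohort distribution).  z-scoring uses the
n − 1 denominator and refuses constant vectors.

## Stay-probability analyses

The lagged design codes every training choice as stay (1) or switch (0)
against the previous choice *in the same game*, with that previous trial's
reward (+1/−1) and transition type (common +1 / rare −1) as predictors;
non-response trials are dropped both as targets and as lag sources.  The
reward main effect is the model-free signature, the reward × transition
interaction the model-based one.

The mixed-effects logistic model
`stay ~ reward * transition * deval_z + (1 + reward*transition | subject)`
is fit by two engines:

* **Two-stage (default, deterministic).**  Per-subject ML logistic fits of
  `stay ~ reward * transition` — with a hand-rolled Firth (Jeffreys-prior)
  fallback so complete separation (all-stay subjects) still yields finite
  coefficients — followed by a random-effects meta-regression of each
  subject-level coefficient on standardized devaluation sensitivity, with
  weights 1/(se²ᵢ + τ²) and τ² from the DerSimonian–Laird moment
  estimator.  The slope of the reward × transition coefficients on
  deval_z is the three-way interaction.
* **Hierarchical Bayesian (reference).**  Subject coefficient vectors are
  Gaussian with full covariance (inverse-Wishart prior, K + 2 df, scale
  0.5·I); each coefficient's group mean is linear in deval_z with
  Normal(0, 1.5²) priors.  Sampling is adaptive Metropolis-within-Gibbs
  (conjugate draws for the group means/covariance, random-walk Metropolis
  shaped by the current covariance for the subject vectors, tuned to ~30%
  acceptance during warmup, 10 subject sweeps per iteration).  Reported
  "p" values are doubled posterior sign probabilities, floored at 2/draws,
  and split-R-hat is reported per fixed term.

Per-subject learning indices (model-free = reward coefficient,
model-based = reward × transition coefficient) come either from the
independent per-subject fits or from the hierarchical model's shrunken
subject effects — in the latter case the hierarchical model must be the
*basic* one (no devaluation covariate), otherwise the devaluation score
would leak into its own predictor.  The index linear model regresses raw
devaluation sensitivity on standardized indices (plus optional covariates
and covariate × model-based-index interactions) by OLS.

## Hybrid-model estimation

The choice likelihood replays the simulator's exact update kernel (one
shared code path), accumulating log P(choice) over training trials;
hidden-feedback trials contribute choice likelihood but trigger no update.
With β = 0 the likelihood is exactly T·ln 2, a useful oracle.

* **MLE**: bounded L-BFGS-B over (α, β, w, π), best of n restarts
  (default 10; the first start is the neutral midpoint), with the full
  per-restart log retained.
* **Hierarchical**: subject parameters live on transformed scales
  (logit α, ln β, logit w, identity π) with the same
  Gibbs/Metropolis machinery as above; the group mean of logit w is
  a + b·deval_z (the covariate can be extended to all parameters for the
  specificity check).  Profiles: full = 4 chains × (1000 warmup + 1000
  kept); reduced = 2 × (300 + 300), intended for CI-scale runs.
  Convergence (split-R-hat, bulk ESS via arviz) is always reported; an
  unconverged run returns with a warning status rather than raising.
  Chains initialize at cheap single-start per-subject MLEs.

The posterior for b is the package's analogue of the group-level
association between the model-based weight and devaluation sensitivity;
under the default linked cohort it concentrates around ≈ +0.8…1.3 on the
logit-w scale, and under the null cohort it straddles zero.

## What the synthetic world does not establish

* Subjects are exactly the model being fit; recovery and calibration
  results say nothing about model misspecification in humans.
* Because a single weight w trades the two systems off against each
  other, the model-free index is mechanically anti-correlated with w
  (corr ≈ −0.65 in the default cohort).  When devaluation behavior is
  generated from w, the model-free index therefore carries real
  (negative) information about devaluation sensitivity.  The empirical
  dissociation in human cohorts — a model-based index that predicts
  devaluation while the model-free index is flat — can only arise if
  model-free strength varies independently of w across people; no
  single-w cohort reproduces it, and this package deliberately does not
  force it.
* No reaction times, no learned transition model (the .7/.3 mapping is
  known to the agent throughout), one shared learning rate for both
  stages, no forgetting of unchosen options, no second-stage choices.
* The respond/withhold mechanism and the consumption probabilities are
  conventions; only their qualitative structure (model-based branch
  devaluation-sensitive, model-free branch blind) is meaningful.

## Numerical notes

Reward walks clamp pathological multi-width overshoots by modular
reflection; the constrained game interleave maintains feasibility
analytically rather than by rejection.  The likelihood kernel is
numba-compiled when numba is importable and falls back to identical pure
Python otherwise (a test asserts bit-level agreement).  Logistic fits are
declared separated when ML fails to converge, |coef| ≥ 8, or an SE
exceeds 20, and are then refit by Firth with damped Newton steps.  MCMC
child seeds are derived per chain as seed + 7919·chain (mod 2³¹);
pipeline stages use seed·1009 + 9973·stage (mod 2³¹ − 1), so any stage
can be rerun in isolation and deterministic stages reproduce
byte-identical CSVs.
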