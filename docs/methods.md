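# Methods

This note documents the models, estimators, and numerical choices the
package implements, the design decisions taken where more than one
reasonable construction exists, and what the synthetic-data generator does
and does not emulate.

## Generative model of one trial

Choice states are fully observed (the agent always knows which arm it
chose), so the POMDP reduces to belief updating over the reward likelihood
only. Beliefs are Dirichlet concentration counts `a` over (win, loss)
outcomes per arm, reset to the uniform value `a_0` at each game boundary
because reward probabilities change between games. Expected free energy
per arm is

    G_k = −IG_k − Σ_o Ā_ok · ln C_o ,

with `Ā` the column-normalised counts, `C = softmax([0, c_r, 0])` over
(neutral, win, loss), and

    IG_k = Σ_o Ā_ok · ½ (1/a_ok − 1/Σ_o' a_o'k)

the standard Dirichlet novelty bound on the expected information gain.
Because states are observed, the risk term's predicted-outcome entropy and
the ambiguity term cancel exactly, leaving the two-term expression above.
An exact alternative — the expected KL divergence
`E_{o~Ā_k} KL[Dir(a_k + e_o) ‖ Dir(a_k)]` — is available behind a flag
(`information_gain(..., exact=True)`); with two outcomes it reduces to
Beta-distribution KLs and is used as a numerical cross-check, not as the
default, to stay consistent with the scheme the field's reference software
uses. Note the bound and the exact KL can order arms differently in corner
cases; both are positive and both shrink monotonically as counts grow,
which is the behaviour the model relies on.

Actions are sampled from `softmax(α · (−G))`. The literature states the
policy distribution as `σ(−G)` with precision modulating determinacy but
does not print the algebraic composition; for single-step policies the
natural reading (temperature directly on −G) is adopted as the single
canonical choice, and recovered α values are interpretable only under that
convention. After the outcome, the one observed (outcome, arm) cell of `a`
is incremented by `η_win` or `η_loss`. The neutral/start outcome row is
never updated.

## The nested model family

Ten nested models toggle which of {α, c_r, η (shared), η_win/η_loss, a_0}
are estimated; reward sensitivity is always estimated. Fixed values for
non-estimated parameters: α = 4, a_0 = 0.25. A model whose learning rate
is "removed" reverts to the standard Bayesian count update with unit
increment (η = 1), which the learning-rate parameter generalises. The
alternative reading — no belief updating at all — degenerates: frozen
uniform beliefs give every arm the same expected free energy on every
trial, so all four reduced models would collapse onto the chance model and
their remaining parameters would be vacuous. The unit-rate convention
keeps every model a substantive competitor, which model comparison
requires.

## Per-subject estimation

Parameters are estimated in an unconstrained space (log for α, c_r, a_0;
logit for learning rates; log chosen for a_0 for positivity) under
independent Gaussian priors with means at the transforms of (4, 4, 0.5,
0.25) and variance 2⁻² per parameter — deliberately precise to deter
over-fitting. The likelihood advances beliefs along the subject's observed
choices and outcomes. Because beliefs reset per game and each event adds
one learning-rate increment, the whole 320-trial count trajectory is an
affine function of (a_0, η_win, η_loss) given the data; the implementation
exploits this to evaluate the likelihood with batched array operations
(~0.1 ms per evaluation), which is what keeps cohort-scale refitting
cheap.

MAP optimisation uses L-BFGS-B from the prior mean plus four seeded
jittered starts (gradient tolerance 1e-5, 500 iterations); the posterior
covariance is the inverse of a central finite-difference Hessian of the
negative log joint at the optimum (step 1e-3 scaled per coordinate),
projected to the nearest positive-definite matrix with a logged warning if
needed. The model evidence is the Laplace bound
`F = log p(y, θ̂) + ½ log det(2π Σ)`. This reproduces the contract of a
variational-Laplace fit — the (mean, covariance, evidence) triple — not
the reference implementation's iteration-by-iteration internals.

Accuracy metrics are computed at posterior-mean parameters: the mean
probability assigned to observed actions, and the percentage of trials on
which the observed action attains the maximum action probability. Ties
(every game's symmetric first trial) credit any tied action, which keeps
the metric invariant under consistent arm relabelling; this inflates
accuracy relative to a fixed tie-break by roughly the tie frequency
(~6 points), which matters when comparing against externally reported
accuracies.

### Identifiability structure

The model has a soft scale ridge: multiplying a_0, η_win and η_loss by a
common factor leaves the expected reward probabilities `Ā` untouched and
only rescales the novelty term. Estimation therefore projects parameter
combinations onto an identifiable manifold; combinations drawn
independently of each other recover poorly even when each marginal is
plausible. Parameter-recovery studies consequently use a two-stage
procedure (see `diagnostics.parameter_recovery`): stage 1 draws agents
from estimation-space Gaussians moment-matched to the published follow-up
parameter moments and fits them; stage 2 uses the inferred posterior
combinations — which lie on the manifold, as real subjects' inferred
values do — as generative values, simulates fresh sessions, refits, and
correlates. Recovery correlations for the win learning rate and a_0 run
below the other parameters in this implementation: wins concentrate on the
exploited arm, where choice is insensitive to the exact reward belief once
behaviour saturates, so η_win's likelihood information is weakest exactly
where its values are extreme, and a_0 shares the ridge with both rates.

## Random-effects model selection

Subject-level Laplace evidences feed the variational Dirichlet update
over model frequencies (uniform prior concentration 1). Exceedance
probabilities come from 10⁵ seeded Dirichlet Monte-Carlo draws
(reproducible to ±0.005 across seeds). The Bayes omnibus risk compares
the free energy of the random-effects model against the equal-frequency
null, `bor = 1/(1 + exp(F1 − F0))`, and protected exceedance
probabilities are `pxp = (1 − bor)·ep + bor/M`. With identical evidences
for two models at N = 20 the construction gives bor ≈ 0.79 (it approaches
1 slowly in N), with pxp exactly symmetric.

## Group inference ("PEB-lite")

Group analyses run per parameter in estimation space. Each
subject-session contributes its posterior mean with its posterior variance
as known observation noise. The observation covariance is
`diag(var_i + σ²_e) + σ²_b ZZ'` (Z the subject incidence matrix), with
both components estimated by marginal maximum likelihood — a deliberate
simplification of the reference hierarchical scheme to a single
between-subject component plus a subject random intercept, preserving its
inferential target (effect posteriors and model-reduction posterior
probabilities) at desk scale. Predictors are intercept, group (SUD = 1),
session (follow-up = 1), their interaction, and always-included covariates
(mean-centred age and premorbid IQ, sex coded male = 1). Priors on betas
are N(0, 1) for effects and covariates and N(0, 10) for the intercept;
prior scales are recorded in the result metadata, and the Gaussian
evidence is exact, so sensitivity to the prior scale can be probed by
re-running with a different `prior_var_effect`. Bayesian model reduction
scores all 2³ on/off combinations of {group, session, interaction} by
exact Gaussian log evidence (an excluded effect's prior variance collapses
to 1e-8). Reported quantities: model-averaged betas with credible
intervals, per-effect inclusion probabilities, the winning reduced model,
and conditional-on-inclusion effect posteriors (the magnitude estimate
unshrunk by null-model mass). The frequentist arm fits the same design
with a subject random intercept (statsmodels MixedLM), reporting Wald
F(1, ·), p, and partial η² with denominator df approximated as rows minus
fixed effects; singular fits fall back to OLS with a flag.

## Reliability and prediction statistics

- **ICC(3,1)** — two-way mixed, consistency, single measures:
  `(MS_rows − MS_err)/(MS_rows + MS_err)` for k = 2, p from
  F = MS_rows/MS_err with (n−1, n−1) df; zero between-subject variance is
  a defined error, not a NaN.
- **JZS correlation Bayes factor** — stretched-beta prior
  `(ρ+1)/2 ~ Beta(1/rscale, 1/rscale)` with rscale = 1/3, marginal
  likelihood by adaptive quadrature of the exact sampling density of the
  observed correlation (hypergeometric form). Agrees with an independent
  implementation to six significant figures.
- **Grubbs trimming** — iterative two-sided test at α = .01, removing the
  single most extreme value per iteration until no outlier remains;
  applied per subject-session to RT distributions before averaging.
- **Stay/shift counts** — for each within-game transition (15 per game,
  300 per complete session), stay/shift classified by the previous trial's
  outcome. The early/late split assigns transitions at trials 2–8 to the
  early phase (7 per game) and 9–16 to late (8 per game) so that every
  transition is classified; this canonical rule is flagged here because
  verbal descriptions of the split are ambiguous between transition- and
  choice-indexed conventions.
- **Predictive correlations** — "accounting for" covariates residualizes
  the outcome on them (raw Pearson on the residualized outcome); a
  both-sides partial-correlation variant exists behind `partial_both`.
  Change-score analyses correlate follow-up-minus-baseline differences and
  exclude baseline symptom-floor subjects (DAST = 0) with a returned
  count. Bonferroni flags are attached at the two conventional thresholds
  .05/6 and .05/30.

## Synthetic cohorts

`CohortSpec` describes a two-group, two-session study. Parameters are
drawn per subject from bivariate Gaussians in estimation space
(moment-matched per group and session to the published native means/SDs —
closed form for lognormal coordinates, Gauss-Hermite inversion for
logit-normal), with per-parameter cross-session correlations defaulting to
the published pooled test-retest values, so the planted correlation
reappears as the ICC(3,1) of the generated true parameters. Covariates
(age, sex, premorbid IQ), substance-class strata, and symptom scores
(DAST/PHQ/OASIS; integer, floor/ceiling-clipped Gaussians) follow the
published group-level moments. Planted effects compose: group offsets and
session drifts shift estimation-space means; parameter-symptom and
change-change correlations enter through a shared Gaussian latent (a
copula on the latent scale), with the change-change plant analytically
compensated for the variance of the differenced symptom scale and a joint
feasibility check (sum of squared planted coefficients ≤ 1). Reaction
times are lognormal with per-subject location loaded on z-scored
parameters (faster with higher reward sensitivity and win learning rate,
slower with higher loss learning rate and information insensitivity).
Dropout (the follow-up return rate) is available but off by default.

What passing tests on these cohorts show — and what they do not: the
generator produces exactly the model family the estimator assumes, with
Gaussian heterogeneity and independent parameters. Real data add model
mismatch, wider and correlated fitted-parameter spreads, attention lapses,
and non-stationary strategies; recovery and power results on synthetic
cohorts are therefore best-case calibrations, not guarantees about
participant data. Integer rounding and the floor of the symptom scale
attenuate planted correlations slightly (left-censoring of the follow-up
score is the main contributor), which the plant-and-recover tolerances
(±.15) absorb.

## Problem sizes and numerics

Validation studies run at the published scale where that is cheap
(122-agent recovery, study-sized group cohorts) and at 60 agents for the
ten-model identifiability study, where model 9's protected exceedance
probability is already saturated at 1.00; counts are configurable.
Numerical floors: concentration counts clipped at 1e-8, log-softmax with
max subtraction, Dirichlet Monte-Carlo draws at 10⁵. Estimation-space
round trips are exact to 1e-10 and tested. Degenerate inputs (constant
vectors, zero variances, rank-deficient designs, incomplete sessions)
raise typed errors naming the offending rows or columns rather than
propagating NaNs.

## Known limitations

- Policies are single-step by design; multi-step planning, habit terms and
  state-estimation uncertainty are out of scope for this task.
- The Laplace posterior is a local Gaussian; multimodality along the
  scale ridge is summarised by whichever mode wins the multi-start.
- The PEB simplification estimates one between-subject variance per
  parameter; full covariance-component estimation across parameters is not
  implemented.
- Recovery correlations depend on the estimator's noise profile and on
  the generative cloud's geometry (see the identifiability section);
  cross-implementation comparisons of exact recovery values should expect
  differences even when both implementations are correct.
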