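# Methods

This note records the modelling assumptions, numerical choices and known
limitations of `emrmpt`, in the spirit of a statistical software methods
appendix. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The EMR processing tree

The encoding-maintenance-retrieval model assigns each studied word pair a
path through Bernoulli process steps: encoding (*e*); initial cued-recall
retrieval of a stored association (*r*<sub>c</sub>); maintenance across the
retention interval conditional on the initial-recall outcome
(*m*<sub>s</sub>/*m*<sub>u</sub>); associative retrieval in delayed free
recall (*r*<sub>f</sub>); and, when the association is not retrieved or not
stored, independent per-word production (*s*<sub>x</sub> for stored,
*u*<sub>x</sub> for unstored associations, *x* indexing the initial-recall
outcome). Maintained associations face the final cued recall with the same
*r*<sub>c</sub> as the initial test; unstored associations fail cued recall
deterministically, because the pairs are only weakly associated and a
guessing step would not be identifiable (and was not needed in prior
validations of the paradigm). Never-encoded pairs fail both cued recalls and
produce single words at rate *u*<sub>u</sub>.

Two structural conventions matter for bookkeeping:

- The two "exactly one word" orderings (word 1 only / word 2 only) are kept
  as distinct branches and pooled only at the observable level. This gives
  the canonical count of 32 branches: per initial-recall outcome, 2
  (associative retrieval × final recall) + 8 (four word patterns × final
  recall) + 4 (not maintained) = 14, twice, plus 4 unencoded branches.
- The *s*/*u* parameters are conditioned on whether the association is
  *stored at test*, not on encoding success: an encoded but unmaintained
  pair uses *u*<sub>x</sub>. This is the only conditioning under which
  *u*<sub>s</sub> (unstored association after a successful initial recall)
  is a meaningful quantity.

Model variants are label-sharing maps over the always-carried 9-parameter
set (`ModelSpec`), never separate code paths: the baseline collapses
*m*, *s*, *u* within conditions and shares *r*<sub>c</sub> across them
(11 free parameters, df = 22 − 11 = 11 for two conditions), the generalized
model splits all three families (df = 5), and the redefined baseline splits
only *u* (df = 9). Degrees of freedom are always 11 free category
frequencies per condition minus the free-parameter count.

## Maximum likelihood

The multinomial log-likelihood kernel is maximised over logit-transformed
free parameters with L-BFGS-B and analytic gradients derived from the branch
exponent matrices; the transform keeps iterates off the boundary, and the
default 10 uniform-random restarts (plus a fixed mid-range start) guard
against local optima. Convergence tolerance is 1e-10 on the objective.
Estimates within 1e-4 of 0 or 1 are flagged as boundary cases but not fatal.

G² = 2·Σ n·log(n/(N·p̂)) with 0·log 0 := 0; a positive count on a
zero-probability category yields an infinite G² reported as misfit.
AIC = −2lnL + 2k; BIC uses n = total word-pair observations, on the view
that each pair is one multinomial trial (documented because other software
may count participants instead — comparisons are internally consistent
either way). Confidence intervals are Wald intervals from the inverse
observed Fisher information (finite differences of the analytic gradient),
delta-transformed to the probability scale and clipped to [0, 1].

ΔG² tests refit the restricted model warm-started from the general optimum
and clamp tiny negative differences (optimizer slack ≤ 1e-6) to zero; if the
restricted fit beats the general one, the general model is refit from the
restricted optimum before comparing. For single constraints the directional
test uses z = sign·√ΔG² with the sign read from the unrestricted estimates;
when the estimates contradict the predicted direction the one-tailed p
exceeds .5 by construction.

Power analysis for 1-df constraints follows the noncentral-χ² recipe: the
constrained model is fitted to the expected H1 frequencies, twice the
(allocation-weighted) per-pair Kullback–Leibler divergence is the
per-observation noncentrality, and power at a total N uses either the
noncentral χ²(1) (two-tailed) or the signed-root normal approximation
(one-tailed). The construction of the H1 parameter sets (which condition
anchors the gap, how the remaining parameters are set) is exposed to the
caller rather than fixed, because different defensible anchorings move the
required N by several participants.

## Hierarchical latent-trait model

Person *i*'s value of free-parameter group *j* is
θ<sub>ij</sub> = Φ(μ<sub>j</sub> + δ<sub>ij</sub>) with
δ<sub>i</sub> ~ MVN(0, Σ) over a condition's free groups; parameters equated
within a condition share one trait. Each condition is fitted separately, so
*r*<sub>c</sub> — shared across conditions in the aggregated ML analysis —
is per-condition here; this asymmetry is deliberate and mirrors how the
individual-level analysis is usually run.

Priors: μ<sub>j</sub> ~ N(0, 1) on the probit scale and
Σ ~ inverse-Wishart(I, k + 1), a weakly informative default; both are
configurable (`McmcOptions`). The exact prior hyperparameters used by
external packages for this model are not standardised, so these defaults are
fixed by documentation, not inference.

The sampler is Metropolis-within-Gibbs: random-walk updates of μ, vectorised
per-person random-walk updates of δ columns, a likelihood-free joint
translation move (μ<sub>j</sub> up, δ<sub>·j</sub> down by the same amount)
that decorrelates the group mean from the deviations, and a conjugate
inverse-Wishart draw for Σ. Proposal scales adapt toward 44% acceptance
during burn-in and are frozen afterwards, keeping the kept draws a valid
Markov chain. Defaults are 4 chains × (2,000 burn-in + 8,000 kept);
convergence is flagged when any classic Gelman–Rubin R̂ exceeds 1.05.
Group-level parameters are reported as Φ(μ), the median-person probability.

Model fit uses posterior-predictive statistics: T₁ compares observed and
expected mean category counts (χ²-style, normalised by the expected mean),
T₂ compares the observed covariance matrix of category counts across persons
with its expectation under the draw (between-person spread of expected
counts plus mean multinomial noise), each against replicated data sets; p is
the fraction of draws whose replicated statistic is at least the observed
one. Ties in difference posteriors count half toward the one-tailed
Bayesian p, so comparing a fit with itself gives p = .5 exactly.

## Sequential and Bayes-factor analyses

The SPRT t test accumulates LR = f<sub>nct</sub>(t; ν, d₁√(n₁n₂/(n₁+n₂))) /
f<sub>t</sub>(t; ν) and stops at B = β/(1−α), A = (1−β)/α. The caller
declares the predicted direction by group order (group 1 = predicted
larger), because different outcomes in the same study can have opposite
predictions. When a second stopping rule keeps recruitment going after the
SPRT has decided, the trace records later likelihood ratios without revising
the decision.

The JZS Bayes factor integrates the noncentral-t density over a Cauchy prior
(default scale √2/2) on the standardized effect; the directional variant
truncates the prior to the predicted side. Both are always reported, since
published analyses often omit which convention they used; the package's own
cross-check against the study summaries it emulates indicates the
directional variant matches the printed values. An independent
inverse-gamma-mixture quadrature serves as the test-suite oracle.

Fixed-n planning returns the smallest even total N whose noncentral-t power
reaches the target.

## Study pipeline

Exclusion boundaries read "<30%" and ">80%" strictly: of 40 pairs, immediate
cued-recall counts below 12 or above 32 are excluded, 12 and 32 retained.
Procedure-related criteria (placebo-content guess below 1%, communication
about the first phase, active rehearsal, drinking within 48 h) remove
flagged participants; merely *thinking* about the pairs is recorded but only
rehearsal excludes, because passive reminiscence is near-universal and was
not treated as a protocol violation. Exclusion is idempotent and audited.

The model-selection ladder accepts the baseline when its G² p-value exceeds
.05; on misfit it fits the generalized model and re-restricts each family
(m, s, u) whose split is not supported by a ΔG²(1) test at .05, yielding the
re-restricted baseline used for the hypothesis tests. The r_f and m
difference tests are one-tailed ΔG²(1) tests with the predicted-larger
condition set in the configuration; the hierarchical stage reports the
corresponding Bayesian one-tailed p from the difference posterior.

The recruitment simulator enforces both stopping rules of the sequential
design — an SPRT decision for both manifest hypotheses *and* a minimum of 30
included participants per condition after the model-related exclusion —
continuing in group-sized looks until both hold.

## Synthetic data

The generator walks the tree with sequential Bernoulli draws per pair —
an implementation deliberately independent of the analytic branch
enumeration, so the two cross-validate (their agreement is a build-failing
test). Defaults emulate the study design the package targets: 46/47
participants, 40 pairs each, group-level parameters at the published
posterior means (alcohol e=.59, m=.93, r_f=.51, r_c=.98, s=.05, u_s=.18,
u_u=.11; placebo e=.60, m=.90, r_f=.43, r_c=.98, s=.11, u_s=.20, u_u=.11),
questionnaire flag rates at the reported frequencies, and probit-scale
person heterogeneity of SD 0.4 per free group with zero cross-correlations —
mid-range variability that keeps parameters identifiable at 30–50
participants per condition. Word identity is abstracted: free-recall
outcomes are drawn at the both/one/neither level, with a separate scorer
(`score_free_recall`) for raw word lists.

What the generator does *not* emulate: serial-position and item effects,
output interference during free recall, correlated flags (e.g. communicators
clustering in sessions), and any time structure within the retention
interval. Passing tests therefore demonstrate correctness of the estimators
under the model's own assumptions plus latent-trait heterogeneity, not
robustness to these real-data features.

## Problem sizes and tolerances in the test suite

Simulation-based checks run at the scale the analyses target: ML parameter
recovery uses 200 replicates of 31/40 participants × 40 pairs (mean absolute
error of e, m, r_f below .03, measured under zero heterogeneity where the
aggregate truth is well defined); hierarchical interval coverage uses 50
replicates of 40 persons with 2 chains × (500 + 1,000) draws — settings
chosen from R̂ diagnostics as the smallest giving acceptably converged
chains; type-I calibration of the ΔG²(1) test uses 1,000 null replicates
(acceptance band [.03, .07] at α = .05, about ±3 Monte-Carlo SEs); SPRT
error calibration uses 600 sequential experiments per regime. The
Monte-Carlo branch-sampling oracle uses 10⁶ draws with a 3-SE band per
category. Published summary statistics are asserted to ±0.01 where they are
recomputed from 2-decimal table entries, and to the printed precision
otherwise.

## Known limitations

- Wald CIs can be poor for parameters near the boundary (notably
  *r*<sub>c</sub> ≈ .98); profile or bootstrap intervals are an extension
  point, not implemented.
- The one-tailed ΔG² test relies on the asymptotic normality of the signed
  root; at very small samples its size can drift from nominal.
- The latent-trait sampler is a random-walk scheme: adequate at the target
  scale (verified by R̂), but slower-mixing than gradient-based samplers for
  much larger problems.
- The multiverse's individual-data cells inherit whatever MCMC settings the
  configuration carries; at the fast test settings their Bayesian p-values
  are noisier than the aggregated cells' ΔG² p-values.
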