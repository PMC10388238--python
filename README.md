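# emrmpt

Multinomial-processing-tree (MPT) analyses for placebo-controlled memory
experiments in the **free-then-cued-recall** paradigm: participants study
weakly associated word pairs, take an immediate cued recall test, receive a
beverage (alcohol or placebo), and after a retention interval take a free
recall test followed by a final cued recall. The package is written for
memory researchers who want to decompose a net performance difference between
conditions into latent **encoding**, **maintenance** and **retrieval**
contributions — e.g. to decide whether an alcohol-induced "retrograde
facilitation" effect reflects better consolidation (maintenance) or reduced
retroactive interference (retrieval).

## The model

Each studied pair ends in one of 2 × 3 × 2 = 12 observable outcomes
E₁…E₁₂ (initial cued recall correct/incorrect × free recall both/one/neither
word × final cued recall correct/incorrect). The
encoding-maintenance-retrieval (EMR) model explains these via a processing
tree with 32 branches over the latent probabilities

| parameter | meaning |
|---|---|
| *e* | associative encoding at study |
| *r*<sub>c</sub> | cued-recall retrieval of a stored association (both tests) |
| *m*<sub>s</sub>, *m*<sub>u</sub> | maintenance across retention, by initial-recall outcome |
| *r*<sub>f</sub> | associative retrieval in free recall |
| *s*<sub>s</sub>, *s*<sub>u</sub> | per-word free recall when the association is stored |
| *u*<sub>s</sub>, *u*<sub>u</sub> | per-word free recall when it is not stored |

A branch's probability is the product of its step probabilities; a category's
probability is the sum over its branches. Model variants are equality
constraints (e.g. *m*<sub>s</sub> = *m*<sub>u</sub> within conditions,
*r*<sub>c</sub> shared across conditions), giving the baseline (df = 11),
generalized (df = 5) and redefined-baseline (df = 9) two-condition models.

On top of the tree the package provides

- **Maximum likelihood**: logit-scale L-BFGS-B with analytic gradients and
  random restarts; G² goodness of fit, AIC/BIC, Wald CIs, nested ΔG² tests
  (one-tailed via z = ±√ΔG²), local identifiability checks, and
  noncentral-χ² power planning for 1-df constraints.
- **Hierarchical Bayes**: the probit latent-trait model
  θ<sub>ij</sub> = Φ(μ_j + δ<sub>ij</sub>), δ_i ~ MVN(0, Σ), fitted per
  condition by Metropolis-within-Gibbs MCMC with Gelman–Rubin R̂,
  posterior-predictive T₁/T₂ checks and Bayesian difference tests.
- **Sequential/design-based tools**: pooled-SD Cohen's d, the group-sequential
  probability-ratio (SPRT) t test, JZS default-prior Bayes factors, and
  fixed-n sample-size planning.
- **A study pipeline**: trial categorisation, exclusion rules, a
  model-selection ladder, and a 2×2×2 multiverse analysis; plus a
  **synthetic-data generator** that emulates the full study design with
  latent-trait person heterogeneity.

## Worked example

```python
from emrmpt import (GroupSummary, cohens_d, sprt_t,
                    generate_study_fixture, run_study, StudyConfig)

# design-based stage: sequential t test on published N=18 look summaries
h1 = GroupSummary(n=(9, 9), mean=(1.67, 2.56), sd=(1.50, 1.81))
look = sprt_t(h1, d1=0.5, alpha=0.05, beta=0.20)
print(f"Cohen's d = {cohens_d(h1):.2f}")
print(f"LR_18 = {look.lr:.2f} vs lower threshold {look.lower:.2f} -> {look.decision}")

# model-based stage on a synthetic study-scale data set
design, trials, participants = generate_study_fixture(seed=11)
report = run_study(trials, participants, StudyConfig(), seed=1)
sel = report["model_selection"]
print(f"baseline G2(11) p = {sel['baseline']['p']:.3f}; selected: {sel['selected']}")
for fam in ("r_f", "m"):
    t = report["difference_tests"][fam]
    print(f"{fam}: dG2(1) = {t['delta_G2']:.2f}, one-tailed p = {t['p_one_tailed']:.3f}")
```

prints

```
Cohen's d = -0.54
LR_18 = 0.18 vs lower threshold 0.21 -> accept_H0
baseline G2(11) p = 0.000; selected: re-restricted (split: ['u'])
r_f: dG2(1) = 7.45, one-tailed p = 0.003
m: dG2(1) = 0.13, one-tailed p = 0.358
```

Reading: the sequential likelihood ratio falls below β/(1−α) = 0.21, so the
manifest cued-recall hypothesis is rejected in favour of H₀ (the effect size
even points the other way), while the latent analysis — on data generated
with a retrieval gap but equal maintenance — correctly flags the retrieval
parameter *r*<sub>f</sub> (p = .003) and not maintenance *m* (p = .358).

The same analyses are available from the shell:

```bash
emrmpt simulate --out study/ --seed 3
emrmpt run --trials study/trials.tsv --participants study/participants.tsv --seed 1
emrmpt fit-ml --counts counts.tsv          # aggregated-count ML fit
emrmpt fit-bayes --trials study/trials.tsv --condition alcohol --seed 1
```

## Layout

- `src/emrmpt/emr_model.py` — tree, category probabilities, model specs
- `src/emrmpt/ml_inference.py` — ML fitting, ΔG² tests, identifiability, power
- `src/emrmpt/hierarchical_bayes.py` — latent-trait MCMC, R̂, T₁/T₂, difference posteriors
- `src/emrmpt/sequential_inference.py` — Cohen's d, SPRT t test, Bayes factors, planning
- `src/emrmpt/study_pipeline.py` — categorisation, exclusions, orchestration, multiverse
- `src/emrmpt/synthetic_data.py` — study-like synthetic data with heterogeneity
- `docs/methods.md` — modelling and numerical choices in detail
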