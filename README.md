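# birt — Bayesian binary item response theory

`birt` fits the nested 1PL–4PL family of logistic item response models to
dichotomous test data (correct/incorrect answers), compares the fitted
models by approximate leave-one-out cross-validation, and checks item- and
person-level fit with posterior-predictive statistics.  It is aimed at
psychometric analyses of ability tests — the motivating use case is a
12-item hardest-block matrix-reasoning short form — and at methodologists
who want a fully testable, simulation-validated pipeline with known-truth
synthetic data built in.

## The model

For person *j* and item *i*, the probability of a correct response is

    P(y_ji = 1) = γ_i + (1 − γ_i − ψ_i) · logistic(β_i + α_i θ_j)

with easiness β_i, slope (discrimination) α_i > 0, guessing probability
γ_i, lapse probability ψ_i, and a unidimensional ability θ_j ~
normal(0, σ_θ).  Fixing ψ = 0 gives the 3PL, additionally γ = 0 the 2PL,
and additionally α = 1 the 1PL (Rasch) model.  Item parameters are modeled
on unconstrained scales (β, log α, logit γ, logit ψ) with either
non-hierarchical weakly-informative normal priors or a hierarchical prior
with estimated class means, scales, and a between-class correlation matrix.

Four estimation routes share this one probability model:

| route | machinery |
|---|---|
| MCMC-H | adaptive Metropolis-within-Gibbs + slice sampling, hierarchical priors, non-centered |
| MCMC-NH | same kernel, fixed non-hierarchical priors |
| MAP | EM with fixed-point Gauss–Hermite quadrature over θ, prior-penalized |
| ML | same EM without item priors (marginal maximum likelihood) |

Model comparison uses Pareto-smoothed importance-sampling leave-one-out
cross-validation (PSIS-LOO) with pointwise ELPD, standard errors, pairwise
differences and Pareto-k̂ reliability diagnostics.  Predictive checks
compare the observed log-likelihood statistic T(y, p) against replicated
T(y_rep, p) draw by draw, per item or per person.

## Worked example

```python
import numpy as np
from birt import (GeneratorConfig, ModelSpec, simulate_dataset, mcmc_sample,
                  pointwise_loglik, psis_loo, comparison_table)

cfg = GeneratorConfig(n_persons=500, n_items=12, model_class="2PL", seed=42)
data, truth = simulate_dataset(cfg)

results = {}
for model in ("1PL", "2PL"):
    draws = mcmc_sample(data, ModelSpec(model, hierarchical=True),
                        n_chains=2, n_warmup=600, n_draws=600, seed=7)
    print(model, "max R-hat", round(draws.max_rhat, 3),
          "theta r", round(np.corrcoef(draws.theta_mean(), truth.theta)[0, 1], 3))
    results[model] = psis_loo(pointwise_loglik(draws, data))
print(comparison_table(results).round(1))
```

Output from this exact script:

```
1PL max R-hat 1.035 theta r 0.879
2PL max R-hat 1.038 theta r 0.885
         elpd  se_elpd  elpd_diff  se_diff  n_high_khat
model
2PL   -3351.2     35.4        0.0      0.0           13
1PL   -3377.8     35.3      -26.6      6.7            6
```

Read it as: both fits converged acceptably (split R-hat near 1),
posterior-mean abilities rank persons accurately against the known truth
(r ≈ 0.88), and leave-one-out predictive fit prefers the generating 2PL
over the 1PL by 26.6 ELPD — about four times the standard error of the
difference, a decisive margin.  `n_high_khat` counts observations whose
importance weights are unreliable (Pareto k̂ > 0.7); a handful out of 6000
is unremarkable at this number of draws.

The same analysis is available from the shell:

```bash
birt simulate --persons 500 --items 12 --model 2PL --seed 42 --out sim/
birt fit --data sim/responses.csv --model 2PL --chains 2 --warmup 600 \
         --draws 600 --seed 7 --out fit2pl/
birt compare --fit-dir fit2pl/ --data sim/responses.csv --out comparison.csv
birt report --data sim/responses.csv --models 1PL,2PL --seed 7 --out report/
```

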