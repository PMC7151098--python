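# Methods

## Model

`birt` fits the nested family of unidimensional logistic item response
models for binary data.  For person *j* with ability θ<sub>j</sub> and item
*i* with easiness β<sub>i</sub>, slope α<sub>i</sub> > 0, guessing
probability γ<sub>i</sub> and lapse probability ψ<sub>i</sub>,

    P(y_ji = 1) = γ_i + (1 − γ_i − ψ_i) · logistic(β_i + α_i θ_j)

The 4PL estimates all four item-parameter classes; the 3PL fixes ψ = 0, the
2PL additionally γ = 0, and the 1PL (Rasch) additionally α = 1.  Item
parameters live on unconstrained scales — β directly, log α, logit γ, logit
ψ — where all priors and proposals act.  Abilities follow θ<sub>j</sub> ~
normal(0, σ<sub>θ</sub>).  No overall person intercept is estimated: it
would trade off one-for-one against the mean item easiness, and only
differences between abilities carry meaning on the latent scale.

Likelihood evaluations are performed in the log domain throughout
(`log P(y=1) = logaddexp(log γ, log(1−γ−ψ) + log logistic(x))`, and
`log logistic(−x) = log logistic(x) − x`), so extreme abilities or slopes
never underflow before the logarithm is taken.

## Priors

Two regimes share the same class-wise weakly-informative anchors:

| class | normal prior (location, scale) | rationale |
|---|---|---|
| β | (0, 3) | covers ±3 logits of plausible easiness without flatness |
| log α | (0, 1) | slopes mostly within e<sup>±2</sup> |
| logit γ | (−2, 1) | prior median guessing ≈ 0.12, near the 1/8 of an 8-alternative item |
| logit ψ | (−4, 1) | lapses a-priori rare for untimed click-response items |

*Non-hierarchical* (NH): each item's unconstrained parameter gets the
class prior directly.  *Hierarchical* (H): the class prior applies to an
overall mean b̄<sub>c</sub>, item deviations b̃<sub>ci</sub> get a
multivariate normal with estimated scales σ<sub>c</sub> ~ half-normal(0, 1)
and an LKJ(1) (uniform) prior on the between-class correlation matrix Ω,
parameterized through its Cholesky factor via tanh-transformed canonical
partial correlations.  σ<sub>θ</sub> is estimated with a half-normal(0, 1)
prior in all model classes (a fixed-at-1 switch exists for the conventional
2PL+ identification).  All density constants are included so optimization
and sampling target literally the same function; the only omitted constant
is the η-dependent LKJ normalizer, fixed given the prior shape.

`log_prior` is defined on the natural (centered) hierarchical
parameterization.  The MCMC kernel samples the non-centered standardized
deviations (with standard-normal prior), an exact reparameterization that
differs only by a Jacobian and therefore targets the same posterior.

## MCMC

The sampler is adaptive Metropolis-within-Gibbs with slice-sampled
hyperparameters.  Within one sweep:

1. **Persons** — all θ<sub>j</sub> are proposed jointly and accepted
   coordinate-wise (valid because persons are conditionally independent
   given items); per-person step sizes adapt toward 0.44 acceptance.
2. **Items** — per parameter class, all items' standardized deviations are
   proposed jointly and accepted item-wise with class-specific adaptive
   steps; an additional whole-row proposal, preconditioned by the per-item
   empirical covariance accumulated over warmup, follows correlated
   within-item directions such as the easiness–guessing ridge of hard items.
3. **Hyperparameters** — means b̄<sub>c</sub> move by scalar random-walk MH.
   The scales σ<sub>c</sub> are slice-sampled twice, in two coordinate
   systems: non-centered (deviations fixed, likelihood-coupled) and
   centered (item predictors fixed, prior-coupled).  Interweaving the two
   parameterizations is what lets the scales traverse their funnel-shaped
   posteriors; either alone mixes an order of magnitude slower.  The
   correlation coordinates are slice-sampled in centered form (likelihood
   unchanged).
4. **Ridge moves** — two likelihood-invariant reparameterization proposals
   handle the weakly identified directions the priors only softly pin:
   (θ, σ<sub>θ</sub>, slopes) → (cθ, cσ<sub>θ</sub>, slopes/c), whose
   Jacobian cancels the θ-prior normalization exactly, and
   (θ, easiness) → (θ+δ, easiness −αδ).

Adaptation runs only during warmup; the post-warmup kernel is fixed, so
the retained chains have the correct invariant distribution.  Defaults are
4 chains, 1000 warmup, 1000 retained draws.  Convergence is checked with
rank-normalized split R-hat on every stored parameter; any value above
1.05 flags the result and emits a warning — never a silent success.
Diagnostics (R-hat, bulk ESS) are delegated to ArviZ, with explicit
handling of degenerate chains: identical constant chains give NaN with a
warning, constant chains at different values give +∞, and ESS is capped at
the total draw count.

The kernel was validated against a deterministic 61-node Gauss–Hermite
quadrature oracle on a single-person problem (posterior mean and sd within
3 Monte-Carlo standard errors) and by a 20-replicate recovery study at the
reference design (12 items × 500 persons, 2PL-H): 90% central intervals
for β cover truth at their nominal rate and EAP abilities correlate ≥ 0.85
with truth in every replicate.

## MAP and ML (EM with Gauss–Hermite quadrature)

Optimization-based fitting maximizes the ability-marginalized objective:
abilities are integrated out on a fixed-point Gauss–Hermite grid (21 nodes
by default, rescaled by the provisional σ<sub>θ</sub>; because the grid in
standardized units is fixed, the discretized model is an exact finite
mixture and the EM ascent property holds exactly, which the tests assert
per iteration).  The E-step computes per-person node responsibilities; the
M-step maximizes each item's expected complete-data log-likelihood
(L-BFGS-B on the unconstrained scales, bounded at ±15) plus, for MAP, the
class-wise NH prior penalty; σ<sub>θ</sub>, when estimated, gets its own
bounded one-dimensional maximization.  Convergence is declared at relative
objective change < 1e−5.

Identification choices: σ<sub>θ</sub> is estimated for the 1PL and fixed
at 1 for 2PL+ in the EM routes (the conventional marginal-ML
identification — the slope scale carries it); the MCMC route estimates it
in all classes.  MAP under a hierarchical spec applies the class priors as
fixed NH penalties; hyperparameters are not optimized.

Person scores from both EM routes are expected-a-posteriori (EAP) values
under the fitted items, keeping all four routes' person estimates
commensurable.  Approximate standard errors come from a central-difference
observed-information matrix with delta-method transformation to the
natural scale; a non-positive-definite information matrix marks SEs
unavailable rather than fabricating them, and guessing/lapse estimates
within 10⁻³ of the boundary carry a boundary flag (ML theory does not hold
there).

## Model comparison (PSIS-LOO)

Pointwise log-likelihood matrices (draws × observations) feed
Pareto-smoothed importance sampling: per observation, the largest
M = min(0.2 S, 3√S) importance ratios are replaced by expected order
statistics of a generalized Pareto distribution fitted by the
profile-likelihood method of Zhang & Stephens (grid over the
reparameterized scale, posterior-mean under the profile likelihood, shape
stabilized toward 0.5 with weight 10), truncated at the raw maximum.
ELPD = Σ elpd<sub>n</sub>, SE = √(N·var(elpd<sub>n</sub>)); pairwise
differences use the pointwise difference SE.  Tail shapes k̂ ≤ 0.5 are
good, ≤ 0.7 ok, above 0.7 flagged (no automatic refit).  Degenerate cases:
a point-mass posterior returns the in-sample value with undefined k̂;
infinite ratios flag the observation.  The implementation is cross-checked
in the tests against ArviZ's independent PSIS path, and against exact
leave-one-out by N refits on a small instance.

## Posterior-predictive fit checks

The fit statistic T is the summed pointwise Bernoulli log-likelihood over
a unit's (item's or person's) observations.  Per posterior draw s,
replicated responses y<sup>rep</sup>(s) ~ Bernoulli(p(s)) give
D<sub>s</sub> = T(y<sup>rep</sup>(s), p(s)) − T(y, p(s)); per-draw
differencing (rather than marginal comparison of the two T distributions)
is standard posterior-predictive practice and makes "mass above zero ⇒
misfit" exact: replicates can only beat the observed data where the model
predicts them better.  Summaries are the posterior mean of D, the central
95% interval and P(D > 0).  All draws are used by default.

Calibration and power were quantified by simulation: fitting the
generating 1PL (12 × 500, 20 replicates) flags ≤ 15% of items at the
two-sided 95% level, while a 1PL fitted to strongly guessing-contaminated
3PL data (2000 persons, γ ≈ 0.35 — a hard test with roughly
three-alternative guessing — heterogeneous slopes) flags at least 3 of 12
items at P(D > 0) > 0.95.  The strong-guessing alternative is deliberate:
the item-wise log-likelihood discrepancy carries irreducible replication
noise of order √J, so per-item power at the 0.95 level requires either
large samples or large misfit; under modest guessing the statistic shows
the expected "majority of mass above zero" pattern without clearing 0.95.

## Synthetic data

The generator draws item parameters on their unconstrained scales from a
multivariate normal around configurable class means (defaults: β ~ (0, 1);
log α ~ (0.4, 0.3), median discrimination ≈ 1.5 as for a well-constructed
ability test; logit γ ~ (−2.2, 0.3), guessing ≈ 0.10; logit ψ ~ (−4, 0.3)),
with an optional between-class correlation matrix, then simulates complete
Bernoulli response matrices.  The bundled 499 × 12 fixture mimics the
shape of a hardest-block matrix-reasoning short form: easiness declines
linearly from +1.5 to −3.0 so the hardest items sit near the guessing
floor for most of the ability range, which is what makes the 3PL's lower
asymptote decisively visible to predictive model comparison.

What the generator does *not* emulate: distractor-level (polytomous)
response behavior, person or item covariates, multidimensional traits,
learning/practice effects within the test, and missing responses.  Tests
passing on this synthetic data therefore demonstrate the correctness and
calibration of the inference machinery under the model's own assumptions,
not the adequacy of these models for any particular real instrument.

## Problem sizes and numerical choices

Simulation-based tests run at deliberately chosen scales: recovery and
calibration suites use 2 chains with 600–1200 retained draws per fit,
which pilot runs showed is where interval coverage and rank-correlation
stabilize for this design; the model-selection ladder uses 2 × 1250 draws
(the 4PL needs the longest chains); the full-scale convergence contract
(all R-hat < 1.01) runs once at 4 × 2500.  Slice steps use widths 0.5–1.0
with Neal's stepping-out (cap 50) and shrinkage.  Ties and degenerate
inputs: constant chains, point-mass posteriors, impossible observations
(p exactly 0 or 1 on the wrong side → −∞ likelihood, never an exception)
are all handled explicitly and tested.

## Known limitations

- The 3PL/4PL hierarchical posteriors mix slowly in their hyperparameters
  at a few thousand draws; results carry honest R-hat flags rather than
  longer default runs.  ELPD and person scores are insensitive to this;
  hyperparameter intervals of the 4PL should be taken with care.
- MAP agrees with MCMC marginal posterior modes only up to the skewness of
  small-sample posteriors (and KDE mode-estimation noise in the test), so
  agreement is asserted within 0.2 on a 40-person toy together with an
  exact optimality check of the MAP objective.
- No bootstrap/resampling standard errors, no variational inference, no
  WAIC/Bayes factors, no polytomous models.
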