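# Methods

This note documents the statistical model, the synthetic-trial generator,
the numerical choices, and the known limitations of `famix`.

## Tracer mixing with multiplicative trophic modification

Stable-isotope mixing models write the consumer's tracer value as a
proportion-weighted sum of source means plus an *additive* trophic
modification. Fatty acids are proportions of a total, and their
prey-to-predator modification is *multiplicative*: the consumer's value of
FA *j* is the prey's value times a calibration coefficient (CC) `t_j`.
`famix` follows the standard reconciliation: source means and SDs are
multiplied by their CCs ("predator space") before fitting, and the additive
modification term inside the model is fixed at zero. The model object
refuses prey-space sources so the transform cannot be skipped silently.

CCs are computed from feeding trials at (near-)complete turnover as
consumer mean ÷ diet mean, where the diet mean of a mixed diet is the
mass-proportion-weighted average of the prey means (the exact weighting for
mixed-diet CCs is not standardised in the literature; mass weighting is the
natural reading). When CCs are computed from the same consumers being fit
on a single-prey diet, the predator-space source mean equals the consumer
mean *exactly* — this algebraic identity is why single-prey validation fits
recover the truth almost perfectly, and it is exercised directly in the
benchmarks.

A deliberate consequence of the multiplicative transform: predator-space
sources no longer sum to 100 %. No renormalisation is applied — the
likelihood operates per tracer and never uses the row sum.

### Likelihood and priors

For consumer *i* at factor level *l* and tracer *j*:

- mean: `mu_ij = sum_k p_lk * mu'_jk` (predator-space source means `mu'`);
- variance: `sigma_ij^2 = eps_j * sum_k p_lk^2 * sigma'_jk^2`.

This is the "Residual\*Process" structure: the process variance induced by
source spread is scaled by a per-tracer multiplicative residual term
`eps_j`. The construction follows the residual-scaling formulation of
modern mixing-model software; `eps_j ~ Uniform(0, upper)` with
`upper = 20` by default — vague relative to percent-scale tracers, and
configurable. Tracers are conditionally independent given `p` and `eps`
(sources enter as per-FA mean/SD summaries); a full consumer covariance
model is out of scope.

Diet proportions get independent Dirichlet priors per factor level
(no pooling across levels): `Dir(1,…,1)` by default. Informative priors are
built from prior mass proportions `w` as `alpha_k = K * w_k`, floored at
0.01, so the total concentration — the prior's overall strength — matches
the non-informative prior and only its shape changes.

### Parameterisation and sampling

Sampling runs in unconstrained space: each level's diet vector through an
additive-log-ratio softmax (reference = last source; Jacobian `prod_k p_k`),
and each `eps_j` through a scaled sigmoid (Jacobian `eps (upper−eps)/upper`).
Every stored draw therefore lies exactly on the simplex — sums equal 1 to
machine precision without post-hoc renormalisation. Zero-SD predator-space
sources receive a variance floor of 1e-6 to keep the likelihood proper.

The sampler is emcee's affine-invariant ensemble with an 80/20 mixture of
differential-evolution and DE-snooker moves, which cut integrated
autocorrelation times roughly threefold versus the default stretch move on
these tightly correlated simplex posteriors. One "chain" is an independent
ensemble run; `n_iter` and `n_burnin` count scalar draws per chain
(ensemble steps × walkers), so the conventional long-run defaults
(3 chains × 100 000 draws, half burn-in, thin 50) remain affordable. The
likelihood is evaluated vectorised across walkers through per-level
sufficient statistics (counts, sums, sums of squares), making its cost
independent of the number of consumers. Initialisation is at the prior mean
(uniform diet, `eps ≈ 1`) with small jitter, re-jittered up to 20 times if
the initial ensemble has non-finite posterior density.

### Convergence diagnostics

Gelman–Rubin R-hat uses the classic between/within-chain formula on the
transformed draws; zero within-chain variance with disagreeing chains
returns an `inf` sentinel. Geweke z compares the first 10 % and last 50 %
window means, standardised by long-run variances estimated with Geyer's
initial-positive-sequence method (the window adapts to however long the
autocorrelation persists). Geweke runs on the per-step ensemble-mean trace,
whose stationarity directly reflects burn-in adequacy and which avoids the
lag-structure artefacts of interleaved walker draws.

The report's pass rule: all R-hat < 1.05 (configurable), and all |z| below
a Bonferroni-adjusted two-sided 5 % critical value. Because the early
Geweke window often holds only tens of effective draws, the scores are
t-like rather than normal; the critical value uses a conservative
t-reference with 20 degrees of freedom. Short runs on multi-level models
are honestly flagged as unconverged; medians stabilise much earlier than
the diagnostics clear, which is the expected ordering.

### Brute-force cross-check

For two-source problems `famix.benchmarks.grid_posterior_mean` computes the
posterior mean by quadrature: a 2001-point grid on the 1-simplex, with each
`eps_j` marginalised by trapezoidal integration over its Uniform prior
(3000-point grid, dense near zero). It shares no code with the sampler and
is the reference in the MCMC-versus-quadrature benchmark; agreement is
measured in Monte-Carlo standard errors estimated from the between-chain
spread of chain means.

## Data preparation

- **Consumer simulation from summaries.** Published FA tables usually give
  mean ± SD; raw rows are reconstructed as independent per-FA normal draws.
  Negative draws are redrawn per cell (truncation would bias the mean
  upward more). Rows are *not* renormalised to 100 — the model never uses
  the row sum, and renormalising would distort the per-FA moments being
  matched.
- **Row-sum check.** Raw empirical profiles must total 100 ± 2 percentage
  points by default (published tables routinely omit trace FAs);
  predator-space and simulated tables are exempt (the CLI passes no
  tolerance by default for this reason, and a tolerance can be set in the
  YAML config).
- **Tracer selection.** An FA is retained iff its consumer grand-mean
  abundance exceeds 0.5 %, it is classed dietary or extended-dietary, and
  its CC is ≤ 2 (a consumer holding twice the prey proportion points to
  endogenous origin or preferential accrual, not diet). The
  dietary/extended-dietary/endogenous classification ships as replaceable
  data (`FAClassTable.default()` covers ~30 common marine FAs); FA name
  matching is exact after whitespace stripping — no nomenclature fuzzing.
- **Source separation.** One-way PERMANOVA on Bray–Curtis dissimilarities
  (Euclidean available), permuting raw labels; p = (#{F* ≥ F} + 1)/(B + 1)
  with B = 999 by default, so the smallest attainable p is 0.001. Pairwise
  comparisons are Bonferroni-adjusted (the least surprising of the common
  corrections). The CLI treats weak separation as a warning, not an error:
  the fit is still valid, only less informative between similar sources.
  scikit-bio's PERMANOVA is used in the test suite as an independent
  cross-check, never as the implementation.

## The synthetic feeding-trial generator

The generator emulates the statistical structure of controlled feeding
trials, not seal physiology:

- **Sources** are log-normal perturbations of a shared base composition;
  `separation` scales the perturbation (0 → indistinguishable sources), and
  SDs default to 10 % of means. Compositions are renormalised to 100.
- **Turnover** is daily geometric replacement: each day a fraction
  `lambda = turnover_rate × deposition_fraction` of the tissue signature is
  replaced by the current diet's predator-space target. This exponential
  approach is the simplest kinetics consistent with qualitative turnover
  statements in the feeding-trial literature ("near complete by N days");
  preset rates are back-solved from such statements (e.g. 0.043/day ≈ 95 %
  replacement in 69 days) and remain free parameters, because true rates
  are not known quantitatively.
- **Low-fat deposition** enters multiplicatively on `lambda`: a consumer
  storing 25 % of dietary FAs moves toward the new diet a quarter as fast.
- **Noise** is independent per-FA normal, with SD equal to the
  tissue-weighted predator-space source SD times `noise_sd_scale` —
  mirroring how consumer rows are themselves reconstructed from mean/SD
  tables. Negative draws are redrawn.
- Because the signature is linear in the per-source tissue weights, the
  generator reports both the **diet fed** and the **tissue mixture** at
  each sampling point; under incomplete turnover the tissue mixture is what
  a correctly specified estimator recovers, and it is the truth used by the
  recovery benchmarks.

What passing benchmarks do *not* show about real data: real FA profiles are
compositional and correlated within an individual, real turnover is not a
single-rate exponential, blubber is stratified (outer layers barely track
diet), and field CCs differ from captive-derived ones. The generator
reproduces none of these; it verifies the estimator under its own
assumptions plus the kinetic structure above.

### Scenario presets

Five presets transcribe published feeding-trial designs (true diets, sample
sizes, schedules); FA compositions and CCs are synthetic and seeded:

- `eider_switch` — 8 sea ducks, 5 sources, maintenance diet
  (1/3/88/4/4 %) to 69 d, then 56/44 krill/formula for 21 d, then 48/52
  formula/silverside for 29 d; biopsies at days 0/21/50.
- `salmon_cc` — four fish groups (n = 36/28/34/34) on 100:0, 0:100, 70:30,
  30:70 herring-to-krill-oil feeds for 22 weeks (complete turnover); CC
  provenance experiments.
- `puffin_priors` — 6 nestlings parent-fed a mixed fish diet ~10 d, then
  herring-only 27 d; prior weights (0.72, 0.15, 0.07, 0.04, 0.02) — the
  printed record gives the two leading shares, the remainder is split
  plausibly; the two main parental prey are built as near-neighbours and
  herring as strongly distinct, matching the reported ordination structure.
- `harpseal_lowfat` — 5 seals, herring to pollock switch with
  deposition 0.25.
- `harbourseal_groups` — groups of 3/6/7 on herring, smelt, and
  smelt-then-herring, sampled at day 42.

Two purpose-built benchmark scenarios complement the presets:
`absent_source_scenario` (five separable sources, one never eaten, every
eaten source above 5 % so minimality is meaningful) and
`confusable_pair_scenario` (two near-identical sources, few consumers, few
tracers, doubled noise — the regime where the likelihood leaves the pair's
split to the prior).

## Benchmark and test sizing

Benchmarks run at toy dimensions (K ≤ 5 sources, J ≤ 15 tracers, n ≤ 10
consumers per level) with 3 chains × 150 000 draws (4 × 200 000 for the
quadrature comparison), which gives effective sample sizes in the
thousands for diet proportions; posterior medians are stable to well under
a percentage point across seeds at these sizes. The PERMANOVA calibration
uses 1000 null datasets × 199 permutations, made cheap by evaluating all
permuted pseudo-F values vectorised.

## Known limitations

- No concentration dependence: fat-rich prey contribute FAs
  disproportionately per unit mass eaten; the model estimates FA-mass
  proportions, not ingested-mass proportions.
- No joint FA + stable-isotope model, no random effects or continuous
  covariates, one-way PERMANOVA only, no dispersion (PERMDISP) test.
- Diet proportions can never be exactly zero; absent sources appear as
  small positive shares and are surfaced by `rank_sources`.
- The Uniform(0, 20) residual prior is vague but proper; posteriors for
  `eps_j` are heavy-tailed and mix more slowly than the diet proportions —
  diagnostics are dominated by them on short runs.
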