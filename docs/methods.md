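# Methods

`twinmr` implements structural equation models for twin-family data that
combine Mendelian randomization (MR) with the Direction-of-Causation (DoC)
twin design — the MR-DoC model — together with the surrounding pipeline:
preprocessing, constrained correlational models, bivariate common-pathway
ACE models, phenotypic MR, and the decomposition of a phenotypic
correlation into causal and residual-genetic parts. This note records the
model, the conventions and numerical choices the implementation makes, and
what the synthetic-data generator does and does not emulate.

## The structural model

Every model is a system over latent variables η and unit-variance exogenous
*sources* u:

    η = B η + Γ u        (latent regressions and factor paths)
    y = Λ η + K s + μ    (measurement model and specific residuals)

Sources carry a *kind* tag that fixes how they correlate between the
members of a family:

| kind | meaning                        | cross-member correlation |
|------|--------------------------------|--------------------------|
| A    | additive genetic               | genetic relatedness r    |
| C    | shared environment             | 1                        |
| E    | individual-specific environment| 0                        |
| PS   | polygenic score (wholly genetic)| genetic relatedness r   |
| F    | generic factor                 | free per group (correlational models) |

With total effects `T = Λ(I−B)⁻¹Γ | K`, the within-person covariance is
`T Φ T'` (Φ the source correlation matrix) and the cross-member block
between members m, m′ is `T (Φ ∘ M) T'`, where `M` multiplies each entry by
the kind multiplier at pairwise relatedness `R[m, m′]`. MZ twins have
r = 1; DZ twins and ordinary siblings r = 0.5. A relatedness class is
therefore just a pairwise relatedness matrix, which makes twin-pair groups
and mixed twin+sibling trios the same code path.

### The MR-DoC model

For an exposure factor F1 (e.g. same-sex attraction, indicators `ssi` and
`ssp`), an outcome factor F2 (e.g. psychological distress, indicators
`dep` and `anx`) and a polygenic-score instrument factor P (indicators:
two polygenic scores for the exposure trait):

* `b1` — instrumental path P → F1,
* `g1` — unidirectional causal path F1 → F2,
* `b2` — horizontal-pleiotropy path P → F2,
* factor-level A/C/E paths `af1, cf1, ef1, af2, cf2, ef2` with
  correlations `r_a, r_c, r_e` between the exposure- and outcome-side
  factors,
* equality-constrained indicator-specific A/C/E residuals per factor,
* free residuals on each polygenic-score indicator.

The model with both `r_e` and `b2` free is locally unidentified (the
moment Jacobian loses exactly one rank); the default fixes `r_e = 0`,
which restores full rank. `build_mrdoc` refuses the unidentified
configuration unless explicitly overridden, and `check_identification`
exposes the rank report. A reverse-direction builder attaches the
instrument to the outcome trait and runs the causal path the other way; a
bidirectional variant (both instruments, both paths) is deliberately not a
default — it is unstable in practice.

Single-indicator factors (risky sexual behavior) fix the loading at 1 and
the residual at 0 to identify the measurement model.

### Scaling conventions

Everything variance-like is a path coefficient from a unit-variance
source: the instrument-factor scale is `sdP` (variance `sdP²`), score
residuals are `es` coefficients (variance `es²`). One convention keeps the
implied-moment algebra, the optimizer bounds (paths ≥ 0 where sign is a
pure reflection; correlations in [−1, 1]) and standardization uniform.
Each latent factor is scaled by fixing its first loading to 1;
standardized tables rescale every path by SD(origin)/SD(target) at the
estimates. Variance proportions are computed per kind (A, C, E, PS) from
the kind-partitioned quadratic form, so they sum to one exactly; for
factors downstream of a causal path the A share includes genetically
transmitted variance, and the heritability of an instrumented factor is
the A share plus the PS share.

## Estimation

Full-information maximum likelihood on family blocks: the deviance is
−2 Σ_f ln φ(y_f; μ_f, Σ_f), each family reduced to its observed entries.
Families within a relatedness group sharing a missingness pattern share
the reduced covariance, so the deviance is accumulated from per-pattern
sufficient statistics (count, mean, centered scatter); one evaluation
costs the same regardless of the number of families. Missingness is
handled by masking, never listwise deletion, so a family without
polygenic scores still contributes its phenotypes.

* Optimizer: L-BFGS-B with box bounds; multi-start (default 3: the
  builder start plus two seeded jitters).
* Gradient: analytic in moment space (the classical Gaussian derivatives
  with respect to μ and Σ) chained through forward finite differences of
  the polynomial parameter-to-moment map (step 1e−7·max(1, |θ|)).
* Non-PSD covariances during the search get an escalating ridge, then a
  large penalty; convergence requires optimizer success and a gradient
  norm small relative to the deviance, and a non-converged fit is flagged,
  never silently returned.
* Start values assume roughly unit-scale data (which the preprocessing
  produces); `FitOptions(start="scaled")` rescales them by the sample
  scale for raw-scale inputs. Note that rescaling a *single* phenotype
  indicator is not absorbable when its specific residuals are
  equality-constrained to its sibling indicator — that constraint is on
  the unstandardized scale by design.
* Saturated models parameterize Σ by its Cholesky factor; the MLE uses
  the 1/n covariance convention, matching the closed form
  n[p ln 2π + ln|Σ̂| + p].

Likelihood-ratio tests clip the χ² at zero and report the nominal-df
p-value with no boundary mixture correction (so a C-drop test on
boundary-zero components can legitimately print χ² = 0, p = 1).
Confidence intervals are profile-likelihood (bounds where the profiled
deviance rises by the χ²₁ quantile, other parameters re-optimized with
warm starts; boundary hits are flagged one-sided) with a family-resampling
bootstrap as fallback.

The local identification check differentiates the stacked unique moments
(means plus the lower triangle of each group covariance) at a generic
interior point — loadings 0.8, regressions/correlations 0.2, paths and
variances 0.6 — since identification is a generic property and special
points such as zero can mask deficiencies. The finite-differenced Jacobian
makes structural zeros surface at the differencing noise level, so the
rank tolerance is √ε-scaled rather than machine-ε-scaled.

## Preprocessing

The mean effects of age and sex are removed by pooled ordinary least
squares (only mean effects are removed, so family clustering is
irrelevant to the point estimates), and the residuals are transformed by a
rank-based inverse-normal transform with the Blom offset (ties share the
average rank). Rank-INT is the default because the raw interest and
risk-behavior scales are heavily skewed; a plain z-score is available.
Descriptives include per-zygosity-group means/SDs, category percentages
and standardized Cronbach's alpha `k r̄ / (1 + (k−1) r̄)`.

An upstream completeness filter (participants answering at least 80% of
the items per scale) operates on item-level data that never reach this
package; it is assumed to have been applied before ingestion.

## The synthetic-data generator

`simulate_families` draws family-level sources — A-sources correlated at
the pairwise relatedness, C perfectly shared, E independent, instrument
sources correlating like A — and propagates them through explicit
structural recursion (deliberately independent of the matrix path-tracing,
so the two implementations cross-check each other). Default generating
values are standardized and emulate the study conditions:

* causal path `g1 = 0.13`; pleiotropy `b2 = 0.04` (small, within the
  0.02–0.06 range the fitted models report);
* weak instrument `b1 = 0.10` (≈1% of exposure variance — the correlation
  between a polygenic-score factor and its target trait in this domain is
  of order 0.05–0.10);
* factor genetic paths `af1 = 0.75`, `af2 = 0.63`, genetic correlation
  `r_a = 0.26`, shared environment zero; the E paths are solved so every
  factor has exactly unit variance (implied heritabilities ≈ 0.58 and
  0.45 for exposure and outcome);
* indicator loadings (0.75, 0.73) and (0.86, 0.76), specific genetic
  paths 0.29 and 0.24, with one unstandardized specific-residual value
  per factor (matching the model's equality constraint; non-first
  indicators sit marginally below unit variance);
* score loadings (0.81, 0.99) with residual fill;
* an outcome-side instrument (`b1_rev = 0.10`) so reverse models have
  scores to work with;
* 500 MZ pairs, 950 DZ pairs, 590 twin–sibling pairs (a quarter-scale
  rendition of the cohort composition), 37% genotyped, missing completely
  at random (a family-level all-or-none mode emulates kit-return
  clustering).

Scenario presets (`paper_like`, `null_g1`, `confounded`, `pleiotropic`)
alter only the named parameters and record the full generating map in a
replicate manifest; replicate i of master seed s uses the seed sequence
(s, i), so extending a stream never perturbs earlier replicates.

What the generator does **not** emulate: item-level responses (indicators
are continuous; `likertize` exists only to reproduce marginal category
frequencies for preprocessing tests), genotype or GWAS structure (scores
are drawn directly as heritable traits), assortative mating,
informative missingness, age/sex effects unless requested, and
sex-limitation of the genetic architecture. Passing tests therefore
demonstrate correctness of the estimators under the stated generating
model, not robustness to violations of the classical twin assumptions.

## Validation battery and problem sizes

The acceptance studies (also runnable via `scripts/acceptance.py`) use
problem sizes chosen to keep the full battery within a few CPU-minutes:
the Monte-Carlo moment oracle uses 200,000 pairs per zygosity group
(agreement < 0.01 entrywise); parameter recovery uses 50 quarter-scale
replicates (mean causal path within 0.05, heritabilities within 0.04);
the type-I study uses 500 reduced-scale replicates (≈200/380/236 families
per group) and checks the 5% test rejects in 3–8% of replicates; the
MR-vs-MR-DoC comparison uses 50 confounded replicates. The unit suite
exercises the same machinery at smaller sizes, including a 300-replicate
null-distribution check of the likelihood-ratio statistic against χ²(1)
on a univariate pair model simulated by an independent oracle.

## Known limitations

* Continuous-liability Gaussian likelihood only: no ordinal thresholds,
  definition variables, or sex-limitation models.
* The correlational models are fit on pair-extracted data (a trio
  contributes its twin pair plus a sibling singleton) because their
  cross-member correlations are free per group; the ACE and MR-DoC models
  use full trio blocks.
* Standard errors come from profile likelihood or bootstrap; no sandwich
  corrections.
* Cross-twin correlations of the correlational model absorb
  indicator-specific genetic covariance (their residuals are plain E),
  so they exceed the factor-level A share — the same behavior the
  corresponding published tables show; within-person correlations are
  unaffected.
* Polygenic-score residuals default to E-kind (uncorrelated across
  members). Real scores are identical in MZ twins; the factor carries all
  shared genetic signal, and the residual mode matters only if the two
  score indicators disagree systematically within person.
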