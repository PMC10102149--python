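# twinmr

Structural equation modelling for twin-family data that combines
**Mendelian randomization** (polygenic scores as instrumental variables)
with the **Direction-of-Causation twin design** — the MR-DoC model — to
ask whether the association between two traits reflects a causal path, and
in which direction, using cross-sectional family data.

The package is aimed at behavior-genetics and genetic-epidemiology
analysts working with twin/sibling cohorts in which a subset of
participants is genotyped. It implements the full analysis chain around a
motivating application — the relationship of same-sex attraction (SSA)
with psychological distress (PD) and risky sexual behavior (RSB):

* ingestion and validation of one-row-per-individual family tables
  (MZ/DZ twins and siblings, missingness masked, never dropped);
* preprocessing: age/sex residualization and rank-based inverse-normal
  transformation;
* constrained correlational (correlated-factors) models;
* bivariate common-pathway ACE models with a factor-level Cholesky
  decomposition and a shared-environment drop test;
* forward and reverse **MR-DoC models**: instrumental path `b1`, causal
  path `g1`, pleiotropy path `b2`, correlated factor-level genetic
  residuals `r_a`, identified by fixing the residual E correlation to 0
  (verified by a Jacobian-rank identification check);
* phenotypic MR models (no twin structure) for comparison;
* decomposition of the exposure-outcome correlation into causal,
  pleiotropic and residual-genetic contributions;
* a synthetic family-data generator that reproduces the statistical
  structure the models assume, so everything is testable end to end.

Estimation is full-information maximum likelihood on family blocks with
missingness patterns collapsed into sufficient statistics, multi-start
quasi-Newton optimization, likelihood-ratio tests, and profile-likelihood
confidence intervals. See `docs/methods.md` for the model algebra,
conventions, and limitations.

## The model in brief

For exposure factor F1, outcome factor F2 and polygenic-score instrument
factor P (each factor measured by observed indicators):

    F1 = b1·P + af1·A1 + cf1·C1 + ef1·E1
    F2 = g1·F1 + b2·P + af2·A2 + cf2·C2 + ef2·E2

with corr(A1, A2) = r_a, corr(C1, C2) = r_c, corr(E1, E2) = r_e, and
cross-member correlations fixed by biology: A and P correlate at 1 in MZ
pairs and 0.5 in DZ/sibling pairs, C at 1, E at 0. The instrument `b1`
identifies `g1` while `b2` absorbs horizontal pleiotropy; `r_e` is fixed
to 0 for identification. The standardized implied factor correlation
decomposes exactly as

    r(F1, F2) = g1  +  b1·b2  +  af1·r_a·af2   (+ C and E terms if present)

which is the path-tracing arithmetic the decomposition module reports.

## Worked example

Simulate a quarter-scale cohort and run the full pipeline (preprocess →
correlations → ACE factor model with C-drop test → forward/reverse MR-DoC
→ phenotypic MR → decomposition):

```bash
twinmr pipeline --out run1 --seed 3
twinmr report run1
```

which prints:

```text
twinmr run report
============================================================

Constrained correlational model
  r(exposure, outcome)  = +0.264
  r(instrument, exposure) = +0.131

Biometric common-pathway model
  C-drop LRT: chi2[5] = 5.425, p = 0.366 -> AE
  SSA      A2=0.56  E2=0.44
  PD       A2=0.45  E2=0.55

Measurement model (standardized loadings / specifics)
  ssi      loading=0.74  a_s=0.30  c_s=0.00  e_s=0.60
  ssp      loading=0.74  a_s=0.30  c_s=0.00  e_s=0.60
  dep      loading=0.85  a_s=0.23  c_s=0.00  e_s=0.48
  anx      loading=0.85  a_s=0.23  c_s=0.00  e_s=0.48

mrdoc-forward model
  standardized causal path g1 = +0.114
  share of observed correlation r = 0.26:
    causal                43%
    residual genetic      55%
    pleiotropic            2%

mrdoc-reverse model
  standardized causal path g1 = +0.090
  share of observed correlation r = 0.26:
    causal                34%
    residual genetic      65%
    pleiotropic            1%

Phenotypic MR model
  standardized causal path g1 = +0.267
```

Reading the output: the two traits correlate at 0.26; the common-pathway
model attributes ~56% and ~45% of the factor variances to additive
genetics with no detectable shared environment (so downstream models are
AE-parameterized); the forward MR-DoC estimates a standardized causal
path of 0.11 — close to the generating value 0.13 at this sample size —
with about 43% of the observed correlation causal and most of the rest
residual genetic correlation; and the phenotypic MR estimate (0.27) is
much larger, because without the twin structure the genetically
confounded covariance is absorbed into the causal path.

The same stages are available programmatically
(`twinmr.build_mrdoc`, `twinmr.fit_fiml`, `twinmr.decompose_fit`, ...)
and as single CLI commands (`twinmr simulate`, `twinmr preprocess`,
`twinmr fit mrdoc-forward ...`).

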