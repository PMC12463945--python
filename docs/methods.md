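# Methods

`combkit` implements a complete analysis chain for COM-B questionnaire
studies of occupational-health behavior: a synthetic Likert-data generator
with a known latent structure, psychometric scale evaluation, structural
equation modeling with bootstrap mediation tests, score discretization, and
association-rule mining over the discretized domain profiles. This note
documents the models, the numerical choices, and what the simulation-based
tests do and do not demonstrate.

## The behavioral model

The COM-B framework treats Behavior (B) as jointly determined by
Capability (C), Opportunity (O) and Motivation (M), with Motivation also
mediating the effects of Capability and Opportunity. In standardized form
the structural part is

    M = beta_MC * C + beta_MO * O + zeta_M
    B = beta_BC * C + beta_BO * O + beta_BM * M + zeta_B

Each module is a second-order construct measured through first-order
domains (e.g. BR = behavioral regulation under Capability, PN = policies
and norms under Opportunity); each domain carries at least three 5-point
Likert items, except the eight target behaviors, which are single items.

## Synthetic data generator

The generator is a thresholded latent-normal (graded-response style)
mechanism:

1. (C, O) are drawn from a bivariate standard normal with correlation
   `exog_correlation` (default 0.5 — the module-level correlation is not
   identified from published tables, and 0.5 sits between the reported
   within-module domain correlations of roughly 0.45–0.78);
2. M and B follow the structural equations above, with disturbance
   variances chosen so both composites stay unit-variance, making the path
   coefficients directly comparable to standardized estimates;
3. each first-order domain factor is `gamma * module + sqrt(1-gamma^2) * z`,
   with `gamma` its second-order loading;
4. each item latent is `lambda * domain + sqrt(1-lambda^2) * z`
   (standardized), then cut at thresholds (−1.5, −0.5, 0.5, 1.5) into 1–5.

Default parameters are the fitted values of the published COM-B solution:
structural paths (0.21, 0.18, −0.04, 0.26, 0.41), the reported second-order
loadings per domain, and the reported first-order item loadings where
printed (0.78 for opportunity items and 0.70 for behavior items, which have
no printed per-item loadings). The symmetric default thresholds put item
means near 3, matching the reported score distribution. Missing data are
off by default; an MCAR rate can be requested.

The generator encodes the inter-domain correlation structure
hierarchically — cross-domain correlations arise only through module
factors and structural paths — rather than through a free first-order
correlation matrix. This is exactly the structure the downstream structural
model assumes, which is what makes parameter-recovery simulation
meaningful; it also means the generator cannot emulate, e.g., correlated
residuals or domain-specific cross-loadings. What passing recovery tests
show is therefore internal consistency of generator + estimator, not
robustness to real-data misspecification. Response styles (acquiescence,
extreme responding), item-specific thresholds and non-MCAR missingness are
deliberately out of scope.

## Psychometrics

- **Item screening**: corrected item-total correlation (item vs. sum of the
  remaining items of its subscale); items below 0.5 are flagged. An item
  whose rest score is degenerate (zero variance) gets NaN rather than a
  value.
- **Sampling adequacy**: KMO from anti-image partial correlations via the
  inverse correlation matrix; Bartlett's sphericity
  chi2 = −(n−1−(2p+5)/6)·ln|R| on p(p−1)/2 df.
- **EFA**: principal-component factoring of the correlation matrix,
  components retained at eigenvalue > 1.0, varimax rotation with Kaiser
  normalization (SVD-based iteration; convergence when the criterion gain
  falls below 1e-8 relative, 200 sweeps max, both configurable). Sign
  convention: each factor's largest-|loading| entry is made positive;
  factors are ordered by explained variance after rotation.
- **Retention rules**, applied in a fixed order: item-total -> primary
  loading <= 0.5 -> cross-loading > 0.5 -> factors left with fewer than
  three items are dissolved (each item gets exactly one primary reason).
  The pipeline applies one EFA pass after item-total screening, mirroring a
  single re-analysis.
- **Reliability/validity**: Cronbach's alpha (sample variances, n−1
  denominator throughout), AVE = mean squared standardized loading,
  CR = (Σλ)²/((Σλ)²+Σ(1−λ²)), and the Fornell–Larcker check
  sqrt(AVE_i) > |r_ij| (strict; equality fails).
- The EFA/CFA **sample split** is an ordered first-half/second-half split
  by default, with a seeded random split available.

## Structural equation modeling

Models are written in a four-line DSL (`factor`, `second`, `path`, `cov`)
and compiled to all-variable form: directed coefficients in A, symmetric
(co)variances in S, so the implied covariance of the observed block is
`[(I−A)^−1 S (I−A)^−T]_obs`. `F_ML = ln|Σ| + tr(SΣ^−1) − ln|S| − p` is
minimized by L-BFGS-B with the analytic gradient (a handful of matrix
products per evaluation), multi-start: one structured start (loadings from
marginal SDs, small paths) plus seeded random perturbations. Non-PD
candidate Σ gets a large penalty and the line search backs off.

Identification: exogenous latent variances are fixed to 1 with all
loadings free; endogenous latents are scaled by fixing their first loading
to 1. The standardized solution — which is invariant to this choice — is
derived from the fitted total covariance and is what all reported paths and
mediation effects use. Negative variance estimates (Heywood cases) are
flagged, not constrained away.

Fit indices use the chi2 = (n−1)·F convention (which also enters the RMSEA
denominator): chi2/df, GFI, AGFI, RMSEA, SRMR (RMS of standardized
residuals over the lower triangle including the diagonal), NFI, TLI, CFI
against the diagonal independence baseline. With df = 0, RMSEA/AGFI are
reported as absent with a reason.

**Mediation** uses case-resampling bootstrap: refit per resample
(warm-started from the full-sample solution), indirect effect = product of
the standardized a and b paths, percentile and bias-corrected (BC) 95%
intervals, and percentile-based two-sided p-values — inference rests on
the bootstrap, not on normal-theory standard errors, and the reported
standard error is the bootstrap SD. Classification: *full* mediation when
the BC interval of the indirect effect excludes 0 and that of the direct
effect does not; *partial* when both exclude 0; *none* otherwise.
Resamples with non-PD covariances or failed fits are dropped and counted;
more than 10% dropped is an error.

The packaged COM-B structural model uses **domain mean scores as
indicators** of the four module factors (23 observed variables: 15 domain
scores and 8 behavior items) rather than all 59 items. Score parcels keep
the second-order structure identified while making a single ML fit take
tens of milliseconds, so that bootstrap mediation with thousands of
replicates remains a routine operation; the same machinery accepts a full
item-level hierarchical model via the `second` directive when wanted.
Because Likert thresholding attenuates item correlations roughly
proportionally, standardized structural paths remain nearly unbiased under
this parcel model, which the parameter-recovery suite verifies (bootstrap
CIs at n = 484 cover the generator's path values).

## Discretization and rule mining

Domain scores (arithmetic means over the domain's — by default retained —
items) are cut at the fixed rule: score < 3 -> L, 3 <= score < 4 -> M,
score >= 4 -> H; each respondent becomes one transaction with exactly one
`DOMAIN=LEVEL` element per domain and behavior. Level recodes (e.g.
merging M into L for a domain observed only at M/H) are explicit audited
operations.

Apriori is implemented from scratch (level-wise join of sorted frequent
k-itemsets with subset pruning), since the mining measures are part of the
method under study; candidate generation accepts an anti-monotone filter,
used to cap itemsets at one behavior element. Rules have a single behavior
consequent and, by default, antecedents restricted to the 15 determinant
domains. Thresholds: support >= 5%, confidence >= 50%, lift **strictly**
> 2 (the minima are inclusive, the lift bound exclusive, following the
stated operators). Rules are partitioned by behavior x level (up to 16
partitions), M-level antecedents are eliminated with explicit per-partition
exception sets, the top 10 by lift (ties: confidence, then support, then
lexicographic antecedent) are the strong rules, and domains appearing at
least 5 times across a partition's strong rules are flagged as
high-frequency determinants. Support is always computed over all
transactions, never partition-locally.

## Problem sizes used in the test suite

The simulation suites run at the study's sample size n = 484. Parameter
recovery uses 20 generator replicates with 500 bootstrap resamples each;
null-indirect coverage uses 50 replicates at 500 resamples on a compact
three-factor mediation model (the coverage property concerns the bootstrap
machinery, not model size). Rule-mining equivalence uses 50 random tables
of up to 12 elements and 200 transactions against exhaustive enumeration.
Production mediation runs default to B = 5000.

A caveat on power: with the default calibration (structural paths of
moderate size, module correlation 0.5), the standardized C→M path has a
sampling SD near 0.066 at n = 484, so a single survey of this size detects
the Capability→Motivation→Behavior indirect effect (0.21 × 0.41 ≈ 0.086)
with only moderate probability; simulation replicates will sometimes
classify the mediation as absent even though the generator encodes it.
This is a property of the design size, not of the estimator — the same
Monte-Carlo shows the estimator unbiased with bootstrap SDs matching the
true sampling SD.

## Known limitations

- Pearson covariances on ordinal 5-point items attenuate absolute loadings
  (by roughly 8–10% at the default thresholds); standardized structural
  paths are affected far less. No polychoric option is provided.
- The EFA/retention flow reproduces decision rules, not any particular
  commercial implementation's modification indices; respecification after
  CFA is by exact leave-one-item-out refit ranked by ΔF_ML rather than
  Lagrange-multiplier approximations.
- Bootstrap mediation p-values are percentile-based and hence granular at
  small B.
- The mining step's complexity is exponential in the vocabulary in the
  worst case; the behavior-element cap and optional `max_len` keep the
  default analysis small, but unrestricted mining on dense tables can be
  slow.
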