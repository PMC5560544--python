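# Methods note

This note documents the models, numerical choices, and design decisions in
`calfsid`, and states precisely what the synthetic-data-based tests do and
do not demonstrate.

## Acid-base model

Two frameworks are computed per calf from one admission blood sample.

*Henderson-Hasselbalch*: actual bicarbonate `S·pCO2·10^(pH−pK1')` with the
calf-plasma constants pK1' = 6.105 and S = 0.0307 mmol/L/mm Hg, and the
van Slyke in-vitro base excess
`(1 − 0.014·Hb)·[(HCO3 − 24.8) + (1.43·Hb + 7.7)·(pH − 7.4)]` with
hemoglobin in g/dL. Both use the 37 °C analyzer measurements — that is the
convention of the blood-gas unit, and the derived values are comparable
across patients regardless of body temperature.

*Simplified strong ion model*: Atot = 0.343·(total protein in g/L),
A⁻ = Atot/(1+10^(pKa−pH)) with pKa = 7.08 (experimentally determined calf
values), SIDm including the measured D- and L-lactate, SIG = A⁻ − AG, and
USI = SIG + D-lactate + L-lactate. Two identities hold by construction and
are enforced to 1e−9 in tests: `USI − SIG − lactates ≡ 0` and
`USI + SIDm ≡ A⁻ + HCO3`.

*Temperature correction* uses the common linear-in-log forms
pH_T = pH − 0.0146(T−37), pCO2_T = pCO2·10^(0.019(T−37)),
pO2_T = pO2·10^(0.0052(T−37)). Analyzer vendors differ in the exact
algorithm (especially for pO2); the coefficients are therefore a
`TemperatureCorrection` configuration object, and the defaults are an
assumption, not a vendor specification.

*Units are fixed*: protein g/L, hemoglobin g/dL (the van Slyke buffer
coefficients require g/dL), gases mm Hg. The cohort-CSV reader rejects a
file whose units row disagrees, because a silent g/L↔g/dL mix-up corrupts
every derived quantity. Validation distinguishes impossible values
(negative concentrations, pH outside 6.0–8.0 → error) from implausible
ones (Na ≤ Cl → warning).

## Rule-based classifiers

SIRS is positive with ≥ 2 of four criteria; the reference intervals
(leukocytes 5–12 G/L, rectal temperature 38.5–39.5 °C) are inclusive —
abnormal means strictly outside — matching the strict `>` of the
tachycardia (120/min) and tachypnea (36/min) thresholds. Missing inputs
make the result *indeterminate* rather than negative, because SIRS feeds
downstream models as a covariate and "unknown" must stay distinguishable
from "no". Clinical septicemia = SIRS plus ≥ 1 suspicion sign. The
external septicemia-prediction model (age, recumbency, absent suckling
reflex, focal infection) ships as a user-suppliable model-JSON slot with
its 0.3 probability threshold; its coefficients are not public in the
sources available to this package, so only the threshold and the reported
69%/75% sensitivity/specificity are recorded as metadata.

## Synthetic cohort generator

The generator's purpose is structural fidelity: every downstream stage
(derivation, classification, trees, regression, evaluation) can be
exercised on data with the right shape, margins, missingness and outcome
mechanism.

- **Margins.** Each analyte is matched to published median/quartile
  targets by a quantile-matched family: shifted log-normal (3 parameters,
  closed-form solution of the 3 quantile equations) for right-skewed
  analytes — lactates, urea, creatinine, enzyme activities, potassium,
  glucose, cell counts, age — and normal for symmetric ones (electrolytes,
  pH, gases, proteins, hematology indices). Samples are truncated to
  physiologic bounds chosen to bracket the quartiles, so the matched
  quartiles are unaffected. The default targets are the survivor-column
  summaries (survivors are 77.6% of the cohort and the closest available
  proxy for the full-cohort margin; the non-survivor margin emerges only
  through the outcome model, which is a simplification).
- **Rectal temperature** is normal with sd 0.8 °C and mean solved so that
  P(T < 38.5 °C) equals the configured hypothermia prevalence
  (572/1400 ≈ 40.9% by default).
- **Dependence.** A Gaussian copula links only configured pairs (default
  pH–pCO2 and L-lactate–creatinine at rank correlation 0.3). Full joint
  dependence is not identifiable from marginal summaries; the defaults are
  assumptions recorded in the sidecar JSON that `simulate` writes.
- **Clinical categories** are sampled at the published prevalences; the
  septicemia-suspicion-sign prevalences are set so the emergent clinical
  septicemia rate (SIRS ∧ sign) is near the published 16%.
- **Outcome.** Binary death is Bernoulli(inverse-logit(η)) where η comes
  from the published clinical+laboratory model evaluated on *generated*
  values — binary model features (pH < 6.85, cachexia, flags) are computed
  from the continuous/ordinal columns, never sampled directly, so feature
  prevalences emerge from the margins. The expert-review alternative label
  flips a configurable fraction (default 57/313) of non-survivors to
  survivors.
- **Missingness** is injected per column after outcome assignment, at the
  footnote-implied rates; identifier and outcome columns are protected.
- **Determinism.** One `numpy` Generator seeded from the spec; identical
  specs give byte-identical CSVs.

What passing tests show: the estimators are unbiased and correctly
calibrated *under the generating mechanism* (independent-given-margins
analytes, logistic outcome, MCAR missingness). What they do not show:
performance on real cohorts, where analytes are strongly cross-correlated,
missingness is informative, and the outcome mechanism includes euthanasia
decisions no logistic model captures.

## Classification trees

A from-scratch CART for binary outcomes: exhaustive Gini splitting over
every midpoint between distinct observed values; 3-point ordinal scores
treated as ordered (splits at 1.5/2.5), flags as 0/1. Growing controls
default to min_split 20, min_bucket 7, cp 0.001, ≤ 5 surrogates — grow
generously, prune by cross-validation. Tie-breaks are deterministic
(smaller variable index, then smaller cutpoint). Class priors are
empirical; no case weights or loss matrix.

Surrogate splits are searched in both orientations and kept only when
their agreement with the primary split beats the majority-direction
baseline; cases missing the primary variable route by the first applicable
surrogate, then by majority direction. With complete data, predictions are
identical with or without surrogates (tested).

Pruning computes the nested weakest-link cost-complexity sequence on
misclassification risk, then 10-fold cross-validation (stratified by
outcome to stabilize error on a ~22% event rate; fold assignment
reproducible from the seed) evaluated at the geometric means of
consecutive alphas. The returned subtree minimizes CV error; among ties
the largest alpha (smallest subtree) wins. The 1-SE rule is available as
an option but is not the default, because the selection rule here is the
*lowest* cross-validated error. Exact growing controls and fold
stratification of the original analysis are unknown, so published tree
topologies are emulation targets, not exact-reproduction targets.

## Logistic regression and univariate statistics

Maximum-likelihood fitting delegates to statsmodels' `Logit`; the modelling
strategy around it is implemented here. Complete-case analysis per model
(rows missing any model term are dropped and the model's n reported, which
is why the published per-model n's differ). Coefficients beyond ±15 on the
log-odds scale, or a singular information matrix, raise an explicit
separation error naming the offending term. Backward elimination removes
the largest-Wald-p term while p > α (default 0.01), refitting each step,
intercept always retained, order logged. Wald CIs use z = 1.96. Zero cells
in 2×2 tables get the Haldane-Anscombe 0.5 correction with a warning (the
study's own counts never exercise this).

Hosmer-Lemeshow grouping is rank-based and tie-aware: cases sharing a
predicted value stay in one group, so binary-feature models collapse to
few groups and df = g − 2 can be as low as 1. The original analysis
software's exact collapsing rule is undocumented, so printed HL statistics
are treated as emulation metadata, not reproduction targets.

Mann-Whitney U uses exact enumeration for tie-free samples with both
n ≤ 20 and the tie-corrected normal approximation otherwise; two identical
constant groups return p = 1 by convention.

## Evaluation

ROC curves enumerate all distinct score thresholds; the AUC is the
trapezoid integral, equal to the tie-corrected pair-counting statistic
(verified against exhaustive pair counting for n ≤ 50); its CI is the
DeLong placement-value interval. Youden's J breaks ties toward the lowest
threshold. Rule sensitivity/specificity carry exact Clopper-Pearson
intervals; rows missing the rule variable are excluded and counted.

Decile survival analysis bins by rank (ties to a single bin, boundaries
reported, single-value deciles flagged), picks the reference decile by
maximal overlap fraction between its observed value range and the
analyte's reference interval (ties: median closest to the interval
midpoint — the published description "best lay within the reference range"
is verbal, so this rule is an interpretation recorded in the output), and
compares each decile to the reference with a df = 1 Pearson chi-square
without continuity correction at the Bonferroni-adjusted level 0.05/9
(displayed as P ≤ 0.006).

## Published model registry

The four printed prognostic models are embedded read-only with
coefficients, SEs, per-term printed ORs and probability cutpoints (0.25,
0.27, 0.27, 0.19). Classification uses probability ≥ cutpoint (the ≥
convention is a documented choice; the source is silent on the boundary).
Published AUCs, HL statistics and the pH-rule operating point are stored
as metadata flagged `emulation_target`: they are facts about the original
cohort, not quantities this package recomputes.

## Problem sizes in tests and the acceptance script

Chosen to probe each claim at the smallest scale that is statistically
informative: identity suites use 10⁴ random panels; coefficient recovery
uses 20 cohorts of n = 5×10⁴ (SEs small enough that a ±3 SE check is a
sharp bias test); tree recovery uses a noiseless n = 2000 two-rule cohort
plus 20 permuted-label replicates; backward-selection calibration uses 200
null simulations of n = 500. The default `pytest` run and the acceptance
script are deterministic given their seeds.

## Known limitations

- The generator reproduces margins and a thin copula, not the real joint
  distribution; real-data correlations (e.g. dehydration linking PCV,
  protein, urea, creatinine) are absent.
- Ordinal clinical scores are treated as ordered-continuous in the tree;
  unordered categorical splitting is not implemented (no such variables
  exist in this data model).
- No profile-likelihood or exact logistic CIs, no penalized regression,
  no regression trees or ensembles, no arterial/venous conversion, no
  oxygen-content computation.
- Constants are calf-specific; other species require an explicit
  `AcidBaseConstants` configuration.
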