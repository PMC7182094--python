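# Methods

## Liability-threshold model

A binary trait with prevalence *p* is modelled as an indicator that a
latent standard-normal liability exceeds τ = Φ⁻¹(1 − *p*). A twin pair's
liabilities are bivariate normal with correlation ρ. Because twin order
within a pair is arbitrary, pair tables are symmetric and trinomial —
(concordant unaffected, discordant, concordant affected) — with cell
probabilities

    P(both)     = Φ̄₂(τ, τ; ρ)
    P(one)      = 2·(Φ̄(τ) − Φ̄₂(τ, τ; ρ))
    P(neither)  = 1 − 2·Φ̄(τ) + Φ̄₂(τ, τ; ρ)

where Φ̄₂ is the upper-orthant probability of the standard bivariate
normal. A single threshold is shared by both pair members and (by default)
across zygosity groups, which assumes one trait distribution for all
twins; a per-zygosity threshold can be obtained by fitting the groups
separately.

**Orthant computation.** Φ̄₂ is evaluated through Owen's T function
(`scipy.special.owens_t`): Φ̄₂(h,k;ρ) = ½(Φ̄(h)+Φ̄(k)) − T(h,a_h) − T(k,a_k) − β,
with the standard corrections for sign and the degenerate |ρ| → 1 limits.
This is exact to ~1e-14, vectorized, and avoids the cancellation that the
1 − Φ(h) − Φ(k) + Φ₂ route suffers at large thresholds (rare diseases sit
at τ ≈ 2.2–3.5). Exact zeros of h or k are perturbed by 1e-13, which is
inconsequential by continuity. Tests compare against adaptive double
integration of the density.

**Tetrachoric MLE.** (τ, ρ) maximize the trinomial log-likelihood;
ρ is optimized through atanh for an unconstrained search (Nelder–Mead,
multistart at ρ₀ ∈ {0, 0.5, 0.9, −0.5}, function tolerance 1e-10). A
property of the symmetric MLE — fitted marginal prevalence equals the
observed individual prevalence — is asserted in tests to 1e-6.
Confidence intervals are profile likelihood at the χ²₁ 95% cutoff (3.84),
bracketed to |ρ| ≤ 0.999; |ρ̂| ≥ 1 − 1e-3 sets a boundary flag (perfectly
concordant tables push ρ → 1).

## Variance components

MZ pairs share A, C, and D fully; DZ pairs share C fully, half of A, and a
quarter of D, giving ρ_MZ = a²+c²+d², ρ_DZ = ½a²+c²+¼d². The ACE, ADE,
AE, CE, and E models are fitted by maximizing the summed trinomial
log-likelihood of the MZ and DZ tables with one shared threshold. Free
components live on the unit simplex through a softmax transform (the last
logit pinned to 0 for e²); estimates within 1e-6 of a boundary are
reported exactly at 0. Starting values are Falconer-style:
a²₀ = clip(2(r̂_MZ − r̂_DZ), 0.05, 0.95) from tetrachoric point estimates,
threshold from pooled prevalence. AIC = 2k − 2ℓ with k = threshold + free
components; ties in model selection go to the smaller model. When AE wins
and an ADE fit lies within 2 AIC units, the ADE broad-sense heritability
a²+d² is attached to the report, since twin data alone barely
distinguishes the two. The 95% CI for a² is profile likelihood with the
other free quantities re-optimized at each fixed a²; it respects the
[0, 1] boundary (e.g. near-unity heritabilities get intervals like
0.88–1.00).

Unadjusted pair-table fits on the bundled published tables are expected to
*approximate* the published covariate-adjusted, censoring-corrected
heritabilities — they reproduce the ordering and range (gastritis lowest
≈ 0.48, Addison's highest ≈ 0.97) but not the exact values, which is why
the reference checks on heritability are qualitative.

## Truncation and censoring (IPW fit)

Register cohorts observe status only inside a window: entry at
max(birth, registry start), exit at min(onset, death, registry end).
A person censored before their would-be onset is recorded unaffected,
thinning cases, raising the apparent threshold and biasing the fitted
correlation — in simulations with ~30% of cases censored, naive AE fits
underestimate a² by ≈ 0.09.

The correction: estimate the censoring process' survival S_c(age) by a
product-limit (Kaplan–Meier) curve on the age scale with delayed entry,
treating non-disease exit as the event; weight each affected person by
w = 1/S_c(exit age) (unaffected persons keep weight 1); truncate weights
at their 99th percentile for variance stability. Pairs then enter a
weighted composite pairwise likelihood whose cells are bivariate-probit
orthants with person-specific thresholds τᵢ = τ₀ + βᵀxᵢ (female indicator
and 10-year birth-year bins by default) and zygosity-structured
correlations. Identical likelihood contributions are grouped (zygosity ×
cell × covariate pattern, weights summed), so an evaluation costs a
handful of orthant calls regardless of cohort size; optimization is
L-BFGS-B with a Nelder–Mead fallback.

This scheme is an approximation to full-likelihood treatments of
truncated twin data. It is exact in reduction: with no censoring and no
covariates it equals the pair-table fit to 1e-4 (asserted in tests), and
setting all weights to 1 reproduces the unweighted fit exactly. It
corrects most but not all of the censoring bias (censored-unaffected
misclassification remains in the unaffected cells); simulations show
|bias| roughly halved at 30% case censoring. Bootstrap (pair-level
resampling) is the intended route to interval estimates; the composite
likelihood's curvature is not a valid variance. Prevalent-at-entry
persons are retained as affected (their status is known even though their
onset predates entry); a flag marks them for sensitivity analyses.

## Co-aggregation

Each twin is followed on the age scale from max(birth, disease
observation start) to own outcome, death, or registry end; the co-twin's
diagnosis of the index disease is a time-varying exposure that switches
strictly *after* the co-twin's diagnosis date — a same-day pair of onsets
counts the event in the unexposed state, avoiding immortal-time
artifacts; the zero-length exposed episode is dropped. Outcomes: the same
disease, a different studied disease, or any studied disease. In
different-disease mode an own index-disease diagnosis does not terminate
follow-up (the person remains at risk of the other diseases).

Hazard ratios come from Cox partial likelihood (lifelines) with delayed
entry, Efron tie handling, sex and 10-year birth-year-bin covariates, and
a pair-clustered sandwich variance for the reported CIs (model-based SEs
retained for comparison; robust ≥ model-based under positive within-pair
correlation, asserted on simulations). Rare events with strong exposure
effects make the default full Newton step overshoot into overflow, so
fits use a damped step (step size 0.5) with a fallback ladder: smaller
steps, then sex-only, then exposure-only covariates — fallbacks are
flagged in the result. Estimates are validated against a brute-force
partial-likelihood grid search in tests. Strata with no events or no
exposed person-time are reported not-estimable rather than fitted.

## Synthetic cohort generator

The generator draws what the analyses assume: pairs with ~1/3 MZ, births
uniform over 1886–2006, MZ same-sex, per-trait liabilities built from
additive (cross-twin correlation 1 MZ / 0.5 DZ — the DZ value is a
parameter so that "no DZ sharing" designs are expressible), shared-
environment (correlation 1), dominance (1 / 0.25), and unique factors;
cross-trait additive correlations through a common factor correlation
matrix (default: uniform 0.3, a moderate genetic overlap consistent with
observed autoimmune co-aggregation). Default traits mirror the published
cohort: prevalences from 25 (Addison's) to 1520 (thyroiditis) per
100 000, AE heritabilities 0.38–0.97, female excess as a threshold shift
calibrated from the published per-sex prevalences, lognormal onset ages
truncated to [0, 100] with disease-typical medians (15 y for type 1
diabetes through 60 y for gastritis).

Onset age is drawn independently of liability: liability fixes lifetime
status, timing is separate. This is the simplest generator consistent
with a time-invariant liability; it omits liability-dependent onset,
cohort effects in incidence, and calibrated national life tables (death
uses a coarse per-decade conditional survival table — enough to exercise
the 1976 survival-truncation rule and censoring machinery). Passing tests
therefore demonstrate correctness of the estimators under the model's own
assumptions, not robustness to real-world violations of them.

Register event streams are emitted only inside the observation windows
(patient register 1964–2015; drug register from 2005-07) and during life:
a case visible in the window gets two inclusion ICD events (onset-date
clipped to the window start, plus a 90-day repeat), and traits with a
prescription requirement get two dispensations for persons alive after
2005-12-31. Downstream ascertainment therefore experiences realistic
truncation: affected persons who die before 1964 or onset after 2015
produce no events.

Randomness: one root seed; independent component streams derived as
`SeedSequence([seed, k])` for structure, liabilities, onsets, deaths;
per-trait liability substreams via generator spawning, so appending a
trait leaves earlier traits' draws byte-identical (asserted in tests).

## Problem sizes used in the checks

Recovery studies run at 20 000 pairs per zygosity with 50 replicates per
condition (the scale at which the ±0.05 mean-bias bound is meaningful);
co-aggregation direction checks use 4 000 pairs per zygosity at 5%
prevalence with genetic sharing confined to MZ pairs, and 6 000-pair null
cohorts for CI coverage. The published pair tables are refitted exactly
as printed.

## Known limitations

* The ascertainment code lists shipped in `data/diseases.yaml` are
  illustrative configuration, not a canonical register extract; the rule
  engine (prefix matching, ≥2-code exclusion logic, prescription
  requirements) is the tested artifact.
* The ≥2-exclusion rule counts exclusion *events*; whether distinct codes
  or distinct dates should be required is a registry-convention choice
  exposed to the caller only through the event stream itself.
* The IPW composite-likelihood fit is a documented approximation, not a
  full-likelihood estimator; its point estimates are validated by
  simulation, its dispersion is not reported.
* No sex-limitation models and no bivariate/multivariate (cross-trait)
  variance decomposition; the simulator supports cross-trait genetic
  correlations so such fitters can be validated later.
* Probandwise CIs are Wilson intervals on dependent proband observations
  (concordant pairs contribute two); they are descriptive.
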