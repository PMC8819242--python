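# Methods

## Risk model

A patient's type-2 stratum is determined by two stable-state biomarkers,
blood eosinophils (Eos, ×10⁹ per L) and exhaled nitric oxide fraction
(FENO, ppb), against four thresholds (defaults Eos 0.15 / 0.30, FENO
25 / 50, all inclusive):

* **very high**: Eos ≥ 0.30 **and** FENO ≥ 50 — both biomarkers very high;
* **high**: Eos ≥ 0.15 **or** FENO ≥ 25 (and not very high) — any
  biomarker high;
* **low**: otherwise — both biomarkers low.

Evaluating the predicates in that order makes the three labels mutually
exclusive and exhaustive; a profile with one biomarker very high and the
other low is *high*, not very high. Strict `<` therefore defines the low
stratum, matching the usual epidemiological phrasing of these cut-offs.

The risk scale is multiplicative: the annualised severe-attack rate of a
stratum's control arm is the biomarker-low rate λ_low times a stratum
multiplier *m* (m_low = 1). The default multipliers, m_high = 1/0.58 and
m_very_high = 1/0.28, are the values implied by predicted reductions of 42%
and 72%; they are configuration (overridable via YAML/JSON), not estimated
by this package — deriving them from the original stratified derivation
trials is out of scope. Rates are continuous non-negative reals with no
upper cap.

**Counterfactual treatment rule.** The theragnostic hypothesis is that
type-2 anti-inflammatory treatment removes exactly the biomarker-conferred
excess risk: the predicted active-arm rate of every stratum equals λ_low,
and there is no treatment effect when biomarkers are low. Consequences used
throughout: predicted RR = 1/m per stratum, a trial-independent constant,
and predicted reduction 1 − 1/m = 0% / 42% / 72% under the default scale.

## Trial-level data

Input tables are tidy CSV with header
`trial_id,stratum,arm,n,rate,incidence,source` (empty cell = NA; `source`
is `observed` or `predicted`). Each row carries exactly one of
rate/incidence; incidence-only rows (trials reporting only the proportion
of patients with ≥1 attack over 52 weeks) are annualised as
rate = −log₁₀(1 − incidence). The incidence enters as a proportion; a
percent column must be declared explicitly (`incidence_unit="percent"`) —
no auto-detection, since a proportion is the only reading under which the
formula has full domain. A `ln` switch implements the exponential
waiting-time convention rate = −ln(1 − incidence) for sensitivity; log₁₀ is
the default because it is what the packaged reference table used. Every
imputation and FENO-band regrouping (20–<50 ppb → 25–<50 ppb) is logged
with before/after values; ingest never silently alters a rate.

The packaged fixture carries the published stratified summary of four
trials (Novel START, CAPTAIN, QUEST, DREAM) at printed precision: 20
observed stratum-arm cells (the QUEST and DREAM very-high cells were not
reported) and 24 predicted cells. Printed per-trial and weighted percentage
reductions ship alongside as a separate table.

## Comparison and aggregation

Per (trial, stratum) with both observed arms: RR = active/control (a zero
control rate is an error, not infinity) and reduction = 1 − RR, reported
as-is when negative (observed harm is not clipped). Strata missing an
observed arm are excluded and listed. Per-trial values are aggregated with
a frequency-weighted mean Σwᵢvᵢ/Σwᵢ, weights = stratum total n (both
arms) — the only weighting that reproduces the published weighted columns.
NA values drop out pairwise with their weights.

Two summary modes:

* **recomputed** (default): per-trial RRs recomputed from the (printed or
  user-supplied) rates;
* **printed mode** (used when reproducing the reference table): the printed
  per-trial reductions are the inputs. This reproduces the published
  low-stratum summary (RR 0.86, 14%) and the very-high summary (69% vs
  72%) exactly.

Rounding for display is half-away-from-zero, integer percent for
reductions and 2 decimals for rate ratios — this matches every printed cell
that is reproducible at all.

**Diff block.** Some printed cells cannot be recomputed from the other
printed numbers under any of these conventions; they were evidently
computed from unrounded internal values that the source does not report.
The pipeline enumerates them explicitly instead of matching them: the Novel
START reductions (e.g. printed 35% in the high stratum vs 40% from the
printed rates 0.05/0.03), the high-stratum observed weighted summary
(printed RR 0.59 / 41% vs 0.56 / 44% from the printed per-trial
reductions), the DREAM very-high predicted control rate (printed 2.60 vs
0.74/0.28 = 2.64), and the QUEST/DREAM very-high predicted active rates
(printed 0.82 / 1.14, where the counterfactual rule gives the biomarker-low
rates 0.53 / 0.74). The last two are a genuine internal inconsistency of
the source table: the implementation follows the stated rule and flags the
cells. No reconciliation is guessed.

Confidence intervals are deliberately absent: the regrouping of trial arms
and biomarker strata that produced the inputs precludes them, so the report
is point estimates only. Random-effects meta-analysis and heterogeneity
statistics are out of scope.

## Synthetic trials

`simulate_trial` generates a two-arm patient-level RCT with the structure
the analysis assumes. Per patient: a stratum from `stratum_probs`,
biomarkers uniform within stratum-consistent bands (so classification
round-trips exactly — the simulation re-checks this and rejects
inconsistent band configurations), fixed exposure (default 1 year, optional
uniform jitter), and an attack count from a negative binomial with mean

μ = λ_low · m(stratum) · RR_treat(stratum, arm) · exposure

and dispersion k (variance μ + μ²/k). Defaults, chosen once as realistic
study conditions:

| parameter | default | why |
|---|---|---|
| n_per_arm | 50 000 | large enough that MC error is small against the effect sizes |
| stratum_probs | 0.1634 / 0.7878 / 0.0488 | pooled composition of the four reference trials (814/3925/243 of 4982) |
| λ_low (`base_rate_low`) | 0.5 /pt-yr | mid-range of the trials' low-stratum control rates (0.05–1.98) |
| scale | m = 1, 1/0.58, 1/0.28 | the default risk scale |
| treatment RR | 1 / 0.58 / 0.28 | the counterfactual rule (1/m; no effect in low) |
| dispersion k | 0.7 | conventional exacerbation-trial overdispersion; not a value from the reference analysis |
| followup_years | 1.0 | annualised rates |

Counts are gamma-mixed Poisson because exacerbation counts in asthma trials
are overdispersed; `dispersion=inf` gives the Poisson limit (the tests
check variance/mean → 1 there). All sampling flows through one
`numpy.random.Generator` seeded from `SimConfig.seed`; identical configs
give bit-identical output. Aggregation recomputes each patient's stratum
from the biomarkers (it does not trust the generator's labels) and forms
n and total-attacks/total-exposure per (stratum, arm). A helper derives the
52-week binary endpoint so the incidence imputation can be exercised
end-to-end against the known simulated rate.

**Parameter recovery.** `recover_scale` inverts the aggregation:
m̂ = stratum control rate / low control rate, treatment RR = active/control
per stratum; on a noiseless table built from the model it is exact.
`recovery_study` replicates simulate→aggregate→recover with child seeds
drawn from one master seed. The validation test averages 30 replicates at
50 000 patients/arm: a single replicate's low-stratum reduction has MC
standard deviation ≈3 percentage points under k = 0.7 (the gamma-mixing
term √(2/(n·k)) floors it regardless of the event rate), so averaging — not
a wider band — is what brings the check safely inside ±2 points and ±0.02
on the high-stratum RR. The 30×100 000-patient study runs in a few seconds
on one CPU.

What the simulation does *not* emulate: attack timing and seasonality,
dropout, adherence, biomarker measurement error, and realistic marginal
biomarker distributions (bands are uniform boxes chosen for exact
round-trip classification). Passing recovery therefore shows the pipeline's
estimators are consistent for the generative model it assumes, not that the
model fits any particular real trial.

## Numerical choices

* Imputation round-trip: incidence → rate → incidence is stable to 1e−12
  across [0, 1); the reverse direction is similarly stable for rates up to
  a few attacks/pt-yr (beyond that, 1 − 10^(−rate) saturates in double
  precision). A zero incidence yields exactly 0.0 (the −0.0 of the naive
  formula is normalised).
* Zero control-arm rates make RR undefined and raise, rather than
  producing infinities that would poison weighted means.
* Weighted means validate positive weights and raise on an all-NA summary
  rather than returning NaN.
* Display rounding is half away from zero (so −3.57% prints as −4%),
  applied only at rendering; all stored values keep full precision.
* Predicted-versus-printed rate checks use a 0.04 attacks/pt-yr band,
  absorbing the worst-case rounding of the 2-decimal printed anchor rates;
  the one cell outside it (DREAM very-high control, deviation 0.043) is
  flagged in the diff block with the others.

## Known limitations

* The analysis is trial-level throughout; nothing here estimates
  patient-level absolute risk, and the scale multipliers are inputs, not
  estimates with uncertainty.
* The irreproducible printed cells (see diff block) mean the published
  high-stratum observed weighted RR of 0.59 cannot be verified from printed
  data; this package reports 0.56 from the printed per-trial reductions and
  flags the difference.
* The binary-endpoint imputation is a deterministic transform, not a
  survival model; it understates rates when attacks cluster within
  patients.
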