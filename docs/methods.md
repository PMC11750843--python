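# Methods

This note documents the statistical procedures implemented in `faersig`,
the conventions chosen where the underlying methodology is genuinely open,
and what the synthetic-data tests do and do not establish about behaviour on
real spontaneous-report data.

## Data model and deduplication

A spontaneous report is keyed by a case identifier and a case version.
Because the same case is re-submitted across quarters as information
accrues, the analysis universe keeps, per case, the row with the greatest
(case version, receipt date, file order) key. This rule is deterministic and
order-independent: sorting candidates by `(case_id, version_key)` and taking
the last entry per case yields the same universe regardless of input file
order. Deduplication is idempotent by construction. Child rows (drugs,
reactions, outcomes, therapy dates, indications) are attached per case
*version* via the primary identifier, so superseded versions never leak
rows into the retained report.

Unit conversions: age codes DEC/YR/MON/WK/DY/HR are converted to years
(1 year = 365.25 days = 8,766 hours; 1 week = 52.1775⁻¹ year); weight codes
KG/LBS/GMS to kilograms (1 lb = 0.453592 kg). Plausibility windows — ages
in [0, 120] years, weights in (0, 500] kg — turn unit-entry errors into
missing values rather than propagating them. Dates are parsed from
YYYYMMDD; partial dates (YYYYMM, YYYY) are accepted for demographics but
treated as missing wherever day precision is required (time-to-onset).

## Cohorting

Groups follow FAERS drug role codes. A report is *A-only* when drug A
appears as primary suspect (PS) and drug B appears in no role; *B-only*
symmetrically; *combination* when either drug is PS and the other appears in
any role (PS, SS, C, I); otherwise *excluded*. Drug names are matched
case-insensitively after trimming trailing salt and dose tokens, against an
editable ingredient→synonym table (brand names and biosimilar suffixes
included), because FAERS drug names are free text.

Tumor events are selected by a flat preferred-term → system-organ-class
lexicon. The bundled `tumor_lexicon.csv` is a **synthetic fixture** of ~80
neoplasm preferred terms assigned to the MedDRA-style neoplasms SOC; it is
not, and does not substitute for, the licensed MedDRA dictionary. Users with
a MedDRA licence should supply their own lexicon CSV. No hierarchy traversal
(HLT/HLGT/SMQ) is performed; the lookup is flat.

Descriptive bands are lower-closed/upper-open — ages [18, 45), [45, 60),
[60, 75), with <18 and >75 at the ends — so the boundary ages 18, 45, 60
and 75 each belong to exactly one band; the middle weight band is the
closed interval [50, 100] kg. Published tables in this field often print
overlapping band labels; a fixed convention makes counts reproducible.

## Disproportionality statistics

For each (cohort, PT) pair the 2×2 table counts reports, not reaction rows:
a report with the same PT listed twice contributes 1 to cell *a*. The
background (cells *c*, *d*) is every other deduplicated report in the loaded
universe, i.e. the other cohorts and the excluded reports together — the
standard case/non-case construction. A 0.5 continuity correction is applied
to all four cells only when a zero cell makes a statistic undefined, and the
output row is flagged `corrected`.

* **ROR** = ad/bc with the Woolf interval
  exp(ln ROR ± 1.96·√(1/a + 1/b + 1/c + 1/d)).
* **PRR** = [a/(a+b)] / [c/(c+d)]; χ² is the Pearson statistic without the
  Yates correction (the χ² ≥ 4 threshold is conventionally applied to the
  uncorrected statistic; a flag enables Yates).
* **BCPNN information component.** Under independent beta posteriors for the
  joint and marginal reporting probabilities with symmetric unit-style
  hyperpriors (joint prior count 1; marginal priors Beta(1, 1); the joint
  prior scale tied to the marginals so the prior IC expectation is zero),
  IC = log₂ p₁₁ − log₂(p₁·p·₁) has exact posterior moments in terms of
  digamma and trigamma functions. E(IC) and V(IC) are computed from those
  closed forms — no sampling in production — and IC025 = E(IC) − 2·√V(IC).
  Tests verify agreement with a 10⁶-draw posterior-sampling oracle to
  < 0.05 bits (measured < 0.001 for a ≥ 3).
* **MGPS.** The relative reporting rate λ has a two-component gamma mixture
  prior fitted by marginal maximum likelihood across all (cohort, PT) pairs:
  observed counts are negative-binomial mixtures given the expected counts
  E = (a+b)(a+c)/N. Optimization runs on log/logit-transformed parameters,
  multi-start (default start α₁=0.2, β₁=0.1, α₂=2, β₂=4, P=⅓ — the
  conventional starting point for this model) with L-BFGS-B followed by a
  Nelder-Mead polish; non-convergence from all starts is fatal. On null-like
  data the mixture may degenerate to one component; the mixing weight is
  then clamped away from the boundary, which leaves the fitted distribution
  unchanged. The posterior is again a two-component gamma mixture;
  EBGM = exp(E[ln λ | a]) via digamma, and EB05 solves the posterior mixture
  CDF at 0.05 by Brent root-finding (tolerance 10⁻⁸). Tests verify EB05
  against 10⁷ posterior draws to < 0.01.

**Conjunction rule.** A pair is a significant signal only if all four
criteria hold: a ≥ 3 with ROR CI lower bound > 1; a ≥ 3, PRR ≥ 2 and
χ² ≥ 4; IC025 > 0; EB05 > 2. All thresholds are configuration, not
constants, and the MGPS criterion can be switched to EBGM > 2 — both
variants circulate in the literature. The conjunction is deliberately
conservative: under the null its false-flag rate is far below any single
algorithm's nominal level (measured 0 of ~1,800 tested pairs across 200
null universes), at the cost of sensitivity for weak signals.

Shrinkage behaviour worth knowing: for elevated tables the estimates are
bounded above by the raw ratio (IC ≤ log₂(a/E), EBGM ≤ a/E), but for small
counts they can shrink *past* the null point — a table with a/E > 1 but
a < ~10 can have IC < 0 or EBGM < 1, because the prior carries mass below 1.
This is correct behaviour, not a defect.

## Logistic risk-factor comparison

The outcome per report is carrying at least one PT that is a significant
signal for the report's own cohort. Covariates are sex, age band, weight
band and treatment group as categorical factors with references female,
<18 years, <50 kg and the combination group. Fitting is standard maximum
likelihood (statsmodels GLM/Binomial); this module's own content is the
design construction, the univariate p < 0.05 gate for inclusion in the
multivariate model (the gate threshold is a choice; "meaningful" univariate
results have no canonical definition), and reporting. Complete-case handling
is the default, with a missing-as-level flag, since spontaneous reports are
heavily incomplete and silently imputing them would be worse than either
documented option. Complete separation (e.g. an empty band) is flagged and
the CI reported as unbounded rather than trusting a huge Wald SE.
Between-group comparisons pool the two cohorts with a group indicator.

## Time-to-onset

Onset = event date − earliest therapy start date of the target drug, day
precision required on both ends; negative onsets are excluded and counted.
There is **no censoring model**: a spontaneous report exists only because
the event occurred, so every record is an event. This is an interpretive
limitation — the onset distribution describes *reported* events, not the
at-risk experience of a treated population — and cumulative incidence here
is simply the empirical CDF of onset times.

* **Weibull shape-parameter (WSP) classification.** Maximum-likelihood
  shape/scale via the 1-D profile score equation (Brent), with a 95% CI for
  the shape from observed information on the log-shape scale. CI entirely
  below 1 → "early failure" (decreasing hazard); containing 1 → "random"
  (constant hazard); above 1 → "wear-out" (increasing hazard). The normal
  log-scale CI was chosen over profile likelihood for speed; tests confirm
  agreement within 5% at n = 200. Classification is refused below n = 10
  (configurable): with fewer onsets the interval almost always straddles 1
  and the label would be noise. One terminology caveat: "random failure"
  is sometimes described in the applied literature as compatible with an
  increasing hazard; under the Weibull model it means a constant hazard,
  and this implementation follows the model.
* **Rank-sum comparison.** Two-sided Wilcoxon rank-sum with midranks and
  tie-corrected variance, continuity-corrected normal approximation; exact
  enumeration of all assignments when both samples have ≤ 8 observations.
  The approximation is within 0.02 of the exhaustive p for every 6+6
  partition of distinct ranks.
* **Log-rank test** (lifelines) on the all-events-observed samples, verified
  against a hand-tallied risk-set computation and calibrated to a type-I
  error of 0.03–0.07 at α = 0.05 over 1,000 null simulations.
* Quartiles use the linear-interpolation convention (numpy default); the
  convention is switchable because published medians/IQRs rarely state
  theirs. Onset histograms use 0–1 y / 1–5 y / > 5 y bands.

## Synthetic-data generator

The generator emits the exact `$`-delimited FAERS dialect the reader
consumes, with ground truth recorded for every stage: distinct case count,
per-report group, per-(group, PT) counts, tumor flags and onset parameters.
Bit-reproducible per seed.

Defaults define the emulated study conditions:

* demographic mixes (sex, age bands, weight bands, indications, reporters,
  outcomes, including missingness rates) mirror the published combination-
  cohort margins of a large FAERS infliximab/azathioprine extraction, so
  synthetic descriptive tables resemble real ones;
* group mix 0.30 / 0.10 / 0.15 / 0.45 (A-only / B-only / combination /
  background) — monotherapy-heavy, as in real data, while keeping every
  cohort large enough to test at n = 10⁴;
* 20 tumor PTs at a baseline reporting probability of 0.0064 each (≈ 12%
  of reports carry some tumor term); planted signals multiply one (group,
  PT) baseline by a relative reporting rate λ;
* onset lags are Weibull: shape 1.0, scale 900 days for the monotherapy and
  background groups (constant hazard) and shape 0.7 for the combination
  group (decreasing hazard) — the two failure-type profiles the WSP test
  must distinguish;
* 10% duplicate case versions, emitted as an earlier version with one
  perturbed field, exercising the latest-version dedup rule; 25% of therapy
  and event dates independently missing.

The generator does **not** model reporting biases of real spontaneous data:
no Weber effect or stimulated-reporting waves over calendar time, no
drug-specific demographic confounding, no masking by co-reported events,
no free-text misspellings beyond salt/dose tokens, and independence of PTs
within a report. Passing tests therefore establish that the statistics,
rules and plumbing are implemented correctly and calibrated under clean
conditions — not that any particular real-world extraction's signal list is
correct.

## Test problem sizes

The test and acceptance workloads use: 1,000 random tables for the
closed-form oracle sweep; 20 fixture tables × 10⁶ (IC) and 10⁷ (EB05)
posterior draws; 5,000 pairs for mixture-prior recovery; 200 universes of
10⁴ reports for null calibration; 50 disk-round-trip universes of 10⁴
reports for planted-signal recovery (λ = 10); 200 seeds at n = 604 and
n = 112 for WSP classification; all 924 partitions for rank-sum exactness;
1,000 simulations for log-rank calibration; n = 2×10⁴ for logistic
recovery. These sizes give the stated statistical tolerances comfortable
margins while keeping the whole suite at a few minutes on one CPU.
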