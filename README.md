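# faersig

Combination-versus-monotherapy safety-signal mining for FAERS-style
spontaneous adverse-event reports.

`faersig` is a tested, reusable implementation of the pharmacovigilance
workflow used to compare tumor-related adverse-event reporting between a
biologic (drug A, e.g. infliximab), an immunosuppressant (drug B, e.g.
azathioprine) and their combination:

1. **Ingestion & deduplication** — reads `$`-delimited quarterly FAERS ASCII
   tables (DEMO/DRUG/REAC/OUTC/THER/INDI/RPSR), converts age/weight units,
   and keeps one report per case (latest case version, ties broken by
   receipt date and file order).
2. **Cohorting** — assigns each report to *A-only* (A as primary suspect, no
   B in any role), *B-only* (symmetric), *combination* (one as primary
   suspect with the other in any role) or *excluded*, and restricts events
   to a tumor preferred-term lexicon.
3. **Disproportionality analysis** — per (cohort, preferred term) 2×2 table
   against all other reports, four algorithms are computed:

   | algorithm | statistic | signal criterion |
   |---|---|---|
   | ROR | reporting odds ratio `ad/bc`, Woolf 95% CI | a ≥ 3 and CI lower bound > 1 |
   | PRR | `[a/(a+b)] / [c/(c+d)]`, Pearson χ² | a ≥ 3, PRR ≥ 2, χ² ≥ 4 |
   | BCPNN | information component IC = shrunk log₂(observed/expected) | IC025 > 0 |
   | MGPS | empirical-Bayes geometric mean under a two-component gamma-Poisson mixture prior | EB05 > 2 |

   A pair is a **significant signal** only when all four criteria hold
   simultaneously (conjunction rule). Thresholds are configurable.
4. **Risk-factor regression** — univariate logistic fits for sex / age band /
   weight band / treatment group with a p < 0.05 gate into a multivariate
   fit; forest-plot-ready odds-ratio tables.
5. **Time-to-onset analysis** — onset = event date − therapy start date;
   Weibull shape-parameter (WSP) failure-type classification (shape CI < 1
   "early failure", contains 1 "random", > 1 "wear-out"), Wilcoxon rank-sum
   comparison (exact enumeration for small samples), and cumulative
   incidence with the log-rank test.

A bundled synthetic spontaneous-report generator emulates the FAERS file
dialect with known ground truth (planted relative reporting rates, per-group
Weibull onset lags, duplicate case versions, demographic missingness), so
the whole pipeline is testable end to end without downloading anything.

## Worked example

Generate a synthetic quarter with a planted tenfold reporting-rate signal
in the combination cohort, then run the full analysis:

```bash
cat > synth.yaml <<'EOF'
n_reports: 5000
seed: 42
planted_signals:
  - [A_plus_B, Basal cell carcinoma, 10.0]
EOF
faersig synth --outdir demo/quarter --config synth.yaml --seed 42
faersig run-all --indir demo/quarter --outdir demo/out --seed 42
```

which prints:

```
wrote 7 tables for 5000 cases to demo/quarter
done: {'loaded_demo_rows': 5500, 'deduplicated_reports': 5000,
 'group_A_only': 1541, 'group_B_only': 482, 'group_A_plus_B': 771,
 'group_excluded': 2206, 'tumor_reports': 669, 'signals_A_only': 0,
 'tested_pts_A_only': 20, 'signals_B_only': 0, 'tested_pts_B_only': 19,
 'signals_A_plus_B': 1, 'tested_pts_A_plus_B': 20, 'onset_records': 33, ...}
```

Reading the funnel: 5,500 raw DEMO rows collapse to 5,000 distinct cases
(the 10% duplicate case versions are removed), the role-code rules split
them into the three analysis cohorts plus the background, and 669 reports
carry at least one tumor preferred term. Exactly one pair clears all four
algorithms — the planted one. From `demo/out/signals_A_plus_B.csv`:

```
                  pt  a      ror  ror_lo95       prr       chi2    ic025     eb05  significant
Basal cell carcinoma 53 11.07506  6.958767 10.382481 157.897883 1.466682 4.218798         True
```

53 combination reports carry the term against a background expectation
roughly ten times smaller; the ROR of 11.1 (95% CI lower bound 7.0), PRR of
10.4 with χ² = 158, IC025 of 1.47 bits and EB05 of 4.2 all clear their
thresholds, so the conjunction flag is set. The other 19 tested terms, whose
reporting rate is the background rate, are all left unflagged.
`demo/out/weibull_summary.csv` then characterizes onset timing among the 33
signal reports with day-precision dates (median 534 days; fitted shape 0.88
with CI [0.66, 1.16] — "random", since 33 onsets cannot resolve the
generator's shape of 0.7 from 1). `demo/out/` also contains
`clinical_characteristics.csv`, `regression_*.csv`, `onsets.csv`,
`onset_comparisons.csv` and a `manifest.json` with input hashes and stage
counts.

The same pipeline is available as a library:

```python
from faersig import (read_quarter, deduplicate, assign_groups, load_lexicon,
                     load_synonyms, build_tables, fit_gps_prior, evaluate_signals)

lexicon = load_lexicon()                      # or load_lexicon("my_terms.csv")
syn = load_synonyms()
quarter = read_quarter({"demo": "DEMO24Q2.txt", "drug": "DRUG24Q2.txt",
                        "reac": "REAC24Q2.txt"})
reports = deduplicate([quarter], soc_map=lexicon.entries)
assignments = assign_groups(reports, syn["infliximab"], syn["azathioprine"])
tables = build_tables(reports, assignments, lexicon, "A_plus_B")
prior = fit_gps_prior(tables)
signals = evaluate_signals(tables, prior, lexicon)
print(signals[signals.significant])
```

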