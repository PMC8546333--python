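# pvdispro

Disproportionality signal mining for FAERS-style spontaneous
adverse-event reports.

Spontaneous reporting systems such as the FDA Adverse Event Reporting
System (FAERS) collect voluntary reports of suspected adverse drug
events. Because there is no denominator of drug use, safety signals are
screened by *disproportionality analysis*: for a drug of interest and an
event of interest, every deduplicated report in the database is placed
in a 2×2 table

|                        | drug of interest | all other drugs |
|------------------------|------------------|-----------------|
| event of interest      | a                | b               |
| all other events       | c                | d               |

and reporting of the event among the drug's reports is compared with
the background of all other reports. `pvdispro` implements the four
classical statistics with their conventional signal criteria
(N = a, the case count):

| algorithm | statistic | signal criterion |
|-----------|-----------|------------------|
| ROR   | `ROR = ad/(bc)`, `95% CI = exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d))` | CI lower bound > 1, N ≥ 2 |
| PRR   | `PRR = [a/(a+c)] / [b/(b+d)]`, Pearson `χ² = Σ (O−E)²/E` over the four cells | PRR ≥ 2, χ² ≥ 4, N ≥ 3 |
| BCPNN | `IC = log2[a·n / ((a+b)(a+c))]`, `IC025 = IC − (1.96/ln 2)·√(1/a+1/b+1/c+1/d)` | IC025 > 0 |
| MGPS (simplified) | `EBGM = a·n / ((a+b)(a+c))`, `EBGM05 = exp(ln EBGM − 1.64·√(…))` | EBGM05 > 2, N > 0 |

In these simplified forms IC = log2(EBGM) identically; the EBGM here is
the raw observed/expected ratio, *not* the shrunken estimate of a full
gamma-Poisson mixture fit, and will exceed true MGPS values at small
counts (see `docs/methods.md`).

The package covers the whole workflow:

* **`pvdispro.io`** — read/write FAERS-dialect `$`-delimited quarterly
  tables (DEMO/DRUG/REAC/OUTC/THER/INDI), both the current
  `primaryid/caseid` and the legacy `ISR/CASE` header dialects,
  normalised into one schema.
* **`pvdispro.cases`** — case-version deduplication (latest receipt
  date per case identifier), drug-name normalisation and dictionary
  matching restricted to suspect roles (PS/SS), indication filtering,
  event-term flagging, mutually exclusive outcome classification
  (death > disability > other-serious > none), demographics
  (age-unit conversion, age bands, country → continent).
* **`pvdispro.stats`** — contingency tables, the four statistics,
  configurable criteria, batch screening.
* **`pvdispro.reporting`** — characteristics summary, per-drug yearly
  trend grids, outcome-class proportions, and a one-call pipeline
  driver writing TSVs plus a run manifest.
* **`pvdispro.synthetic`** — a generator of synthetic reporting
  systems with configurable margins, injected drug–event association
  strength, duplicate report versions and missingness, with closed-form
  expected 2×2 cells (`ground_truth`), so the whole pipeline is
  testable without any data download.

## Worked example

```python
import pvdispro as pv

cfg = pv.default_config(n_reports=20_000, seed=7)   # injected RR = 3 for
bundle = pv.generate_bundle(cfg)                    # adalimumab x cardiac failure
case_def = pv.default_case_definition()             # 4 biologics, 6 cardiac PTs
cases = pv.assemble_cases(bundle, case_def, keep="all")
signals = pv.screen_all_pairs(cases, sorted(case_def.drug_dictionary))
print(signals.round(3))
```

prints (abridged):

```
    drug_id   n   ror  ror_ci_low  ror_ci_high   prr    chi2     ic  ic025  ebgm  ebgm05
  abatacept  23 0.769       0.505        1.172 0.776   1.501 -0.353 -0.961 0.783   0.550
 adalimumab 193 2.434       2.057        2.879 2.321 114.160  0.999  0.756 1.998   1.736
 etanercept  74 0.939       0.735        1.198 0.941   0.259 -0.079 -0.431 0.946   0.772
tocilizumab  20 0.885       0.563        1.391 0.889   0.281 -0.165 -0.817 0.892   0.611
```

Adalimumab — the drug carrying the injected association — is flagged by
the ROR (CI lower bound 2.06 > 1), PRR (2.32 ≥ 2, χ² 114 ≥ 4) and BCPNN
(IC025 0.76 > 0) criteria; the three null drugs are flagged by none.
The point estimate 2.43 is *attenuated* relative to the injected ratio
because the default case definition aggregates three preferred terms
while the ratio was injected into one ("Cardiac failure"); screening
against that single term alone recovers the closed-form population ROR
3.18 (`pv.ground_truth(cfg)` prints the expected cells and population
value per pair).

The same run from a shell:

```bash
pv-dispro simulate --n 20000 --seed 7 --out q1
pv-dispro run --bundle q1 --out out/     # signals.tsv, summary.tsv, trends.tsv,
                                         # outcomes.tsv, manifest.json
```

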