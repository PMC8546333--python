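# Methods

## The case/non-case model

`pvdispro` screens drug–event pairs in a spontaneous reporting system
by the case/non-case method. After deduplication, each report is one
observation; *cases* are reports carrying the event of interest,
*non-cases* are all other reports, and exposure is the presence of the
drug of interest among the report's suspect drugs (primary or secondary
suspect; concomitant and interacting records never qualify). The 2×2
cells a/b/c/d are counted against the full background of the database,
never against a restricted subset, so the b and d columns genuinely
represent "all other drugs".

A flagged pair is a *signal of disproportionate reporting* — a
hypothesis that the pair is reported more often than the background
predicts. It is not an incidence estimate and not evidence of
causation: reporting rates confound exposure prevalence, notoriety,
reporting culture and time on market.

## Statistics and numerical conventions

All four statistics are deterministic functions of the four cells.

* **ROR** `ad/(bc)` with the Woolf log-scale variance
  `1/a+1/b+1/c+1/d`; two-sided 95% CI.
* **PRR** `[a/(a+c)]/[b/(b+d)]`; the accompanying χ² is the plain
  four-cell Pearson statistic with expectations from the margins. No
  Yates correction by default (a `yates=` flag exists); with the large
  d cell typical of these tables the correction is immaterial, and the
  plain form is what the criterion χ² ≥ 4 was calibrated against.
* **BCPNN IC** `log2[a·n/((a+b)(a+c))]`, the information component of
  the observed-to-expected reporting ratio. The default lower bound is
  a normal approximation *on the log2 scale*:
  `IC025 = IC − (1.96/ln 2)·√(1/a+1/b+1/c+1/d)`. A `mode="multiplicative"`
  variant computes the multiplicative form
  `IC·exp(−1.96·√(…))`, which is only meaningful for IC > 0 (it returns
  NaN otherwise); it is retained because some published tables use it.
  Neither is the full Bayesian credibility interval of the original
  BCPNN; at the cell sizes where signals are declared the normal
  approximation is standard practice.
* **Simplified EBGM** `a·n/((a+b)(a+c))` — identical to 2^IC — with the
  one-sided bound `exp(ln EBGM − 1.64·√(1/a+1/b+1/c+1/d))`.

**This EBGM is not MGPS.** A true multi-item gamma-Poisson shrinker
fits a two-component gamma mixture over all pairs by empirical Bayes
and shrinks small-count observed/expected ratios toward 1. The
simplified form here applies no shrinkage: for small a it is biased
upward relative to a real MGPS run, and its normal-approximation bound
is not a posterior quantile. Interpret small-count EBGM/EBGM05 values
accordingly. Implementing the full DuMouchel fit is out of scope by
design.

**Zero cells.** A zero cell makes ROR/IC/EBGM undefined; they are
returned as NaN and a NaN statistic never satisfies a signal criterion.
An optional Haldane–Anscombe correction (`correction="haldane"`) adds
0.5 to all four cells of a table that has a zero cell, leaving
non-degenerate tables untouched. It is off by default so the default
output reflects the data as observed.

**Criteria boundaries** follow the conventional printed forms exactly:
strict `>` for the ROR CI bound, IC025 and EBGM05 thresholds; inclusive
`≥` for PRR ≥ 2, χ² ≥ 4 and the minimum case counts (N ≥ 2 for ROR,
N ≥ 3 for PRR).

## Case pipeline conventions

* **Deduplication** keeps, per case identifier, the version with the
  latest receipt date. Ties are broken by the greatest report
  identifier (numerically when the identifiers are numeric), since
  report identifiers increase with resubmission. Partial dates
  (year or year-month) are accepted and compared at their available
  precision with missing components treated as earliest; they are never
  interpolated.
* **Drug matching** normalises verbatim names (case-fold, punctuation
  strip, whitespace collapse, trailing dose/formulation tokens
  removed) and requires exact equality with a dictionary synonym by
  default. A substring mode exists for sensitivity analysis. A synonym
  claimed by two drug identifiers is a configuration error, not a
  silent choice.
* **Event matching** is exact term-level equality after normalisation:
  preferred-term vocabularies are controlled, and substring matching
  over-captures ("cardiac failure" would swallow "cardiac failure
  congestive", a different term). A substring mode is available
  explicitly.
* **Indication filtering** is applied per drug *record* (report +
  drug sequence), not per report: the qualifying indication must be
  attached to the matched drug record itself. An empty indication list
  disables the filter.
* **Outcome classes** are mutually exclusive, most serious first:
  death (DE) ≻ disability (DS or congenital anomaly CA) ≻
  other-serious (LT, HO, RI, OT) ≻ none, so each report is counted
  once. The descriptive summary *also* reports raw per-code counts,
  labelled non-exclusive, because a report can carry several codes.
* **Demographics.** Ages convert to years by unit (decade ×10, year ×1,
  month ÷12, week ÷52.1429, day ÷365.25, hour ÷8766) and are banded as
  <18, 18–44, 45–64, 65–74, 75–84, ≥85 (the last band is labelled
  ">85" as conventionally printed). Countries map to six continents via
  a bundled ~220-entry table (ISO codes and English names); unmapped
  strings become "unknown". Trend years use the receipt date, which is
  never missing after deduplication.
* **Percentages** in summary tables are round-half-up to 2 decimals,
  computed in decimal arithmetic (53.835 → 53.84). One convention is
  applied everywhere.

## The synthetic reporting system

The generator emulates the structural features the pipeline depends
on: one demographic record per report version, duplicate versions
sharing a case identifier with later receipt dates and larger report
identifiers, multiple drug records with role codes, multiple reaction
terms, independent outcome codes, configurable demographic margins and
missingness.

Association is **multiplicative on the event probability**: a report
carrying drug D has event probability `min(1, p_bg·RR)`. This is the
simplest mechanism with a closed-form population reporting odds ratio,
`ROR = RR(1−p_bg)/(1−RR·p_bg)`, slightly above RR for rare events. Its
corollary: the population observed/expected ratio (EBGM) is *diluted*
to `RR/(1+(RR−1)·p_drug)` because exposed reports raise the marginal
event rate. These two facts pull the design of a recovery experiment in
opposite directions — a small background rate keeps ROR near RR but
inflates variance; a small drug prevalence keeps EBGM near RR but
inflates variance too.

The default injected-association scenario (`default_config`) uses
drug prevalence 0.12 and background event rate 0.028 for the injected
pair. These were fixed once by a closed-form power analysis (normal
approximation on the log-odds scale) that maximises the smaller of the
two margins: population ROR 3.183 inside a [2.5, 3.5] recovery band,
and population EBGM 2.42 with its lower bound above the signal
threshold 2, at n = 50,000 reports. Both margins are then roughly 1.7–2
standard errors, so a recovery experiment at that size is expected to
succeed for the large majority of seeds but is intrinsically
stochastic; individual replicates can land just outside the band. The
experiment sizes used by the validation suite — 2,000 null pairs in
20,000-report bundles for calibration, 20 replicates of 50,000 reports
for recovery — were chosen as the smallest sizes at which these margins
are meaningful.

What the generator does **not** emulate: drug co-prescription
structure, time-varying reporting rates, masking/competition between
signals, event-term misspelling, cross-case duplicates (the same
patient reported under two case identifiers). Passing tests therefore
demonstrate the pipeline's arithmetic and contracts, not robustness to
those real-data pathologies.

The null-calibration contract deserves one caveat: with rare events the
2×2 cells are small (a ≈ 20–30), and the log-normal CI is an
approximation, so the realized flag rate of the nominally one-sided
2.5% ROR criterion varies around 2.5–3.5% across seeds; the contract
bound is 4%.

## File-format conventions

Quarterly tables are `$`-delimited with one header row. Literal `$`
and backslash characters in values are backslash-escaped on write and
unescaped on read, so round-trips are exact even for adversarial drug
names (public FAERS extracts do not quote fields; the escape is this
package's own convention, applied only when needed). Files with
`ISR`/`CASE` headers are treated as the legacy dialect and mapped onto
the same internal schema; unknown columns are preserved as opaque
extras. Input is decoded as UTF-8 with undecodable bytes replaced and
logged. Malformed rows are counted and logged; exceeding a configurable
tolerance (default 5%) is a parse error naming the file.

## Known limitations

* No stratified (age/sex/year) or regression-adjusted
  disproportionality; estimates are crude.
* No multiple-testing control across screened pairs — flags are
  hypothesis generators, and screening many pairs at the ~2.5% nominal
  rate will produce false positives in proportion.
* No probabilistic duplicate detection across distinct case
  identifiers.
* The simplified EBGM caveat above.
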