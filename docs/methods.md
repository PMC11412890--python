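# Methods

`pvsignal` implements disproportionality-based signal detection for
spontaneous adverse-event report databases of the FAERS type. This note
records the statistical models, the defaults and why they were chosen, the
numerical decisions, and what the synthetic-data tests do and do not
demonstrate.

## Data model and cleaning

A quarterly extract consists of five `$`-delimited tables (DEMO, DRUG,
REAC, INDI, OUTC) keyed by a report-version identifier (`primaryid`;
legacy `ISR` accepted). A *case* (`caseid`) may appear as several report
versions, so ingestion keeps, per case, the version with the latest FDA
receipt date, breaking ties by the larger `primaryid` — the rule FDA's
packet documentation recommends. Case identifiers found in a
deleted-case file are removed entirely; such files only exist from 2019Q1
onward, so their absence is not an error. Deduplication is idempotent and
the audit counts (kept + dropped-duplicate + dropped-deleted = input) are
enforced by construction.

Cleaning normalises age to years from the `AGE_COD` unit (`YR`, `DEC`,
`MON`, `WK`, `DY`, `HR`); unknown units or results outside [0, 130] years
become missing with a warning, never an error. A report is *serious* when
any outcome code in {DE, LT, HO, DS, CA, RI} is present; `OT` alone makes
a non-serious report, reproducing the usual serious/non-serious
dichotomy. Reports with no reaction PT are excluded — they cannot
contribute to any contingency cell.

Target selection keeps reports with at least one primary-suspect (PS)
drug entry whose drug name **or** product active ingredient contains any
configured pattern, case-insensitively (default patterns
`rivaroxaban`/`xarelto`, covering both the substance and the brand
field). The matching entry's route and indications are attached to the
report. The background is every other cleaned report in the same period;
a report is never in both arms.

## Counting unit

All 2×2 cells count distinct (report, term) *combinations*, not reports:
a report naming three distinct PTs contributes three combinations, a PT
repeated within one report contributes once. This matches how published
FAERS analyses can report far more combinations than reports. At SOC
level each PT maps to exactly one SOC (a single-primary-SOC convention; a
PT missing from the user-supplied map is pooled under a reserved
`unmapped` bucket and logged). For a term *t* and target drug:

|            | term *t* | other terms |
|------------|----------|-------------|
| target drug| a        | b           |
| other drugs| c        | d           |

with a+b the target drug's total combinations and n = a+b+c+d.
Year/sex/age-band strata are disjoint and exhaustive over non-missing
values (missing values land in an audit bucket); indication strata select
reports whose PS-drug indications contain the PT and may overlap.
Indication subgroup analyses restrict *both* arms to reports carrying the
indication: the question asked is "is this event over-reported for the
drug among patients treated for this condition", which requires an
indication-matched background.

## The five statistics

* **ROR** = ad/bc, 95% CI = exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d)).
* **PRR** = [a/(a+b)]/[c/(c+d)], CI on the log scale with
  se = √(1/a − 1/(a+b) + 1/c − 1/(c+d)).
* **MHRA χ²** = n(|ad−bc| − n/2)²/((a+b)(c+d)(a+c)(b+d)), Yates-corrected
  by default (the MHRA convention; an uncorrected option exists because
  published analyses do not always say which they used). The continuity
  term is floored so the statistic is never negative.
* **BCPNN IC**: the information component log2[p11/(p1·p2)] with
  independent Beta posteriors for the joint and marginal reporting
  probabilities, hyperparameters α1 = β1 = γ11 = 1, α = β = 2, and γ
  chosen so the prior IC expectation is exactly zero. Two moment modes
  are provided. `approx` (default) is the conventional closed form —
  E(IC) as the log2 ratio of posterior means plus the matching
  first-order variance — which is what published IC and IC−2SD screening
  values follow, and which gives IC = 0 exactly on the all-zero table.
  `exact` evaluates E(IC) and V(IC) of the same posterior exactly via
  digamma/trigamma functions; it is the mode validated against a
  posterior-sampling oracle, because the conventional form carries an
  O(1/a) delta-method bias that no sampling check at realistic precision
  would accept. The two agree as counts grow. The screening bound is
  IC − 2·SD; ±1.96·SD bounds are also exported since printed "IC 95% CI"
  columns follow that convention.
* **MGPS EBGM**: DuMouchel's gamma-Poisson shrinker. The relative
  reporting rate λ = a/E with E = (a+b)(a+c)/n carries a two-component
  gamma mixture prior fitted across all (a, E) cells by marginal maximum
  likelihood (the marginal is a two-component negative-binomial mixture).
  Fitting uses an unconstrained log/logit reparameterisation, L-BFGS-B
  with box bounds (|log θ| ≤ 20) to keep the likelihood finite, and six
  starting points — DuMouchel's canonical start (0.2, 0.1, 2, 4, 1/3)
  first. Components are reported in ascending-shape order so fits are
  comparable. The posterior is again a two-gamma mixture;
  EBGM = 2^{E[log2 λ]} via digamma, and EB05/EB95 solve the mixture CDF
  by bisection to 1e-6 in λ. The prior is fitted unstratified by default.
  At least 50 cells are required; below that the MGPS column is omitted
  with a warning rather than fitted to noise.

Zero cells: ROR/PRR/χ² optionally apply the Haldane 0.5 correction to all
four cells (only when a zero cell exists; flag recorded per result); with
the correction off such statistics are returned undefined-flagged, never
raised. The Bayesian statistics need no correction.

The identity PRR = (a/M)(1 + ROR·(M−a)/a), with M = a+b, reconstructs
PRR from a published (count, total, ROR) triple independently of how the
background splits into c and d. It is used to check published ROR/PRR
pairs for internal consistency when the full database is unavailable.

## Signal criteria and overlap

ROR-positive: a ≥ 3 and ROR 95% lower bound > 1. PRR-positive: the same
rule on the PRR bound (CI-based rather than point-based, mirroring the
ROR rule). MHRA-positive: PRR > 2 and χ² > 4 and a > 3 — note the
deliberate ≥3 / >3 asymmetry between the ROR/PRR gate and the MHRA gate;
both conventions are kept verbatim as distinct defaults rather than
harmonised. BCPNN-positive: IC − 2SD > 0, with strength tiers − / + /
++ / +++ cut at 0, 1.5 and 3 (upper bounds inclusive). MGPS-positive:
EB05 > 2. Undefined statistics evaluate negative; terms with a = 0 are
excluded from decision tables entirely. IME flagging is case-insensitive
exact PT membership in a user-supplied list (the EMA important-medical-
events list is licensed content and therefore an input, not shipped).

Overlap summaries count every non-empty membership pattern over the five
algorithms (the UpSet input; patterns partition the union of positives)
plus per-algorithm totals, Venn counts and an IME split of the all-five
intersection.

## IC over time

Per-year mode rebuilds all four cells from a single year's reports, so a
sparse year (e.g. a partial final quarter) shows a wide interval;
cumulative mode uses all reports up to each year and therefore ends at
exactly the pooled analysis. Both are provided because published
time-trend figures are usually ambiguous between the two; per-year is the
default since wide final-period intervals only arise under it. Year is
assigned from the FDA receipt date.

## Synthetic data generator

The generator emulates a single-drug extract: one PS drug per report
drawn from a power-law marginal over 20 drugs (occasionally plus a
concomitant role-C entry), 1–2 indications, 1 + Poisson(1.3) reaction-PT
draws from a power-law marginal over 100 events (distinct PTs kept, so
mean combinations/report ≈ 2.3, matching the ratio seen in the real
extract), receipt years 2014–2024 with the published yearly report
shares, and demographics with the published distributions: sex
46.2/47.7/6.0 (F/M/missing), age ~ N(70, 14²) truncated with 20.8%
missing (reproducing median ≈ 72, IQR ≈ 61–80), consumer-majority
reporters, US-majority countries, 98.7% oral route, 86.2% serious with
the published outcome mix. Duplicate case versions are injected at a
configurable rate with strictly later receipt dates and perturbed
demographics but identical reactions, and the ground-truth keep set is
recorded so deduplication can be checked exactly.

A signal pair (drug, event, ρ) multiplies the event's sampling
probability by ρ for that drug's reports and renormalises.
`expected_tables` gives the exact expected cells: with K ~ 1+Poisson(μ)
draws, P(event with probability p appears) = 1 − (1−p)e^{−μp} by the
Poisson generating function, and renormalisation is applied before this
formula, so recovery tests compare against the true generative
expectation rather than a heuristic.

What passing synthetic tests show: the pipeline's counting, statistics
and criteria behave correctly under a known generative model, a ρ=5 pair
at n = 50,000 is reliably flagged by all five algorithms, and the null
false-positive rate of the ROR rule stays near nominal. What they do not
show: behaviour under real MedDRA vocabularies, real drug co-reporting
and duplication structure, reporting-rate secular trends, or any causal
property — a flagged pair is a statistical signal only.

## Problem sizes in the test suite

The validation suite uses n = 50,000 reports and 20 seeds for signal
recovery and null calibration, 50,000 cells for MGPS prior recovery,
100 random tables × 1e5 posterior draws for the BCPNN oracle and 100
tables for the MGPS quadrature oracle — sizes at which Monte-Carlo bands
are tight enough to be informative while the whole suite runs in a couple
of minutes on one CPU.

## Known limitations

* Exact BCPNN moments are exact for the *independent*-Beta posterior;
  the dependence between p11 and the margins induced by conditioning on
  the same table is ignored, as in the original formulation.
* The MGPS mixture likelihood is multimodal; multi-start L-BFGS-B is a
  practical, not certified, global optimiser (the fit records
  convergence diagnostics and the attained log-likelihood).
* Single-primary-SOC mapping discards MedDRA multi-axiality.
* No HLT/HLGT intermediate levels, no regression adjustment for
  confounding, no drug–drug interaction analysis.
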