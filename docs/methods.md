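# Methods

## Scope and model

`faerspv` implements post-marketing signal detection on spontaneous
adverse-event reports in the public FAERS quarterly dialect.  The core
object is the 2×2 contingency table for one drug–event pair,

|              | target event | other events |
|--------------|--------------|--------------|
| target drug  | a            | b            |
| other drugs  | c            | d            |

with `N = a+b+c+d`.  By default all counts are **unique (report, PT)
pairs**, not reports: a cohort of 1,770 reports listing 3,137 reactions
contributes 3,137 pairs to the target row.  A report-level counting mode
(`unit="reports"`) is available for sensitivity analysis; the choice
matters only when reports carry many reactions.

The background row (`c`, `d`) covers every deduplicated report without a
primary-suspect mention of the target drug.  Target-drug reports removed
by the reporter-occupation filter are excluded from *both* arms: leaving
them in the background would contaminate the comparator with the very
exposure under study.  At realistic database shares (the target drug is
a fraction of a percent of all reports) this choice is numerically
irrelevant; at desk-scale simulation shares it is what makes the
reporting odds ratio estimate the generator's relative risk.

## The four statistics

* **ROR** — `ad/bc` with the 95% Wald interval
  `exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d))`.
* **MHRA** — PRR `[a/(a+b)]/[c/(c+d)]` plus the Yates-corrected
  chi-square `N(|ad−bc|−N/2)²/[(a+b)(c+d)(a+c)(b+d)]`, continuity
  correction floored at zero.
* **BCPNN** — information component
  `IC = log2 p11/(p1.·p.1)` under independent beta posteriors with
  pseudo-counts `α1=β1=γ11=1`, `α=β=2` and the joint pseudo-count γ
  scaled so the prior IC expectation is near zero.  Because IC is a sum
  of independent log-beta variables, its posterior mean and variance are
  computed **exactly** via digamma/trigamma functions rather than by the
  truncated moment expansion sometimes quoted; the expansion misses the
  Monte-Carlo posterior quantile by up to ~0.6 bits at single-digit
  cells, while the exact moments stay within 0.05 bits for cells ≥ 5
  (verified by a sampling oracle in the test suite).  The signal bound is
  `IC025 = E(IC) − 2√V(IC)`.
* **MGPS** — gamma-Poisson shrinkage of `λ = a/E`, `E = (a+b)(a+c)/N`.
  `simplified` mode (the default, matching common FAERS-paper practice)
  reports the relative report rate `aN/((a+b)(a+c))` with a Wald-style
  5% lower bound.  `full_eb` mode is the principled empirical-Bayes
  implementation: the prior is DuMouchel's two-component gamma mixture,
  hyperparameters are fitted by maximum marginal likelihood jointly over
  all event rows (the marginal of each count is a negative-binomial
  mixture; Nelder-Mead followed by L-BFGS-B on log/logit-transformed
  parameters, three seeded starts, 1e-8 tolerance), and the posterior of
  λ is again a gamma mixture, giving `EBGM = exp E[ln λ]` in closed form
  (digamma) and `EBGM05` by root-finding on the mixture CDF.

**Zero cells.** Any zero cell triggers the Haldane–Anscombe +0.5
correction on all four cells for ratio estimates, and the result is
flagged `corrected`; the MHRA chi-square always uses the raw counts.

**Combined criterion.** A pair is a signal when `a ≥ 3` and all four
thresholds hold simultaneously: ROR 95% lower bound > 1; PRR ≥ 2 with
χ² ≥ 4; IC025 > 0; EBGM05 > 2.  Events below the minimum case count are
excluded from output entirely.  All thresholds are configurable.

## Ingestion and cleaning

Quarterly "$"-delimited tables are parsed with case-insensitive,
alias-mapped column names; rows with the wrong field count or blank
mandatory fields are skipped and tallied; child-table rows whose
`primaryid` is unknown to DEMO are counted and dropped.  Deduplication
keeps, per case id, the version with the latest FDA receipt date,
breaking ties by the larger `primaryid`; partial dates are padded to
their earliest covered day for comparison only.

Ages are converted to years from the FAERS unit code (DEC×10, YR×1,
MON÷12, WK÷52.14, DY÷365.25, HR÷8766).  Implausible ages (outside
[0, 120]) are **nulled and the record retained** by default — dropping
whole reports would distort event counts while the characteristic tables
show a large explicit "missing age" class — with `age_rule=
"drop_record"` available for the stricter reading.  The
healthcare-professional filter keeps occupation codes {MD, PH, RN, OT};
blank occupations are dropped, since the filter's purpose is provenance.
Summary percentages use decimal half-up rounding to one decimal, and the
outcome classes are made mutually exclusive with precedence
Death > Life-threatening > Hospitalization > Other serious events.

## Time-to-onset

Onset is `EVENT_DT − START_DT` in calendar days, per report, using the
earliest fully-specified start date among the matched suspect-drug
therapy rows.  Records with missing or partial dates, or negative
intervals, are excluded and tallied by reason; day-0 events are retained.
Quartiles use linear interpolation (the inclusive spreadsheet
convention — the method is configurable and echoed in the summary
metadata), and proportions are reported over the fixed bins 0–30, 31–60,
61–90, 91–180, >180 days, closed on both ends as labelled.

## Between-drug comparison

Clinically related PTs are pooled into named groups (defaults: every
"injection site…" PT; conjunctivitis + allergic conjunctivitis;
keratitis).  The numerator sums unique matching (report, PT) pairs and
the denominator is the cohort report count — this is the convention
under which the published grouped percentages (e.g. 276/1,770 = 15.6%)
reproduce exactly; a report-based numerator is also emitted.  The two
proportions are compared by Pearson chi-square with the Yates correction
when any expected cell is below 5; degenerate margins return p = 1,
flagged.

## Synthetic data generator

The generator emits full quarterly table sets with known ground truth.
Each case draws a reporting quarter, arm (target drug with probability
`target_drug_share`), reporter occupation, demographics, one
primary-suspect drug row (name/brand casing randomized to exercise
substring matching, plus occasional concomitant rows including the
target drug in a non-suspect role), therapy start and event dates, an
outcome code and an indication.  Event PTs are drawn per report —
`max(1, Poisson(events_per_report))` draws with selection weight
`background_prob · RR(arm)` — so the pair-level reporting odds ratio of
a spiked PT converges to its configured relative risk.  Duplicate case
versions, missing/implausible ages, partial dates and negative onsets
are injected at configurable rates.  One PRNG stream per table is
derived from the master seed, so adding a table never perturbs another
table's draws, and equal seeds give byte-identical files.

Defaults are chosen to emulate the structure of the tralokinumab report
cohort: sex split 37.1/62.4/0.5, ~18% missing age, 93% US, outcome mix
≈ 4% hospitalization / 1.1% death, indication two-thirds atopic
dermatitis, onset log-normal with `μ = ln 37`, `σ = 1.6` (median 37
days, quartiles ≈ 13 and 111).  `target_drug_share` defaults to 0.05:
real databases put the target drug well below 1% of reports, but at desk
scale that would starve every statistic; 5% keeps the target arm a small
fraction of all pairs (so PRR and the relative report rate still
approximate the ROR) while leaving hundreds of cohort reports at the
default `n_cases = 5000`.

What the generator does **not** model: reporting waves and stimulated
reporting, signal masking/competition between drugs, correlated events
within a report, secular trends, real MedDRA coding noise.  Passing
recovery tests therefore show the pipeline's rules and estimators are
implemented correctly under the stated sampling model — not that the
statistics are unbiased on real spontaneous-report data, which carries
all of the biases above.

## Validation design

Every statistic is checked against an independent direct-formula oracle
on 1,000 random tables to 1e-12; the BCPNN bound against a 10⁶-draw
posterior-sampling oracle (0.1-bit tolerance, cells ≥ 5); full-EB MGPS
against numeric posterior integration (1e-6) plus shrinkage-bound and
large-count-limit properties; the chi-square routes against
`scipy.stats.chi2_contingency`.  End-to-end: a PT spiked at RR = 8 must
be covered by the 95% ROR interval in ≥ 90 of 100 replicates at
n = 50,000 cases; all-RR-1 data must flag ≤ 2% of events on the combined
criterion; deduplication recall against ground truth is exactly 1.0;
the onset median is recovered within 5% at n = 10,000; the comparison
test's null rejection rate stays ≤ 6% at α = 0.05 over 10,000 pairs.
Simulation sizes (100×50,000; 20×5,000; 10,000 draws) are the package's
validation conditions and are reproduced by `scripts/acceptance.py`.

## Known limitations

* The PT→SOC map shipped as a fixture covers only the packaged PTs plus
  the generator catalog; real analyses must supply a licensed MedDRA map.
* No stratified (age/sex/year) MGPS and no multi-item shrinkage; no
  masking-bias adjustment; no RxNorm/ATC name normalization (matching is
  case-insensitive substring only).
* Published IC025 columns from FAERS papers are frequently not
  reproducible from any single closed form; this package's IC025 is the
  exact-moment bound documented above, validated against sampling, and
  is not expected to match every printed table digit-for-digit.
* Onset is computed per report (FAERS carries one event date per
  report), not per reaction.
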