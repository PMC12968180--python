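# faerspv

Disproportionality signal detection, time-to-onset analysis and
between-drug comparison for FAERS-style spontaneous adverse-event
reports — built around the tralokinumab (anti-IL-13, atopic dermatitis)
safety analysis, and reusable for any drug cohort in the public FAERS
quarterly ASCII dialect.

Pharmacovigilance teams mine spontaneous-report databases for drug–event
pairs reported more often than independence would predict.  For a 2×2
table (a = target drug ∧ event, b = target drug ∧ other events, c/d the
same for all other drugs) the package computes the four standard
statistics and their combined signal criterion:

* **ROR** = ad/bc, signal when the 95% lower bound exceeds 1;
* **PRR** = [a/(a+b)]/[c/(c+d)] with Yates χ² (MHRA criterion: PRR ≥ 2,
  χ² ≥ 4);
* **IC** = log₂ of observed over expected joint reporting probability
  under a Bayesian beta model (BCPNN), signal when IC025 > 0;
* **EBGM**, the gamma-Poisson–shrunken relative report rate (MGPS),
  signal when EBGM05 > 2 — both a simplified mode and a full
  empirical-Bayes fit are provided.

A pair with at least 3 cases flagged by all four algorithms
simultaneously is a combined signal.  Around that core the package
ships: a FAERS quarterly reader with case deduplication (latest FDA_DT,
ties to the larger PRIMARYID) and demographic cleaning; PS-role drug
cohort selection and a healthcare-professional reporter filter; MedDRA
PT→SOC rollup; time-to-onset summaries; grouped-event chi-square
comparison between two drugs; and a synthetic report generator with
ground truth for end-to-end validation.  See `docs/methods.md` for the
full model description.

## Worked example

```python
from faerspv import io, signals, synth
from faerspv.pipeline import RunConfig, SynthSpec, run_pipeline

cfg = RunConfig(
    synth=SynthSpec(n_cases=20000, target_rr={"keratitis": 8.0}),
    seed=11, outdir="pv_out",
)
bundle = run_pipeline(cfg)
row = bundle.signals_pt.query("event.str.lower() == 'keratitis'").iloc[0]
print(f"a={row.a}  ROR={row.ror:.2f} ({row.ror_low:.2f}-{row.ror_high:.2f})  "
      f"PRR={row.prr:.2f} chi2={row.chi2:.1f}  IC025={row.ic025:.2f}  "
      f"EBGM05={row.ebgm05:.2f}  all_four={row.all_four}")
```

prints

```
a=41  ROR=6.50 (4.56-9.25)  PRR=6.36 chi2=138.1  IC025=1.69  EBGM05=3.58  all_four=True
```

Twenty thousand synthetic cases are generated with keratitis reported at
8× its background rate when the target drug is the primary suspect; the
pipeline deduplicates, filters to healthcare-professional reports,
builds (report, PT) pairs and recovers the spike: the ROR interval
covers the true relative risk of 8 and all four algorithms flag the
event, while unspiked PTs stay unflagged.  `pv_out/` receives the
characteristics summary, PT- and SOC-level signal tables, onset summary
and a JSON manifest with row counts for every stage.

The same machinery runs on real quarterly extracts via a YAML config
(`quarters:` maps quarter labels to per-table file paths) and the CLI:

```bash
pvrun synth --outdir data --seed 7 --n-cases 5000   # synthetic quarters
pvrun run --config cfg.yaml                         # full analysis
```

Packaged fixtures (`faerspv.tables`) reproduce the published
tralokinumab report tables: the characteristics summary over 1,770
reports (62.5% female, 93.2% US, 4.1% hospitalization), 49 PT-level and
25 SOC-level signal rows, and the grouped reporting proportions —
injection-site reactions 276/1,770 = 15.6%, conjunctivitis 42/1,770 =
2.4%, keratitis 4/1,770 = 0.2%.

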