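# pvsignal

Pharmacovigilance signal detection on FAERS-style spontaneous
adverse-event reports.

Post-marketing safety surveillance asks: among the events spontaneously
reported for a drug, which are reported *disproportionately* often
compared with the rest of the database? `pvsignal` implements the
standard answer end to end for FDA Adverse Event Reporting System
(FAERS) quarterly ASCII tables:

* **ingestion** of '$'-delimited DEMO/DRUG/REAC/THER tables, FDA-rule
  case deduplication (latest `fda_dt`, then highest `primaryid`), date
  windowing and primary-suspect drug filtering;
* **disproportionality analysis** of every MedDRA PT and SOC on 2×2
  report–reaction-pair tables with four algorithms —
  ROR = ad/bc with lognormal CI, PRR with Pearson χ²,
  EBGM = aN/[(a+b)(a+c)] with its one-sided EBGM05 bound, and the
  BCPNN information component IC = log₂ EBGM with IC025 — and
  classification of each event by how many algorithms concur (0–4);
* **Weibull time-to-onset modelling**: exact MLE of
  f(t) = (β/α)(t/α)^{β−1}e^{−(t/α)^β} on days from therapy start to
  event, observed-information CIs, and the early / random / wear-out
  hazard call from the shape CI's position relative to 1;
* a **synthetic FAERS generator** with planted signals, injected
  duplicate report versions, configurable missingness and
  Weibull-distributed onset dates, so the whole pipeline is testable
  with known ground truth and no licensed data.

The package was built around the published FAERS analysis of Tyrvaya
(varenicline nasal spray, dry-eye disease): its printed descriptive,
signal and onset tables serve as fixed reference inputs in the test
suite, and the synthetic defaults mirror that reporting profile.
See `docs/methods.md` for models, assumptions and limitations.

## Worked example

Generate a synthetic database (2178 target reports vs 20000 background,
nasal/ocular signal profile planted, 5% duplicated cases), screen it,
and fit the onset model — either via the numbered scripts:

```sh
python analysis/01_simulate.py
python analysis/02_screen_signals.py
python analysis/03_tto_weibull.py
python analysis/04_report.py
```

which prints (seed 1):

```
pipeline counts: {'raw_demo_rows': 23287, 'dedup_cases': 22178,
 'windowed_cases': 22178, 'ps_cases': 2178, 'target_pairs': 4721,
 'total_pairs': 49840}
screened 42 PTs / 11 SOCs
9 PTs positive in all four algorithms: SNEEZING, NASAL DISCOMFORT,
 RHINORRHOEA, THROAT IRRITATION, EPISTAXIS, LACRIMATION INCREASED,
 RHINALGIA, NASAL DRYNESS, PRODUCT AFTER TASTE
n=125 onset times (excluded: 22 negative, 2031 missing)
mean 26.6 d, median 12 d (IQR 2-32); 72.8% within the first month
Weibull alpha=20.92 (16.12-27.16), beta=0.71 (0.62-0.81) -> early failure mode
2178 target cases; female 1622 (74.5%), consumer-reported 1842 (84.6%)
```

Reading this: deduplication removed exactly the 1109 injected duplicate
versions (23287 → 22178 unique cases); the planted nasal and ocular PTs
are the ones reaching 4-of-4 algorithm concordance while null PTs stay
quiet; and the onset fit recovers a shape well below 1 — a decreasing
hazard, i.e. adverse events concentrate right after treatment start.
Result tables land in `results/`, the generated database in `scratch/`.

The same is available as a CLI (`pvsignal simulate|run|signals|tto`)
driven by a YAML config, e.g.

```sh
pvsignal simulate --out scratch/db --seed 1
pvsignal signals --config cfg.yaml --level soc --paper-layout
```

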