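# sclc-ehr

Identification, validation and characterisation of incident **small cell
lung cancer (SCLC)** cases in primary-care electronic health record (EHR)
databases such as THIN or CPRD, where SCLC has no dedicated diagnostic
code and the deciding evidence sits in free-text comments.

The package is aimed at pharmacoepidemiologists building or auditing
EHR phenotyping algorithms: it provides the full multi-step case
ascertainment pipeline, a simulated chart-review validation layer, the
downstream incidence/mortality/survival estimators, and a synthetic-EHR
generator with gold-standard truth labels so that every stage is testable
without access to a real (access-restricted) database.

## The algorithm

Given an eligible cohort (age 18–89 at entry, registration status
permanent or died, ≥ 730 days enrolled, ≥ 730 days since first
prescription, an encounter in the preceding 730 days, no prior
lung-cancer code), case ascertainment proceeds in four steps:

1. **Index detection** — the first lung-cancer code during follow-up puts
   a patient in *group 1*, the first small-cell-cancer (SCC) code in
   *group 2* (SCC wins same-day ties).
2. **Cross-coding** — a complementary code within ±90 days of the index
   code confirms the case outright.
3. **Free-text search** — remaining patients are searched for text
   strings in the window [−30, +90] days around the index code:
   group 1 splits into `SCLC-text-only`, `non-text-only` (a negation
   token such as "non" immediately preceding the SCLC string, or
   "NSCLC"), `both`, or `no-text`; group 2 splits on a `lung cancer`
   string.
4. **Extrapolation** — confirmation rates measured by (simulated) manual
   review of small stratum samples are applied to the full stratum
   counts. With rates *r* per stratum the expected case count is

   N̂ = n_cross1 + ⌊r_sclc·n_sclc⌉ + ⌊r_both·n_both⌉ + n_cross2 + ⌊r_lung·n_lung⌉

   (each term rounded half away from zero); the ambiguous `both` term is
   reported but excluded from the final case count.

On top sit the epidemiological estimators: incidence per 10,000
person-years with log-normal CIs, positive predictive value with exact
Clopper–Pearson intervals, a baseline characterisation table
(latest-before-diagnosis lifestyle, ever-before comorbidities,
current-use medications), one-year all-cause mortality per 100
person-months, and a hand-implemented Kaplan–Meier product-limit
estimator with median survival.

## Worked example

The bundled engineered bundle reproduces the flowchart arithmetic at full
scale — 25,241 code-detected patients flowing through all four steps:

```python
from sclc_ehr import SCLCPhenotype, flowchart_bundle

rates = {"text_sclc_only": 1.0, "text_both": 0.05, "text_lung": 1.0}
res = SCLCPhenotype(flowchart_bundle()).fit(confirmation_rates=rates, seed=0)
print(res.summary())
```

```
SCLC case ascertainment summary
==============================================
Eligible cohort                       25,241
Person-years of follow-up            138,860
Group 1 (lung-cancer code)            24,508
Group 2 (SCC code)                       733
  cross-coded, group 1                   364
  cross-coded, group 2                   137
  'SCLC' text only                     2,000
  'non' text only                      4,166
  both 'SCLC' and 'non'                  353
  'lung cancer' text (group 2)           437
Expected SCLC cases (total)             2956
Expected SCLC cases (final)             2938
```

Reading the output: of 25,241 patients detected with a cancer code, 501
are cross-code confirmed; applying the stratum confirmation rates to the
text strata yields 2,956 expected SCLC cases (11.7% of detected), of
which 18 derive from the ambiguous both-strings stratum and are dropped
from the final count of 2,938. (The incidence line in this example
reflects the engineered bundle's own compressed person-time, not a
population rate.)

A fully synthetic population instead exercises every stage stochastically:

```python
from sclc_ehr import SCLCPhenotype, SimConfig, generate_bundle

bundle = generate_bundle(SimConfig(n_patients=60_000, seed=3))
res = SCLCPhenotype(bundle).fit(seed=3)   # oracle chart review of truth labels
res.summary()                              # incidence ≈ 1 per 10,000 py
res.save("out/")                           # tables, step counts, reports
```

The same pipeline is scriptable from the shell:

```bash
sclc-ehr simulate --n 20000 --seed 7 --out bundle/
sclc-ehr ascertain --bundle bundle/ --out run/ \
    --rates '{"text_sclc_only":1.0,"text_both":0.05,"text_lung":1.0}'
sclc-ehr report --config run_config.yaml
```

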