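# Methods

## Scope and design

`sclc-ehr` implements a code-plus-free-text phenotyping algorithm for
incident small cell lung cancer (SCLC) in UK-style primary-care EHR
databases, together with its validation machinery and the downstream
epidemiological estimators. The package is organised as a model/results
pair (`SCLCPhenotype.fit()` → `SCLCPhenotypeResults`) layered over six
functional modules: `synth` (data generation), `cohort` (eligibility and
person-time), `textmine` (negation-aware string search), `ascertain`
(the four-step algorithm), `validate` (review simulation and PPV) and
`epistats` (rates, baseline table, mortality, Kaplan–Meier). A `click`
CLI (`sclc-ehr`) and a config-driven `run_pipeline` wrap the same code.

## Conventions

- Dates are calendar dates; durations are whole days. One **year** is
  365 days and one **month** 30.4375 days (365.25/12) in all person-time
  conversions. "Two years" in eligibility rules is exactly 730 days.
- Follow-up is half-open `[start, end)`: an index code on the start date
  counts as an event during follow-up with zero person-time.
- Age is the whole-year difference from the birth date. The 18–89 band
  is an entry criterion only; follow-up is not truncated when a
  participant later turns 90.
- All closed windows are inclusive at both ends: cross-coding ±90 days,
  free-text search −30/+90 days, backdating look-back 90 days (the
  look-back length is a package choice; the backdating rule itself —
  earliest related symptom/procedure, never later than the recorded
  code — is fixed).

## Text matching

Matching is case-insensitive raw substring search, deliberately not a
general clinical NLP engine. Two refinements beyond plain substrings:

- **Left word boundary.** A pattern occurrence preceded immediately by an
  alphanumeric character is not a mention ("sclc" inside "nsclc",
  "small cell" inside "nonsmall"). Without this rule the abbreviation
  "NSCLC" would raise the positive SCLC flag, inverting its meaning.
- **Adjacent negation.** An SCLC pattern is negated when a negation
  prefix ("non") ends at most one space or hyphen before it and sits at
  its own word boundary. Dedicated negated tokens ("nsclc") raise the
  negated flag directly. Adjacency avoids over-negation in long
  comments; bidirectional NegEx-style scope is out of scope.

The matcher is verified against an independently written regular
expression oracle on a random fragment corpus.

## Extrapolation arithmetic

Expected cases = cross-coded (both groups, taken at face value) plus the
confirmation-rate-weighted text strata, each term rounded to the nearest
integer half away from zero before summation. Both the total (including
the ambiguous both-strings term) and the final count (excluding it) are
reported; incidence uses the final count, and the total-based rate is
also exposed (`incidence_total`) because the two differ only in the
ambiguous term.

## Statistical choices

- **Proportion CIs** (PPV, confirmation rates): exact Clopper–Pearson
  from the beta distribution, preferred over asymptotic intervals
  because reviewed strata are small (n = 18–25). Cross-checked against
  `statsmodels.proportion_confint(method="beta")` in the tests.
- **Rate CIs** (incidence, mortality): log-normal approximation
  `exp(log r ± 1.96/√events)`; a zero-event rate carries the exact
  Poisson upper bound `3.69/PT`. The log-normal choice reproduces
  printed one-year mortality intervals to ≤ 0.02 per 100 person-months
  at the published margins, which is how the method was selected among
  the (unstated) alternatives.
- **Kaplan–Meier** is implemented directly (product-limit over the
  risk-set enumeration; censored subjects at a death time remain at risk
  through that time). `lifelines` is used only as a cross-check oracle.
  Median survival is the first time S(t) ≤ 0.5 and is reported as
  undefined — not infinite — when never reached.
- **Mortality follow-up** runs 12 months (365.25 days, tracked at hour
  resolution so that an uncensored year is exactly 12.0 months) from the
  final (backdated) event date; cases whose record closes on or before
  the event date are excluded from the mortality analysis.
- Percentages print to 1 decimal place and rates to 2 in the summary
  tables.

## The synthetic-EHR generator

The generator emulates the structure of an anonymized primary-care
database: staggered registration, routine encounters every 6–18 months,
lifestyle/comorbidity coding, prescriptions with supply durations, and a
truth table recording each patient's true disease, onset and death.

Key default parameters (all configurable through `SimConfig`):

| parameter | default | meaning |
|---|---|---|
| `annual_sclc_hazard` | 1e-4 /person-year | true SCLC onset hazard (≈ 1 case per 10,000 person-years) |
| `nsclc_to_sclc_ratio` | 6.0 | competing NSCLC hazard multiplier |
| `p_code_lung_given_sclc` / `p_code_scc_given_sclc` | 0.80 / 0.20 | which index code a true SCLC case receives (≈ 80/20 group split) |
| `p_cross_code` | 0.16 | complementary code within ±90 days |
| `p_text_sclc`, `p_text_lung` | 0.95, 0.90 | SCLC / lung-cancer comment within [−30, +90] days |
| `p_text_non` | 0.60 | negated comment for NSCLC cases |
| `p_text_ambiguous` | 0.02 | NSCLC comment carrying both an SCLC and a "non" string |
| `p_symptom_before`, `symptom_lead_days_max` | 0.84, 90 | pre-diagnosis symptom coding (backdating signal) |
| `median_survival_months` | 7.4 | exponential survival after SCLC onset |
| `censor_dropout_rate` | 0.05 | cases whose record ends 30–365 days after diagnosis |

Onsets arise as competing exponentials on the clock that starts once a
patient has 730 days of registration inside the study window; comment
and cross-code offsets are capped at the record end (no documentation
after death). Free-text templates, including spelling variants and
ambiguous phrasings, live in the config, not the code.

What the generator does **not** emulate: realistic Read-code
dictionaries and hierarchies, practice-level clustering and data-quality
windows, clinically plausible comorbidity co-occurrence, misspellings in
free text, and age/sex gradients in cancer risk. Passing tests therefore
demonstrate correctness of the algorithmic machinery and calibration of
the estimators under the stated generative model — not performance on
real clinical text.

## The engineered worked example

`flowchart_bundle()` constructs a deterministic 25,241-patient bundle in
which every patient is trivially eligible and the four steps reproduce a
prescribed set of stratum counts exactly (group sizes 24,508/733,
cross-coded 364/137, text strata 2,000/4,166/353/437). It demonstrates
the extrapolation arithmetic at full scale — 2,956 expected cases, an
18-case ambiguous term, 2,938 final — and feeds the acceptance script.
Its person-time is compressed (all index codes on one date), so its
incidence is not meaningful; population-scale rates come from the
stochastic generator.

## Problem sizes used in the checks

The calibration properties are checked at desk scale: the incidence
parameter-recovery test pools 6 generator seeds of 60,000 patients each
(≈ 3.2 million person-years, ≈ 320 expected cases) and requires the
pipeline estimate to lie within 3 Monte-Carlo standard errors of the
configured hazard; PPV unbiasedness averages 200 review-sample draws
against the population precision of one classified case set; the
Kaplan–Meier oracle comparison uses 600 random records and requires
exact equality. These sizes are the package's chosen trade-off between
statistical resolution and a test suite that runs in well under a
minute per property.

## Known limitations

- The review step is an oracle read of the truth table (optionally
  corrupted at a configurable error rate); it does not model systematic
  reviewer bias or inter-reviewer disagreement.
- Confirmation-rate extrapolation treats cross-coded patients as
  confirmed without review, as the algorithm specifies; false positives
  entering through cross-coding are therefore corrected only via the
  separately reported PPV, not the case count.
- The eligibility criterion "an encounter in the preceding two years" is
  anchored at the candidate start date (the earliest date all criteria
  hold), one of several defensible readings.
- Stratified PPV by age/sex/smoking is implemented
  (`validate.stratified_ppv`) but has no reference values to compare
  against.
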