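# tripodscore

Completeness-of-reporting scores for multivariable prediction-model studies,
against the TRIPOD checklist.

Multivariable prediction models estimate an individual's probability that a
condition is present (diagnostic) or will occur (prognostic) from several
predictors. TRIPOD (Transparent Reporting of a multivariable prediction model
for Individual Prognosis Or Diagnosis) is the 22-item reporting guideline for
studies that develop, externally validate, or extend such models.
Meta-research teams audit the literature by decomposing each checklist item
into *elements* (atomic pieces of required information), judging every
element of every publication as reported or not, and aggregating those
judgements into adherence scores. `tripodscore` is the scoring half of that
workflow: it ships the checklist as data, validates element-level extraction
records, computes the scores at every level, and generates calibrated
synthetic cohorts so the whole pipeline is testable without any extraction
campaign.

## The scoring model

Let a model extraction carry a judgement for every element of every item
applicable to its study type. Development-only items are 10a, 10b, 14a, 14b,
15a, 15b; validation-only items are 10c, 10e, 12, 13c, 17, 19a; the other 25
apply to both, giving applicable sets of 31 (development or validation), 37
(combined development and validation), and 36 (incremental value, which has
no model-updating item).

* **Item level** — item *i* is complete for model *m* iff every element of
  *i* is `reported`, `not_applicable` (e.g. blinding when the outcome is
  all-cause mortality), or, for items 4b/5a/6a/7a, `reported_by_reference`.
* **Model level** — with scored set *S(m)* = applicable items minus item 21
  (supplementary material, excluded from all calculations) minus conditional
  "if done" items (5c, 10e, 11, 14b, 17) flagged inapplicable,

  adherence(m) = |{i ∈ S(m) : complete(m, i)}| / |S(m)|.

* **Publication level** — identical to the model score for single-type
  publications; for publications carrying several study types the item
  universe is the union of the members' scored sets, an item counting
  complete iff complete in every member that scores it, except items 3a and
  18–20, where either member suffices.
* **Item across models** — adherence(i) = (models reporting *i* completely) /
  (models where *i* was applicable).

Fractions are exact rationals; percentages are rounded (half away from zero)
only when a table is rendered.

## Worked example

```
$ tripod-adherence simulate --out demo --seed 1
simulated 146 publications / 167 models into demo/records

$ tripod-adherence report --input demo/records --out demo/report
wrote report for 146 publications to demo/report

$ head -4 demo/report/adherence_summary.csv
stratum,n,median,p25,p75,min,max
overall,146,44,39,50,26,66
diagnostic,32,44,38,52,27,59
prognostic,114,44,39,50,26,66
```

The simulated audit finds publications adhering to a median of 44% of
applicable TRIPOD items (quartiles 39–50%) — reporting is judged complete
for fewer than half of the items — with diagnostic and prognostic models
comparable. `model_scores.csv` holds each model's exact tally, e.g.
`P001-m1,development,13,29,0.448…`: 13 of 29 scored items complete (31
applicable items, minus item 21, minus one conditional item flagged not
applicable). `table1.md` ranks items: overall interpretation (19b, 96%) and
source of data (4a, 96%) are well reported, while title and abstract land
near the bottom. `regression.csv` fits publication adherence on sample size,
journal impact factor, predictor count, and prospective design; in the
default cohort these are generated independently of reporting quality, and
the fit finds no association (all p ≥ 0.29).

The same operations are available as library functions
(`load_checklist`, `read_records`, `model_adherence`,
`publication_adherence`, `item_adherence_table`, `summarize_adherence`,
`regress_adherence`, `generate_cohort`, …); see the module docstrings and
`docs/methods.md`.

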