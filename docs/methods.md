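# Methods

## The checklist as data

The TRIPOD statement's 22 main items expand into 37 scoreable labels (items
3, 4, 6, 7, 14, 15, 19 split in two; 5 and 13 in three; 10 in five; the rest
undivided). `tripodscore` ships the checklist as a versioned YAML definition
(`src/tripodscore/data/tripod_checklist.yaml`) rather than code: each record
carries the item label, study-type applicability (`D`, `V`, or `DV`), the
conditional / reference-acceptable / excluded-from-scores /
either-type-suffices flags, and an ordered element list. The loader enforces
the fixed 37-label universe (the guideline's structure is not editable) but
takes flags and element lists from the file, so element decompositions can be
refined against the published extraction form without code changes. Three
element counts are pinned by well-known worked decompositions — title (4
elements), abstract (12), key study dates (3) — and the remaining items
default to one element per reporting requirement in the item's phrasing
(e.g. the development-versus-validation comparison item decomposes into
setting, eligibility, outcome, and predictor differences). These defaults are
a reading of the item texts, not a reproduction of the extraction form; any
analysis that depends on exact element granularity should supply its own
definition file.

Two structural choices are configurable in the definition file because the
guideline leaves them open:

* **Incremental-value exclusion.** Incremental-value studies score 36 items.
  The excluded item defaults to 17 (model updating), the only item with no
  incremental-value analogue.
* **Partially applicable items.** For incremental-value records, items 10c,
  12 and 19a behave like conditional items, driven by per-model flags —
  published applicability counts show them applying to only a subset of such
  models, with no stated rule. (Audited cohorts also show 19a occasionally
  inapplicable to combined development-and-validation models; the record
  schema does not model that case.)

## Extraction records and validation

The unit of extraction is one element judgement: `reported`, `not_reported`,
`not_applicable`, or `reported_by_reference` (valid only for items 4b, 5a,
6a, 7a, where a citation to another article is acceptable). A model carries
judgements for *all* elements of its study-type applicable set — including
conditional items flagged "not done", which scoring then excludes — plus
explicit applicability flags for the conditional items (absent flag =
applicable; applicability is recorded, never inferred, because it varies by
model in real audits). A publication carries at most one model per study
type, its 2012-scale journal impact factor, and a prospective-design flag.

Validation is checklist-aware and total: every missing, surplus, or
ill-typed judgement is reported with publication/model/element coordinates.
The interchange formats are a long CSV directory (one row per element
judgement, with companion CSVs for publication covariates, model metadata,
and conditional flags) and a one-to-one JSON mirror; both serialize
canonically (sorted by publication, model, item, element ordinal), so
`read(write(x)) == x` and identical inputs give byte-identical files.

When a publication reports development and external validation of the *same*
model, the two parts are extracted separately and merged element-wise. The
default merge is favourable — per shared element the better judgement wins,
under reported > reported-by-reference > not-applicable > not-reported —
reflecting the question "is the information anywhere in the publication?"; a
`strict` mode (both parts must report) is available since the combination
rule is a convention, not a published algorithm.

## Scoring

See the README for the formal definitions. Numerical conventions:

* Adherence fractions are `fractions.Fraction` internally; rounding to whole
  percentages (half away from zero, so 8/170 renders as 5 and 3/170 as 2)
  happens only in rendering.
* A development or validation model with every conditional item applicable
  scores over 30 items (31 applicable − item 21); each flagged-off
  conditional removes one from numerator and denominator alike.
* Querying an item outside a model's applicable or flagged-applicable set
  raises rather than returning false, to surface extraction errors early.
* In the per-item-across-models tally, item 21's denominator is the total
  model count: its applicability is unobservable, so the tally is
  descriptive rather than applicability-restricted.
* Publication-level combination builds the item universe as the union of the
  member models' scored sets; an item scored by only one member is judged on
  that member alone.
* An empty scored set (possible only with custom checklists) is a
  degenerate-input error, not a 0/0.

## Cohort summaries

Percentile summaries default to linear interpolation between order
statistics; the mode is configurable (`lower`, `higher`, `nearest`,
`midpoint`) because quartiles of ~150 observations shift by about a point
across conventions and no single convention is canonical in this literature.
The per-item table is partitioned at ≥ 75% / < 25% by default (both
thresholds configurable; classification uses exact percentages, before
rounding). The adherence regression is ordinary least squares of publication
adherence (percent) on sample size, journal impact factor, predictor count,
and prospective design, complete cases only, sample size untransformed by
default with a log switch; per-publication sample size and predictor count
come from the publication's primary model (the one studied in the largest
sample). Rank-deficient designs raise an error naming the collinear
covariates. Standard errors are classical; publications contributing several
models are *not* treated as clustered, matching the descriptive intent.

## The synthetic cohort generator

The generator emulates a pre-guideline audit cohort: 146 publications, a
second same-publication model of a different type with probability 24/146
(≈170 models in expectation), study-type mix 43/25/19/12% over development /
external validation / incremental value / combined, 84% prognostic
publications, and log-normal covariates matched to medians and IQRs —
journal impact factor 5.3 (4.0–7.1), sample size 450 (200–2005), predictor
count 5 (3–8; discretized, floored at 1). The log-scale spread is set from
the IQR as σ = ln(q75/q25)/(2·z0.75); since the printed IQRs are asymmetric
around the median on the log scale, the tails are a compromise, but medians
and central mass are reproduced (acceptance checks: median predictors 5,
median sample size within [350, 570] per 170-model replicate).

Element judgements are independent. Each item has a target completeness
probability; given *k* elements still applicable after not-applicable
substitution, each is reported with probability t^(1/k), so item-level
completeness equals the target exactly for every model. Targets for the 25
items with published adherence rates are those rates; the remaining 12
targets were set once so the simulated publication-adherence distribution
matches the audited headline (median 44%, quartiles ≈ 38–50 at large n).
Not-applicable judgements are generated only where the scoring rules create
them: blinding elements (6b, 7b) when the predicted outcome is all-cause
mortality (publication rate 23/146), and the end-of-follow-up element (4b)
for diagnostic models. Because a fully not-applicable item counts as
complete, the blinding items cannot fall below the mortality rate; their
targets are back-solved and saturate at that floor where infeasible (7b's
published 6% sits below the ≈16% floor, an internal tension of the audit
conventions themselves). `expected_item_completeness` returns the exact
analytic expectation, which the calibration tests check to 3 binomial
standard errors on a ~2000-model cohort.

Conditional-item applicability flags are drawn at published rates (5c
169/170, 11 70/170, 14b 94/127, 17 7/64, 10e 23/97; incremental-value
partials 10c 20/33, 12 17/33, 19a 29/33). The prospective-design rate is not
published and defaults to 0.5.

`planted_effect_cohort` makes expected adherence depend linearly on chosen
covariates (slopes in percentage points per unit, anchored at the configured
medians) by tilting per-item probabilities proportionally to their headroom,
normalised by the cohort-mean headroom — the expectation shift is exactly
the requested tilt while every probability stays in [0, 1]; infeasible
slopes raise a range error. With zero slopes the output is draw-for-draw
identical to the plain generator.

**What passing tests do and do not show.** The generator reproduces the
audited cohort's marginal structure — type mix, covariate medians, per-item
rates, headline adherence distribution. It deliberately models no
correlation: none between items (real reporting quality is correlated within
a publication), none between the two models of a multi-type publication, and
none between covariates and reporting. Consequently multi-type publications
score lower under the complete-in-all rule than correlated real pairs would,
and calibration tests validate the scoring arithmetic and the generator's own
targets, not the behaviour of the pipeline on correlated human extractions.

## Problem sizes

Default test and acceptance workloads are sized for a laptop: exhaustive
oracle enumeration uses miniature checklists (hundreds of assignments),
calibration uses one ~2000-model cohort, regression recovery one 500-
publication cohort, and the acceptance script twenty 170-model cohorts; the
full suite runs in well under a minute.

## Known limitations

* Element decompositions beyond items 1, 2, and 4b are package defaults, not
  the published extraction form.
* The record schema fixes at most one model per study type per publication
  (the audit's own selection protocol); selecting the primary model from a
  richer set is out of scope.
* No risk-of-bias or conduct-quality assessment — completeness of reporting
  only.
* Rendered figures (adherence histograms, per-item bars) are out of scope;
  the CSV outputs feed any plotting tool directly.
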