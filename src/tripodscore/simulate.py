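"""Synthetic extraction cohorts with the structure of a pre-guideline
prediction-model literature audit.

The generator emulates a cohort of prediction-model publications as a
reporting-quality audit would extract them: 146 publications carrying 170
models, a study-type mix of 43/25/19/12% over development / external
validation / incremental value / combined development-and-validation, mostly
prognostic models (84%), right-skewed journal impact factors (median 5.3,
IQR 4.0–7.1), study sample sizes (median 450, IQR 200–2005) and final-model
predictor counts (median 5, IQR 3–8).

Element judgements are drawn independently.  Each item carries a target
completeness probability (calibrated to published per-item adherence rates);
with :math:`k` elements still applicable after not-applicable substitution,
each is reported with probability :math:`t^{1/k}`, so the *item* completeness
hits the target exactly.  Not-applicable judgements arise only where the
scoring rules create them: the blinding elements (6b, 7b) when the predicted
outcome is all-cause mortality, and the end-of-follow-up element (4b) for
diagnostic models.  Because a fully not-applicable item counts as complete,
the blinding items cannot fall below the all-cause-mortality rate; the
generator back-solves their targets and saturates where infeasible
(:func:`expected_item_completeness` gives the exact analytic value).

Conditional "if done" items receive per-model applicability flags drawn at
rates matching the published applicability counts (e.g. treatments received
in 169/170 models, model updating in 7/64 validation reports).

No correlation structure is modelled: judgements are independent across
items and models, and covariates are independent of reporting quality —
except in :func:`planted_effect_cohort`, which tilts per-item probabilities
so that expected adherence depends linearly on chosen covariates (for
regression power/recovery studies).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import yaml

from .checklist import Checklist, StudyType, applicable_item_set, load_checklist
from .errors import TripodScoreError
from .records import (
    ElementJudgement,
    ModelExtraction,
    ModelMetadata,
    PublicationExtraction,
)

__all__ = [
    "GeneratorConfig",
    "InfeasibleEffectError",
    "generate_cohort",
    "generate_cohort_with_composition",
    "planted_effect_cohort",
    "expected_item_completeness",
    "DEFAULT_ITEM_TARGETS",
]

_Z75 = 0.6744897501960817  # third-quartile z-score of the standard normal


class InfeasibleEffectError(TripodScoreError):
    """A planted covariate effect pushes an item probability outside [0, 1]."""


def _lognormal_sigma(q25: float, q75: float) -> float:
    return math.log(q75 / q25) / (2.0 * _Z75)


#: Default per-item completeness targets: published per-item adherence rates
#: where available; the remaining items are set once so that the simulated
#: publication-adherence distribution matches the published one (median 44%).
DEFAULT_ITEM_TARGETS: dict[str, float] = {
    "1": 0.05, "2": 0.02,
    "3a": 0.81, "3b": 0.63,
    "4a": 0.95, "4b": 0.65,
    "5a": 0.70, "5b": 0.79, "5c": 0.60,
    "6a": 0.80, "6b": 0.28,
    "7a": 0.25, "7b": 0.06,
    "8": 0.25, "9": 0.39,
    "10a": 0.29, "10b": 0.24, "10c": 0.50, "10d": 0.21, "10e": 0.40,
    "11": 0.90, "12": 0.11,
    "13a": 0.55, "13b": 0.21, "13c": 0.11,
    "14a": 0.50, "14b": 0.40,
    "15a": 0.17, "15b": 0.45,
    "16": 0.14, "17": 0.14,
    "18": 0.88,
    "19a": 0.60, "19b": 0.96,
    "20": 0.59, "21": 0.55, "22": 0.27,
}

#: Applicability rates of the conditional items, and of the validation-only
#: items that are only partially applicable to incremental-value models,
#: matching the published applicability counts.
DEFAULT_CONDITIONAL_RATES: dict[str, float] = {
    "5c": 169 / 170,
    "10e": 23 / 97,
    "11": 70 / 170,
    "14b": 94 / 127,
    "17": 7 / 64,
    "10c": 20 / 33,
    "12": 17 / 33,
    "19a": 29 / 33,
}

_DOMAINS = (
    ("critical care medicine", 0.11),
    ("obstetrics and gynaecology", 0.09),
    ("gastroenterology and hepatology", 0.07),
    ("cardiology", 0.07),
    ("oncology", 0.07),
    ("neurology", 0.06),
    ("general and internal medicine", 0.53),
)

_BLINDING_ELEMENT_ITEMS = ("6b", "7b")
_FOLLOW_UP_ELEMENT = "4b.3"


@dataclass(frozen=True)
class GeneratorConfig:
    """Tunable knobs of the synthetic cohort, with audit-calibrated defaults.

    ``item_report_probability`` maps each item to a target completeness
    probability, either a single float or a mapping from study-type value to
    float.  ``multi_type_rate`` is the probability that a publication carries
    a second model of a different study type (24/146, reproducing 170 models
    in 146 publications in expectation).
    """

    n_publications: int = 146
    type_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            StudyType.DEVELOPMENT.value: 0.43,
            StudyType.EXTERNAL_VALIDATION.value: 0.25,
            StudyType.INCREMENTAL_VALUE.value: 0.19,
            StudyType.DEVELOPMENT_AND_VALIDATION.value: 0.12,
        }
    )
    multi_type_rate: float = 24 / 146
    item_report_probability: Mapping[str, Union[float, Mapping[str, float]]] = field(
        default_factory=lambda: dict(DEFAULT_ITEM_TARGETS)
    )
    conditional_applicability_probability: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONDITIONAL_RATES)
    )
    purpose_mix: float = 0.84  # P(prognostic) per publication
    jif_median: float = 5.3
    jif_iqr: tuple[float, float] = (4.0, 7.1)
    sample_size_median: float = 450.0
    sample_size_iqr: tuple[float, float] = (200.0, 2005.0)
    n_predictors_median: float = 5.0
    n_predictors_iqr: tuple[float, float] = (3.0, 8.0)
    prospective_rate: float = 0.5
    all_cause_mortality_rate: float = 23 / 146
    follow_up_na_for_diagnostic: bool = True
    blinding_na_for_mortality: bool = True
    reference_report_rate: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_publications < 1:
            raise ValueError("n_publications must be >= 1")
        total = sum(self.type_mix.values())
        if total <= 0:
            raise ValueError("type_mix must have positive mass")
        for key, value in self.type_mix.items():
            StudyType(key)
            if value < 0:
                raise ValueError(f"type_mix[{key!r}] must be >= 0")
        for name in (
            "multi_type_rate", "purpose_mix", "prospective_rate",
            "all_cause_mortality_rate", "reference_report_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for item_id, value in self.item_report_probability.items():
            probs = value.values() if isinstance(value, Mapping) else (value,)
            for p in probs:
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"item_report_probability[{item_id!r}] outside [0, 1]")
        for item_id, p in self.conditional_applicability_probability.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(
                    f"conditional_applicability_probability[{item_id!r}] outside [0, 1]"
                )

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        raw = yaml.safe_load(open(path, encoding="utf-8")) or {}
        if "jif_iqr" in raw:
            raw["jif_iqr"] = tuple(raw["jif_iqr"])
        if "sample_size_iqr" in raw:
            raw["sample_size_iqr"] = tuple(raw["sample_size_iqr"])
        if "n_predictors_iqr" in raw:
            raw["n_predictors_iqr"] = tuple(raw["n_predictors_iqr"])
        return cls(**raw)


def _item_target(config: GeneratorConfig, item_id: str, study_type: StudyType) -> float:
    value = config.item_report_probability.get(item_id, 0.5)
    if isinstance(value, Mapping):
        return float(value.get(study_type.value, 0.5))
    return float(value)


def expected_item_completeness(
    config: GeneratorConfig, item_id: str, study_type: StudyType
) -> float:
    """Analytic completeness probability of an item under the generator.

    Equals the configured target for every item except the blinding items,
    whose completeness cannot fall below the all-cause-mortality rate (a
    fully not-applicable item counts as complete), so their expectation is
    ``max(target, mortality_rate)``.
    """
    t = _item_target(config, item_id, study_type)
    if config.blinding_na_for_mortality and item_id in _BLINDING_ELEMENT_ITEMS:
        return max(t, config.all_cause_mortality_rate)
    return t


def _blinding_adjusted_target(config: GeneratorConfig, t: float) -> float:
    # back-solve so that mortality auto-completion plus draws hits the target
    r = config.all_cause_mortality_rate
    if r >= 1.0:
        return 0.0
    return max(0.0, (t - r) / (1.0 - r))


def _draw_judgements(
    rng: np.random.Generator,
    checklist: Checklist,
    study_type: StudyType,
    config: GeneratorConfig,
    mortality_outcome: bool,
    diagnostic: bool,
    tilt: float = 0.0,
    headroom_scale: Optional[float] = None,
) -> dict[str, ElementJudgement]:
    judgements: dict[str, ElementJudgement] = {}
    items = applicable_item_set(checklist, study_type)
    for item in checklist.items:
        if item.item_id not in items:
            continue
        t = _item_target(config, item.item_id, study_type)
        na_elements: set[str] = set()
        if (
            config.blinding_na_for_mortality
            and mortality_outcome
            and item.item_id in _BLINDING_ELEMENT_ITEMS
        ):
            na_elements = {el.element_id for el in item.elements}
        elif (
            config.blinding_na_for_mortality
            and item.item_id in _BLINDING_ELEMENT_ITEMS
        ):
            t = _blinding_adjusted_target(config, t)
        if config.follow_up_na_for_diagnostic and diagnostic and item.item_id == "4b":
            na_elements.add(_FOLLOW_UP_ELEMENT)
        if tilt:
            t = _tilt_probability(t, tilt, headroom_scale)
        k = sum(1 for el in item.elements if el.element_id not in na_elements)
        p_element = t ** (1.0 / k) if k > 0 else 1.0
        for el in item.elements:
            if el.element_id in na_elements:
                judgements[el.element_id] = ElementJudgement.NOT_APPLICABLE
                continue
            if rng.random() < p_element:
                if (
                    item.reference_acceptable
                    and rng.random() < config.reference_report_rate
                ):
                    judgements[el.element_id] = ElementJudgement.REPORTED_BY_REFERENCE
                else:
                    judgements[el.element_id] = ElementJudgement.REPORTED
            else:
                judgements[el.element_id] = ElementJudgement.NOT_REPORTED
    return judgements


def _draw_flags(
    rng: np.random.Generator,
    checklist: Checklist,
    study_type: StudyType,
    config: GeneratorConfig,
) -> dict[str, bool]:
    items = applicable_item_set(checklist, study_type)
    keys = checklist.conditional_items & items
    if study_type is StudyType.INCREMENTAL_VALUE:
        keys = keys | (checklist.incremental_value_partial & items)
    flags = {}
    for item_id in sorted(keys):
        p = config.conditional_applicability_probability.get(item_id, 1.0)
        flags[item_id] = bool(rng.random() < p)
    return flags


def _draw_metadata(
    rng: np.random.Generator, config: GeneratorConfig, purpose: str, domain: str,
    mortality_outcome: bool,
) -> ModelMetadata:
    sigma_n = _lognormal_sigma(*config.sample_size_iqr)
    sigma_p = _lognormal_sigma(*config.n_predictors_iqr)
    sample_size = max(1, int(round(float(
        rng.lognormal(math.log(config.sample_size_median), sigma_n)
    ))))
    n_predictors = max(1, int(round(float(
        rng.lognormal(math.log(config.n_predictors_median), sigma_p)
    ))))
    outcome = "all-cause mortality" if mortality_outcome else "disease-specific outcome"
    return ModelMetadata(
        clinical_domain=domain,
        purpose=purpose,  # type: ignore[arg-type]
        sample_size=sample_size,
        n_predictors=n_predictors,
        outcome=outcome,
    )


def _tilt_probability(t: float, tilt: float, headroom_scale: Optional[float]) -> float:
    """Shift an item probability so the cohort-mean shift equals ``tilt``.

    The shift is distributed proportionally to each item's headroom (distance
    to 1 for positive tilts, to 0 for negative), normalised by the cohort
    mean headroom, so expected adherence moves linearly while every item
    stays inside [0, 1].
    """
    if headroom_scale is None or headroom_scale <= 0:
        raise InfeasibleEffectError("tilt requested without available headroom")
    h = (1.0 - t) if tilt > 0 else t
    shifted = t + tilt * h / headroom_scale
    if not 0.0 <= shifted <= 1.0:
        raise InfeasibleEffectError(
            f"tilted probability {shifted:.3f} outside [0, 1]"
        )
    return shifted


def _mean_headroom(config: GeneratorConfig, checklist: Checklist, upward: bool) -> float:
    targets = [
        _item_target(config, it.item_id, StudyType.DEVELOPMENT_AND_VALIDATION)
        for it in checklist.items
    ]
    if upward:
        return float(np.mean([1.0 - t for t in targets]))
    return float(np.mean(targets))


_COVARIATE_NAMES = ("journal_impact_factor", "sample_size", "n_predictors", "prospective_design")


def _generate(
    config: GeneratorConfig,
    checklist: Checklist,
    covariate_slopes: Optional[Mapping[str, float]],
) -> list[PublicationExtraction]:
    rng = np.random.default_rng(config.seed)
    sigma_jif = _lognormal_sigma(*config.jif_iqr)
    type_values = sorted(config.type_mix)
    type_probs = np.array([config.type_mix[v] for v in type_values], dtype=float)
    type_probs = type_probs / type_probs.sum()
    domain_names = [d for d, _ in _DOMAINS]
    domain_probs = np.array([w for _, w in _DOMAINS], dtype=float)
    domain_probs = domain_probs / domain_probs.sum()

    if covariate_slopes:
        unknown = set(covariate_slopes) - set(_COVARIATE_NAMES)
        if unknown:
            raise ValueError(f"unknown covariate(s): {', '.join(sorted(unknown))}")

    centers = {
        "journal_impact_factor": config.jif_median,
        "sample_size": config.sample_size_median,
        "n_predictors": config.n_predictors_median,
        "prospective_design": config.prospective_rate,
    }

    width = len(str(config.n_publications))
    publications: list[PublicationExtraction] = []
    for i in range(1, config.n_publications + 1):
        pub_id = f"P{i:0{width}d}"
        jif = float(rng.lognormal(math.log(config.jif_median), sigma_jif))
        prospective = bool(rng.random() < config.prospective_rate)
        prognostic = bool(rng.random() < config.purpose_mix)
        purpose = "prognostic" if prognostic else "diagnostic"
        domain = domain_names[int(rng.choice(len(domain_names), p=domain_probs))]
        mortality = bool(rng.random() < config.all_cause_mortality_rate)

        first = StudyType(type_values[int(rng.choice(len(type_values), p=type_probs))])
        types = [first]
        if rng.random() < config.multi_type_rate:
            others = [v for v in type_values if v != first.value]
            other_probs = np.array([config.type_mix[v] for v in others], dtype=float)
            if other_probs.sum() > 0:
                other_probs = other_probs / other_probs.sum()
                types.append(StudyType(others[int(rng.choice(len(others), p=other_probs))]))

        models = []
        for j, study_type in enumerate(types, start=1):
            metadata = _draw_metadata(rng, config, purpose, domain, mortality)
            tilt = 0.0
            headroom_scale = None
            if covariate_slopes:
                values = {
                    "journal_impact_factor": jif,
                    "sample_size": metadata.sample_size,
                    "n_predictors": metadata.n_predictors,
                    "prospective_design": float(prospective),
                }
                # slopes are in adherence percentage points per covariate unit
                tilt = sum(
                    slope * (values[name] - centers[name])
                    for name, slope in covariate_slopes.items()
                ) / 100.0
                headroom_scale = _mean_headroom(config, checklist, upward=tilt > 0)
            judgements = _draw_judgements(
                rng, checklist, study_type, config,
                mortality_outcome=mortality, diagnostic=not prognostic,
                tilt=tilt, headroom_scale=headroom_scale,
            )
            flags = _draw_flags(rng, checklist, study_type, config)
            models.append(
                ModelExtraction(
                    model_id=f"{pub_id}-m{j}",
                    publication_id=pub_id,
                    study_type=study_type,
                    judgements=judgements,
                    conditional_applicability=flags,
                    metadata=metadata,
                )
            )
        publications.append(
            PublicationExtraction(
                publication_id=pub_id,
                journal_impact_factor=jif,
                prospective_design=prospective,
                models=tuple(models),
            )
        )
    return publications


def generate_cohort(
    config: Optional[GeneratorConfig] = None, checklist: Optional[Checklist] = None
) -> list[PublicationExtraction]:
    """Generate a fully valid synthetic cohort (deterministic per seed)."""
    config = config or GeneratorConfig()
    checklist = checklist or load_checklist()
    return _generate(config, checklist, covariate_slopes=None)


def planted_effect_cohort(
    config: GeneratorConfig,
    covariate_slopes: Mapping[str, float],
    checklist: Optional[Checklist] = None,
) -> list[PublicationExtraction]:
    """Generate a cohort whose expected adherence depends linearly on
    covariates.

    ``covariate_slopes`` maps covariate names (``journal_impact_factor``,
    ``sample_size``, ``n_predictors``, ``prospective_design``) to slopes in
    adherence percentage points per covariate unit, anchored at the
    configured medians.  With all slopes zero the output is draw-for-draw
    identical to :func:`generate_cohort`.

    Raises
    ------
    InfeasibleEffectError
        If a slope pushes an implied item probability outside [0, 1].
    """
    checklist = checklist or load_checklist()
    return _generate(config, checklist, covariate_slopes=covariate_slopes)


def generate_cohort_with_composition(
    counts: Mapping[str, int],
    config: Optional[GeneratorConfig] = None,
    checklist: Optional[Checklist] = None,
) -> list[PublicationExtraction]:
    """Generate single-model publications with an exact study-type composition.

    ``counts`` maps study-type values to model counts, e.g. 73 development /
    43 external validation / 33 incremental value / 21 combined for the
    audited 170-model cohort.  Used for applicability-count checks where the
    composition must be exact rather than multinomially sampled.
    """
    config = config or GeneratorConfig()
    checklist = checklist or load_checklist()
    n_total = sum(counts.values())
    base = replace(config, n_publications=n_total, multi_type_rate=0.0)
    rng = np.random.default_rng(config.seed)
    # reuse the main generator, then overwrite study types deterministically
    publications = _generate(base, checklist, covariate_slopes=None)
    assigned: list[StudyType] = []
    for value in sorted(counts):
        assigned.extend([StudyType(value)] * counts[value])
    out = []
    for pub, study_type in zip(publications, assigned):
        model = pub.models[0]
        judgements = _draw_judgements(
            rng, checklist, study_type, config,
            mortality_outcome=model.metadata.outcome == "all-cause mortality",
            diagnostic=model.metadata.purpose == "diagnostic",
        )
        flags = _draw_flags(rng, checklist, study_type, config)
        out.append(
            replace(
                pub,
                models=(
                    replace(
                        model,
                        study_type=study_type,
                        judgements=judgements,
                        conditional_applicability=flags,
                    ),
                ),
            )
        )
    return out
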