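"""Element-level extraction records for prediction-model publications.

The unit of extraction is one *element judgement*: for one element of one
checklist item, for one model, an extractor records whether the requested
information was present.  A model carries a judgement for every element of
every item applicable to its study type; a publication carries one model per
study type it reports (a publication may, for example, develop one model and
externally validate a different one).

Conditional ("if done / if applicable") items — treatments received (5c),
model updating (10e, 17), risk groups (11), and unadjusted associations
(14b) — carry an explicit per-model applicability flag, as do the
validation-only items that apply to only some incremental-value models.
Flags are recorded rather than inferred; an absent flag means the item is
applicable.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Literal, Optional, Sequence

from .checklist import Applicability, Checklist, StudyType, applicable_item_set
from .errors import MergeError, RecordValidationError

__all__ = [
    "ElementJudgement",
    "ModelMetadata",
    "ModelExtraction",
    "PublicationExtraction",
    "AdherenceScore",
    "validate_publications",
    "merge_same_model_parts",
]


class ElementJudgement(str, enum.Enum):
    """Verdict on one extraction element of one model."""

    REPORTED = "reported"
    NOT_REPORTED = "not_reported"
    NOT_APPLICABLE = "not_applicable"
    REPORTED_BY_REFERENCE = "reported_by_reference"


# favourability for merging development and validation parts of the same model:
# a directly reported element beats a citation, which beats "not applicable",
# which beats an absent element
_FAVOURABILITY = {
    ElementJudgement.REPORTED: 3,
    ElementJudgement.REPORTED_BY_REFERENCE: 2,
    ElementJudgement.NOT_APPLICABLE: 1,
    ElementJudgement.NOT_REPORTED: 0,
}


@dataclass(frozen=True)
class ModelMetadata:
    """Descriptive covariates extracted for every model."""

    clinical_domain: str
    purpose: Literal["diagnostic", "prognostic"]
    sample_size: int
    n_predictors: Optional[int]
    outcome: str


@dataclass(frozen=True)
class ModelExtraction:
    """All element judgements plus metadata for one model in one publication."""

    model_id: str
    publication_id: str
    study_type: StudyType
    judgements: dict[str, ElementJudgement]
    conditional_applicability: dict[str, bool] = field(default_factory=dict)
    metadata: Optional[ModelMetadata] = None

    def item_applicable(self, item_id: str) -> bool:
        """Per-model conditional flag; items without a flag are applicable."""
        return self.conditional_applicability.get(item_id, True)


@dataclass(frozen=True)
class PublicationExtraction:
    """One publication: covariates plus one model extraction per study type."""

    publication_id: str
    journal_impact_factor: float
    prospective_design: bool
    models: tuple[ModelExtraction, ...]

    def __post_init__(self) -> None:
        if not isinstance(self.models, tuple):
            object.__setattr__(self, "models", tuple(self.models))


@dataclass(frozen=True)
class AdherenceScore:
    """Completely reported scored items over applicable scored items."""

    numerator: int
    denominator: int

    def __post_init__(self) -> None:
        if self.denominator < 1:
            raise ValueError("denominator must be >= 1")
        if not 0 <= self.numerator <= self.denominator:
            raise ValueError("numerator must lie in [0, denominator]")

    @property
    def fraction(self) -> Fraction:
        """Exact adherence fraction; rounding happens only at presentation."""
        return Fraction(self.numerator, self.denominator)

    @property
    def percent(self) -> float:
        return 100.0 * self.numerator / self.denominator


def _allowed_flag_keys(checklist: Checklist, study_type: StudyType) -> frozenset[str]:
    keys = checklist.conditional_items
    if study_type is StudyType.INCREMENTAL_VALUE:
        keys = keys | checklist.incremental_value_partial
    return keys


def validate_publications(
    publications: Sequence[PublicationExtraction], checklist: Checklist
) -> list[str]:
    """Check every schema invariant; return diagnostics (empty if valid).

    Each diagnostic carries publication/model/element coordinates so a
    violation in a large extraction file can be located directly.
    """
    violations: list[str] = []
    seen_pubs: set[str] = set()
    for pub in publications:
        where = f"publication {pub.publication_id!r}"
        if pub.publication_id in seen_pubs:
            violations.append(f"{where}: duplicate publication_id")
        seen_pubs.add(pub.publication_id)
        if not pub.models:
            violations.append(f"{where}: no models")
        if not pub.journal_impact_factor > 0:
            violations.append(f"{where}: journal_impact_factor must be positive")
        seen_types: set[StudyType] = set()
        for model in pub.models:
            coords = f"{where}, model {model.model_id!r}"
            if model.publication_id != pub.publication_id:
                violations.append(f"{coords}: publication_id mismatch")
            try:
                study_type = StudyType(model.study_type)
            except ValueError:
                violations.append(f"{coords}: unknown study_type {model.study_type!r}")
                continue
            if study_type in seen_types:
                violations.append(
                    f"{coords}: study_type {study_type.value!r} occurs twice in the publication"
                )
            seen_types.add(study_type)

            applicable = applicable_item_set(checklist, study_type)
            expected = {el.element_id: el for el in checklist.elements_of(applicable)}
            for element_id in sorted(set(expected) - set(model.judgements)):
                violations.append(f"{coords}: missing judgement for element {element_id!r}")
            for element_id, judgement in model.judgements.items():
                if element_id not in expected:
                    violations.append(
                        f"{coords}: judgement for element {element_id!r} outside the "
                        f"applicable item set"
                    )
                    continue
                item = checklist.item(expected[element_id].parent_item)
                if (
                    judgement is ElementJudgement.REPORTED_BY_REFERENCE
                    and not item.reference_acceptable
                ):
                    violations.append(
                        f"{coords}: element {element_id!r} judged reported_by_reference "
                        f"but item {item.item_id} does not accept references"
                    )
            allowed = _allowed_flag_keys(checklist, study_type)
            for key in sorted(set(model.conditional_applicability) - allowed):
                violations.append(
                    f"{coords}: conditional_applicability flag for non-conditional item {key!r}"
                )
            if model.metadata is not None:
                meta = model.metadata
                if meta.sample_size < 1:
                    violations.append(f"{coords}: sample_size must be >= 1")
                develops = study_type in (
                    StudyType.DEVELOPMENT,
                    StudyType.DEVELOPMENT_AND_VALIDATION,
                )
                if develops and (meta.n_predictors is None or meta.n_predictors < 1):
                    violations.append(
                        f"{coords}: n_predictors must be >= 1 for a development model"
                    )
                if meta.purpose not in ("diagnostic", "prognostic"):
                    violations.append(f"{coords}: unknown purpose {meta.purpose!r}")
    return violations


def ensure_valid(
    publications: Sequence[PublicationExtraction], checklist: Checklist
) -> None:
    """Raise :class:`RecordValidationError` if any invariant is violated."""
    violations = validate_publications(publications, checklist)
    if violations:
        raise RecordValidationError(violations)


def merge_same_model_parts(
    dev_part: ModelExtraction,
    val_part: ModelExtraction,
    checklist: Checklist,
    mode: Literal["favourable", "strict"] = "favourable",
) -> ModelExtraction:
    """Combine separately extracted development and validation reporting of
    the same model into one development-and-validation record.

    Elements of items applicable to both study types get, per element, the
    more favourable of the two judgements (``favourable`` mode, the default:
    information reported anywhere in the publication counts) or the less
    favourable one (``strict`` mode: both parts must report).  Development-only
    elements come from the development part, validation-only elements from
    the validation part.
    """
    if dev_part.model_id != val_part.model_id:
        raise MergeError(
            f"model_id mismatch: {dev_part.model_id!r} vs {val_part.model_id!r}"
        )
    if dev_part.publication_id != val_part.publication_id:
        raise MergeError(
            f"publication_id mismatch: {dev_part.publication_id!r} "
            f"vs {val_part.publication_id!r}"
        )
    if StudyType(dev_part.study_type) is not StudyType.DEVELOPMENT:
        raise MergeError("dev_part must have study_type 'development'")
    if StudyType(val_part.study_type) is not StudyType.EXTERNAL_VALIDATION:
        raise MergeError("val_part must have study_type 'external_validation'")
    if mode not in ("favourable", "strict"):
        raise ValueError(f"unknown merge mode {mode!r}")

    pick = max if mode == "favourable" else min
    judgements: dict[str, ElementJudgement] = {}
    for item in checklist.items:
        for el in item.elements:
            if item.applicability is Applicability.DEVELOPMENT_ONLY:
                judgements[el.element_id] = dev_part.judgements[el.element_id]
            elif item.applicability is Applicability.VALIDATION_ONLY:
                judgements[el.element_id] = val_part.judgements[el.element_id]
            else:
                judgements[el.element_id] = pick(
                    dev_part.judgements[el.element_id],
                    val_part.judgements[el.element_id],
                    key=_FAVOURABILITY.__getitem__,
                )

    flags: dict[str, bool] = {}
    for item_id in checklist.conditional_items:
        in_dev = item_id in dev_part.conditional_applicability
        in_val = item_id in val_part.conditional_applicability
        if in_dev and in_val:
            combine = any if mode == "favourable" else all
            flags[item_id] = combine(
                (
                    dev_part.conditional_applicability[item_id],
                    val_part.conditional_applicability[item_id],
                )
            )
        elif in_dev:
            flags[item_id] = dev_part.conditional_applicability[item_id]
        elif in_val:
            flags[item_id] = val_part.conditional_applicability[item_id]

    metadata = dev_part.metadata
    if metadata is not None and val_part.metadata is not None:
        metadata = replace(
            metadata, sample_size=max(metadata.sample_size, val_part.metadata.sample_size)
        )
    return ModelExtraction(
        model_id=dev_part.model_id,
        publication_id=dev_part.publication_id,
        study_type=StudyType.DEVELOPMENT_AND_VALIDATION,
        judgements=judgements,
        conditional_applicability=flags,
        metadata=metadata,
    )
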