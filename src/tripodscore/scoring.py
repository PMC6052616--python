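"""The three-level adherence scoring procedure.

Scoring runs at three levels:

1. **Item** — a checklist item is completely reported by a model iff *every*
   element of that item is judged ``reported``, ``not_applicable`` (an
   element that cannot apply, e.g. blinding when the outcome is all-cause
   mortality, counts as reported), or — for the items that accept a citation
   in place of repeated text (4b, 5a, 6a, 7a) — ``reported_by_reference``.

2. **Model** — the number of completely reported items divided by the number
   of items scored for that model.  The scored set is the study-type
   applicable set minus the supplementary-information item (21, excluded
   from all calculations) minus any conditional "if done" item flagged
   inapplicable for that model (excluded from numerator and denominator
   alike).

3. **Publication** — for publications carrying a single model, identical to
   the model score.  For publications carrying models of several study
   types, the item universe is the union of the members' scored sets; an
   item counts complete iff it is complete in every member model that scores
   it, except the background (3a) and discussion items (18, 19a, 19b, 20),
   for which completeness in either member suffices.

A fourth view tallies each item *across* models: the number of models
reporting the item completely over the number of models in which the item
was applicable (for item 21 the denominator is the full model count, since
its applicability is unobservable).

Fractions are exact rationals internally; rounding to whole percentages
happens only at presentation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .checklist import Checklist, StudyType, applicable_item_set
from .errors import ApplicabilityError, DegenerateInputError
from .records import (
    AdherenceScore,
    ElementJudgement,
    ModelExtraction,
    PublicationExtraction,
)

__all__ = [
    "ItemAdherence",
    "item_complete",
    "scored_item_set",
    "model_adherence",
    "publication_adherence",
    "item_adherence_across_models",
    "item_adherence_table",
]

_COMPLETE_PLAIN = frozenset({ElementJudgement.REPORTED, ElementJudgement.NOT_APPLICABLE})
_COMPLETE_WITH_REF = _COMPLETE_PLAIN | {ElementJudgement.REPORTED_BY_REFERENCE}


@dataclass(frozen=True)
class ItemAdherence:
    """Per-item tally across a cohort of models."""

    item_id: str
    n_complete: int
    n_applicable: int

    def __post_init__(self) -> None:
        if self.n_complete > self.n_applicable:
            raise ValueError("n_complete cannot exceed n_applicable")

    @property
    def percent(self) -> Optional[float]:
        """Exact percentage, or ``None`` when the item never applied."""
        if self.n_applicable == 0:
            return None
        return 100.0 * self.n_complete / self.n_applicable


def _check_applicable(model: ModelExtraction, item_id: str, checklist: Checklist) -> None:
    study_type = StudyType(model.study_type)
    if item_id not in applicable_item_set(checklist, study_type):
        raise ApplicabilityError(
            f"item {item_id} does not apply to a {study_type.value} model"
        )
    item = checklist.item(item_id)
    flag_driven = item.conditional or (
        study_type is StudyType.INCREMENTAL_VALUE
        and item_id in checklist.incremental_value_partial
    )
    if flag_driven and not model.item_applicable(item_id):
        raise ApplicabilityError(
            f"item {item_id} is flagged not applicable for model {model.model_id!r}"
        )


def item_complete(model: ModelExtraction, item_id: str, checklist: Checklist) -> bool:
    """Whether a model reports every element of an applicable item.

    Raises
    ------
    ApplicabilityError
        If the item is outside the model's applicable set, or flagged
        inapplicable — querying such an item signals an extraction error.
    """
    _check_applicable(model, item_id, checklist)
    item = checklist.item(item_id)
    accepted = _COMPLETE_WITH_REF if item.reference_acceptable else _COMPLETE_PLAIN
    return all(model.judgements[el.element_id] in accepted for el in item.elements)


def scored_item_set(model: ModelExtraction, checklist: Checklist) -> set[str]:
    """The items entering the model's adherence numerator and denominator."""
    study_type = StudyType(model.study_type)
    items = applicable_item_set(checklist, study_type)
    items -= {it.item_id for it in checklist.items if it.excluded_from_scores}
    items -= {i for i in checklist.conditional_items if not model.item_applicable(i)}
    if study_type is StudyType.INCREMENTAL_VALUE:
        items -= {
            i for i in checklist.incremental_value_partial if not model.item_applicable(i)
        }
    return items


def model_adherence(model: ModelExtraction, checklist: Checklist) -> AdherenceScore:
    """Completely reported scored items over scored items, for one model."""
    scored = scored_item_set(model, checklist)
    if not scored:
        raise DegenerateInputError(
            f"model {model.model_id!r} has an empty scored item set"
        )
    n = sum(item_complete(model, i, checklist) for i in scored)
    return AdherenceScore(numerator=n, denominator=len(scored))


def publication_adherence(
    pub: PublicationExtraction, checklist: Checklist
) -> AdherenceScore:
    """Adherence of a publication, combining its study types.

    The item universe is the union of the member models' scored sets; an
    item scored in only one member is judged on that member alone.
    """
    if len(pub.models) == 1:
        return model_adherence(pub.models[0], checklist)
    if not pub.models:
        raise DegenerateInputError(f"publication {pub.publication_id!r} has no models")
    scored_sets = {m.model_id: scored_item_set(m, checklist) for m in pub.models}
    universe = set().union(*scored_sets.values())
    if not universe:
        raise DegenerateInputError(
            f"publication {pub.publication_id!r} has an empty item universe"
        )
    n = 0
    for item_id in universe:
        verdicts = [
            item_complete(m, item_id, checklist)
            for m in pub.models
            if item_id in scored_sets[m.model_id]
        ]
        if checklist.item(item_id).either_type_suffices:
            n += any(verdicts)
        else:
            n += all(verdicts)
    return AdherenceScore(numerator=n, denominator=len(universe))


def item_adherence_across_models(
    models: Sequence[ModelExtraction], item_id: str, checklist: Checklist
) -> ItemAdherence:
    """Tally one item across a cohort of models.

    ``n_applicable`` counts the models whose scored set contains the item;
    for the supplementary-information item (excluded from model scores, and
    with unobservable applicability) the denominator is the total number of
    models carrying it in their study-type set.
    """
    if not models:
        raise DegenerateInputError("empty model cohort")
    item = checklist.item(item_id)
    if item.excluded_from_scores:
        eligible = [
            m
            for m in models
            if item_id in applicable_item_set(checklist, StudyType(m.study_type))
        ]
        n_complete = sum(item_complete(m, item_id, checklist) for m in eligible)
        return ItemAdherence(item_id, n_complete, len(eligible))
    eligible = [m for m in models if item_id in scored_item_set(m, checklist)]
    n_complete = sum(item_complete(m, item_id, checklist) for m in eligible)
    return ItemAdherence(item_id, n_complete, len(eligible))


def item_adherence_table(
    models: Sequence[ModelExtraction],
    checklist: Checklist,
    item_ids: Optional[Iterable[str]] = None,
) -> list[ItemAdherence]:
    """Per-item tallies for every checklist item, in document order."""
    ids = list(item_ids) if item_ids is not None else list(checklist.item_ids)
    return [item_adherence_across_models(models, i, checklist) for i in ids]
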