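"""The TRIPOD checklist as data.

TRIPOD (Transparent Reporting of a multivariable prediction model for
Individual Prognosis Or Diagnosis) is a 22-item reporting guideline for
studies that develop, validate, or extend multivariable clinical prediction
models.  Ten of the main items are split into sub-items (3, 4, 6, 7, 14, 15
and 19 in two; 5 and 13 in three; 10 in five), giving 37 scoreable item
labels.  Each item decomposes into one or more *elements* — atomic pieces of
information an extractor judges as reported or not.

This module encodes the checklist — items, elements, study-type
applicability, conditionality, scoring flags — as a versioned, human-editable
YAML definition, and answers applicability queries:

* six items apply only to model development (10a, 10b, 14a, 14b, 15a, 15b),
* six only to external validation (10c, 10e, 12, 13c, 17, 19a),
* the remaining 25 apply to both,

so a development-only or validation-only study is scored against 31 items, a
combined development-and-validation study against all 37, and an
incremental-value study against 36 (all items except model updating, item 17,
the one item with no incremental-value analogue).

The item *universe* is fixed — a definition file may refine element lists and
flags but cannot invent item labels — because the checklist structure is set
by the guideline itself.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Union

import yaml

from .errors import ChecklistDefinitionError

__all__ = [
    "StudyType",
    "Applicability",
    "ElementSpec",
    "ChecklistItem",
    "Checklist",
    "CANONICAL_ITEM_IDS",
    "load_checklist",
    "save_checklist",
    "applicable_item_set",
    "element_count",
]


class StudyType(str, enum.Enum):
    """The four types of prediction-model study a record can describe."""

    DEVELOPMENT = "development"
    EXTERNAL_VALIDATION = "external_validation"
    INCREMENTAL_VALUE = "incremental_value"
    DEVELOPMENT_AND_VALIDATION = "development_and_validation"


class Applicability(str, enum.Enum):
    """Study-type annotation of an item: development-only, validation-only, or both."""

    DEVELOPMENT_ONLY = "D"
    VALIDATION_ONLY = "V"
    BOTH = "DV"


#: The 37 item labels of the checklist, in document order.
CANONICAL_ITEM_IDS: tuple[str, ...] = (
    "1", "2",
    "3a", "3b",
    "4a", "4b",
    "5a", "5b", "5c",
    "6a", "6b",
    "7a", "7b",
    "8", "9",
    "10a", "10b", "10c", "10d", "10e",
    "11", "12",
    "13a", "13b", "13c",
    "14a", "14b",
    "15a", "15b",
    "16", "17",
    "18",
    "19a", "19b",
    "20", "21", "22",
)


@dataclass(frozen=True)
class ElementSpec:
    """One atomic reporting requirement within a checklist item."""

    element_id: str
    description: str
    parent_item: str


@dataclass(frozen=True)
class ChecklistItem:
    """One scoreable checklist item with its applicability and scoring flags."""

    item_id: str
    main_item: int
    applicability: Applicability
    conditional: bool
    reference_acceptable: bool
    excluded_from_scores: bool
    either_type_suffices: bool
    elements: tuple[ElementSpec, ...]


@dataclass(frozen=True)
class Checklist:
    """A versioned checklist definition.

    Parameters
    ----------
    version
        Free-text version label of the definition file.
    items
        The 37 items in document order.
    incremental_value_excluded
        Items with no incremental-value analogue, removed from the
        incremental-value applicable set (default: item 17).
    incremental_value_partial
        Validation-only items that apply to only some incremental-value
        models; their applicability is recorded per model (default:
        10c, 12, 19a).
    """

    version: str
    items: tuple[ChecklistItem, ...]
    incremental_value_excluded: frozenset[str] = frozenset({"17"})
    incremental_value_partial: frozenset[str] = frozenset({"10c", "12", "19a"})
    _by_id: dict = field(init=False, repr=False, compare=False, hash=False, default=None)

    def __post_init__(self) -> None:
        object.__setattr__(self, "_by_id", {it.item_id: it for it in self.items})

    def item(self, item_id: str) -> ChecklistItem:
        try:
            return self._by_id[item_id]
        except KeyError:
            raise ChecklistDefinitionError(f"unknown item_id {item_id!r}") from None

    def __contains__(self, item_id: str) -> bool:
        return item_id in self._by_id

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(it.item_id for it in self.items)

    @property
    def conditional_items(self) -> frozenset[str]:
        return frozenset(it.item_id for it in self.items if it.conditional)

    def elements_of(self, item_ids: Iterable[str]) -> list[ElementSpec]:
        """All elements of the given items, in document order."""
        wanted = set(item_ids)
        return [el for it in self.items if it.item_id in wanted for el in it.elements]


def _validate(checklist: Checklist) -> None:
    ids = [it.item_id for it in checklist.items]
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ChecklistDefinitionError(f"duplicate item_id(s): {', '.join(dupes)}")
    unknown = [i for i in ids if i not in CANONICAL_ITEM_IDS]
    if unknown:
        raise ChecklistDefinitionError(
            f"item_id(s) outside the checklist universe: {', '.join(unknown)}"
        )
    missing = [i for i in CANONICAL_ITEM_IDS if i not in ids]
    if missing:
        raise ChecklistDefinitionError(f"missing item_id(s): {', '.join(missing)}")
    mains = {it.main_item for it in checklist.items}
    if mains != set(range(1, 23)):
        raise ChecklistDefinitionError("main items must cover 1–22 with no gaps")
    seen_elements: set[str] = set()
    for it in checklist.items:
        if not it.elements:
            raise ChecklistDefinitionError(f"item {it.item_id} has no elements")
        expected_main = int("".join(c for c in it.item_id if c.isdigit()))
        if it.main_item != expected_main:
            raise ChecklistDefinitionError(
                f"item {it.item_id}: main_item {it.main_item} does not match the label"
            )
        for el in it.elements:
            if el.element_id in seen_elements:
                raise ChecklistDefinitionError(
                    f"item {it.item_id}: duplicate element_id {el.element_id!r}"
                )
            seen_elements.add(el.element_id)
            if el.parent_item != it.item_id:
                raise ChecklistDefinitionError(
                    f"element {el.element_id}: parent_item {el.parent_item!r} "
                    f"does not match item {it.item_id}"
                )


def _item_from_mapping(raw: dict) -> ChecklistItem:
    try:
        item_id = str(raw["id"])
        elements = tuple(
            ElementSpec(
                element_id=str(el["id"]),
                description=str(el["description"]),
                parent_item=item_id,
            )
            for el in raw["elements"]
        )
        return ChecklistItem(
            item_id=item_id,
            main_item=int(raw["main_item"]),
            applicability=Applicability(raw["applicability"]),
            conditional=bool(raw.get("conditional", False)),
            reference_acceptable=bool(raw.get("reference_acceptable", False)),
            excluded_from_scores=bool(raw.get("excluded_from_scores", False)),
            either_type_suffices=bool(raw.get("either_type_suffices", False)),
            elements=elements,
        )
    except (KeyError, TypeError, ValueError) as exc:
        label = raw.get("id", "<missing id>") if isinstance(raw, dict) else "<not a mapping>"
        raise ChecklistDefinitionError(f"malformed item {label!r}: {exc}") from exc


def load_checklist(source: Union[str, Path, None] = None) -> Checklist:
    """Load a checklist definition.

    Parameters
    ----------
    source
        Path to a YAML definition file, or ``None`` for the bundled default
        (the TRIPOD statement with the scoring conventions of the adherence
        pipeline).

    Raises
    ------
    ChecklistDefinitionError
        If the file is malformed or violates a checklist invariant; the
        message names the offending item.
    """
    if source is None:
        text = resources.files("tripodscore.data").joinpath("tripod_checklist.yaml").read_text(
            encoding="utf-8"
        )
    else:
        text = Path(source).read_text(encoding="utf-8")
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ChecklistDefinitionError(f"cannot parse definition file: {exc}") from exc
    if not isinstance(raw, dict) or "items" not in raw:
        raise ChecklistDefinitionError("definition must be a mapping with an 'items' list")
    items = tuple(_item_from_mapping(r) for r in raw["items"])
    checklist = Checklist(
        version=str(raw.get("version", "unversioned")),
        items=items,
        incremental_value_excluded=frozenset(
            str(x) for x in raw.get("incremental_value_excluded", ["17"])
        ),
        incremental_value_partial=frozenset(
            str(x) for x in raw.get("incremental_value_partial", ["10c", "12", "19a"])
        ),
    )
    _validate(checklist)
    return checklist


def _item_to_mapping(it: ChecklistItem) -> dict:
    return {
        "id": it.item_id,
        "main_item": it.main_item,
        "applicability": it.applicability.value,
        "conditional": it.conditional,
        "reference_acceptable": it.reference_acceptable,
        "excluded_from_scores": it.excluded_from_scores,
        "either_type_suffices": it.either_type_suffices,
        "elements": [
            {"id": el.element_id, "description": el.description} for el in it.elements
        ],
    }


def save_checklist(checklist: Checklist, path: Union[str, Path]) -> None:
    """Write a checklist definition in canonical YAML (bit-exact round trip)."""
    doc = {
        "version": checklist.version,
        "incremental_value_excluded": sorted(checklist.incremental_value_excluded),
        "incremental_value_partial": sorted(checklist.incremental_value_partial),
        "items": [_item_to_mapping(it) for it in checklist.items],
    }
    text = yaml.safe_dump(doc, sort_keys=False, allow_unicode=True, width=100)
    Path(path).write_text(text, encoding="utf-8")


def applicable_item_set(checklist: Checklist, study_type: StudyType) -> set[str]:
    """Item labels applicable to a study type, before scoring exclusions.

    Development and external validation each map to 31 items, combined
    development-and-validation to all 37, and incremental value to 36.  The
    returned set still contains item 21 and the conditional items; the
    scoring engine removes those.
    """
    study_type = StudyType(study_type)
    if study_type is StudyType.DEVELOPMENT:
        keep = {Applicability.BOTH, Applicability.DEVELOPMENT_ONLY}
        return {it.item_id for it in checklist.items if it.applicability in keep}
    if study_type is StudyType.EXTERNAL_VALIDATION:
        keep = {Applicability.BOTH, Applicability.VALIDATION_ONLY}
        return {it.item_id for it in checklist.items if it.applicability in keep}
    if study_type is StudyType.DEVELOPMENT_AND_VALIDATION:
        return set(checklist.item_ids)
    # incremental value: the full checklist minus the structurally excluded items
    return set(checklist.item_ids) - checklist.incremental_value_excluded


def element_count(checklist: Checklist, item_id: str) -> int:
    """Number of extraction elements of an item (e.g. 4 for the title item)."""
    return len(checklist.item(item_id).elements)
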