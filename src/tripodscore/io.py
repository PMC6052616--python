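"""Reading and writing extraction records.

Two interchange formats are supported:

``csv_long``
    A directory of four UTF-8, RFC-4180 CSV files mirroring the extraction
    form: ``judgements.csv`` (one row per element judgement),
    ``models.csv`` (per-model metadata), ``publications.csv`` (per-publication
    covariates), and ``applicability.csv`` (per-model conditional flags).
``json``
    One JSON file mirroring the record types one-to-one.

Writing is canonical — records sorted by publication, model, item and element
ordinal, stable number formatting — so identical record lists serialize to
byte-identical files and ``read(write(x)) == x``.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Literal, Optional, Sequence, Union

from .checklist import Checklist, StudyType, load_checklist
from .errors import RecordValidationError
from .records import (
    ElementJudgement,
    ModelExtraction,
    ModelMetadata,
    PublicationExtraction,
    ensure_valid,
)

__all__ = ["read_records", "write_records"]

Format = Literal["csv_long", "json"]

_JUDGEMENT_COLUMNS = ["publication_id", "model_id", "study_type", "item_id", "element_id", "judgement"]
_MODEL_COLUMNS = [
    "publication_id", "model_id", "study_type", "clinical_domain", "purpose",
    "sample_size", "n_predictors", "outcome",
]
_PUBLICATION_COLUMNS = ["publication_id", "journal_impact_factor", "prospective_design"]
_APPLICABILITY_COLUMNS = ["publication_id", "model_id", "item_id", "applicable"]


def _element_order(checklist: Checklist) -> dict[str, tuple[int, int]]:
    """element_id -> (item position in document order, element ordinal)."""
    order: dict[str, tuple[int, int]] = {}
    for i, item in enumerate(checklist.items):
        for j, el in enumerate(item.elements):
            order[el.element_id] = (i, j)
    return order


def _item_order(checklist: Checklist) -> dict[str, int]:
    return {item.item_id: i for i, item in enumerate(checklist.items)}


def _sorted_models(pub: PublicationExtraction) -> list[ModelExtraction]:
    return sorted(pub.models, key=lambda m: m.model_id)


def _bool_str(value: bool) -> str:
    return "true" if value else "false"


def _parse_bool(text: str, where: str) -> bool:
    if text == "true":
        return True
    if text == "false":
        return False
    raise RecordValidationError([f"{where}: cannot parse boolean {text!r}"])


# ---------------------------------------------------------------------------
# csv_long


def _write_csv(path: Path, columns: list[str], rows: list[list[str]]) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, quoting=csv.QUOTE_MINIMAL, lineterminator="\r\n")
        writer.writerow(columns)
        writer.writerows(rows)


def _write_csv_long(
    records: Sequence[PublicationExtraction], path: Path, checklist: Checklist
) -> None:
    path.mkdir(parents=True, exist_ok=True)
    el_order = _element_order(checklist)
    it_order = _item_order(checklist)
    pubs = sorted(records, key=lambda p: p.publication_id)

    judgement_rows, model_rows, pub_rows, flag_rows = [], [], [], []
    for pub in pubs:
        pub_rows.append(
            [pub.publication_id, repr(float(pub.journal_impact_factor)),
             _bool_str(pub.prospective_design)]
        )
        for model in _sorted_models(pub):
            meta = model.metadata
            model_rows.append([
                pub.publication_id, model.model_id, model.study_type.value,
                meta.clinical_domain if meta else "",
                meta.purpose if meta else "",
                str(meta.sample_size) if meta else "",
                "" if meta is None or meta.n_predictors is None else str(meta.n_predictors),
                meta.outcome if meta else "",
            ])
            for item_id in sorted(model.conditional_applicability, key=it_order.__getitem__):
                flag_rows.append([
                    pub.publication_id, model.model_id, item_id,
                    _bool_str(model.conditional_applicability[item_id]),
                ])
            for element_id in sorted(model.judgements, key=el_order.__getitem__):
                parent = element_id.rsplit(".", 1)[0]
                judgement_rows.append([
                    pub.publication_id, model.model_id, model.study_type.value,
                    parent, element_id, model.judgements[element_id].value,
                ])

    _write_csv(path / "judgements.csv", _JUDGEMENT_COLUMNS, judgement_rows)
    _write_csv(path / "models.csv", _MODEL_COLUMNS, model_rows)
    _write_csv(path / "publications.csv", _PUBLICATION_COLUMNS, pub_rows)
    _write_csv(path / "applicability.csv", _APPLICABILITY_COLUMNS, flag_rows)


def _read_csv(path: Path, columns: list[str]) -> list[dict[str, str]]:
    if not path.exists():
        raise RecordValidationError([f"{path}: file not found"])
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != columns:
            raise RecordValidationError(
                [f"{path}: expected columns {columns}, found {reader.fieldnames}"]
            )
        return list(reader)


def _read_csv_long(path: Path) -> list[PublicationExtraction]:
    pub_rows = _read_csv(path / "publications.csv", _PUBLICATION_COLUMNS)
    model_rows = _read_csv(path / "models.csv", _MODEL_COLUMNS)
    flag_rows = _read_csv(path / "applicability.csv", _APPLICABILITY_COLUMNS)
    judgement_rows = _read_csv(path / "judgements.csv", _JUDGEMENT_COLUMNS)

    flags: dict[tuple[str, str], dict[str, bool]] = {}
    for row in flag_rows:
        key = (row["publication_id"], row["model_id"])
        where = f"applicability.csv, model {row['model_id']!r}"
        flags.setdefault(key, {})[row["item_id"]] = _parse_bool(row["applicable"], where)

    judgements: dict[tuple[str, str], dict[str, ElementJudgement]] = {}
    for row in judgement_rows:
        key = (row["publication_id"], row["model_id"])
        where = f"judgements.csv, model {row['model_id']!r}, element {row['element_id']!r}"
        try:
            value = ElementJudgement(row["judgement"])
        except ValueError:
            raise RecordValidationError(
                [f"{where}: unknown judgement {row['judgement']!r}"]
            ) from None
        judgements.setdefault(key, {})[row["element_id"]] = value

    models: dict[str, list[ModelExtraction]] = {}
    for row in model_rows:
        where = f"models.csv, model {row['model_id']!r}"
        study_type = _parse_study_type(row["study_type"], where)
        key = (row["publication_id"], row["model_id"])
        meta = None
        if row["clinical_domain"] or row["purpose"] or row["sample_size"]:
            meta = ModelMetadata(
                clinical_domain=row["clinical_domain"],
                purpose=row["purpose"],  # type: ignore[arg-type]
                sample_size=int(row["sample_size"]),
                n_predictors=int(row["n_predictors"]) if row["n_predictors"] else None,
                outcome=row["outcome"],
            )
        models.setdefault(row["publication_id"], []).append(
            ModelExtraction(
                model_id=row["model_id"],
                publication_id=row["publication_id"],
                study_type=study_type,
                judgements=judgements.get(key, {}),
                conditional_applicability=flags.get(key, {}),
                metadata=meta,
            )
        )

    publications = []
    for row in pub_rows:
        pub_id = row["publication_id"]
        publications.append(
            PublicationExtraction(
                publication_id=pub_id,
                journal_impact_factor=float(row["journal_impact_factor"]),
                prospective_design=_parse_bool(
                    row["prospective_design"], f"publications.csv, publication {pub_id!r}"
                ),
                models=tuple(models.get(pub_id, [])),
            )
        )
    orphans = set(models) - {p.publication_id for p in publications}
    if orphans:
        raise RecordValidationError(
            [f"models.csv: model(s) reference unknown publication {pid!r}" for pid in sorted(orphans)]
        )
    return publications


def _parse_study_type(text: str, where: str) -> StudyType:
    try:
        return StudyType(text)
    except ValueError:
        raise RecordValidationError([f"{where}: unknown study_type {text!r}"]) from None


# ---------------------------------------------------------------------------
# json


def _to_json_obj(records: Sequence[PublicationExtraction], checklist: Checklist) -> dict:
    el_order = _element_order(checklist)
    it_order = _item_order(checklist)
    pubs = []
    for pub in sorted(records, key=lambda p: p.publication_id):
        models = []
        for model in _sorted_models(pub):
            meta = model.metadata
            models.append({
                "model_id": model.model_id,
                "study_type": model.study_type.value,
                "metadata": None if meta is None else {
                    "clinical_domain": meta.clinical_domain,
                    "purpose": meta.purpose,
                    "sample_size": meta.sample_size,
                    "n_predictors": meta.n_predictors,
                    "outcome": meta.outcome,
                },
                "conditional_applicability": {
                    k: model.conditional_applicability[k]
                    for k in sorted(model.conditional_applicability, key=it_order.__getitem__)
                },
                "judgements": {
                    k: model.judgements[k].value
                    for k in sorted(model.judgements, key=el_order.__getitem__)
                },
            })
        pubs.append({
            "publication_id": pub.publication_id,
            "journal_impact_factor": float(pub.journal_impact_factor),
            "prospective_design": pub.prospective_design,
            "models": models,
        })
    return {"publications": pubs}


def _from_json_obj(obj: dict) -> list[PublicationExtraction]:
    if not isinstance(obj, dict) or "publications" not in obj:
        raise RecordValidationError(["JSON root must be a mapping with a 'publications' list"])
    publications = []
    for pub in obj["publications"]:
        models = []
        for m in pub.get("models", []):
            where = f"model {m.get('model_id')!r}"
            study_type = _parse_study_type(m.get("study_type", ""), where)
            meta_obj = m.get("metadata")
            meta = None
            if meta_obj is not None:
                meta = ModelMetadata(
                    clinical_domain=meta_obj["clinical_domain"],
                    purpose=meta_obj["purpose"],
                    sample_size=int(meta_obj["sample_size"]),
                    n_predictors=(
                        None if meta_obj.get("n_predictors") is None
                        else int(meta_obj["n_predictors"])
                    ),
                    outcome=meta_obj["outcome"],
                )
            try:
                judgements = {
                    k: ElementJudgement(v) for k, v in m.get("judgements", {}).items()
                }
            except ValueError as exc:
                raise RecordValidationError([f"{where}: {exc}"]) from None
            models.append(
                ModelExtraction(
                    model_id=m["model_id"],
                    publication_id=pub["publication_id"],
                    study_type=study_type,
                    judgements=judgements,
                    conditional_applicability={
                        k: bool(v) for k, v in m.get("conditional_applicability", {}).items()
                    },
                    metadata=meta,
                )
            )
        publications.append(
            PublicationExtraction(
                publication_id=pub["publication_id"],
                journal_impact_factor=float(pub["journal_impact_factor"]),
                prospective_design=bool(pub["prospective_design"]),
                models=tuple(models),
            )
        )
    return publications


# ---------------------------------------------------------------------------
# public API


def write_records(
    records: Sequence[PublicationExtraction],
    path: Union[str, Path],
    format: Format = "csv_long",
    checklist: Optional[Checklist] = None,
    validate: bool = True,
) -> None:
    """Write validated records in canonical form.

    ``csv_long`` writes a directory of four CSV files; ``json`` writes a
    single file.  Output is deterministic: the same records always produce
    byte-identical files.
    """
    checklist = checklist or load_checklist()
    if validate:
        ensure_valid(records, checklist)
    path = Path(path)
    if format == "csv_long":
        _write_csv_long(records, path, checklist)
    elif format == "json":
        obj = _to_json_obj(records, checklist)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(obj, indent=1) + "\n", encoding="utf-8")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_records(
    path: Union[str, Path],
    format: Format = "csv_long",
    checklist: Optional[Checklist] = None,
    validate: bool = True,
) -> list[PublicationExtraction]:
    """Read records and validate them against the checklist.

    Raises :class:`~tripodscore.errors.RecordValidationError` with
    publication/model/element coordinates on any schema violation.
    """
    checklist = checklist or load_checklist()
    path = Path(path)
    if format == "csv_long":
        records = _read_csv_long(path)
    elif format == "json":
        try:
            obj = json.loads(path.read_text(encoding="utf-8"))
        except json.JSONDecodeError as exc:
            raise RecordValidationError([f"{path}: invalid JSON: {exc}"]) from None
        records = _from_json_obj(obj)
    else:
        raise ValueError(f"unknown format {format!r}")
    if validate:
        ensure_valid(records, checklist)
    return records
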