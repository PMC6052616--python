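"""Cohort-level summaries of adherence scores.

Provides the descriptive outputs of a reporting-adherence audit: the
distribution of publication adherence (overall and stratified by prediction
purpose or study-type composition), the per-item ranking with its
well-reported (>= 75%) / poorly reported (< 25%) classification, an
ordinary-least-squares regression of publication adherence on publication
covariates, and deterministic CSV/markdown table rendering.

All percentages are carried as exact values and rounded — half away from
zero — only when a table is rendered.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .checklist import Checklist, StudyType, load_checklist
from .errors import CollinearityError, DegenerateInputError
from .records import PublicationExtraction
from .scoring import ItemAdherence, model_adherence, publication_adherence

__all__ = [
    "AdherenceSummary",
    "CoefficientEstimate",
    "RegressionResult",
    "ItemClassification",
    "round_half_away",
    "summarize_adherence",
    "classify_items",
    "regress_adherence",
    "render_tables",
    "scores_frame",
]

logger = logging.getLogger(__name__)

PercentileMode = Literal["linear", "lower", "higher", "nearest", "midpoint"]


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class AdherenceSummary:
    """Distribution of adherence percentages within one stratum."""

    stratum: str
    n: int
    median: float
    p25: float
    p75: float
    min: float
    max: float


@dataclass(frozen=True)
class CoefficientEstimate:
    slope: float
    std_error: float
    p_value: float


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit of publication adherence (percent) on publication covariates."""

    coefficients: dict[str, CoefficientEstimate]
    intercept: CoefficientEstimate
    n: int


@dataclass(frozen=True)
class ItemClassification:
    """Partition of items into well-reported, poorly reported, and middle."""

    high: tuple[ItemAdherence, ...]
    low: tuple[ItemAdherence, ...]
    middle: tuple[ItemAdherence, ...]


def _percentiles(values: Sequence[float], mode: PercentileMode) -> tuple[float, float, float]:
    arr = np.asarray(values, dtype=float)
    p25, median, p75 = np.percentile(arr, [25.0, 50.0, 75.0], method=mode)
    return float(p25), float(median), float(p75)


def _publication_percent(pub: PublicationExtraction, checklist: Checklist) -> float:
    return publication_adherence(pub, checklist).percent


def _publication_purpose(pub: PublicationExtraction) -> Optional[str]:
    """Purpose of the primary model (the one studied in the largest sample)."""
    with_meta = [m for m in pub.models if m.metadata is not None]
    if not with_meta:
        return None
    primary = max(with_meta, key=lambda m: m.metadata.sample_size)
    return primary.metadata.purpose


def _publication_type_label(pub: PublicationExtraction) -> str:
    if len(pub.models) == 1:
        return StudyType(pub.models[0].study_type).value
    return "multiple"


def summarize_adherence(
    publications: Sequence[PublicationExtraction],
    stratifier: Literal["overall", "purpose", "study_type"] = "overall",
    checklist: Optional[Checklist] = None,
    percentile_mode: PercentileMode = "linear",
) -> list[AdherenceSummary]:
    """Summarise publication adherence within strata.

    Strata are ``overall`` (one summary), ``purpose`` (diagnostic vs
    prognostic, from the primary model), or ``study_type`` (single-type
    publications by their type, multi-type ones under ``multiple``).  Empty
    strata are omitted with a logged warning.
    """
    checklist = checklist or load_checklist()
    if not publications:
        raise DegenerateInputError("no publications to summarise")
    if stratifier == "overall":
        groups: dict[str, list[PublicationExtraction]] = {"overall": list(publications)}
    elif stratifier == "purpose":
        groups = {"diagnostic": [], "prognostic": []}
        for pub in publications:
            purpose = _publication_purpose(pub)
            if purpose is not None:
                groups[purpose].append(pub)
    elif stratifier == "study_type":
        groups = {st.value: [] for st in StudyType}
        groups["multiple"] = []
        for pub in publications:
            groups[_publication_type_label(pub)].append(pub)
    else:
        raise ValueError(f"unknown stratifier {stratifier!r}")

    summaries = []
    for stratum, pubs in groups.items():
        if not pubs:
            logger.warning("stratum %r is empty; omitted from the summary", stratum)
            continue
        percents = [_publication_percent(p, checklist) for p in pubs]
        p25, median, p75 = _percentiles(percents, percentile_mode)
        summaries.append(
            AdherenceSummary(
                stratum=stratum,
                n=len(pubs),
                median=median,
                p25=p25,
                p75=p75,
                min=float(np.min(percents)),
                max=float(np.max(percents)),
            )
        )
    return summaries


def classify_items(
    item_stats: Sequence[ItemAdherence], high: float = 75.0, low: float = 25.0
) -> ItemClassification:
    """Partition items into >= ``high`` %, < ``low`` %, and the middle band.

    Each list is sorted by percent descending; items that never applied
    (undefined percent) fall into the middle band, last.
    """
    if not 0.0 < low < high < 100.0:
        raise ValueError("thresholds must satisfy 0 < low < high < 100")
    hi, lo, mid = [], [], []
    for stat in item_stats:
        if stat.percent is None:
            mid.append(stat)
        elif stat.percent >= high:
            hi.append(stat)
        elif stat.percent < low:
            lo.append(stat)
        else:
            mid.append(stat)
    key = lambda s: (-(s.percent if s.percent is not None else -1.0), s.item_id)
    return ItemClassification(
        high=tuple(sorted(hi, key=key)),
        low=tuple(sorted(lo, key=key)),
        middle=tuple(sorted(mid, key=key)),
    )


_DEFAULT_COVARIATES = (
    "sample_size",
    "journal_impact_factor",
    "n_predictors",
    "prospective_design",
)


def _covariate_frame(
    publications: Sequence[PublicationExtraction],
    checklist: Checklist,
    log_sample_size: bool,
) -> pd.DataFrame:
    rows = []
    for pub in publications:
        with_meta = [m for m in pub.models if m.metadata is not None]
        primary = (
            max(with_meta, key=lambda m: m.metadata.sample_size) if with_meta else None
        )
        rows.append({
            "publication_id": pub.publication_id,
            "adherence_percent": _publication_percent(pub, checklist),
            "journal_impact_factor": pub.journal_impact_factor,
            "prospective_design": float(pub.prospective_design),
            "sample_size": (
                float(primary.metadata.sample_size) if primary else np.nan
            ),
            "n_predictors": (
                float(primary.metadata.n_predictors)
                if primary and primary.metadata.n_predictors is not None
                else np.nan
            ),
        })
    frame = pd.DataFrame(rows).set_index("publication_id")
    if log_sample_size:
        frame["sample_size"] = np.log(frame["sample_size"])
    return frame


def regress_adherence(
    publications: Sequence[PublicationExtraction],
    covariates: Sequence[str] = _DEFAULT_COVARIATES,
    checklist: Optional[Checklist] = None,
    log_sample_size: bool = False,
) -> RegressionResult:
    """OLS of publication adherence percent on publication covariates.

    Uses complete cases only.  Sample size and predictor count come from the
    publication's primary model (largest sample); sample size enters
    untransformed unless ``log_sample_size`` is set.

    Raises
    ------
    CollinearityError
        Naming the involved covariates, if the design matrix is rank
        deficient.
    """
    checklist = checklist or load_checklist()
    frame = _covariate_frame(publications, checklist, log_sample_size)
    cols = list(covariates)
    unknown = [c for c in cols if c not in frame.columns]
    if unknown:
        raise ValueError(f"unknown covariate(s): {', '.join(unknown)}")
    data = frame[["adherence_percent", *cols]].dropna()
    if len(data) < len(cols) + 2:
        raise DegenerateInputError(
            f"need at least {len(cols) + 2} complete-case publications, have {len(data)}"
        )
    X = sm.add_constant(data[cols].to_numpy(), has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        involved = []
        base = np.ones((len(data), 1))
        for j, name in enumerate(cols):
            candidate = np.column_stack([base, data[name].to_numpy()])
            if np.linalg.matrix_rank(candidate) == np.linalg.matrix_rank(base):
                involved.append(name)
            else:
                base = candidate
        if not involved:
            involved = cols
        raise CollinearityError(involved)
    fit = sm.OLS(data["adherence_percent"].to_numpy(), X).fit()
    names = ["const", *cols]
    estimates = {
        name: CoefficientEstimate(
            slope=float(fit.params[i]),
            std_error=float(fit.bse[i]),
            p_value=float(fit.pvalues[i]),
        )
        for i, name in enumerate(names)
    }
    return RegressionResult(
        coefficients={c: estimates[c] for c in cols},
        intercept=estimates["const"],
        n=int(fit.nobs),
    )


def scores_frame(
    publications: Sequence[PublicationExtraction], checklist: Optional[Checklist] = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-model and per-publication score tables."""
    checklist = checklist or load_checklist()
    model_rows, pub_rows = [], []
    for pub in sorted(publications, key=lambda p: p.publication_id):
        for model in sorted(pub.models, key=lambda m: m.model_id):
            score = model_adherence(model, checklist)
            model_rows.append({
                "publication_id": pub.publication_id,
                "model_id": model.model_id,
                "study_type": StudyType(model.study_type).value,
                "numerator": score.numerator,
                "denominator": score.denominator,
                "fraction": float(score.fraction),
            })
        score = publication_adherence(pub, checklist)
        pub_rows.append({
            "publication_id": pub.publication_id,
            "numerator": score.numerator,
            "denominator": score.denominator,
            "fraction": float(score.fraction),
        })
    return pd.DataFrame(model_rows), pd.DataFrame(pub_rows)


def _fmt_percent(value: Optional[float]) -> str:
    return "NA" if value is None else str(round_half_away(value))


def render_tables(
    summaries: Sequence[AdherenceSummary],
    item_stats: Sequence[ItemAdherence],
    out_dir: Union[str, Path],
    regression: Optional[RegressionResult] = None,
    high: float = 75.0,
    low: float = 25.0,
) -> list[Path]:
    """Write the report tables; byte-deterministic for fixed inputs.

    Produces ``adherence_summary.csv``, ``item_adherence.csv``, ``table1.md``
    (the well-/poorly reported item table) and, when a regression result is
    given, ``regression.csv``.  Percentages in rendered tables are integers,
    rounded half away from zero.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    summary_frame = pd.DataFrame(
        [
            {
                "stratum": s.stratum,
                "n": s.n,
                "median": round_half_away(s.median),
                "p25": round_half_away(s.p25),
                "p75": round_half_away(s.p75),
                "min": round_half_away(s.min),
                "max": round_half_away(s.max),
            }
            for s in summaries
        ]
    )
    path = out_dir / "adherence_summary.csv"
    summary_frame.to_csv(path, index=False, lineterminator="\n")
    written.append(path)

    item_frame = pd.DataFrame(
        [
            {
                "item_id": s.item_id,
                "n_complete": s.n_complete,
                "n_applicable": s.n_applicable,
                "percent": _fmt_percent(s.percent),
            }
            for s in item_stats
        ]
    )
    path = out_dir / "item_adherence.csv"
    item_frame.to_csv(path, index=False, lineterminator="\n")
    written.append(path)

    partition = classify_items(item_stats, high=high, low=low)
    lines = [
        f"# Items reported completely in >= {round_half_away(high)}% "
        f"or < {round_half_away(low)}% of models",
        "",
        "| Well reported | % | Poorly reported | % |",
        "| --- | --- | --- | --- |",
    ]
    for i in range(max(len(partition.high), len(partition.low))):
        hi = partition.high[i] if i < len(partition.high) else None
        lo = partition.low[i] if i < len(partition.low) else None
        lines.append(
            "| {} | {} | {} | {} |".format(
                hi.item_id if hi else "",
                _fmt_percent(hi.percent) if hi else "",
                lo.item_id if lo else "",
                _fmt_percent(lo.percent) if lo else "",
            )
        )
    path = out_dir / "table1.md"
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    written.append(path)

    if regression is not None:
        rows = [
            {
                "covariate": "intercept",
                "slope": repr(regression.intercept.slope),
                "std_error": repr(regression.intercept.std_error),
                "p_value": repr(regression.intercept.p_value),
            }
        ]
        rows += [
            {
                "covariate": name,
                "slope": repr(est.slope),
                "std_error": repr(est.std_error),
                "p_value": repr(est.p_value),
            }
            for name, est in regression.coefficients.items()
        ]
        path = out_dir / "regression.csv"
        pd.DataFrame(rows).to_csv(path, index=False, lineterminator="\n")
        written.append(path)
    return written
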