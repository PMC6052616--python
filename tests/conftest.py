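"""Shared fixtures: the default checklist, record builders, seeded cohorts."""

from __future__ import annotations

import pytest

from tripodscore import (
    ElementJudgement,
    GeneratorConfig,
    ModelExtraction,
    ModelMetadata,
    PublicationExtraction,
    StudyType,
    applicable_item_set,
    generate_cohort,
    load_checklist,
)


@pytest.fixture(scope="session")
def checklist():
    return load_checklist()


def build_model(
    checklist,
    study_type=StudyType.DEVELOPMENT,
    judgement=ElementJudgement.REPORTED,
    overrides=None,
    flags=None,
    model_id="m1",
    publication_id="p1",
    sample_size=500,
    n_predictors=5,
    purpose="prognostic",
):
    """A model with uniform judgements, selectively overridden per element."""
    study_type = StudyType(study_type)
    items = applicable_item_set(checklist, study_type)
    judgements = {
        el.element_id: judgement for el in checklist.elements_of(items)
    }
    judgements.update(overrides or {})
    return ModelExtraction(
        model_id=model_id,
        publication_id=publication_id,
        study_type=study_type,
        judgements=judgements,
        conditional_applicability=dict(flags or {}),
        metadata=ModelMetadata(
            clinical_domain="cardiology",
            purpose=purpose,
            sample_size=sample_size,
            n_predictors=n_predictors,
            outcome="disease-specific outcome",
        ),
    )


def build_publication(*models, publication_id="p1", jif=5.0, prospective=True):
    return PublicationExtraction(
        publication_id=publication_id,
        journal_impact_factor=jif,
        prospective_design=prospective,
        models=tuple(models),
    )


@pytest.fixture(scope="session")
def default_cohort(checklist):
    """Default-condition synthetic cohort, fixed seed, shared across tests."""
    return generate_cohort(GeneratorConfig(seed=20260927), checklist)


@pytest.fixture(scope="session")
def big_cohort(checklist):
    """~2300-model cohort for calibration checks (fixed seed)."""
    return generate_cohort(GeneratorConfig(seed=3, n_publications=2000), checklist)
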