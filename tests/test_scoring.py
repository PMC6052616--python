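"""Scoring engine: worked examples, brute-force oracle equivalence on
miniature checklists, and cohort-level invariants."""

from __future__ import annotations

import dataclasses
import itertools
from fractions import Fraction

import numpy as np
import pytest

from tripodscore import (
    ApplicabilityError,
    ElementJudgement,
    ModelExtraction,
    StudyType,
    item_adherence_across_models,
    item_adherence_table,
    item_complete,
    model_adherence,
    publication_adherence,
    scored_item_set,
)
from tripodscore.checklist import (
    Applicability,
    Checklist,
    ChecklistItem,
    ElementSpec,
)
from tripodscore.simulate import GeneratorConfig, generate_cohort_with_composition

from conftest import build_model, build_publication

R = ElementJudgement.REPORTED
NR = ElementJudgement.NOT_REPORTED
NA = ElementJudgement.NOT_APPLICABLE
REF = ElementJudgement.REPORTED_BY_REFERENCE


class TestItemComplete:
    def test_one_missing_element_makes_item_incomplete(self, checklist):
        model = build_model(checklist, overrides={"1.2": NR})
        assert item_complete(model, "1", checklist) is False
        assert item_complete(model, "2", checklist) is True

    def test_reference_counts_for_reference_acceptable_items(self, checklist):
        model = build_model(checklist, overrides={"4b.3": REF})
        assert item_complete(model, "4b", checklist) is True

    def test_not_applicable_element_counts_as_reported(self, checklist):
        # blinding is a non-issue when the outcome is all-cause mortality
        model = build_model(checklist, overrides={"6b.1": NA})
        assert item_complete(model, "6b", checklist) is True

    def test_querying_inapplicable_item_raises(self, checklist):
        dev = build_model(checklist, StudyType.DEVELOPMENT)
        with pytest.raises(ApplicabilityError):
            item_complete(dev, "13c", checklist)
        flagged = build_model(checklist, flags={"11": False})
        with pytest.raises(ApplicabilityError):
            item_complete(flagged, "11", checklist)


class TestScoredItemSet:
    def test_development_with_all_conditionals_applicable(self, checklist):
        model = build_model(checklist)
        scored = scored_item_set(model, checklist)
        assert len(scored) == 30  # 31 applicable − item 21, conditionals retained
        assert "21" not in scored
        assert {"5c", "11", "14b"} <= scored

    def test_development_with_conditionals_flagged_off(self, checklist):
        model = build_model(checklist, flags={"5c": False, "11": False, "14b": False})
        assert len(scored_item_set(model, checklist)) == 27

    def test_external_validation_with_conditionals_flagged_off(self, checklist):
        model = build_model(
            checklist,
            StudyType.EXTERNAL_VALIDATION,
            flags={"10e": False, "11": False, "17": False},
        )
        assert len(scored_item_set(model, checklist)) == 27

    def test_incremental_value_partial_items_flag_driven(self, checklist):
        model = build_model(
            checklist,
            StudyType.INCREMENTAL_VALUE,
            flags={"10c": False, "12": False, "19a": False},
        )
        scored = scored_item_set(model, checklist)
        assert len(scored) == 32  # 36 − item 21 − the three flagged-off items
        assert "17" not in scored

    def test_denominator_bounds_over_a_cohort(self, checklist, default_cohort):
        for pub in default_cohort:
            for model in pub.models:
                d = len(scored_item_set(model, checklist))
                assert 25 - len(checklist.conditional_items) <= d <= 36


class TestModelAndPublicationAdherence:
    def test_all_reported_scores_one(self, checklist):
        assert model_adherence(build_model(checklist), checklist).fraction == 1

    def test_nothing_reported_scores_zero(self, checklist):
        model = build_model(checklist, judgement=NR)
        score = model_adherence(model, checklist)
        assert score.fraction == 0
        assert score.denominator == 30

    def test_fraction_is_exact_rational(self, checklist):
        model = build_model(checklist, overrides={"1.1": NR, "16.2": NR})
        score = model_adherence(model, checklist)
        assert score.fraction == Fraction(28, 30) == Fraction(14, 15)

    def test_single_model_publication_equals_model_adherence(self, checklist):
        model = build_model(checklist, overrides={"9.1": NR})
        pub = build_publication(model)
        assert publication_adherence(pub, checklist) == model_adherence(model, checklist)

    def test_discussion_items_complete_if_complete_in_either_type(self, checklist):
        dev = build_model(
            checklist, StudyType.DEVELOPMENT, overrides={"18.1": NR}, model_id="m1"
        )
        val = build_model(checklist, StudyType.EXTERNAL_VALIDATION, model_id="m2")
        pub = build_publication(dev, val)
        score = publication_adherence(pub, checklist)
        assert score.numerator == score.denominator == 36  # item 18 rescued

    def test_other_items_require_completeness_in_every_type(self, checklist):
        dev = build_model(checklist, StudyType.DEVELOPMENT, model_id="m1")
        val = build_model(
            checklist, StudyType.EXTERNAL_VALIDATION, overrides={"5b.1": NR},
            model_id="m2",
        )
        pub = build_publication(dev, val)
        score = publication_adherence(pub, checklist)
        assert (score.denominator - score.numerator) == 1  # exactly item 5b

    def test_single_model_identity_on_random_cohort(self, checklist, default_cohort):
        for pub in default_cohort:
            if len(pub.models) == 1:
                assert publication_adherence(pub, checklist) == model_adherence(
                    pub.models[0], checklist
                )


@pytest.fixture(scope="module")
def audit_composition_cohort(checklist):
    counts = {
        StudyType.DEVELOPMENT.value: 73,
        StudyType.EXTERNAL_VALIDATION.value: 43,
        StudyType.INCREMENTAL_VALUE.value: 33,
        StudyType.DEVELOPMENT_AND_VALIDATION.value: 21,
    }
    pubs = generate_cohort_with_composition(counts, GeneratorConfig(seed=11), checklist)
    return [m for p in pubs for m in p.models]


class TestItemAdherenceAcrossModels:
    def test_applicability_counts_from_cohort_composition(
        self, checklist, audit_composition_cohort
    ):
        """Unconditional items' denominators are set by composition alone:
        a development-only analysis item applies to 73+33+21 models, a
        validation-only results item to 43+33+21."""
        stat_10a = item_adherence_across_models(audit_composition_cohort, "10a", checklist)
        stat_13c = item_adherence_across_models(audit_composition_cohort, "13c", checklist)
        assert stat_10a.n_applicable == 127
        assert stat_13c.n_applicable == 97

    def test_supplementary_item_uses_total_model_count(
        self, checklist, audit_composition_cohort
    ):
        stat = item_adherence_across_models(audit_composition_cohort, "21", checklist)
        assert stat.n_applicable == 170

    def test_never_applicable_item_flagged_not_divided(self, checklist):
        models = [
            build_model(checklist, flags={"11": False}, model_id=f"m{i}")
            for i in range(3)
        ]
        stat = item_adherence_across_models(models, "11", checklist)
        assert stat.n_applicable == 0
        assert stat.percent is None

    def test_aggregation_consistency(self, checklist, default_cohort):
        """Summing per-item complete counts over scored items equals summing
        per-model numerators."""
        models = [m for p in default_cohort for m in p.models]
        stats = item_adherence_table(models, checklist)
        total_by_item = sum(
            s.n_complete for s in stats if not checklist.item(s.item_id).excluded_from_scores
        )
        total_by_model = sum(model_adherence(m, checklist).numerator for m in models)
        assert total_by_item == total_by_model


# ---------------------------------------------------------------------------
# brute-force oracle equivalence on miniature checklists


def mini_item(item_id, applicability, n_elements, **flags):
    return ChecklistItem(
        item_id=item_id,
        main_item=int(item_id),
        applicability=applicability,
        conditional=flags.get("conditional", False),
        reference_acceptable=flags.get("reference_acceptable", False),
        excluded_from_scores=flags.get("excluded_from_scores", False),
        either_type_suffices=flags.get("either_type_suffices", False),
        elements=tuple(
            ElementSpec(f"{item_id}.{k}", f"element {k}", item_id)
            for k in range(1, n_elements + 1)
        ),
    )


MINI = Checklist(
    version="mini",
    items=(
        mini_item("1", Applicability.BOTH, 2, reference_acceptable=True),
        mini_item("2", Applicability.DEVELOPMENT_ONLY, 1, conditional=True),
        mini_item("3", Applicability.BOTH, 1, excluded_from_scores=True),
    ),
    incremental_value_excluded=frozenset(),
    incremental_value_partial=frozenset(),
)

MINI_PUB = Checklist(
    version="mini-pub",
    items=(
        mini_item("1", Applicability.BOTH, 1, either_type_suffices=True),
        mini_item("2", Applicability.BOTH, 1),
        mini_item("3", Applicability.DEVELOPMENT_ONLY, 1),
    ),
    incremental_value_excluded=frozenset(),
    incremental_value_partial=frozenset(),
)


def oracle_applicable(cl, study_type):
    # direct transcription of the study-type applicability rule
    if study_type is StudyType.DEVELOPMENT:
        keep = {Applicability.BOTH, Applicability.DEVELOPMENT_ONLY}
    elif study_type is StudyType.EXTERNAL_VALIDATION:
        keep = {Applicability.BOTH, Applicability.VALIDATION_ONLY}
    else:
        keep = set(Applicability)
    ids = {it.item_id for it in cl.items if it.applicability in keep}
    if study_type is StudyType.INCREMENTAL_VALUE:
        ids -= cl.incremental_value_excluded
    return ids


def oracle_scored(cl, model):
    scored = set()
    for item_id in oracle_applicable(cl, model.study_type):
        it = cl.item(item_id)
        if it.excluded_from_scores:
            continue
        if it.conditional and not model.conditional_applicability.get(item_id, True):
            continue
        if (
            model.study_type is StudyType.INCREMENTAL_VALUE
            and item_id in cl.incremental_value_partial
            and not model.conditional_applicability.get(item_id, True)
        ):
            continue
        scored.add(item_id)
    return scored


def oracle_complete(cl, model, item_id):
    it = cl.item(item_id)
    ok = {R, NA} | ({REF} if it.reference_acceptable else set())
    return all(model.judgements[el.element_id] in ok for el in it.elements)


def oracle_model_score(cl, model):
    scored = oracle_scored(cl, model)
    return sum(oracle_complete(cl, model, i) for i in scored), len(scored)


def oracle_publication_score(cl, pub):
    universe = set().union(*(oracle_scored(cl, m) for m in pub.models))
    n = 0
    for item_id in universe:
        verdicts = [
            oracle_complete(cl, m, item_id)
            for m in pub.models
            if item_id in oracle_scored(cl, m)
        ]
        n += any(verdicts) if cl.item(item_id).either_type_suffices else all(verdicts)
    return n, len(universe)


def enumerate_models(cl, study_type, publication_id="p", model_id="m"):
    items = sorted(oracle_applicable(cl, study_type))
    elements = [el for i in items for el in cl.item(i).elements]
    conditional = [
        i for i in items if cl.item(i).conditional
    ]
    value_sets = [
        [R, NR, NA] + ([REF] if cl.item(el.parent_item).reference_acceptable else [])
        for el in elements
    ]
    for combo in itertools.product(*value_sets):
        judgements = {el.element_id: v for el, v in zip(elements, combo)}
        for flag_combo in itertools.product([True, False], repeat=len(conditional)):
            yield ModelExtraction(
                model_id=model_id,
                publication_id=publication_id,
                study_type=study_type,
                judgements=judgements,
                conditional_applicability=dict(zip(conditional, flag_combo)),
            )


class TestOracleEquivalence:
    @pytest.mark.parametrize(
        "study_type", [StudyType.DEVELOPMENT, StudyType.EXTERNAL_VALIDATION]
    )
    def test_model_level_exhaustive(self, study_type):
        """Engine output equals a direct evaluation of the scoring
        definitions for every judgement assignment and conditionality flag
        of a miniature checklist."""
        count = 0
        for model in enumerate_models(MINI, study_type):
            assert scored_item_set(model, MINI) == oracle_scored(MINI, model)
            for item_id in scored_item_set(model, MINI):
                assert item_complete(model, item_id, MINI) == oracle_complete(
                    MINI, model, item_id
                )
            score = model_adherence(model, MINI)
            assert (score.numerator, score.denominator) == oracle_model_score(MINI, model)
            count += 1
        assert count > 0

    def test_publication_level_exhaustive(self):
        dev_models = list(enumerate_models(MINI_PUB, StudyType.DEVELOPMENT, model_id="d"))
        val_models = list(
            enumerate_models(MINI_PUB, StudyType.EXTERNAL_VALIDATION, model_id="v")
        )
        for dev, val in itertools.product(dev_models, val_models):
            pub = build_publication(dev, val)
            score = publication_adherence(pub, MINI_PUB)
            assert (score.numerator, score.denominator) == oracle_publication_score(
                MINI_PUB, pub
            )


class TestMonotonicity:
    def test_upgrading_an_element_never_decreases_any_score(
        self, checklist, default_cohort
    ):
        """Flipping a single element from not_reported to reported can only
        raise item, model, publication, and per-item scores."""
        rng = np.random.default_rng(42)
        pubs = list(default_cohort[:30])
        models_all = [m for p in default_cohort for m in p.models]
        for _ in range(40):
            pub = pubs[rng.integers(len(pubs))]
            mi = rng.integers(len(pub.models))
            model = pub.models[mi]
            not_reported = [
                e for e, j in model.judgements.items() if j == ElementJudgement.NOT_REPORTED
            ]
            if not not_reported:
                continue
            element = not_reported[rng.integers(len(not_reported))]
            item_id = element.rsplit(".", 1)[0]
            upgraded_model = dataclasses.replace(
                model,
                judgements={**model.judgements, element: ElementJudgement.REPORTED},
            )
            upgraded_models = tuple(
                upgraded_model if k == mi else m for k, m in enumerate(pub.models)
            )
            upgraded_pub = dataclasses.replace(pub, models=upgraded_models)

            before = model_adherence(model, checklist)
            after = model_adherence(upgraded_model, checklist)
            assert after.fraction >= before.fraction

            assert (
                publication_adherence(upgraded_pub, checklist).fraction
                >= publication_adherence(pub, checklist).fraction
            )

            if item_id in scored_item_set(model, checklist) or item_id == "21":
                others = [m for m in models_all if m is not model]
                stat_before = item_adherence_across_models(
                    others + [model], item_id, checklist
                )
                stat_after = item_adherence_across_models(
                    others + [upgraded_model], item_id, checklist
                )
                assert stat_after.n_complete >= stat_before.n_complete
                assert stat_after.n_applicable == stat_before.n_applicable
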