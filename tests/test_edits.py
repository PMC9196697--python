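import random

import pytest

from cohortcraft.edits import (
    add_concept,
    delete_all_in_criterion,
    delete_concept,
    modification_summary,
    replay,
    search_concepts,
    select_criteria,
    update_concept,
)
from cohortcraft.entities import Lexicon, LexiconEntry, annotate_representation
from cohortcraft.errors import AnnotationConflictError, NotFoundError
from cohortcraft.model import (
    Category,
    Provenance,
    read_criteria_text,
)
from tests.conftest import concept


@pytest.fixture
def dementia_rep():
    lex = Lexicon([
        LexiconEntry("dementia", Category.Condition,
                     concept(4182210, "Dementia", "Condition")),
        LexiconEntry("mood", Category.Condition,
                     concept(4183620, "Mood", "Condition")),
        LexiconEntry("caregiver", Category.Observation,
                     concept(4085802, "Caregiver", "Observation")),
    ])
    text = (
        "Inclusion Criteria:\n"
        "- Dementia of mixed type\n"
        "- Severe liver and kidney dysfunction\n"
        "- on a mood stabilizer\n"
        "- Caregiver available\n"
    )
    return annotate_representation(read_criteria_text(text, "NCT04249869"), lex)


class TestSearchConcepts:
    def test_exact_single_hit(self, catalog):
        hits = search_concepts("Osteoporosis", catalog, mode="exact", k=5)
        assert [c.concept_name for c in hits] == ["Osteoporosis"]

    def test_exact_is_case_insensitive_and_uses_synonyms(self, catalog):
        hits = search_concepts("dementia of MIXED type", catalog, mode="exact")
        assert [c.concept_name for c in hits] == ["Mixed dementia"]

    def test_fuzzy_typo_ranks_target_first(self, catalog):
        hits = search_concepts("mixd dementia", catalog, mode="fuzzy", k=3)
        assert hits[0].concept_name == "Mixed dementia"

    def test_fuzzy_matches_edit_distance_oracle(self, catalog):
        import difflib

        query = "mood stabiliser"
        hits = search_concepts(query, catalog, mode="fuzzy", k=1)
        best = max(
            catalog.rows,
            key=lambda r: max(
                difflib.SequenceMatcher(
                    None, query.lower(), n.lower()
                ).ratio()
                for n in (r.concept.concept_name, *r.synonyms)
            ),
        )
        assert hits[0].concept_id == best.concept.concept_id

    def test_standard_ranked_above_non_standard_at_equal_similarity(self, catalog):
        hits = search_concepts("dementia", catalog, mode="exact", k=5)
        assert [c.standard for c in hits] == [True, False]

    def test_exact_miss_returns_empty(self, catalog):
        assert search_concepts("zzz-nonexistent", catalog, mode="exact") == []

    def test_empty_query_is_an_error(self, catalog):
        with pytest.raises(ValueError):
            search_concepts("  ", catalog)

    def test_k_limits_results(self, catalog):
        assert len(search_concepts("d", catalog, mode="fuzzy", k=2)) == 2


class TestAddConcept:
    def test_add_mixed_dementia_for_unrecognized_span(self, dementia_rep, catalog):
        key = "inclusion:0"
        text = dementia_rep.criterion(key).text
        span = (text.index("mixed type"), text.index("mixed type") + len("mixed type"))
        hit = search_concepts("mixed dementia", catalog, mode="fuzzy", k=1)[0]
        rep2 = add_concept(dementia_rep, key, span, hit, Category.Condition)
        added = [a for a in rep2.annotations[key] if a.provenance is Provenance.human]
        assert len(added) == 1
        assert added[0].surface == "mixed type"
        assert added[0].concepts[0].concept_name == "Mixed dementia"
        assert rep2.edit_log[-1].action.value == "add_concept"

    def test_stack_two_concepts_on_one_span(self, dementia_rep, catalog):
        key = "inclusion:1"
        text = dementia_rep.criterion(key).text
        span = (text.index("liver"), len(text))
        liver = search_concepts("Liver finding", catalog, mode="exact")[0]
        kidney = search_concepts("Kidney disease", catalog, mode="exact")[0]
        rep2 = add_concept(dementia_rep, key, span, liver, Category.Condition)
        rep2 = add_concept(rep2, key, span, kidney, Category.Condition)
        human = [a for a in rep2.annotations[key]
                 if a.provenance is Provenance.human]
        assert len(human) == 2
        assert len(rep2.edit_log) == 2

    def test_partial_overlap_with_human_annotation_conflicts(
        self, dementia_rep, catalog
    ):
        key = "inclusion:1"
        text = dementia_rep.criterion(key).text
        liver = search_concepts("Liver finding", catalog, mode="exact")[0]
        rep2 = add_concept(dementia_rep, key, (7, 12), liver, Category.Condition)
        with pytest.raises(AnnotationConflictError):
            add_concept(rep2, key, (7, len(text)), liver, Category.Condition)

    def test_overlapping_machine_annotation_superseded(self, dementia_rep, catalog):
        key = "inclusion:2"
        text = dementia_rep.criterion(key).text
        span = (text.index("mood"), text.index("mood") + len("mood stabilizer"))
        ms = search_concepts("Mood Stabilizer", catalog, mode="exact")[0]
        rep2 = add_concept(dementia_rep, key, span, ms, Category.Drug)
        surfaces = [a.surface for a in rep2.annotations[key]]
        assert "mood" not in surfaces
        assert "mood stabilizer" in surfaces

    def test_span_outside_text_bounds(self, dementia_rep, catalog):
        ms = search_concepts("Mood Stabilizer", catalog, mode="exact")[0]
        with pytest.raises(ValueError):
            add_concept(dementia_rep, "inclusion:2", (0, 10_000), ms, Category.Drug)

    def test_unknown_criterion_key(self, dementia_rep, catalog):
        ms = search_concepts("Mood Stabilizer", catalog, mode="exact")[0]
        with pytest.raises(NotFoundError):
            add_concept(dementia_rep, "inclusion:99", (0, 4), ms, Category.Drug)


class TestOtherMutations:
    def test_delete_nonqueryable_caregiver(self, dementia_rep):
        key = "inclusion:3"
        ann = next(a for a in dementia_rep.annotations[key]
                   if a.surface.lower() == "caregiver")
        rep2 = delete_concept(dementia_rep, key, ann.annotation_id)
        assert all(a.annotation_id != ann.annotation_id
                   for a in rep2.annotations[key])
        assert rep2.edit_log[-1].action.value == "delete_concept"
        # original untouched (pure function)
        assert any(a.annotation_id == ann.annotation_id
                   for a in dementia_rep.annotations[key])

    def test_delete_all_in_criterion(self, dementia_rep, catalog):
        key = "inclusion:1"
        liver = search_concepts("Liver finding", catalog, mode="exact")[0]
        rep2 = add_concept(dementia_rep, key, (7, 12), liver, Category.Condition)
        rep2 = add_concept(rep2, key, (17, 23), liver.model_copy(
            update={"concept_id": 198124, "concept_name": "Kidney disease"}
        ), Category.Condition)
        rep3 = delete_all_in_criterion(rep2, key)
        assert rep3.annotations[key] == []
        assert len(rep3.edit_log) - len(rep2.edit_log) == 1

    def test_update_concept(self, dementia_rep, catalog):
        key = "inclusion:0"
        ann = next(a for a in dementia_rep.annotations[key] if a.concepts)
        new = search_concepts("Mixed dementia", catalog, mode="exact")[0]
        rep2 = update_concept(dementia_rep, key, ann.annotation_id, new)
        updated = next(a for a in rep2.annotations[key]
                       if a.annotation_id == ann.annotation_id)
        assert updated.concepts == [new]
        assert updated.provenance is Provenance.human

    def test_update_unknown_annotation(self, dementia_rep, catalog):
        new = search_concepts("Mixed dementia", catalog, mode="exact")[0]
        with pytest.raises(NotFoundError):
            update_concept(dementia_rep, "inclusion:0", 999, new)

    def test_select_criteria_retains_document(self, dementia_rep):
        rep2 = select_criteria(dementia_rep, ["inclusion:3"], False)
        assert rep2.criterion("inclusion:3").selected is False
        assert len(rep2.criteria) == len(dementia_rep.criteria)


class TestSummaryAndReplay:
    def test_empty_log_all_zeros(self, dementia_rep):
        summary = modification_summary(dementia_rep)
        assert summary["total"] == 0
        assert all(v == 0 for k, v in summary.items() if k != "total")

    def test_counts_match_actions(self, dementia_rep, catalog):
        key = "inclusion:1"
        liver = search_concepts("Liver finding", catalog, mode="exact")[0]
        rep = add_concept(dementia_rep, key, (7, 12), liver, Category.Condition)
        ann_id = rep.annotations[key][-1].annotation_id
        rep = delete_concept(rep, key, ann_id)
        ann = next(a for a in rep.annotations["inclusion:3"] if a.concepts)
        rep = delete_concept(rep, "inclusion:3", ann.annotation_id)
        summary = modification_summary(rep)
        assert summary["add_concept"] == 1
        assert summary["delete_concept"] == 2
        assert summary["total"] == 3

    @pytest.mark.parametrize("seed", range(5))
    def test_random_sequences_counted_exactly(self, dementia_rep, catalog, seed):
        rng = random.Random(seed)
        rep = dementia_rep
        tally = {"add_concept": 0, "delete_concept": 0, "select_criteria": 0,
                 "delete_all_in_criterion": 0}
        liver = search_concepts("Liver finding", catalog, mode="exact")[0]
        for _ in range(rng.randint(3, 10)):
            action = rng.choice(list(tally))
            if action == "add_concept":
                key = "inclusion:1"
                rep = add_concept(
                    rep, key, (0, 6),
                    liver.model_copy(
                        update={"concept_id": rng.randint(1, 10**6)}
                    ),
                    Category.Condition,
                )
            elif action == "delete_concept":
                candidates = [
                    (k, a.annotation_id)
                    for k, anns in rep.annotations.items() for a in anns
                ]
                if not candidates:
                    continue
                k, aid = rng.choice(candidates)
                rep = delete_concept(rep, k, aid)
            elif action == "select_criteria":
                rep = select_criteria(rep, ["inclusion:0"], rng.random() < 0.5)
            else:
                rep = delete_all_in_criterion(rep, "inclusion:2")
            tally[action] += 1
        summary = modification_summary(rep)
        for action, count in tally.items():
            assert summary[action] == count
        assert summary["total"] == sum(tally.values())

    def test_replay_reproduces_final_state(self, dementia_rep, catalog):
        key = "inclusion:0"
        text = dementia_rep.criterion(key).text
        span = (text.index("mixed type"), text.index("mixed type") + 10)
        mixed = search_concepts("Mixed dementia", catalog, mode="exact")[0]
        liver = search_concepts("Liver finding", catalog, mode="exact")[0]
        kidney = search_concepts("Kidney disease", catalog, mode="exact")[0]
        final = add_concept(dementia_rep, key, span, mixed, Category.Condition)
        k1 = "inclusion:1"
        t1 = final.criterion(k1).text
        s1 = (t1.index("liver"), len(t1))
        final = add_concept(final, k1, s1, liver, Category.Condition)
        final = add_concept(final, k1, s1, kidney, Category.Condition)
        final = select_criteria(final, ["inclusion:3"], False)
        replayed = replay(dementia_rep, final.edit_log)
        assert replayed == final
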