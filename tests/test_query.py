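import random
import sqlite3

import pytest

from cohortcraft.edits import select_criteria
from cohortcraft.entities import annotate_representation
from cohortcraft.errors import EmptyQueryError, SchemaMismatchError
from cohortcraft.fixtures import (
    Plant,
    default_end_to_end_suite,
    generate_omop_lite,
    scenario_lexicon,
)
from cohortcraft.model import (
    Category,
    Comparator,
    CriteriaRepresentation,
    CriterionSentence,
    EntityAnnotation,
    Section,
    TemporalConstraint,
    read_criteria_text,
)
from cohortcraft.query import (
    CriterionClause,
    QueryIR,
    build_query_ir,
    execute_cohort,
    generate_sql,
)
from tests.helpers import brute_force_cohort, random_case, _ref


def simple_rep(section=Section.inclusion, negated=False, cid=101,
               category=Category.Condition):
    text = f"entity {cid}"
    ann = EntityAnnotation(
        annotation_id=0, span=(0, len(text)), surface=text,
        category=category, concepts=[_ref(cid, category)], negated=negated,
    )
    sentence = CriterionSentence(trial_id="NCT1", section=section,
                                 index=0, text=text)
    return CriteriaRepresentation(
        trial_id="NCT1", criteria=[sentence],
        annotations={sentence.key: [ann]}, next_annotation_id=1,
    )


class TestBuildQueryIR:
    def test_measurement_value_clause(self):
        lex_rep = read_criteria_text(
            "Inclusion Criteria:\n- serum creatinine > 2.5 mg/dL", "NCT1"
        )
        from cohortcraft.entities import Lexicon, LexiconEntry
        from tests.conftest import concept

        lex = Lexicon([LexiconEntry("serum creatinine", Category.Measurement,
                                    concept(3016723, "Creatinine", "Measurement"))])
        rep = annotate_representation(lex_rep, lex)
        ir = build_query_ir(rep)
        assert len(ir.inclusion_groups) == 1
        clause = ir.inclusion_groups[0][0]
        assert clause.domain is Category.Measurement
        assert clause.value is not None
        assert clause.value.terms[0].operator is Comparator.gt
        assert float(clause.value.terms[0].value) == 2.5

    def test_plain_inclusion_requires_presence(self):
        ir = build_query_ir(simple_rep())
        clause = ir.inclusion_groups[0][0]
        assert clause.require_presence(Section.inclusion) is True

    @pytest.mark.parametrize(
        "section,negated,presence",
        [
            (Section.inclusion, False, True),
            (Section.inclusion, True, False),
            (Section.exclusion, False, False),
            (Section.exclusion, True, True),
        ],
    )
    def test_section_negation_truth_table(self, section, negated, presence):
        ir = build_query_ir(simple_rep(section=section, negated=negated))
        groups = (ir.inclusion_groups if section is Section.inclusion
                  else ir.exclusion_groups)
        assert groups[0][0].require_presence(section) is presence

    def test_deselected_criteria_excluded(self):
        rep = simple_rep()
        rep = select_criteria(rep, ["inclusion:0"], False)
        with pytest.raises(EmptyQueryError):
            build_query_ir(rep)

    def test_no_queryable_annotations(self):
        rep = read_criteria_text("Inclusion Criteria:\n- generally healthy",
                                 "NCT1")
        with pytest.raises(EmptyQueryError):
            build_query_ir(rep)


class TestGenerateSql:
    def test_condition_clause_has_exists_subquery(self):
        ir = build_query_ir(simple_rep())
        sql = generate_sql(ir)
        assert sql.count("EXISTS (SELECT 1 FROM condition_occurrence") == 1
        assert "NOT EXISTS" not in sql

    def test_absence_clause_uses_not_exists(self):
        ir = build_query_ir(simple_rep(section=Section.exclusion))
        assert "NOT EXISTS" in generate_sql(ir)

    def test_deterministic_text(self):
        ir = build_query_ir(simple_rep())
        assert generate_sql(ir) == generate_sql(ir)

    def test_unsupported_dialect(self):
        ir = build_query_ir(simple_rep())
        with pytest.raises(ValueError, match="dialect"):
            generate_sql(ir, dialect="tsql")

    def test_postgresql_uses_date_subtraction(self):
        clause = CriterionClause(
            domain=Category.Drug, concept_ids=(201,),
            temporal=TemporalConstraint(start_days=30, start_offset=-1,
                                        end_days=0, end_offset=-1),
        )
        ir = QueryIR(inclusion_groups=((clause,),))
        pg = generate_sql(ir, dialect="postgresql")
        assert "julianday" not in pg
        assert "BETWEEN -30 AND 0" in pg
        lite = generate_sql(ir, dialect="sqlite")
        assert "julianday" in lite


class TestExecuteCohort:
    def test_planted_carriers_recovered(self):
        conn, truth = generate_omop_lite(
            10, seed=1,
            plants=[Plant(101, Category.Condition, (1, 2, 3))],
        )
        result = execute_cohort(build_query_ir(simple_rep()), conn)
        assert result.person_ids == truth[101] == {1, 2, 3}

    def test_absent_concept_yields_empty_cohort(self):
        conn, _ = generate_omop_lite(10, seed=1)
        result = execute_cohort(build_query_ir(simple_rep()), conn)
        assert result.rows == []

    def test_demographics_shape_and_age(self):
        conn, _ = generate_omop_lite(
            5, seed=3, plants=[Plant(101, Category.Condition, (4,))]
        )
        result = execute_cohort(build_query_ir(simple_rep()), conn)
        (row,) = result.rows
        assert row.person_id == 4
        birth, index = conn.execute(
            "SELECT p.birth_date, op.observation_period_start_date "
            "FROM person p JOIN observation_period op USING (person_id) "
            "WHERE p.person_id = 4"
        ).fetchone()
        from datetime import date

        expected = int(
            (date.fromisoformat(index) - date.fromisoformat(birth)).days / 365.25
        )
        assert row.age == expected
        assert row.gender in ("M", "F")
        assert row.race

    def test_schema_mismatch_reported(self):
        conn = sqlite3.connect(":memory:")
        conn.execute("CREATE TABLE person (person_id INTEGER)")
        with pytest.raises(SchemaMismatchError) as err:
            execute_cohort(build_query_ir(simple_rep()), conn)
        assert "measurement" in str(err.value)
        assert "person.birth_date" in str(err.value)

    def test_widening_temporal_window_never_shrinks_cohort(self):
        rng = random.Random(42)
        for _ in range(20):
            rep, plants, n = random_case(rng)
            conn, _ = generate_omop_lite(n, seed=rng.randint(0, 10**6),
                                         plants=plants)
            ir = build_query_ir(rep)
            narrow = execute_cohort(ir, conn).person_ids

            def widen(clause):
                if clause.temporal is None:
                    return clause
                return clause.model_copy(update={
                    "temporal": TemporalConstraint(
                        start_days=9999, start_offset=-1,
                        end_days=9999, end_offset=1,
                    )
                })

            wide_ir = QueryIR(
                inclusion_groups=tuple(
                    tuple(widen(c) for c in g) for g in ir.inclusion_groups
                ),
                exclusion_groups=ir.exclusion_groups,
            )
            wide = execute_cohort(wide_ir, conn).person_ids
            if not any(c.negated for g in ir.inclusion_groups for c in g):
                assert narrow <= wide


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(4))
    def test_sql_equals_brute_force(self, seed):
        rng = random.Random(seed)
        for _ in range(60):
            rep, plants, n = random_case(rng)
            conn, _ = generate_omop_lite(n, seed=rng.randint(0, 10**6),
                                         plants=plants)
            ir = build_query_ir(rep)
            assert execute_cohort(ir, conn).person_ids == brute_force_cohort(
                ir, conn
            )
            conn.close()

    def test_monotonicity_adding_inclusion_clause(self):
        rng = random.Random(7)
        for _ in range(20):
            rep, plants, n = random_case(rng)
            conn, _ = generate_omop_lite(n, seed=rng.randint(0, 10**6),
                                         plants=plants)
            ir = build_query_ir(rep)
            base = execute_cohort(ir, conn).person_ids
            extra = CriterionClause(domain=Category.Condition,
                                    concept_ids=(101,))
            grown = QueryIR(
                inclusion_groups=ir.inclusion_groups + ((extra,),),
                exclusion_groups=ir.exclusion_groups,
            )
            assert execute_cohort(grown, conn).person_ids <= base
            conn.close()

    def test_exclusion_symmetry(self):
        conn, truth = generate_omop_lite(
            20, seed=5,
            plants=[Plant(101, Category.Condition, tuple(range(1, 9))),
                    Plant(201, Category.Drug, tuple(range(1, 21)))],
        )
        base_clause = CriterionClause(domain=Category.Drug, concept_ids=(201,))
        target = CriterionClause(domain=Category.Condition, concept_ids=(101,))
        as_inclusion = QueryIR(
            inclusion_groups=((base_clause,), (target,)),
        )
        as_exclusion = QueryIR(
            inclusion_groups=((base_clause,),),
            exclusion_groups=((target,),),
        )
        inc = execute_cohort(as_inclusion, conn).person_ids
        exc = execute_cohort(as_exclusion, conn).person_ids
        assert inc | exc == set(range(1, 21))
        assert inc & exc == set()


class TestEndToEnd:
    @pytest.mark.parametrize("scenario", default_end_to_end_suite(),
                             ids=lambda s: s.name)
    def test_planted_cohort_recovery(self, scenario):
        rep = read_criteria_text(scenario.criteria_text, "NCT1")
        rep = annotate_representation(rep, scenario_lexicon(scenario))
        conn, _ = generate_omop_lite(scenario.n_persons, seed=0,
                                     plants=scenario.plants)
        ir = build_query_ir(rep)
        result = execute_cohort(ir, conn)
        assert result.person_ids == scenario.expected_person_ids
        assert brute_force_cohort(ir, conn) == scenario.expected_person_ids
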