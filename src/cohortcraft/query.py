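"""Compile a criteria representation into cohort queries over an
OMOP-CDM-v5-shaped store, execute them on SQLite, and summarize cohort
demographics.

Semantics
---------
Each selected criterion becomes one clause group.  Within a criterion a
person *matches* if any clinical entity matches (OR-within-criterion),
where a negated entity matches when no qualifying record exists.  A person
enters the cohort when every inclusion criterion matches and no exclusion
criterion matches (AND-across-criteria).  This composition yields the
(section, negated) truth table: inclusion+plain and exclusion+negated
require presence; inclusion+negated and exclusion+plain require absence.

The index date is the person's observation_period_start_date.  Temporal
windows are evaluated as signed day offsets of the record date from the
index date; value constraints compare measurement.value_as_number, with
unit string equality enforced when both sides carry a unit.
"""

from __future__ import annotations

import sqlite3
from datetime import date
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field

from .errors import EmptyQueryError, SchemaMismatchError
from .model import (
    Category,
    CLINICAL_CATEGORIES,
    CriteriaRepresentation,
    Section,
    TemporalConstraint,
    ValueConstraint,
    ValueLogic,
)

#: Clinical domain -> (table, concept column, date column).
DOMAIN_TABLES: dict[Category, tuple[str, str, str]] = {
    Category.Condition: (
        "condition_occurrence", "condition_concept_id", "condition_start_date"
    ),
    Category.Drug: ("drug_exposure", "drug_concept_id", "drug_exposure_start_date"),
    Category.Measurement: (
        "measurement", "measurement_concept_id", "measurement_date"
    ),
    Category.Procedure: (
        "procedure_occurrence", "procedure_concept_id", "procedure_date"
    ),
    Category.Observation: ("observation", "observation_concept_id", "observation_date"),
    Category.Person_attribute: ("person", "", ""),
}

#: OMOP-lite DDL shipped with the package (SQLite flavor; PostgreSQL only
#: differs in affinity keywords for these column types).
OMOP_LITE_DDL = """
CREATE TABLE person (
    person_id INTEGER PRIMARY KEY,
    birth_date TEXT NOT NULL,
    gender TEXT NOT NULL,
    race TEXT NOT NULL,
    gender_concept_id INTEGER NOT NULL DEFAULT 0,
    race_concept_id INTEGER NOT NULL DEFAULT 0
);
CREATE TABLE observation_period (
    person_id INTEGER NOT NULL REFERENCES person(person_id),
    observation_period_start_date TEXT NOT NULL,
    observation_period_end_date TEXT NOT NULL
);
CREATE TABLE condition_occurrence (
    person_id INTEGER NOT NULL REFERENCES person(person_id),
    condition_concept_id INTEGER NOT NULL,
    condition_start_date TEXT NOT NULL
);
CREATE TABLE drug_exposure (
    person_id INTEGER NOT NULL REFERENCES person(person_id),
    drug_concept_id INTEGER NOT NULL,
    drug_exposure_start_date TEXT NOT NULL
);
CREATE TABLE measurement (
    person_id INTEGER NOT NULL REFERENCES person(person_id),
    measurement_concept_id INTEGER NOT NULL,
    measurement_date TEXT NOT NULL,
    value_as_number REAL,
    unit TEXT NOT NULL DEFAULT ''
);
CREATE TABLE procedure_occurrence (
    person_id INTEGER NOT NULL REFERENCES person(person_id),
    procedure_concept_id INTEGER NOT NULL,
    procedure_date TEXT NOT NULL
);
CREATE TABLE observation (
    person_id INTEGER NOT NULL REFERENCES person(person_id),
    observation_concept_id INTEGER NOT NULL,
    observation_date TEXT NOT NULL
);
"""

_REQUIRED_COLUMNS: dict[str, set[str]] = {
    "person": {"person_id", "birth_date", "gender", "race",
               "gender_concept_id", "race_concept_id"},
    "observation_period": {"person_id", "observation_period_start_date"},
    "condition_occurrence": {"person_id", "condition_concept_id",
                             "condition_start_date"},
    "drug_exposure": {"person_id", "drug_concept_id", "drug_exposure_start_date"},
    "measurement": {"person_id", "measurement_concept_id", "measurement_date",
                    "value_as_number", "unit"},
    "procedure_occurrence": {"person_id", "procedure_concept_id", "procedure_date"},
    "observation": {"person_id", "observation_concept_id", "observation_date"},
}

SUPPORTED_DIALECTS = ("sqlite", "postgresql")


class CriterionClause(BaseModel):
    model_config = ConfigDict(frozen=True)

    domain: Category
    concept_ids: tuple[int, ...]
    negated: bool = False
    temporal: Optional[TemporalConstraint] = None
    value: Optional[ValueConstraint] = None

    def require_presence(self, section: Section) -> bool:
        return (section is Section.inclusion) == (not self.negated)


class QueryIR(BaseModel):
    model_config = ConfigDict(frozen=True)

    inclusion_groups: tuple[tuple[CriterionClause, ...], ...] = ()
    exclusion_groups: tuple[tuple[CriterionClause, ...], ...] = ()


class CohortRow(BaseModel):
    model_config = ConfigDict(frozen=True)

    person_id: int
    age: int
    gender: str
    race: str


class CohortResult(BaseModel):
    rows: list[CohortRow] = Field(default_factory=list)

    @property
    def person_ids(self) -> set[int]:
        return {r.person_id for r in self.rows}

    def to_csv(self) -> str:
        lines = ["person_id,age,gender,race"]
        for r in self.rows:
            lines.append(f"{r.person_id},{r.age},{r.gender},{r.race}")
        return "\n".join(lines) + "\n"


def build_query_ir(rep: CriteriaRepresentation) -> QueryIR:
    """Translate selected, concept-bearing criteria into clause groups.

    Value entities attach to the nearest preceding Measurement entity in
    the same criterion; a temporal entity's window attaches to every
    clinical entity in its criterion.
    """
    inclusion: list[tuple[CriterionClause, ...]] = []
    exclusion: list[tuple[CriterionClause, ...]] = []
    for criterion in rep.criteria:
        if not criterion.selected:
            continue
        anns = sorted(rep.annotations_for(criterion.key), key=lambda a: a.span)
        clinical = [
            a for a in anns if a.category in CLINICAL_CATEGORIES and a.concepts
        ]
        if not clinical:
            continue
        temporal = next(
            (a.temporal_constraint for a in anns
             if a.category is Category.Temporal and a.temporal_constraint),
            None,
        )
        # value -> nearest preceding Measurement
        values_for: dict[int, ValueConstraint] = {}
        for ann in anns:
            if ann.category is not Category.Value or ann.value_constraint is None:
                continue
            preceding = [
                c for c in clinical
                if c.category is Category.Measurement and c.span[0] <= ann.span[0]
            ]
            if preceding:
                values_for[preceding[-1].annotation_id] = ann.value_constraint
        group = tuple(
            CriterionClause(
                domain=c.category,
                concept_ids=tuple(sorted({ref.concept_id for ref in c.concepts})),
                negated=c.negated,
                temporal=temporal,
                value=values_for.get(c.annotation_id),
            )
            for c in clinical
        )
        (inclusion if criterion.section is Section.inclusion else exclusion).append(
            group
        )
    if not inclusion and not exclusion:
        raise EmptyQueryError(
            "no selected criterion carries a concept-bearing annotation"
        )
    return QueryIR(
        inclusion_groups=tuple(inclusion), exclusion_groups=tuple(exclusion)
    )


# ---------------------------------------------------------------------------
# SQL generation
# ---------------------------------------------------------------------------


def _day_offset_expr(date_col: str, dialect: str) -> str:
    if dialect == "sqlite":
        return (
            f"CAST(julianday({date_col}) - "
            f"julianday(op.observation_period_start_date) AS INTEGER)"
        )
    return f"({date_col} - op.observation_period_start_date)"


def _value_sql(value: ValueConstraint) -> str:
    parts = [
        f"t.value_as_number {term.operator.value} {term.value}"
        for term in value.terms
    ]
    joiner = " OR " if value.logic is ValueLogic.or_ else " AND "
    expr = f"({joiner.join(parts)})"
    if value.unit:
        expr += f" AND t.unit = '{value.unit}'"
    return expr


def _match_sql(clause: CriterionClause, dialect: str) -> str:
    """SQL for 'a qualifying record exists' (presence form) of one clause."""
    if clause.domain is Category.Person_attribute:
        ids = ", ".join(str(i) for i in clause.concept_ids)
        return (
            f"(p.gender_concept_id IN ({ids}) OR p.race_concept_id IN ({ids}))"
        )
    table, concept_col, date_col = DOMAIN_TABLES[clause.domain]
    conds = [
        "t.person_id = p.person_id",
        f"t.{concept_col} IN ({', '.join(str(i) for i in clause.concept_ids)})",
    ]
    if clause.temporal is not None:
        offset = _day_offset_expr(f"t.{date_col}", dialect)
        conds.append(
            f"{offset} BETWEEN {clause.temporal.signed_start} "
            f"AND {clause.temporal.signed_end}"
        )
    if clause.value is not None and clause.domain is Category.Measurement:
        conds.append(_value_sql(clause.value))
    return f"EXISTS (SELECT 1 FROM {table} t WHERE {' AND '.join(conds)})"


def _clause_sql(clause: CriterionClause, section: Section, dialect: str) -> str:
    match = _match_sql(clause, dialect)
    if clause.require_presence(section):
        return match
    return f"NOT {match}"


def generate_sql(ir: QueryIR, dialect: str = "sqlite") -> str:
    """Render the IR as a single deterministic SELECT statement.

    Inclusion criteria OR their clauses within a group; exclusion criteria
    AND the per-clause required forms (the negation of 'any entity
    matches').
    """
    if dialect not in SUPPORTED_DIALECTS:
        raise ValueError(
            f"unsupported dialect {dialect!r}; expected one of {SUPPORTED_DIALECTS}"
        )
    predicates: list[str] = []
    for group in ir.inclusion_groups:
        exprs = [_clause_sql(c, Section.inclusion, dialect) for c in group]
        predicates.append("(" + " OR ".join(exprs) + ")")
    for group in ir.exclusion_groups:
        exprs = [_clause_sql(c, Section.exclusion, dialect) for c in group]
        predicates.append("(" + " AND ".join(exprs) + ")")
    where = "\n  AND ".join(predicates) if predicates else "1=1"
    return (
        "SELECT p.person_id, p.birth_date, p.gender, p.race,\n"
        "       op.observation_period_start_date AS index_date\n"
        "FROM person p\n"
        "JOIN observation_period op ON op.person_id = p.person_id\n"
        f"WHERE {where}\n"
        "ORDER BY p.person_id"
    )


# ---------------------------------------------------------------------------
# Execution
# ---------------------------------------------------------------------------


def create_schema(conn: sqlite3.Connection) -> None:
    conn.executescript(OMOP_LITE_DDL)
    conn.commit()


def check_schema(conn: sqlite3.Connection) -> None:
    """Raise :class:`SchemaMismatchError` listing missing tables/columns."""
    missing: list[str] = []
    for table, cols in _REQUIRED_COLUMNS.items():
        rows = conn.execute(f"PRAGMA table_info({table})").fetchall()
        if not rows:
            missing.append(table)
            continue
        have = {r[1] for r in rows}
        missing.extend(f"{table}.{c}" for c in sorted(cols - have))
    if missing:
        raise SchemaMismatchError(missing)


def age_at(index_date: str, birth_date: str) -> int:
    """Age in whole years at the index date: floor(days / 365.25)."""
    delta = date.fromisoformat(index_date) - date.fromisoformat(birth_date)
    return int(delta.days / 365.25)


def execute_cohort(ir: QueryIR, conn: sqlite3.Connection) -> CohortResult:
    """Run the generated SQL on an OMOP-lite SQLite store and compute
    demographics (patient ID, age at index, gender, race)."""
    check_schema(conn)
    sql = generate_sql(ir, dialect="sqlite")
    rows = []
    for person_id, birth, gender, race, index_date in conn.execute(sql):
        rows.append(
            CohortRow(
                person_id=person_id,
                age=age_at(index_date, birth),
                gender=gender,
                race=race,
            )
        )
    return CohortResult(rows=rows)
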