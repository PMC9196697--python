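"""Shared test utilities: an independent brute-force cohort oracle and a
random (representation, planted-database) case generator.

The oracle re-implements the cohort semantics directly over Python rows and
never touches the SQL generator, so SQL-vs-oracle comparisons are a genuine
dual-route check.
"""

from __future__ import annotations

import random
import sqlite3
from datetime import date
from decimal import Decimal

from cohortcraft.fixtures import Plant
from cohortcraft.model import (
    Category,
    Comparator,
    ConceptRef,
    CriteriaRepresentation,
    CriterionSentence,
    EntityAnnotation,
    Section,
    TemporalConstraint,
    ValueConstraint,
    ValueLogic,
    ValueTerm,
)
from cohortcraft.query import DOMAIN_TABLES, QueryIR

# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------


def _compare(lhs: float, op: Comparator, rhs: Decimal) -> bool:
    r = float(rhs)
    return {
        Comparator.lt: lhs < r,
        Comparator.le: lhs <= r,
        Comparator.gt: lhs > r,
        Comparator.ge: lhs >= r,
        Comparator.eq: lhs == r,
        Comparator.ne: lhs != r,
    }[op]


def brute_force_cohort(ir: QueryIR, conn: sqlite3.Connection) -> set[int]:
    """Evaluate the IR over all persons in pure Python."""
    persons: dict[int, tuple[int, int, date]] = {}
    for pid, g_cid, r_cid in conn.execute(
        "SELECT person_id, gender_concept_id, race_concept_id FROM person"
    ):
        persons[pid] = (g_cid, r_cid, date(1900, 1, 1))
    for pid, idx in conn.execute(
        "SELECT person_id, observation_period_start_date FROM observation_period"
    ):
        g, r, _ = persons[pid]
        persons[pid] = (g, r, date.fromisoformat(idx))

    records: dict[str, list[tuple]] = {}
    for cat, (table, concept_col, date_col) in DOMAIN_TABLES.items():
        if cat is Category.Person_attribute:
            continue
        if table == "measurement":
            rows = conn.execute(
                "SELECT person_id, measurement_concept_id, measurement_date, "
                "value_as_number, unit FROM measurement"
            ).fetchall()
        else:
            rows = conn.execute(
                f"SELECT person_id, {concept_col}, {date_col}, NULL, '' "
                f"FROM {table}"
            ).fetchall()
        records[table] = rows

    def record_exists(pid: int, clause) -> bool:
        if clause.domain is Category.Person_attribute:
            g_cid, r_cid, _ = persons[pid]
            return g_cid in clause.concept_ids or r_cid in clause.concept_ids
        table = DOMAIN_TABLES[clause.domain][0]
        _, _, index = persons[pid]
        for rpid, cid, rdate, value, unit in records[table]:
            if rpid != pid or cid not in clause.concept_ids:
                continue
            if clause.temporal is not None:
                offset = (date.fromisoformat(rdate) - index).days
                if not (clause.temporal.signed_start <= offset
                        <= clause.temporal.signed_end):
                    continue
            if clause.value is not None and clause.domain is Category.Measurement:
                if value is None:
                    continue
                if clause.value.unit and unit != clause.value.unit:
                    continue
                checks = [_compare(value, t.operator, t.value)
                          for t in clause.value.terms]
                ok = any(checks) if clause.value.logic is ValueLogic.or_ else all(checks)
                if not ok:
                    continue
            return True
        return False

    cohort: set[int] = set()
    for pid in persons:
        eligible = True
        for group in ir.inclusion_groups:
            matches = [
                (not c.negated) == record_exists(pid, c) for c in group
            ]
            if not any(matches):
                eligible = False
                break
        if eligible:
            for group in ir.exclusion_groups:
                if any((not c.negated) == record_exists(pid, c) for c in group):
                    eligible = False
                    break
        if eligible:
            cohort.add(pid)
    return cohort


# ---------------------------------------------------------------------------
# Random cases
# ---------------------------------------------------------------------------

CONCEPT_POOL: list[tuple[int, Category]] = [
    (101, Category.Condition),
    (102, Category.Condition),
    (103, Category.Condition),
    (201, Category.Drug),
    (202, Category.Drug),
    (301, Category.Measurement),
    (302, Category.Measurement),
    (401, Category.Procedure),
    (501, Category.Observation),
]

_OFFSETS = [-400, -60, -20, -5, 0, 5, 20, 200]
_VALUES = [2.0, 5.0, 8.0, 11.0]


def _ref(cid: int, category: Category) -> ConceptRef:
    return ConceptRef(
        concept_id=cid, concept_name=f"concept {cid}",
        domain=category.value, vocabulary="TEST", standard=True,
    )


def random_case(
    rng: random.Random,
) -> tuple[CriteriaRepresentation, list[Plant], int]:
    """A random representation plus a matching planted-database description."""
    n_persons = rng.randint(8, 16)
    chosen = rng.sample(CONCEPT_POOL, rng.randint(2, 5))

    plants: list[Plant] = []
    for cid, category in chosen:
        for _ in range(rng.randint(1, 2)):
            k = rng.randint(0, n_persons)
            carriers = tuple(sorted(rng.sample(range(1, n_persons + 1), k)))
            if not carriers:
                continue
            plants.append(
                Plant(
                    cid, category, carriers,
                    days_from_index=rng.choice(_OFFSETS),
                    value=rng.choice(_VALUES)
                    if category is Category.Measurement else None,
                    unit="",
                )
            )

    criteria: list[CriterionSentence] = []
    annotations: dict[str, list[EntityAnnotation]] = {}
    next_id = 0
    n_criteria = rng.randint(1, 3)
    pool = list(chosen)
    for idx in range(n_criteria):
        section = rng.choice([Section.inclusion, Section.exclusion])
        ents = rng.sample(pool, rng.randint(1, min(2, len(pool))))
        parts: list[tuple[str, Category, int | None]] = [
            (f"entity {cid}", category, cid) for cid, category in ents
        ]
        add_temporal = rng.random() < 0.5
        add_value = any(c is Category.Measurement for _, c in ents) and (
            rng.random() < 0.6
        )
        if add_value:
            parts.append(("value marker", Category.Value, None))
        if add_temporal:
            parts.append(("time marker", Category.Temporal, None))

        text = ", ".join(p[0] for p in parts)
        anns: list[EntityAnnotation] = []
        pos = 0
        for surface, category, cid in parts:
            start = text.index(surface, pos)
            span = (start, start + len(surface))
            pos = span[1]
            kwargs: dict = {}
            if category is Category.Value:
                lo = Decimal(rng.choice(["3", "6", "9"]))
                if rng.random() < 0.5:
                    kwargs["value_constraint"] = ValueConstraint(
                        terms=(ValueTerm(operator=rng.choice(
                            [Comparator.lt, Comparator.le,
                             Comparator.gt, Comparator.ge]), value=lo),),
                        logic=ValueLogic.single,
                    )
                else:
                    kwargs["value_constraint"] = ValueConstraint(
                        terms=(
                            ValueTerm(operator=Comparator.ge, value=lo),
                            ValueTerm(operator=Comparator.le, value=lo + 4),
                        ),
                        logic=ValueLogic.and_,
                    )
            elif category is Category.Temporal:
                bounds = sorted(rng.sample(range(-450, 451), 2))
                kwargs["temporal_constraint"] = TemporalConstraint(
                    start_days=abs(bounds[0]),
                    start_offset=-1 if bounds[0] < 0 else 1,
                    end_days=abs(bounds[1]),
                    end_offset=-1 if bounds[1] < 0 else 1,
                )
            anns.append(
                EntityAnnotation(
                    annotation_id=next_id,
                    span=span,
                    surface=surface,
                    category=category,
                    concepts=[_ref(cid, category)] if cid is not None else [],
                    negated=rng.random() < 0.25
                    if category not in (Category.Value, Category.Temporal)
                    else False,
                    **kwargs,
                )
            )
            next_id += 1
        sentence = CriterionSentence(
            trial_id="NCT00000000", section=section,
            index=sum(1 for c in criteria if c.section is section),
            text=text,
        )
        criteria.append(sentence)
        annotations[sentence.key] = anns

    rep = CriteriaRepresentation(
        trial_id="NCT00000000",
        criteria=criteria,
        annotations=annotations,
        next_annotation_id=next_id,
    )
    return rep, plants, n_persons
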