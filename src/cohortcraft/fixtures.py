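"""Deterministic synthetic fixtures: a criteria corpus with gold
normalizations, and OMOP-lite databases with planted, exactly-known cohorts.

Both generators are seeded and pure: the same (n, seed, spec) always yields
byte-identical output, and every gold label is derived from the template
parameters rather than from the code paths under test.
"""

from __future__ import annotations

import json
import random
import sqlite3
from dataclasses import dataclass, field
from datetime import date, timedelta
from decimal import Decimal
from pathlib import Path
from typing import Optional, Sequence, Union

from .errors import FixtureSpecError
from .model import (
    Category,
    ConceptRef,
    Comparator,
    TemporalConstraint,
    UNBOUNDED_DAYS,
    ValueConstraint,
    ValueLogic,
    ValueTerm,
)
from .negation import default_cue_set
from .temporal import to_days
from .values import default_operator_dictionary

# ---------------------------------------------------------------------------
# Criteria corpus with gold labels
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CorpusItem:
    """One generated sentence plus machine-checkable gold labels.

    kind: "value" | "temporal" | "negation" | "negative_temporal".
    span: the gold entity span inside the sentence (value/temporal kinds).
    gold: the expected constraint, the expected error name (negative cases),
    or for negation a list of (span, expected_negated) pairs.
    """

    sentence: str
    kind: str
    span: Optional[tuple[int, int]] = None
    gold: object = None

    def to_json(self) -> str:
        gold = self.gold
        if isinstance(gold, (ValueConstraint, TemporalConstraint)):
            gold = json.loads(gold.model_dump_json())
        return json.dumps(
            {"sentence": self.sentence, "kind": self.kind,
             "span": self.span, "gold": gold},
            default=str,
        )


def _single(op: str, value: Union[int, str], unit: str = "") -> ValueConstraint:
    return ValueConstraint(
        terms=(ValueTerm(operator=Comparator(op), value=Decimal(str(value))),),
        logic=ValueLogic.single,
        unit=unit,
    )


def _range(a: str, b: str, unit: str = "") -> ValueConstraint:
    return ValueConstraint(
        terms=(
            ValueTerm(operator=Comparator.ge, value=Decimal(a)),
            ValueTerm(operator=Comparator.le, value=Decimal(b)),
        ),
        logic=ValueLogic.and_,
        unit=unit,
    )


_POSTFIX_SYMBOLS = {
    "or higher": ">=", "or more": ">=", "or greater": ">=", "or above": ">=",
    "or over": ">=", "and above": ">=", "and over": ">=",
    "or less": "<=", "or lower": "<=", "or fewer": "<=", "or below": "<=",
    "and under": "<=",
}

_ROMAN_FOR = {1: "I", 2: "II", 3: "III", 4: "IV", 5: "V",
              6: "VI", 7: "VII", 8: "VIII", 9: "IX", 10: "X"}
_WORD_FOR = {2: "two", 3: "three", 4: "four", 5: "five", 6: "six"}

_TIME_UNITS = ("hours", "days", "weeks", "months", "years")


def _value_item(sentence: str, value_text: str, gold: ValueConstraint) -> CorpusItem:
    start = sentence.index(value_text)
    return CorpusItem(sentence, "value", (start, start + len(value_text)), gold)


def _temporal_item(
    sentence: str, temporal_text: str, gold: TemporalConstraint
) -> CorpusItem:
    start = sentence.index(temporal_text)
    return CorpusItem(sentence, "temporal", (start, start + len(temporal_text)), gold)


def _operator_items(rng: random.Random) -> list[CorpusItem]:
    """One sentence per operator-dictionary phrase, placed as the phrase's
    grammar requires (prefix vs postfix); 'within' is exercised in its
    temporal role."""
    items: list[CorpusItem] = []
    ops = default_operator_dictionary()
    for phrase, symbol in sorted(ops.entries.items()):
        x = rng.randint(1, 40)
        if phrase == "within":
            n = rng.randint(1, 60)
            text = f"within {n} days prior to screening"
            gold_t = TemporalConstraint(
                start_days=n, start_offset=-1, end_days=0, end_offset=-1
            )
            items.append(
                _temporal_item(f"Hospitalization {text} is required.", text, gold_t)
            )
            continue
        if phrase in _POSTFIX_SYMBOLS:
            value_text = f"{x} {phrase}"
            sentence = f"Tumor grade of {value_text} at baseline."
            items.append(_value_item(sentence, value_text, _single(symbol, x)))
        else:
            value_text = f"{phrase} {x} g/dL"
            sentence = f"Hemoglobin {value_text} at screening."
            items.append(
                _value_item(sentence, value_text, _single(symbol, x, "g/dL"))
            )
    return items


def _special_value_items(rng: random.Random) -> list[CorpusItem]:
    items = []
    # percent: one "%" scales both range bounds, or a single value
    a = rng.randint(10, 40)
    b = a + rng.randint(1, 30)
    items.append(
        _value_item(
            f"Ejection fraction {a}-{b}% on echocardiogram.",
            f"{a}-{b}%",
            _range(str(Decimal(a) / 100), str(Decimal(b) / 100)),
        )
    )
    x = rng.randint(1, 99)
    items.append(
        _value_item(f"Blasts {x}% in bone marrow.", f"{x}%",
                    _single("=", str(Decimal(x) / 100))),
    )
    # Roman numerals
    n = rng.randint(2, 4)
    items.append(
        _value_item(
            f"NYHA class {_ROMAN_FOR[n]} or higher.",
            f"{_ROMAN_FOR[n]} or higher",
            _single(">=", n),
        )
    )
    # "+" suffix
    n = rng.randint(1, 3)
    items.append(
        _value_item(f"ECOG performance status {n}+ required.", f"{n}+",
                    _single(">=", n))
    )
    # word-form number
    n = rng.randint(2, 6)
    items.append(
        _value_item(
            f"Received {_WORD_FOR[n]} or more doses previously.",
            f"{_WORD_FOR[n]} or more doses",
            _single(">=", n, "doses"),
        )
    )
    # unit-denominator trap: the 24 must not become a value
    items.append(
        _value_item("Proteinuria 3 g/24-hours on collection.", "3 g/24-hours",
                    _single("=", 3, "g/24-hours"))
    )
    # explicit range with "between ... and"
    a = rng.randint(1, 5)
    b = a + rng.randint(1, 5)
    items.append(
        _value_item(
            f"Serum creatinine between {a} and {b} mg/dL.",
            f"between {a} and {b} mg/dL",
            _range(str(a), str(b), "mg/dL"),
        )
    )
    # joined comparisons
    a, b = rng.randint(1, 4), rng.randint(8, 12)
    vc = ValueConstraint(
        terms=(
            ValueTerm(operator=Comparator.lt, value=Decimal(a)),
            ValueTerm(operator=Comparator.gt, value=Decimal(b)),
        ),
        logic=ValueLogic.or_,
        unit="mmol/L",
    )
    items.append(
        _value_item(f"Potassium < {a} or > {b} mmol/L.", f"< {a} or > {b} mmol/L", vc)
    )
    return items


def _temporal_items(rng: random.Random) -> list[CorpusItem]:
    items = []
    for unit in _TIME_UNITS:
        n = rng.randint(1, 12)
        d = to_days(n, unit)
        text = f"within {n} {unit} prior to enrollment"
        items.append(
            _temporal_item(
                f"Positive test {text}.", text,
                TemporalConstraint(start_days=d, start_offset=-1,
                                   end_days=0, end_offset=-1),
            )
        )
        text = f"at least {n} {unit} before randomization"
        items.append(
            _temporal_item(
                f"Prior chemotherapy {text}.", text,
                TemporalConstraint(start_days=UNBOUNDED_DAYS, start_offset=-1,
                                   end_days=d, end_offset=-1),
            )
        )
        m = n + rng.randint(1, 6)
        text = f"{n} to {m} {unit} after surgery"
        items.append(
            _temporal_item(
                f"Follow-up visit {text}.", text,
                TemporalConstraint(start_days=d, start_offset=+1,
                                   end_days=to_days(m, unit), end_offset=+1),
            )
        )
    # hour-unit regression: ">72 h" class expressions stay 3 whole days
    text = "within 72 hours prior to informed consent"
    items.append(
        _temporal_item(
            f"Positive diagnostic assay {text}.", text,
            TemporalConstraint(start_days=3, start_offset=-1,
                               end_days=0, end_offset=-1),
        )
    )
    return items


def _negation_items(rng: random.Random) -> list[CorpusItem]:
    conditions = [
        "active hepatitis", "renal impairment", "metastatic disease",
        "uncontrolled hypertension", "severe anemia",
    ]
    items = []
    for cue in sorted(default_cue_set().cues):
        cond = rng.choice(conditions)
        sentence = f"Asthma patients {cue} {cond}."
        c0 = sentence.index("Asthma")
        s = sentence.index(cond)
        items.append(
            CorpusItem(
                sentence, "negation",
                gold=[((c0, c0 + len("Asthma")), False),
                      ((s, s + len(cond)), True)],
            )
        )
    # clause boundary: scope stops at ", with"
    sentence = "No history of lupus, with stable renal function required."
    items.append(
        CorpusItem(
            sentence, "negation",
            gold=[
                ((sentence.index("lupus"), sentence.index("lupus") + 5), True),
                ((sentence.index("renal function"),
                  sentence.index("renal function") + len("renal function")), False),
            ],
        )
    )
    # missing terminal period: the trailing entity is still in scope
    sentence = "Known history of autoimmune disease except prior thyroiditis"
    items.append(
        CorpusItem(
            sentence, "negation",
            gold=[
                ((sentence.index("autoimmune disease"),
                  sentence.index("autoimmune disease") + len("autoimmune disease")),
                 False),
                ((sentence.index("thyroiditis"),
                  sentence.index("thyroiditis") + len("thyroiditis")), True),
            ],
        )
    )
    return items


def _negative_items() -> list[CorpusItem]:
    return [
        CorpusItem("Currently enrolled in another study.", "negative_temporal",
                   gold="NoTimeSpanError"),
        CorpusItem("Hospitalized since January 1, 2020.", "negative_temporal",
                   gold="DateLiteralError"),
        CorpusItem("Prior treatment before the study.", "negative_temporal",
                   gold="NoTimeSpanError"),
    ]


def generate_criteria_corpus(n: int, seed: int) -> list[CorpusItem]:
    """Generate ``n`` sentences with gold labels.

    The first items deterministically cover every rule family (every
    operator-dictionary phrase, every time unit, every negation cue, the
    known error-analysis traps, and the excluded categories as negative
    cases); remaining slots are filled with randomized variants.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = random.Random(seed)
    base = (
        _operator_items(rng)
        + _special_value_items(rng)
        + _temporal_items(rng)
        + _negation_items(rng)
        + _negative_items()
    )
    items = base[:n]
    while len(items) < n:
        extra = rng.choice(
            [_special_value_items, _temporal_items]
        )(rng)
        items.extend(extra[: n - len(items)])
    return items


def write_corpus_jsonl(items: Sequence[CorpusItem], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for item in items:
            fh.write(item.to_json() + "\n")


# ---------------------------------------------------------------------------
# OMOP-lite databases with planted cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Plant:
    """One planted clinical fact: ``concept_id`` records in ``domain`` for
    the given carriers, at a controlled day offset from each person's index
    date, optionally with a measurement value/unit."""

    concept_id: int
    domain: Category
    carriers: tuple[int, ...]
    days_from_index: int = 0
    value: Optional[float] = None
    unit: str = ""


_GENDERS = (("M", 8507), ("F", 8532))
_RACES = (("White", 8527), ("Black or African American", 8516),
          ("Asian", 8515), ("Other", 8522))


def generate_omop_lite(
    n_persons: int,
    seed: int,
    plants: Sequence[Plant] = (),
    conn: Optional[sqlite3.Connection] = None,
) -> tuple[sqlite3.Connection, dict[int, set[int]]]:
    """Create an OMOP-lite SQLite database with ``n_persons`` persons and
    the given planted facts.

    Returns the connection and the ground truth: concept_id -> exact carrier
    set.  Person ids run 1..n_persons; each person's index date is their
    observation_period_start_date.
    """
    from .query import create_schema

    if n_persons < 1:
        raise ValueError("n_persons must be >= 1")
    for plant in plants:
        bad = [p for p in plant.carriers if not (1 <= p <= n_persons)]
        if bad:
            raise FixtureSpecError(
                f"plant {plant.concept_id} references persons {bad} outside "
                f"1..{n_persons}"
            )
        if len(set(plant.carriers)) > n_persons:
            raise FixtureSpecError(
                f"plant {plant.concept_id} has more carriers than persons"
            )

    rng = random.Random(seed)
    if conn is None:
        conn = sqlite3.connect(":memory:")
    create_schema(conn)

    index_dates: dict[int, date] = {}
    for pid in range(1, n_persons + 1):
        birth = date(rng.randint(1930, 2004), rng.randint(1, 12), rng.randint(1, 28))
        gender, gender_cid = rng.choice(_GENDERS)
        race, race_cid = rng.choice(_RACES)
        index = date(2020, 1, 1) + timedelta(days=rng.randint(0, 364))
        index_dates[pid] = index
        conn.execute(
            "INSERT INTO person VALUES (?, ?, ?, ?, ?, ?)",
            (pid, birth.isoformat(), gender, race, gender_cid, race_cid),
        )
        conn.execute(
            "INSERT INTO observation_period VALUES (?, ?, ?)",
            (pid, index.isoformat(),
             (index + timedelta(days=730)).isoformat()),
        )

    truth: dict[int, set[int]] = {}
    for plant in plants:
        truth.setdefault(plant.concept_id, set()).update(plant.carriers)
        table, concept_col, date_col = _plant_table(plant.domain)
        for pid in plant.carriers:
            rec_date = (index_dates[pid]
                        + timedelta(days=plant.days_from_index)).isoformat()
            if table == "measurement":
                conn.execute(
                    "INSERT INTO measurement VALUES (?, ?, ?, ?, ?)",
                    (pid, plant.concept_id, rec_date, plant.value, plant.unit),
                )
            else:
                conn.execute(
                    f"INSERT INTO {table} (person_id, {concept_col}, {date_col}) "
                    "VALUES (?, ?, ?)",
                    (pid, plant.concept_id, rec_date),
                )
    conn.commit()
    return conn, truth


def _plant_table(domain: Category) -> tuple[str, str, str]:
    from .query import DOMAIN_TABLES

    if domain not in DOMAIN_TABLES or domain is Category.Person_attribute:
        raise FixtureSpecError(f"cannot plant records for domain {domain}")
    return DOMAIN_TABLES[domain]


def dump_tables_csv(conn: sqlite3.Connection, out_dir: str | Path) -> list[Path]:
    """Dump every OMOP-lite table as an uncompressed CSV file."""
    import csv as _csv

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    tables = [r[0] for r in conn.execute(
        "SELECT name FROM sqlite_master WHERE type='table' ORDER BY name"
    )]
    for table in tables:
        path = out_dir / f"{table}.csv"
        cur = conn.execute(f"SELECT * FROM {table}")
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = _csv.writer(fh)
            writer.writerow([d[0] for d in cur.description])
            writer.writerows(cur)
        written.append(path)
    return written


# ---------------------------------------------------------------------------
# End-to-end scenarios: criteria text + lexicon + planted DB + expected cohort
# ---------------------------------------------------------------------------


@dataclass
class EndToEndScenario:
    name: str
    criteria_text: str
    lexicon_rows: list[tuple[str, Category, ConceptRef]]
    n_persons: int
    plants: list[Plant]
    expected_person_ids: set[int] = field(default_factory=set)


def _concept(cid: int, name: str, domain: str) -> ConceptRef:
    return ConceptRef(
        concept_id=cid, concept_name=name, domain=domain,
        vocabulary="SNOMED", standard=True,
    )


def default_end_to_end_suite(seed: int = 0) -> list[EndToEndScenario]:
    """Scenarios whose expected cohorts are derived by set algebra over the
    planted carrier sets, independently of the query pipeline."""
    rng = random.Random(seed)
    n = 60
    everyone = set(range(1, n + 1))

    diabetes = set(rng.sample(sorted(everyone), 30))
    high_a1c = set(rng.sample(sorted(everyone), 28))
    low_a1c = everyone - high_a1c
    metformin_recent = set(rng.sample(sorted(everyone), 25))
    metformin_old = set(rng.sample(sorted(everyone - metformin_recent), 15))
    pregnant = set(rng.sample(sorted(everyone), 10))

    s1 = EndToEndScenario(
        name="diabetes-a1c-metformin",
        criteria_text=(
            "Inclusion Criteria:\n"
            "- Type 2 diabetes\n"
            "- Hemoglobin A1c > 7.5\n"
            "- Metformin within 90 days prior to screening\n"
            "Exclusion Criteria:\n"
            "- Pregnancy\n"
        ),
        lexicon_rows=[
            ("type 2 diabetes", Category.Condition,
             _concept(201826, "Type 2 diabetes mellitus", "Condition")),
            ("hemoglobin a1c", Category.Measurement,
             _concept(3004410, "Hemoglobin A1c measurement", "Measurement")),
            ("metformin", Category.Drug, _concept(1503297, "metformin", "Drug")),
            ("pregnancy", Category.Condition,
             _concept(4299535, "Pregnancy", "Condition")),
        ],
        n_persons=n,
        plants=[
            Plant(201826, Category.Condition, tuple(sorted(diabetes))),
            Plant(3004410, Category.Measurement, tuple(sorted(high_a1c)),
                  value=9.0),
            Plant(3004410, Category.Measurement, tuple(sorted(low_a1c)),
                  value=6.0),
            Plant(1503297, Category.Drug, tuple(sorted(metformin_recent)),
                  days_from_index=-30),
            Plant(1503297, Category.Drug, tuple(sorted(metformin_old)),
                  days_from_index=-200),
            Plant(4299535, Category.Condition, tuple(sorted(pregnant))),
        ],
        expected_person_ids=(
            diabetes & high_a1c & metformin_recent
        ) - pregnant,
    )

    hepatitis = set(rng.sample(sorted(everyone), 20))
    colonoscopy = set(rng.sample(sorted(everyone), 35))
    s2 = EndToEndScenario(
        name="negated-inclusion",
        criteria_text=(
            "Inclusion Criteria:\n"
            "- Colonoscopy at least 14 days before enrollment\n"
            "- No active hepatitis\n"
        ),
        lexicon_rows=[
            ("colonoscopy", Category.Procedure,
             _concept(4249893, "Colonoscopy", "Procedure")),
            ("active hepatitis", Category.Condition,
             _concept(4028244, "Active hepatitis", "Condition")),
        ],
        n_persons=n,
        plants=[
            Plant(4249893, Category.Procedure, tuple(sorted(colonoscopy)),
                  days_from_index=-60),
            Plant(4028244, Category.Condition, tuple(sorted(hepatitis))),
        ],
        expected_person_ids=colonoscopy - hepatitis,
    )
    return [s1, s2]


def scenario_lexicon(scenario: EndToEndScenario):
    from .entities import Lexicon, LexiconEntry

    return Lexicon(
        [LexiconEntry(surface, cat, concept)
         for surface, cat, concept in scenario.lexicon_rows]
    )
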