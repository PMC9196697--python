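"""Domain types and the JSON criteria-representation document.

The representation is a versioned JSON document holding the criterion
sentences of one trial (split into inclusion/exclusion sections), the entity
annotations attached to each sentence, and an append-only edit log.  All
other modules operate on these types.

Offsets are 0-based half-open character offsets into the criterion text.
Decimal values are carried as :class:`decimal.Decimal` end to end so that
normalized values like ``0.344`` round-trip exactly.
"""

from __future__ import annotations

import enum
import re
from decimal import Decimal
from typing import Any, Optional

from pydantic import (
    BaseModel,
    ConfigDict,
    Field,
    field_validator,
    model_validator,
)

SCHEMA_VERSION = 1

#: Sentinel used for an unbounded temporal lookback/lookahead, in days.
UNBOUNDED_DAYS = 9999


class Section(str, enum.Enum):
    inclusion = "inclusion"
    exclusion = "exclusion"


class Category(str, enum.Enum):
    Condition = "Condition"
    Drug = "Drug"
    Measurement = "Measurement"
    Procedure = "Procedure"
    Observation = "Observation"
    Person_attribute = "Person_attribute"
    Value = "Value"
    Temporal = "Temporal"
    Negation_cue = "Negation_cue"


#: Categories that carry mapped concepts and map to a clinical-domain table.
CLINICAL_CATEGORIES = frozenset(
    {
        Category.Condition,
        Category.Drug,
        Category.Measurement,
        Category.Procedure,
        Category.Observation,
        Category.Person_attribute,
    }
)


class Provenance(str, enum.Enum):
    machine = "machine"
    human = "human"


class ConceptRef(BaseModel):
    model_config = ConfigDict(frozen=True)

    concept_id: int = Field(gt=0)
    concept_name: str
    domain: str
    vocabulary: str
    standard: bool


class TemporalConstraint(BaseModel):
    """An index-date-relative window: the event starts between
    ``start_offset * start_days`` and ``end_offset * end_days`` days from the
    index start date, with offset ``-1`` meaning *before* and ``+1`` *after*.
    """

    model_config = ConfigDict(frozen=True)

    start_days: int = Field(ge=0)
    start_offset: int
    end_days: int = Field(ge=0)
    end_offset: int

    @field_validator("start_offset", "end_offset")
    @classmethod
    def _offset_sign(cls, v: int) -> int:
        if v not in (-1, 1):
            raise ValueError("offset must be -1 (before) or +1 (after)")
        return v

    @model_validator(mode="after")
    def _non_empty_window(self) -> "TemporalConstraint":
        if self.signed_start > self.signed_end:
            raise ValueError(
                f"empty temporal window: signed start {self.signed_start} > "
                f"signed end {self.signed_end}"
            )
        return self

    @property
    def signed_start(self) -> int:
        return self.start_offset * self.start_days

    @property
    def signed_end(self) -> int:
        return self.end_offset * self.end_days


class Comparator(str, enum.Enum):
    lt = "<"
    le = "<="
    gt = ">"
    ge = ">="
    eq = "="
    ne = "<>"


class ValueTerm(BaseModel):
    model_config = ConfigDict(frozen=True)

    operator: Comparator
    value: Decimal


class ValueLogic(str, enum.Enum):
    and_ = "and"
    or_ = "or"
    single = "single"


class ValueConstraint(BaseModel):
    model_config = ConfigDict(frozen=True)

    terms: tuple[ValueTerm, ...]
    logic: ValueLogic
    unit: str = ""

    @model_validator(mode="after")
    def _logic_consistent(self) -> "ValueConstraint":
        if not self.terms:
            raise ValueError("terms must be non-empty")
        if (self.logic is ValueLogic.single) != (len(self.terms) == 1):
            raise ValueError("logic must be 'single' iff there is exactly one term")
        return self


class EntityAnnotation(BaseModel):
    annotation_id: int = Field(ge=0)
    span: tuple[int, int]
    surface: str
    category: Category
    concepts: list[ConceptRef] = Field(default_factory=list)
    negated: bool = False
    provenance: Provenance = Provenance.machine
    value_constraint: Optional[ValueConstraint] = None
    temporal_constraint: Optional[TemporalConstraint] = None

    @model_validator(mode="after")
    def _check(self) -> "EntityAnnotation":
        start, end = self.span
        if not (0 <= start < end):
            raise ValueError(f"invalid span {self.span}")
        if self.category in (Category.Value, Category.Temporal, Category.Negation_cue):
            if self.concepts:
                raise ValueError(
                    f"{self.category.value} entities must not carry concepts"
                )
        return self


class CriterionSentence(BaseModel):
    trial_id: str
    section: Section
    index: int = Field(ge=0)
    text: str
    selected: bool = True

    @field_validator("text")
    @classmethod
    def _non_blank(cls, v: str) -> str:
        if not v.strip():
            raise ValueError("criterion text must be non-empty")
        return v

    @property
    def key(self) -> str:
        return criterion_key(self.section, self.index)


def criterion_key(section: Section | str, index: int) -> str:
    """Stable string key ``"<section>:<index>"`` used to attach annotations."""
    section = Section(section)
    return f"{section.value}:{index}"


class EditAction(str, enum.Enum):
    add_concept = "add_concept"
    update_concept = "update_concept"
    delete_concept = "delete_concept"
    delete_all_in_criterion = "delete_all_in_criterion"
    select_criteria = "select_criteria"


class ModificationEvent(BaseModel):
    action: EditAction
    criterion_key: str
    payload: dict[str, Any] = Field(default_factory=dict)
    timestamp: int = Field(ge=0, description="monotonic sequence number")
    actor: str = "anonymous"


class CriteriaRepresentation(BaseModel):
    schema_version: int = SCHEMA_VERSION
    trial_id: str
    criteria: list[CriterionSentence] = Field(default_factory=list)
    annotations: dict[str, list[EntityAnnotation]] = Field(default_factory=dict)
    edit_log: list[ModificationEvent] = Field(default_factory=list)
    warnings: list[str] = Field(default_factory=list)
    next_annotation_id: int = 0

    @model_validator(mode="after")
    def _check(self) -> "CriteriaRepresentation":
        seen: set[tuple[str, Section, int]] = set()
        by_key: dict[str, CriterionSentence] = {}
        for c in self.criteria:
            ident = (c.trial_id, c.section, c.index)
            if ident in seen:
                raise ValueError(f"duplicate criterion {ident}")
            seen.add(ident)
            by_key[c.key] = c
        for key, anns in self.annotations.items():
            if key not in by_key:
                raise ValueError(f"annotation key {key!r} has no criterion")
            text = by_key[key].text
            for ann in anns:
                start, end = ann.span
                if end > len(text):
                    raise ValueError(
                        f"annotation {ann.annotation_id} span {ann.span} exceeds "
                        f"criterion {key!r} length {len(text)}"
                    )
                if text[start:end] != ann.surface:
                    raise ValueError(
                        f"annotation {ann.annotation_id} surface "
                        f"{ann.surface!r} != text slice {text[start:end]!r}"
                    )
        ts = [e.timestamp for e in self.edit_log]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("edit_log timestamps must be strictly increasing")
        return self

    def criterion(self, key: str) -> CriterionSentence:
        for c in self.criteria:
            if c.key == key:
                return c
        from .errors import NotFoundError

        raise NotFoundError(f"no criterion with key {key!r}")

    def annotations_for(self, key: str) -> list[EntityAnnotation]:
        return self.annotations.get(key, [])


# ---------------------------------------------------------------------------
# Free-text splitting
# ---------------------------------------------------------------------------

_HEADER_RE = re.compile(r"(inclusion|exclusion)\s+criteria\s*:?", re.IGNORECASE)
_BULLET_RE = re.compile(r"^\s*(?:[-*•·−]+|\(?\d{1,2}[.)])\s+")
# Period followed by whitespace and a capital; decimals ("12.0 g/dL") survive.
_SENT_RE = re.compile(r"(?<=\.)\s+(?=[A-Z])")


def _split_sentences(block: str) -> list[str]:
    out: list[str] = []
    for line in block.splitlines():
        line = _BULLET_RE.sub("", line).strip()
        if not line:
            continue
        for sent in _SENT_RE.split(line):
            sent = sent.strip()
            if sent:
                out.append(sent)
    return out


def read_criteria_text(text: str, trial_id: str) -> CriteriaRepresentation:
    """Split a free-text criteria block into a :class:`CriteriaRepresentation`.

    Sections are delimited by ``Inclusion Criteria`` / ``Exclusion Criteria``
    headers (case-insensitive).  If neither header is present the whole text
    is treated as inclusion criteria and a warning is recorded.
    """
    if not text.strip():
        raise ValueError("criteria text must be non-empty")

    warnings: list[str] = []
    matches = list(_HEADER_RE.finditer(text))
    segments: list[tuple[Section, str]] = []
    if not matches:
        warnings.append(
            "no 'Inclusion Criteria'/'Exclusion Criteria' header found; "
            "treating the whole text as inclusion criteria"
        )
        segments.append((Section.inclusion, text))
    else:
        if matches[0].start() > 0:
            head = text[: matches[0].start()]
            if head.strip():
                warnings.append(
                    "text before the first section header treated as inclusion"
                )
                segments.append((Section.inclusion, head))
        for m, nxt in zip(matches, matches[1:] + [None]):
            end = nxt.start() if nxt is not None else len(text)
            segments.append((Section(m.group(1).lower()), text[m.end() : end]))

    criteria: list[CriterionSentence] = []
    counters = {Section.inclusion: 0, Section.exclusion: 0}
    for section, block in segments:
        for sent in _split_sentences(block):
            criteria.append(
                CriterionSentence(
                    trial_id=trial_id,
                    section=section,
                    index=counters[section],
                    text=sent,
                )
            )
            counters[section] += 1
    return CriteriaRepresentation(trial_id=trial_id, criteria=criteria, warnings=warnings)


def write_json(rep: CriteriaRepresentation) -> str:
    """Serialize to the versioned JSON document (UTF-8 text)."""
    return rep.model_dump_json(indent=2)


def read_json(doc: str | bytes) -> CriteriaRepresentation:
    """Parse and validate a JSON document produced by :func:`write_json`.

    Raises :class:`pydantic.ValidationError`, whose message names the
    offending path, on any schema violation.
    """
    return CriteriaRepresentation.model_validate_json(doc)
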