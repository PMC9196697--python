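"""Lexicon/pattern-based entity recognition.

The default recognizer is deterministic: clinical entities come from a
user-supplied lexicon (longest match first, case-insensitive, on token
boundaries), value entities from number/operator patterns, temporal
entities from number+time-unit patterns, and negation cues from the cue
dictionary.  The recognizer sits behind a plain function interface so a
learned model can be substituted.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from . import negation, temporal, values
from .errors import ParseError
from .model import (
    Category,
    CLINICAL_CATEGORIES,
    ConceptRef,
    CriteriaRepresentation,
    CriterionSentence,
    EntityAnnotation,
    Provenance,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LexiconEntry:
    surface_form: str  # lowercased
    category: Category
    concept: Optional[ConceptRef] = None


@dataclass
class Lexicon:
    entries: list[LexiconEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, Category]] = set()
        normalized = []
        for e in self.entries:
            key = (e.surface_form.lower(), e.category)
            if key in seen:
                raise ValueError(f"duplicate lexicon entry {key}")
            seen.add(key)
            normalized.append(
                LexiconEntry(e.surface_form.lower(), e.category, e.concept)
            )
        self.entries = normalized

    @classmethod
    def from_csv(cls, path: str | Path) -> "Lexicon":
        """Columns: surface_form, category, concept_id, concept_name, domain,
        vocabulary, standard.  Concept columns may be blank."""
        entries = []
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                concept = None
                if row.get("concept_id"):
                    concept = ConceptRef(
                        concept_id=int(row["concept_id"]),
                        concept_name=row["concept_name"],
                        domain=row["domain"],
                        vocabulary=row.get("vocabulary", ""),
                        standard=str(row.get("standard", "")).strip().lower()
                        in ("1", "true", "s", "yes"),
                    )
                entries.append(
                    LexiconEntry(
                        row["surface_form"].lower(),
                        Category(row["category"]),
                        concept,
                    )
                )
        return cls(entries)


@dataclass(frozen=True)
class _Candidate:
    start: int
    end: int
    category: Category
    concepts: tuple[ConceptRef, ...] = ()
    # lower ranks win at equal length
    rank: int = 0


# number (digit/word/roman) reused from the value scanner
_QUALIFIER = r"(?:at\s+least|within|up\s+to|more\s+than|less\s+than|no\s+more\s+than|a\s+minimum\s+of)"
_TUNIT = r"(?:hours?|hrs?|h|days?|d|weeks?|wks?|months?|mos?|years?|yrs?)"
_DIRECTION = r"(?:prior\s+to|before|preceding|after|post|following|since)"
_NUMTOK = r"(?:\d+(?:\.\d+)?|[A-Za-z]+(?:-[A-Za-z]+)?)"

_TEMPORAL_RE = re.compile(
    rf"(?:{_QUALIFIER}\s+|[<>]=?\s*)?"
    rf"{_NUMTOK}[\s-]*{_TUNIT}\b"
    rf"(?:\s*(?:-|to)\s*{_NUMTOK}[\s-]*{_TUNIT}\b)?"
    rf"(?:\s+{_DIRECTION}\b)?",
    re.IGNORECASE,
)

_OPPHRASE = (
    r"(?:>=|<=|<>|[<>=≥≤]|at\s+least|at\s+most|up\s+to|more\s+than|less\s+than|"
    r"greater\s+than|fewer\s+than|no\s+more\s+than|no\s+less\s+than|over|under|"
    r"a\s+minimum\s+of|a\s+maximum\s+of)"
)
_POSTFIX = (
    r"(?:\s+(?:or|and)\s+(?:higher|more|greater|less|lower|fewer|above|below|"
    r"over|under|better|worse))"
)
_UNIT_TOKEN = r"(?:[A-Za-z%µμ][\w%µμ]*(?:[/-][\w%µμ]+)*)"

_VALUE_RE = re.compile(
    rf"(?:{_OPPHRASE}\s*)?"
    rf"{_NUMTOK}"
    rf"(?:\s*(?:-|to)\s*{_NUMTOK})?"
    rf"\s*%?\+?"
    rf"{_POSTFIX}?"
    rf"(?:\s*{_UNIT_TOKEN})?",
    re.IGNORECASE,
)

# words that look like units but are ordinary English; a trailing token in
# this set is not captured as part of a value span
_UNIT_STOPWORDS = frozenset(
    """a an and at by for from in into of on or per the to with within was were
    is are be been being has have had will would study visit screening patients
    subjects prior before after post following since during history presence
    who than""".split()
)


def _token_boundaries(text: str) -> set[int]:
    bounds = {0, len(text)}
    for m in re.finditer(r"[A-Za-z0-9]+", text):
        bounds.add(m.start())
        bounds.add(m.end())
    return bounds


def _lexicon_candidates(text: str, lexicon: Lexicon) -> Iterable[_Candidate]:
    low = text.lower()
    by_span: dict[tuple[int, int, Category], list[ConceptRef]] = {}
    for entry in lexicon.entries:
        pattern = rf"(?<![A-Za-z0-9]){re.escape(entry.surface_form)}(?![A-Za-z0-9])"
        for m in re.finditer(pattern, low):
            key = (m.start(), m.end(), entry.category)
            by_span.setdefault(key, [])
            if entry.concept is not None:
                by_span[key].append(entry.concept)
    for (start, end, category), concepts in by_span.items():
        yield _Candidate(start, end, category, tuple(concepts), rank=0)


def _trim_value_span(text: str, start: int, end: int) -> tuple[int, int]:
    """Drop a trailing ordinary-English token wrongly captured as a unit."""
    m = re.search(rf"\s*({_UNIT_TOKEN})$", text[start:end])
    if m and m.group(1).lower() in _UNIT_STOPWORDS | set(
        temporal._UNIT_ALIASES
    ):
        end = start + m.start()
    return start, end


def _pattern_candidates(text: str) -> Iterable[_Candidate]:
    for m in _TEMPORAL_RE.finditer(text):
        # require a real duration inside (the number-word alternation is loose)
        if temporal._scan_durations(m.group()):
            yield _Candidate(m.start(), m.end() - _trailing_ws(m.group()),
                             Category.Temporal, rank=1)
    for m in _VALUE_RE.finditer(text):
        if values.scan_numbers(m.group()):
            start, end = _trim_value_span(text, m.start(), m.end())
            if values.scan_numbers(text[start:end]):
                yield _Candidate(start, end - _trailing_ws(text[start:end]),
                                 Category.Value, rank=2)
    for start, end in negation.detect_negation_cues(text):
        yield _Candidate(start, end, Category.Negation_cue, rank=3)


def _trailing_ws(s: str) -> int:
    return len(s) - len(s.rstrip())


def recognize_entities(
    sentence: CriterionSentence,
    lexicon: Lexicon,
    start_id: int = 0,
) -> list[EntityAnnotation]:
    """Recognize entities in one criterion sentence.

    Longest match wins; at equal length lexicon entities beat temporal,
    temporal beat value, value beat cue candidates.  Returned spans never
    overlap and are sorted by start offset.  Annotation ids are assigned
    sequentially from ``start_id``.
    """
    if not lexicon.entries:
        raise ValueError("lexicon must be non-empty")
    text = sentence.text
    candidates = list(_lexicon_candidates(text, lexicon))
    candidates.extend(_pattern_candidates(text))
    candidates.sort(key=lambda c: (-(c.end - c.start), c.rank, c.start))

    chosen: list[_Candidate] = []
    for cand in candidates:
        if cand.end <= cand.start:
            continue
        if any(cand.start < c.end and cand.end > c.start for c in chosen):
            continue
        chosen.append(cand)
    chosen.sort(key=lambda c: c.start)

    out = []
    for i, cand in enumerate(chosen):
        out.append(
            EntityAnnotation(
                annotation_id=start_id + i,
                span=(cand.start, cand.end),
                surface=text[cand.start : cand.end],
                category=cand.category,
                concepts=list(cand.concepts),
                provenance=Provenance.machine,
            )
        )
    return out


def annotate_representation(
    rep: CriteriaRepresentation,
    lexicon: Lexicon,
    cue_set: Optional[negation.NegationCueSet] = None,
) -> CriteriaRepresentation:
    """Full machine pass: recognize entities in every criterion, normalize
    value/temporal entities into constraints (failures leave the constraint
    unset and record a warning), then set negation flags."""
    out = rep.model_copy(deep=True)
    next_id = out.next_annotation_id
    for criterion in out.criteria:
        anns = recognize_entities(criterion, lexicon, start_id=next_id)
        next_id += len(anns)
        for ann in anns:
            if ann.category is Category.Value:
                try:
                    ann.value_constraint = values.normalize_value(ann.surface)
                except ParseError as exc:
                    out.warnings.append(
                        f"{criterion.key}: value {ann.surface!r} not normalized: {exc}"
                    )
            elif ann.category is Category.Temporal:
                try:
                    ann.temporal_constraint = temporal.normalize_temporal(ann.surface)
                except ParseError as exc:
                    out.warnings.append(
                        f"{criterion.key}: temporal {ann.surface!r} not normalized: {exc}"
                    )
        out.annotations[criterion.key] = anns
    out.next_annotation_id = next_id
    return negation.apply_negation(out, cue_set)
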