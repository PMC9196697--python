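"""Negation cue detection, word-level scope labeling, and entity-level
aggregation by label-frequency voting.

The word-level labeler is a deterministic clause-boundary rule: words after
a cue are in scope until the sentence ends, a semicolon occurs, or a comma
is immediately followed by a coordinating word.  It sits behind the same
word-label interface a learned scope model would use, so the aggregation
step is independent of how labels are produced.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass
from importlib import resources as importlib_resources
from typing import Optional, Sequence

from .errors import TokenizationMismatchError
from .model import Category, CriteriaRepresentation, EntityAnnotation


class ScopeLabel(str, enum.Enum):
    in_scope = "in_scope"
    out_of_scope = "out_of_scope"


@dataclass(frozen=True)
class WordScopeLabel:
    word_index: int
    label: ScopeLabel


@dataclass(frozen=True)
class Token:
    start: int
    end: int
    text: str


class NegationCueSet:
    """Set of negation cues (multi-word allowed), matched on word boundaries."""

    #: Cues that must always be present in any configured cue set.
    REQUIRED = frozenset(
        {
            "not", "no", "without", "except", "other than", "free of",
            "absence of", "exclude", "excluding", "neither", "nor",
        }
    )

    def __init__(self, cues: set[str]):
        cues = {c.strip().lower() for c in cues if c.strip()}
        missing = self.REQUIRED - cues
        if missing:
            raise ValueError(f"cue set missing required cues: {sorted(missing)}")
        self.cues = cues
        self._ordered = sorted(cues, key=len, reverse=True)

    @classmethod
    def default(cls) -> "NegationCueSet":
        ref = importlib_resources.files("cohortcraft.resources") / "negation_cues.txt"
        lines = ref.read_text(encoding="utf-8").splitlines()
        return cls({ln for ln in lines if ln.strip() and not ln.startswith("#")})


_DEFAULT_CUES: Optional[NegationCueSet] = None


def default_cue_set() -> NegationCueSet:
    global _DEFAULT_CUES
    if _DEFAULT_CUES is None:
        _DEFAULT_CUES = NegationCueSet.default()
    return _DEFAULT_CUES


_TERMINATORS = (".", "!", "?", ";")


def ensure_terminal_period(sentence_text: str) -> str:
    """Append a period when the sentence lacks terminal punctuation.

    Criteria bullets routinely omit the final period, which pushes
    trailing entities out of an earlier cue's scope; this preprocessing is
    applied unconditionally before scope labeling.
    """
    if sentence_text.endswith(_TERMINATORS):
        return sentence_text
    return sentence_text + "."


def detect_negation_cues(
    sentence_text: str, cue_set: Optional[NegationCueSet] = None
) -> list[tuple[int, int]]:
    """All non-overlapping cue occurrences; the longest cue wins at a
    position.  Returns character spans, left to right."""
    cue_set = cue_set or default_cue_set()
    low = sentence_text.lower()
    spans: list[tuple[int, int]] = []
    for cue in cue_set._ordered:
        pattern = rf"\b{re.escape(cue)}\b"
        for m in re.finditer(pattern, low):
            if not any(m.start() < e and m.end() > s for s, e in spans):
                spans.append((m.start(), m.end()))
    spans.sort()
    return spans


def tokenize(sentence_text: str) -> list[Token]:
    """Whitespace tokenization keeping punctuation attached, so clause
    boundaries (trailing ``,``/``;``) stay visible on the token."""
    return [
        Token(m.start(), m.end(), m.group())
        for m in re.finditer(r"\S+", sentence_text)
    ]


#: Words that, straight after a comma, terminate a negation scope.
CLAUSE_BOUNDARY_WORDS = frozenset(
    {"with", "and", "or", "but", "within", "while", "whereas"}
)


def label_word_scope(
    sentence_tokens: Sequence[Token], cue_spans: Sequence[tuple[int, int]]
) -> list[WordScopeLabel]:
    """One label per token: in scope iff the token follows a cue and no
    clause boundary intervenes.

    Boundaries: end of sentence, ``;``, or ``,`` immediately followed by a
    coordinating word (``with``, ``and``, ``or``, ``but``, ``within``,
    ``while``, ``whereas``).  Scope extends rightward only.
    """
    labels = [ScopeLabel.out_of_scope] * len(sentence_tokens)
    for cue_start, cue_end in cue_spans:
        i = 0
        while i < len(sentence_tokens) and sentence_tokens[i].start < cue_end:
            i += 1
        while i < len(sentence_tokens):
            tok = sentence_tokens[i]
            word = tok.text.strip(".,;:!?").lower()
            prev = sentence_tokens[i - 1] if i > 0 else None
            if (
                prev is not None
                and prev.text.endswith(",")
                and word in CLAUSE_BOUNDARY_WORDS
            ):
                break
            labels[i] = ScopeLabel.in_scope
            if tok.text.endswith((";", ".", "!", "?")):
                break
            i += 1
    return [WordScopeLabel(i, lab) for i, lab in enumerate(labels)]


def words_for_span(
    tokens: Sequence[Token], span: tuple[int, int]
) -> list[int]:
    """Indices of tokens overlapping a character span."""
    start, end = span
    return [i for i, t in enumerate(tokens) if t.start < end and t.end > start]


def aggregate_entity_scope(
    word_labels: Sequence[WordScopeLabel],
    entity_span: tuple[int, int],
    tokens: Sequence[Token],
) -> bool:
    """Entity-level negation by majority vote over the entity's word labels;
    a 50/50 tie counts as in scope (negated)."""
    idx = words_for_span(tokens, entity_span)
    if not idx:
        raise TokenizationMismatchError(
            f"entity span {entity_span} maps to zero word tokens"
        )
    by_index = {wl.word_index: wl.label for wl in word_labels}
    in_count = sum(1 for i in idx if by_index.get(i) is ScopeLabel.in_scope)
    out_count = len(idx) - in_count
    return in_count >= out_count


def apply_negation(
    rep: CriteriaRepresentation, cue_set: Optional[NegationCueSet] = None
) -> CriteriaRepresentation:
    """Set the negated flag of every non-cue entity in the representation.

    Pure and idempotent: labels are recomputed from the sentence text, so a
    second application yields an identical document.
    """
    cue_set = cue_set or default_cue_set()
    out = rep.model_copy(deep=True)
    for criterion in out.criteria:
        anns = out.annotations.get(criterion.key)
        if not anns:
            continue
        text = ensure_terminal_period(criterion.text)
        tokens = tokenize(text)
        cues = detect_negation_cues(text, cue_set)
        labels = label_word_scope(tokens, cues)
        for ann in anns:
            if ann.category is Category.Negation_cue:
                ann.negated = False
                continue
            ann.negated = aggregate_entity_scope(labels, ann.span, tokens)
    return out
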