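"""Human-in-the-loop modification of a criteria representation.

Every mutating operation is a pure function: it returns a new
representation with the change applied and one :class:`ModificationEvent`
appended to the edit log.  Replaying the log on the machine-parsed baseline
reproduces the final document exactly, which gives undo-by-replay for free.

Concept lookup is served by a local catalog with the same exact/fuzzy
contract an online vocabulary service would provide.
"""

from __future__ import annotations

import csv
import difflib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .errors import AnnotationConflictError, NotFoundError
from .model import (
    Category,
    ConceptRef,
    CriteriaRepresentation,
    EditAction,
    EntityAnnotation,
    ModificationEvent,
    Provenance,
)


# ---------------------------------------------------------------------------
# Concept catalog + search
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CatalogRow:
    concept: ConceptRef
    synonyms: tuple[str, ...] = ()


@dataclass
class ConceptCatalog:
    rows: list[CatalogRow] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.concept.concept_id for r in self.rows]
        if len(ids) != len(set(ids)):
            raise ValueError("concept_id must be unique in the catalog")

    @classmethod
    def from_csv(cls, path: str | Path) -> "ConceptCatalog":
        """Columns: concept_id, concept_name, domain, vocabulary, standard,
        synonyms (pipe-delimited)."""
        rows = []
        with open(path, newline="", encoding="utf-8") as fh:
            for r in csv.DictReader(fh):
                concept = ConceptRef(
                    concept_id=int(r["concept_id"]),
                    concept_name=r["concept_name"],
                    domain=r["domain"],
                    vocabulary=r.get("vocabulary", ""),
                    standard=str(r.get("standard", "")).strip().lower()
                    in ("1", "true", "s", "yes"),
                )
                syns = tuple(
                    s.strip() for s in (r.get("synonyms") or "").split("|") if s.strip()
                )
                rows.append(CatalogRow(concept, syns))
        return cls(rows)


def _similarity(a: str, b: str) -> float:
    return difflib.SequenceMatcher(None, a.lower(), b.lower()).ratio()


def search_concepts(
    query: str,
    catalog: ConceptCatalog,
    mode: str = "fuzzy",
    k: int = 10,
) -> list[ConceptRef]:
    """Rank catalog concepts against a query.

    exact: case-insensitive full-string match on name or any synonym.
    fuzzy: normalized edit-similarity; ties broken standard-concepts-first,
    then by ascending concept_id.
    """
    if not query.strip():
        raise ValueError("query must be non-empty")
    if not catalog.rows:
        raise ValueError("catalog must be non-empty")
    if mode not in ("exact", "fuzzy"):
        raise ValueError(f"unknown search mode {mode!r}")
    if k < 1:
        raise ValueError("k must be >= 1")

    q = query.strip().lower()
    scored: list[tuple[float, int, int, ConceptRef]] = []
    for row in catalog.rows:
        names = (row.concept.concept_name, *row.synonyms)
        if mode == "exact":
            if any(n.lower() == q for n in names):
                scored.append(
                    (1.0, 0 if row.concept.standard else 1,
                     row.concept.concept_id, row.concept)
                )
        else:
            sim = max(_similarity(q, n) for n in names)
            scored.append(
                (sim, 0 if row.concept.standard else 1,
                 row.concept.concept_id, row.concept)
            )
    scored.sort(key=lambda t: (-t[0], t[1], t[2]))
    return [c for _, _, _, c in scored[:k]]


# ---------------------------------------------------------------------------
# Mutating operations
# ---------------------------------------------------------------------------


def _append_event(
    rep: CriteriaRepresentation,
    action: EditAction,
    criterion_key: str,
    payload: dict,
    actor: str,
) -> None:
    ts = rep.edit_log[-1].timestamp + 1 if rep.edit_log else 0
    rep.edit_log.append(
        ModificationEvent(
            action=action,
            criterion_key=criterion_key,
            payload=payload,
            timestamp=ts,
            actor=actor,
        )
    )


def _find_annotation(
    rep: CriteriaRepresentation, criterion_key: str, annotation_id: int
) -> EntityAnnotation:
    rep.criterion(criterion_key)  # raises NotFoundError for a bad key
    for ann in rep.annotations.get(criterion_key, []):
        if ann.annotation_id == annotation_id:
            return ann
    raise NotFoundError(
        f"no annotation {annotation_id} in criterion {criterion_key!r}"
    )


def add_concept(
    rep: CriteriaRepresentation,
    criterion_key: str,
    span: tuple[int, int],
    concept: ConceptRef,
    category: Category,
    actor: str = "human",
) -> CriteriaRepresentation:
    """Attach a human annotation with the given concept to a text span.

    Multiple concepts may be stacked on the identical span (each call adds
    one annotation).  Partial overlap with another *human* annotation is a
    conflict; overlapped *machine* annotations are superseded (removed).
    """
    out = rep.model_copy(deep=True)
    criterion = out.criterion(criterion_key)
    start, end = span
    if not (0 <= start < end <= len(criterion.text)):
        raise ValueError(
            f"span {span} outside criterion text of length {len(criterion.text)}"
        )
    anns = out.annotations.setdefault(criterion_key, [])
    for ann in anns:
        overlaps = ann.span[0] < end and ann.span[1] > start
        if overlaps and ann.provenance is Provenance.human and tuple(ann.span) != (start, end):
            raise AnnotationConflictError(
                f"span {span} overlaps human annotation {ann.annotation_id} "
                f"at {ann.span}"
            )
    superseded = [
        a.annotation_id
        for a in anns
        if a.provenance is Provenance.machine
        and a.span[0] < end
        and a.span[1] > start
    ]
    out.annotations[criterion_key] = [
        a for a in anns if a.annotation_id not in superseded
    ]
    new_ann = EntityAnnotation(
        annotation_id=out.next_annotation_id,
        span=(start, end),
        surface=criterion.text[start:end],
        category=category,
        concepts=[concept],
        provenance=Provenance.human,
    )
    out.next_annotation_id += 1
    out.annotations[criterion_key].append(new_ann)
    out.annotations[criterion_key].sort(key=lambda a: (a.span, a.annotation_id))
    _append_event(
        out,
        EditAction.add_concept,
        criterion_key,
        {
            "span": [start, end],
            "category": category.value,
            "concept": concept.model_dump(),
            "superseded": superseded,
        },
        actor,
    )
    return out


def update_concept(
    rep: CriteriaRepresentation,
    criterion_key: str,
    annotation_id: int,
    new_concept: ConceptRef,
    actor: str = "human",
) -> CriteriaRepresentation:
    """Replace the concept mapping of an existing annotation."""
    out = rep.model_copy(deep=True)
    ann = _find_annotation(out, criterion_key, annotation_id)
    ann.concepts = [new_concept]
    ann.provenance = Provenance.human
    _append_event(
        out,
        EditAction.update_concept,
        criterion_key,
        {"annotation_id": annotation_id, "concept": new_concept.model_dump()},
        actor,
    )
    return out


def delete_concept(
    rep: CriteriaRepresentation,
    criterion_key: str,
    annotation_id: int,
    actor: str = "human",
) -> CriteriaRepresentation:
    """Remove one annotation from a criterion."""
    out = rep.model_copy(deep=True)
    _find_annotation(out, criterion_key, annotation_id)
    out.annotations[criterion_key] = [
        a for a in out.annotations[criterion_key] if a.annotation_id != annotation_id
    ]
    _append_event(
        out,
        EditAction.delete_concept,
        criterion_key,
        {"annotation_id": annotation_id},
        actor,
    )
    return out


def delete_all_in_criterion(
    rep: CriteriaRepresentation, criterion_key: str, actor: str = "human"
) -> CriteriaRepresentation:
    """Remove every annotation of one criterion (single logged event)."""
    out = rep.model_copy(deep=True)
    out.criterion(criterion_key)
    removed = [a.annotation_id for a in out.annotations.get(criterion_key, [])]
    out.annotations[criterion_key] = []
    _append_event(
        out,
        EditAction.delete_all_in_criterion,
        criterion_key,
        {"removed": removed},
        actor,
    )
    return out


def select_criteria(
    rep: CriteriaRepresentation,
    keys: Sequence[str],
    selected: bool,
    actor: str = "human",
) -> CriteriaRepresentation:
    """Mark criteria as (de)selected; deselected criteria are kept in the
    document but excluded from query generation."""
    out = rep.model_copy(deep=True)
    for key in keys:
        out.criterion(key).selected = selected
    _append_event(
        out,
        EditAction.select_criteria,
        keys[0] if keys else "",
        {"keys": list(keys), "selected": selected},
        actor,
    )
    return out


def modification_summary(rep: CriteriaRepresentation) -> dict[str, int]:
    """Event counts per action type plus their total."""
    counts = {action.value: 0 for action in EditAction}
    for event in rep.edit_log:
        counts[event.action.value] += 1
    counts["total"] = len(rep.edit_log)
    return counts


def replay(
    baseline: CriteriaRepresentation, edit_log: Iterable[ModificationEvent]
) -> CriteriaRepresentation:
    """Re-apply a recorded edit log to the machine-parsed baseline.

    Deterministic: the result is field-for-field identical to the
    representation the log was recorded from.
    """
    rep = baseline.model_copy(deep=True)
    for event in edit_log:
        p = event.payload
        if event.action is EditAction.add_concept:
            rep = add_concept(
                rep,
                event.criterion_key,
                tuple(p["span"]),
                ConceptRef.model_validate(p["concept"]),
                Category(p["category"]),
                actor=event.actor,
            )
        elif event.action is EditAction.update_concept:
            rep = update_concept(
                rep,
                event.criterion_key,
                p["annotation_id"],
                ConceptRef.model_validate(p["concept"]),
                actor=event.actor,
            )
        elif event.action is EditAction.delete_concept:
            rep = delete_concept(
                rep, event.criterion_key, p["annotation_id"], actor=event.actor
            )
        elif event.action is EditAction.delete_all_in_criterion:
            rep = delete_all_in_criterion(rep, event.criterion_key, actor=event.actor)
        elif event.action is EditAction.select_criteria:
            rep = select_criteria(
                rep, p["keys"], p["selected"], actor=event.actor
            )
        else:  # pragma: no cover - enum is closed
            raise ValueError(f"unknown action {event.action}")
    return rep
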