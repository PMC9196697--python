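"""Temporal normalization: free-text expressions -> index-relative windows.

A window states that the event starts between ``start_days`` days
before/after and ``end_days`` days before/after the index start date.  All
durations are unified to the day unit (hours round up; week = 7, month = 30,
year = 365 days).  An open bound uses the ``UNBOUNDED_DAYS`` sentinel.
"""

from __future__ import annotations

import csv
import logging
import math
import re
from dataclasses import dataclass
from decimal import Decimal
from importlib import resources as importlib_resources
from typing import Literal, Optional, Union

from .errors import (
    DateLiteralError,
    DirectionMissingError,
    NoTimeSpanError,
    UnitError,
)
from .model import UNBOUNDED_DAYS, Comparator, TemporalConstraint
from .values import (
    NumberMatch,
    OperatorDictionary,
    default_operator_dictionary,
    scan_numbers,
)

logger = logging.getLogger(__name__)

Direction = Literal["before", "after"]

# unit synonym -> (canonical, days multiplier); hours handled separately
_UNIT_ALIASES: dict[str, str] = {}
for _canon, _names in {
    "hour": ("hour", "hours", "hr", "hrs", "h"),
    "day": ("day", "days", "d"),
    "week": ("week", "weeks", "wk", "wks"),
    "month": ("month", "months", "mo", "mos"),
    "year": ("year", "years", "yr", "yrs"),
}.items():
    for _n in _names:
        _UNIT_ALIASES[_n] = _canon

_DAYS_PER = {"day": 1, "week": 7, "month": 30, "year": 365}

_UNIT_TOKEN_RE = re.compile(
    r"[\s-]*(" + "|".join(sorted(_UNIT_ALIASES, key=len, reverse=True)) + r")\b",
    re.IGNORECASE,
)

_MONTH_NAMES = (
    "january|february|march|april|may|june|july|august|september|october"
    "|november|december|jan|feb|mar|apr|jun|jul|aug|sep|sept|oct|nov|dec"
)
_DATE_LITERAL_RE = re.compile(
    rf"\b(?:{_MONTH_NAMES})\.?\s+\d{{1,2}}(?:\s*,?\s*\d{{4}})?\b"
    rf"|\b(?:{_MONTH_NAMES})\.?\s+\d{{4}}\b"
    rf"|\b\d{{1,2}}[/.]\d{{1,2}}[/.]\d{{2,4}}\b",
    re.IGNORECASE,
)


def to_days(quantity: Union[int, float, Decimal], unit: str) -> int:
    """Unify a (quantity, unit) pair to whole days.

    Hours divide by 24 and round up, so a 72-hour lookback stays 3 full days.
    """
    q = Decimal(str(quantity))
    if q < 0:
        raise ValueError("temporal quantity must be non-negative")
    canon = _UNIT_ALIASES.get(unit.strip().rstrip(".").lower())
    if canon is None:
        raise UnitError(unit)
    if canon == "hour":
        days = q / 24
    else:
        days = q * _DAYS_PER[canon]
    return int(math.ceil(days))


class TimeOrderDictionary:
    """Time-order phrase -> direction map loaded from an editable CSV."""

    def __init__(self, entries: dict[str, Direction]):
        self.entries = {k.lower(): v for k, v in entries.items()}
        self._ordered = sorted(self.entries, key=len, reverse=True)

    @classmethod
    def default(cls) -> "TimeOrderDictionary":
        ref = importlib_resources.files("cohortcraft.resources") / "time_order.csv"
        with ref.open("r", encoding="utf-8") as fh:
            rows = list(csv.DictReader(fh))
        return cls({r["phrase"]: r["direction"] for r in rows})  # type: ignore[arg-type]

    def find(self, text: str) -> Optional[tuple[Direction, tuple[int, int]]]:
        """Longest time-order phrase anywhere in ``text`` (ties: earliest)."""
        low = text.lower()
        best: Optional[tuple[Direction, tuple[int, int]]] = None
        for phrase in self._ordered:
            m = re.search(rf"\b{re.escape(phrase)}\b", low)
            if m and (best is None or (m.end() - m.start()) > (best[1][1] - best[1][0])):
                best = (self.entries[phrase], m.span())
        return best


_DEFAULT_ORDER: Optional[TimeOrderDictionary] = None


def default_time_order_dictionary() -> TimeOrderDictionary:
    global _DEFAULT_ORDER
    if _DEFAULT_ORDER is None:
        _DEFAULT_ORDER = TimeOrderDictionary.default()
    return _DEFAULT_ORDER


def normalize_time_order(
    text: str, order: Optional[TimeOrderDictionary] = None
) -> Direction:
    """Normalize a time-order word to ``"before"`` or ``"after"``
    (e.g. ``"prior to"`` -> before, ``"post"`` -> after)."""
    order = order or default_time_order_dictionary()
    hit = order.find(text)
    if hit is None:
        raise DirectionMissingError(
            f"no before/after reference-time word in: {text!r}"
        )
    return hit[0]


@dataclass(frozen=True)
class _Duration:
    start: int
    end: int  # end of unit token
    days: int


_RANGE_SEP_RE = re.compile(r"\s*(?:-|to|and)\s*", re.IGNORECASE)


def _scan_durations(text: str) -> list[_Duration]:
    nums = scan_numbers(text, guard_denominators=False)
    units: list[Optional[re.Match]] = [
        _UNIT_TOKEN_RE.match(text, n.end) for n in nums
    ]
    out: list[_Duration] = []
    for i, (num, m) in enumerate(zip(nums, units)):
        if m is not None:
            out.append(_Duration(num.start, m.end(), to_days(num.value, m.group(1))))
            continue
        # shared-unit range: "2 to 4 weeks" -> the 2 inherits "weeks"
        if i + 1 < len(nums) and units[i + 1] is not None:
            sep = text[num.end : nums[i + 1].start]
            if _RANGE_SEP_RE.fullmatch(sep):
                out.append(
                    _Duration(
                        num.start,
                        num.end,
                        to_days(num.value, units[i + 1].group(1)),
                    )
                )
    return out


def normalize_temporal(
    text: str,
    ops: Optional[OperatorDictionary] = None,
    order: Optional[TimeOrderDictionary] = None,
) -> TemporalConstraint:
    """Normalize a free-text temporal expression into a window.

    Shapes handled: ``"at least N <unit> before X"`` (open lookback),
    ``"within N <unit> prior to X"``, ``"A to B <unit> post X"`` and their
    mirrored directions, plus ``"N days before X to M days after X"``
    straddling the index date.

    Raises :class:`NoTimeSpanError` when no duration is present
    (e.g. ``"currently"``), :class:`DirectionMissingError` when no
    reference-time word is present, and :class:`DateLiteralError` for
    absolute calendar dates, which carry no index-relative meaning.
    """
    ops = ops or default_operator_dictionary()
    order = order or default_time_order_dictionary()
    s = text.replace("≥", ">=").replace("≤", "<=").replace("–", "-").replace("—", "-")

    if _DATE_LITERAL_RE.search(s):
        raise DateLiteralError(f"absolute date literal in: {text!r}")

    durations = _scan_durations(s)
    if not durations:
        raise NoTimeSpanError(f"no clear time span in: {text!r}")

    if len(durations) >= 2:
        d1, d2 = durations[0], durations[1]
        between = s[d1.end : d2.start]
        # a direction word between the bounds ("5 days before to 3 days
        # after") still denotes a range; strip it before testing the shape
        between_clean = _strip_directions(between, order)
        if _RANGE_SEP_RE.fullmatch(between_clean) or not between_clean.strip():
            return _normalize_range(s, d1, d2, order)

    return _normalize_single(s, durations[0], ops, order)


def _strip_directions(text: str, order: TimeOrderDictionary) -> str:
    out = text
    for phrase in order._ordered:
        out = re.sub(rf"\b{re.escape(phrase)}\b", " ", out, flags=re.IGNORECASE)
    return re.sub(r"[,;]", " ", out)


def _direction_for(
    s: str, dur: _Duration, until: int, order: TimeOrderDictionary
) -> Optional[Direction]:
    hit = order.find(s[dur.end : until])
    return hit[0] if hit else None


def _clamp(days: int) -> int:
    # durations beyond the open-bound sentinel are treated as unbounded
    return min(days, UNBOUNDED_DAYS)


def _normalize_range(
    s: str, d1: _Duration, d2: _Duration, order: TimeOrderDictionary
) -> TemporalConstraint:
    dir1 = _direction_for(s, d1, d2.start, order)
    dir2 = _direction_for(s, d2, len(s), order)
    if dir1 is not None and dir2 is not None and dir1 != dir2:
        # "N days before ... to M days after ...": window straddles the index
        before_days = _clamp(d1.days if dir1 == "before" else d2.days)
        after_days = _clamp(d2.days if dir2 == "after" else d1.days)
        return TemporalConstraint(
            start_days=before_days, start_offset=-1,
            end_days=after_days, end_offset=+1,
        )
    direction = dir2 or dir1 or normalize_time_order(s, order)
    a, b = sorted((_clamp(d1.days), _clamp(d2.days)))
    if direction == "after":
        return TemporalConstraint(
            start_days=a, start_offset=+1, end_days=b, end_offset=+1
        )
    return TemporalConstraint(
        start_days=b, start_offset=-1, end_days=a, end_offset=-1
    )


def _normalize_single(
    s: str, dur: _Duration, ops: OperatorDictionary, order: TimeOrderDictionary
) -> TemporalConstraint:
    n = _clamp(dur.days)
    try:
        direction = normalize_time_order(s, order)
    except DirectionMissingError:
        if re.search(r"\bwithin\b", s, re.IGNORECASE):
            # dominant clinical usage: "within N <unit>" is a lookback
            logger.info(
                "assuming direction 'before' for bare 'within' expression: %r", s
            )
            direction = "before"
        else:
            raise

    hit = ops.find(s[: dur.start])
    op = hit[0] if hit else Comparator.eq

    if direction == "before":
        if op in (Comparator.ge, Comparator.gt):
            return TemporalConstraint(
                start_days=UNBOUNDED_DAYS, start_offset=-1, end_days=n, end_offset=-1
            )
        if op in (Comparator.le, Comparator.lt):
            return TemporalConstraint(
                start_days=n, start_offset=-1, end_days=0, end_offset=-1
            )
        return TemporalConstraint(
            start_days=n, start_offset=-1, end_days=n, end_offset=-1
        )
    if op in (Comparator.ge, Comparator.gt):
        return TemporalConstraint(
            start_days=n, start_offset=+1, end_days=UNBOUNDED_DAYS, end_offset=+1
        )
    if op in (Comparator.le, Comparator.lt):
        return TemporalConstraint(
            start_days=0, start_offset=+1, end_days=n, end_offset=+1
        )
    return TemporalConstraint(start_days=n, start_offset=+1, end_days=n, end_offset=+1)
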