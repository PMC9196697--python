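"""Value normalization: free-text thresholds/ranges -> :class:`ValueConstraint`.

Handles digit, word-form and Roman-numeral numbers, an editable comparison
operator dictionary, percent scaling, ``+`` suffixes, ranges, units, and the
"number inside a unit denominator" trap (``3 g/24-hours`` must yield the
single value 3 with unit ``g/24-hours``).
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from decimal import Decimal
from importlib import resources as importlib_resources
from typing import Optional

from .errors import MalformedRangeError, NotAValueError, NumberParseError
from .model import Comparator, ValueConstraint, ValueLogic, ValueTerm

# ---------------------------------------------------------------------------
# Numbers: digits, words, Roman numerals
# ---------------------------------------------------------------------------

_UNITS_WORDS = {
    "zero": 0, "one": 1, "two": 2, "three": 3, "four": 4, "five": 5,
    "six": 6, "seven": 7, "eight": 8, "nine": 9, "ten": 10, "eleven": 11,
    "twelve": 12, "thirteen": 13, "fourteen": 14, "fifteen": 15,
    "sixteen": 16, "seventeen": 17, "eighteen": 18, "nineteen": 19,
}
_TENS_WORDS = {
    "twenty": 20, "thirty": 30, "forty": 40, "fifty": 50,
    "sixty": 60, "seventy": 70, "eighty": 80, "ninety": 90,
}
# I..X only; clinical grades/stages rarely exceed X, beyond that is an error.
_ROMAN = {
    "i": 1, "ii": 2, "iii": 3, "iv": 4, "v": 5,
    "vi": 6, "vii": 7, "viii": 8, "ix": 9, "x": 10,
}

_DIGIT_RE = re.compile(r"\d+(?:\.\d+)?")
_WORDISH_RE = re.compile(r"[A-Za-z]+(?:-[A-Za-z]+)?")


def words_to_number(text: str) -> Decimal:
    """Convert a digit string, a number word (``"two"``, ``"twenty-five"``)
    or a Roman numeral I..X into a :class:`~decimal.Decimal`."""
    token = text.strip().lower()
    if _DIGIT_RE.fullmatch(token):
        return Decimal(token)
    if token in _UNITS_WORDS:
        return Decimal(_UNITS_WORDS[token])
    if token in _TENS_WORDS:
        return Decimal(_TENS_WORDS[token])
    if "-" in token:
        tens, _, unit = token.partition("-")
        if tens in _TENS_WORDS and unit in _UNITS_WORDS and _UNITS_WORDS[unit] < 10:
            return Decimal(_TENS_WORDS[tens] + _UNITS_WORDS[unit])
    if token in _ROMAN:
        return Decimal(_ROMAN[token])
    raise NumberParseError(text)


def _is_number_word(token: str) -> bool:
    t = token.lower()
    if t in _UNITS_WORDS or t in _TENS_WORDS or t in _ROMAN:
        return True
    if "-" in t:
        tens, _, unit = t.partition("-")
        return tens in _TENS_WORDS and unit in _UNITS_WORDS
    return False


@dataclass(frozen=True)
class NumberMatch:
    start: int
    end: int
    value: Decimal

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


def _in_denominator(text: str, start: int) -> bool:
    """True if the number at ``start`` sits in a unit denominator: it is
    preceded (ignoring spaces/hyphens) by a slash, as in ``g/24-hours``."""
    i = start - 1
    while i >= 0 and text[i] in " -":
        i -= 1
    return i >= 0 and text[i] == "/"


def scan_numbers(text: str, guard_denominators: bool = True) -> list[NumberMatch]:
    """All numbers in ``text`` (digit, word, Roman form), left to right.

    With ``guard_denominators`` numbers inside a ``/N-unit`` denominator are
    skipped so they are never extracted as values.
    """
    out: list[NumberMatch] = []
    taken: list[tuple[int, int]] = []
    for m in _DIGIT_RE.finditer(text):
        if guard_denominators and _in_denominator(text, m.start()):
            continue
        # part of an alphanumeric token like "B12" -> not a standalone number
        if m.start() > 0 and (text[m.start() - 1].isalnum()):
            continue
        out.append(NumberMatch(m.start(), m.end(), Decimal(m.group())))
        taken.append((m.start(), m.end()))
    for m in _WORDISH_RE.finditer(text):
        if any(m.start() < e and m.end() > s for s, e in taken):
            continue
        token = m.group()
        if not _is_number_word(token):
            continue
        # Roman numerals are accepted lowercase only if the whole token is a
        # plausible numeral in context; single "i"/"x" words are left alone.
        if token.lower() in _ROMAN and token not in ("I",) and not token.isupper() \
                and token.lower() not in _UNITS_WORDS and token.lower() not in _TENS_WORDS:
            if token.lower() in ("i", "x", "v"):
                continue
        out.append(NumberMatch(m.start(), m.end(), words_to_number(token)))
    out.sort(key=lambda n: n.start)
    return out


# ---------------------------------------------------------------------------
# Operator dictionary
# ---------------------------------------------------------------------------


class OperatorDictionary:
    """Phrase -> comparison symbol map, loaded from an editable CSV."""

    def __init__(self, entries: dict[str, str]):
        self.entries = {k.lower(): v for k, v in entries.items()}
        # longest phrase first so e.g. "no more than" beats "more than"
        self._ordered = sorted(self.entries, key=len, reverse=True)

    @classmethod
    def default(cls) -> "OperatorDictionary":
        ref = importlib_resources.files("cohortcraft.resources") / "operators.csv"
        with ref.open("r", encoding="utf-8") as fh:
            rows = list(csv.DictReader(fh))
        return cls({r["phrase"]: r["symbol"] for r in rows})

    def find(self, text: str) -> Optional[tuple[Comparator, tuple[int, int]]]:
        """Longest-phrase match anywhere in ``text`` (word-boundary for word
        phrases); returns the operator and its span, or None."""
        low = text.lower()
        for phrase in self._ordered:
            if phrase[0].isalpha():
                m = re.search(rf"\b{re.escape(phrase)}\b", low)
            else:
                m = re.search(re.escape(phrase), low)
            if m:
                return Comparator(self.entries[phrase]), m.span()
        return None


_DEFAULT_OPS: Optional[OperatorDictionary] = None


def default_operator_dictionary() -> OperatorDictionary:
    global _DEFAULT_OPS
    if _DEFAULT_OPS is None:
        _DEFAULT_OPS = OperatorDictionary.default()
    return _DEFAULT_OPS


def parse_comparison(text: str, ops: Optional[OperatorDictionary] = None) -> Comparator:
    """Map an operator phrase/symbol to its comparator; bare text defaults
    to equality."""
    ops = ops or default_operator_dictionary()
    hit = ops.find(text)
    return hit[0] if hit else Comparator.eq


# Postfix operator phrases appearing *after* the number ("III or higher").
_POSTFIX_OPS: list[tuple[str, Comparator]] = [
    ("or higher", Comparator.ge), ("or more", Comparator.ge),
    ("or greater", Comparator.ge), ("or above", Comparator.ge),
    ("or over", Comparator.ge), ("and above", Comparator.ge),
    ("and over", Comparator.ge), ("or better", Comparator.ge),
    ("or less", Comparator.le), ("or lower", Comparator.le),
    ("or fewer", Comparator.le), ("or below", Comparator.le),
    ("and under", Comparator.le), ("or worse", Comparator.le),
]

_NORMALIZE_SYMBOLS = {"≥": ">=", "≤": "<=", "≠": "<>", "–": "-", "—": "-"}

_RANGE_SEP_RE = re.compile(r"\s*(?:-|to|and)\s*", re.IGNORECASE)
_PERCENT_RE = re.compile(r"\s*(?:%|percent\b)", re.IGNORECASE)


def _clean_symbols(text: str) -> str:
    for k, v in _NORMALIZE_SYMBOLS.items():
        text = text.replace(k, v)
    return text


def _percent_after(text: str, pos: int) -> Optional[int]:
    """If a percent marker immediately follows ``pos``, return its end."""
    m = _PERCENT_RE.match(text, pos)
    return m.end() if m else None


def _clean_unit(raw: str) -> str:
    unit = raw.strip().strip(",;:.()").strip()
    # drop leading connective fillers that are not part of a unit
    unit = re.sub(r"^(?:of|per)\s+", "", unit, flags=re.IGNORECASE)
    return unit


def _prefix_operator(
    prefix: str, ops: OperatorDictionary
) -> tuple[Comparator, Optional[tuple[int, int]]]:
    hit = ops.find(prefix)
    if hit is None:
        return Comparator.eq, None
    return hit


def normalize_value(
    text: str, ops: Optional[OperatorDictionary] = None
) -> ValueConstraint:
    """Normalize a free-text value expression.

    Supported shapes: bare numbers (``"3"`` -> = 3), operator phrases before
    or after the number (``"> 200 IU/L"``, ``"III or higher"``), ``N+``
    suffixes, percent scaling (one ``%`` scales both ends of a range),
    hyphen/"to"/"between..and" ranges, and two comparisons joined by a
    logical connective.
    """
    ops = ops or default_operator_dictionary()
    s = _clean_symbols(text)
    nums = scan_numbers(s, guard_denominators=True)
    if not nums:
        raise NotAValueError(f"no number found in value text: {text!r}")

    if len(nums) >= 2:
        n1, n2 = nums[0], nums[1]
        between = s[n1.end : n2.start]
        # "%"-less middle such as "-", "to", "between a AND b"
        pct1_end = _percent_after(s, n1.end)
        between_eff = s[pct1_end:n2.start] if pct1_end else between
        if _RANGE_SEP_RE.fullmatch(between_eff) and ops.find(s[: n1.start]) is None:
            return _normalize_range(s, n1, n2, bool(pct1_end), ops)
        joined = _normalize_joined(s, n1, n2, between, ops)
        if joined is not None:
            return joined
        # fall through: treat as single value on the first number

    return _normalize_single(s, nums[0], ops)


def _normalize_range(
    s: str,
    n1: NumberMatch,
    n2: NumberMatch,
    n1_has_pct: bool,
    ops: OperatorDictionary,
) -> ValueConstraint:
    a, b = n1.value, n2.value
    tail = n2.end
    pct2_end = _percent_after(s, n2.end)
    if pct2_end:
        tail = pct2_end
        b = b / 100
        # a single trailing "%" scales both bounds of the range
        a = a / 100
    elif n1_has_pct:
        a = a / 100
    if a > b:
        raise MalformedRangeError(f"range lower bound {a} exceeds upper bound {b}")
    unit = "" if pct2_end else _clean_unit(s[tail:])
    return ValueConstraint(
        terms=(
            ValueTerm(operator=Comparator.ge, value=a),
            ValueTerm(operator=Comparator.le, value=b),
        ),
        logic=ValueLogic.and_,
        unit=unit,
    )


def _normalize_joined(
    s: str,
    n1: NumberMatch,
    n2: NumberMatch,
    between: str,
    ops: OperatorDictionary,
) -> Optional[ValueConstraint]:
    """Two explicit comparisons joined by "or"/"and", e.g. "< 3 or > 10"."""
    conn = re.search(r"\b(or|and)\b", between, re.IGNORECASE)
    if conn is None:
        return None
    op1 = ops.find(s[: n1.start])
    op2 = ops.find(between[conn.end() :])
    if op1 is None or op2 is None:
        return None
    logic = ValueLogic.or_ if conn.group(1).lower() == "or" else ValueLogic.and_
    unit = _clean_unit(s[n2.end :])
    return ValueConstraint(
        terms=(
            ValueTerm(operator=op1[0], value=n1.value),
            ValueTerm(operator=op2[0], value=n2.value),
        ),
        logic=logic,
        unit=unit,
    )


def _normalize_single(
    s: str, num: NumberMatch, ops: OperatorDictionary
) -> ValueConstraint:
    value = num.value
    unit_start = num.end
    op: Optional[Comparator] = None

    pct_end = _percent_after(s, num.end)
    if pct_end:
        value = value / 100
        unit_start = pct_end

    post = s[unit_start:]
    stripped = post.lstrip()
    pad = len(post) - len(stripped)
    if stripped.startswith("+"):
        op = Comparator.ge
        unit_start += pad + 1
    else:
        for phrase, comp in _POSTFIX_OPS:
            if re.match(rf"{re.escape(phrase)}\b", stripped, re.IGNORECASE):
                op = comp
                unit_start += pad + len(phrase)
                break

    if op is None:
        op, _span = _prefix_operator(s[: num.start], ops)

    unit = "" if pct_end else _clean_unit(s[unit_start:])
    return ValueConstraint(
        terms=(ValueTerm(operator=op, value=value),),
        logic=ValueLogic.single,
        unit=unit,
    )
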