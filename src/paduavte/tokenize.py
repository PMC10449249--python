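"""Lexicon-intervened sentence segmentation and time parsing.

The default segmenter is self-contained: a greedy longest-match scan
against the union of the loaded lexicons yields TERM tokens, negation
cues yield NEG tokens, and date/time expressions yield TIME tokens;
whatever remains is split on whitespace into OTHER tokens.  Spans are
0-based half-open character offsets into the sentence, non-overlapping
and ordered, so the sentence can be reconstructed from the tokens plus
the inter-token separators.  An external tokenizer may replace this
default as long as it preserves the Token contract.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Iterable, List, Optional, Sequence, Set, Tuple

__all__ = [
    "Token",
    "Lexicon",
    "DEFAULT_NEGATION_TERMS",
    "split_sentences",
    "split_clauses",
    "segment",
    "parse_time",
]


@dataclass(frozen=True)
class Token:
    surface: str
    pos: str  # TERM | TIME | NEG | OTHER
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.pos not in ("TERM", "TIME", "NEG", "OTHER"):
            raise ValueError(f"bad token pos {self.pos!r}")


@dataclass
class Lexicon:
    """A named term set (surgery_trauma, hormone, reduced_mobility, symptom, negation)."""

    name: str
    entries: Set[str] = field(default_factory=set)

    VALID_NAMES = ("surgery_trauma", "hormone", "reduced_mobility", "symptom", "negation")

    def __post_init__(self) -> None:
        if self.name not in self.VALID_NAMES:
            raise ValueError(f"bad lexicon name {self.name!r}")
        cleaned = {e.strip() for e in self.entries if e.strip()}
        if not cleaned:
            raise ValueError(f"lexicon {self.name} has no entries")
        self.entries = cleaned


# Cues seeded from common clinical negation phrasing; extensible via file.
DEFAULT_NEGATION_TERMS = (
    "no",
    "not",
    "none",
    "denies",
    "denied",
    "without",
    "not used",
    "not using",
    "not seen",
    "not found",
    "never",
    "absent",
    "negative for",
)


_SENTENCE_BREAK = re.compile(r"[。．！？!?；;\n]|\.(?=\s|$)")


def split_sentences(text: str) -> List[Tuple[str, int]]:
    """Split narrative text into (sentence, offset) pairs.

    Breaks on CJK/ASCII sentence punctuation and newlines; an ASCII
    period only breaks before whitespace or end-of-text so decimals
    like "1.70 m" survive.
    """
    out: List[Tuple[str, int]] = []
    last = 0
    for m in _SENTENCE_BREAK.finditer(text):
        chunk = text[last : m.start()]
        if chunk.strip():
            lead = len(chunk) - len(chunk.lstrip())
            out.append((chunk.strip(), last + lead))
        last = m.end()
    chunk = text[last:]
    if chunk.strip():
        lead = len(chunk) - len(chunk.lstrip())
        out.append((chunk.strip(), last + lead))
    return out


def split_clauses(sentence: str) -> List[Tuple[int, int]]:
    """Clause spans (half-open) delimited by commas/semicolons."""
    spans: List[Tuple[int, int]] = []
    start = 0
    for m in re.finditer(r"[,，;；]", sentence):
        spans.append((start, m.start()))
        start = m.end()
    spans.append((start, len(sentence)))
    return spans


_MONTHS = {
    name: i + 1
    for i, name in enumerate(
        [
            "january",
            "february",
            "march",
            "april",
            "may",
            "june",
            "july",
            "august",
            "september",
            "october",
            "november",
            "december",
        ]
    )
}
_MONTH_ALT = "|".join(_MONTHS)

# "On April 16, 2021" / "April 16, 2021"
_RE_MONTH_NAME = re.compile(rf"(?:On\s+)?(?:{_MONTH_ALT})\s+\d{{1,2}},?\s+\d{{4}}", re.IGNORECASE)
# ISO 2021-04-16 (also 2021/04/16)
_RE_ISO = re.compile(r"\b\d{4}[-/]\d{1,2}[-/]\d{1,2}\b")
# CJK 2021年4月16日
_RE_CJK = re.compile(r"\d{4}年\d{1,2}月\d{1,2}日")
# relative: "3 days ago", "2 weeks ago", "1 month ago"
_RE_RELATIVE = re.compile(r"\b(\d+)\s+(day|week|month)s?\s+ago\b", re.IGNORECASE)

_TIME_PATTERNS = (_RE_MONTH_NAME, _RE_ISO, _RE_CJK, _RE_RELATIVE)


def _find_time_spans(sentence: str) -> List[Tuple[int, int]]:
    spans: List[Tuple[int, int]] = []
    for pat in _TIME_PATTERNS:
        for m in pat.finditer(sentence):
            if not any(m.start() < e and s < m.end() for s, e in spans):
                spans.append((m.start(), m.end()))
    return sorted(spans)


def _is_word_char(ch: str) -> bool:
    # boundary checks only apply to ASCII word characters, so CJK terms
    # embedded in running text still match without spaces around them
    return ch.isascii() and (ch.isalnum() or ch == "_")


def _boundary_ok(sentence: str, start: int, end: int) -> bool:
    if start > 0 and _is_word_char(sentence[start - 1]) and _is_word_char(sentence[start]):
        return False
    if end < len(sentence) and _is_word_char(sentence[end - 1]) and _is_word_char(sentence[end]):
        return False
    return True


def _longest_match(lower: str, sentence: str, pos: int, entries_by_len: Sequence[Tuple[int, Set[str]]]) -> Optional[int]:
    for length, entries in entries_by_len:
        end = pos + length
        if end > len(lower):
            continue
        if lower[pos:end] in entries and _boundary_ok(sentence, pos, end):
            return end
    return None


def segment(sentence: str, lexicons: Iterable[Lexicon]) -> List[Token]:
    """Greedy longest-match segmentation of one sentence.

    Lexicon entries are matched case-insensitively; the negation
    lexicon (when present among ``lexicons``) produces NEG tokens and
    every other lexicon produces TERM tokens.  NEG wins ties with TERM
    only when its match is strictly longer.
    """
    if not sentence:
        return []
    lexicons = list(lexicons)
    term_entries: Set[str] = set()
    neg_entries: Set[str] = set()
    for lx in lexicons:
        target = neg_entries if lx.name == "negation" else term_entries
        target.update(e.lower() for e in lx.entries)

    def by_len(entries: Set[str]) -> List[Tuple[int, Set[str]]]:
        grouped: dict = {}
        for e in entries:
            grouped.setdefault(len(e), set()).add(e)
        return sorted(((k, v) for k, v in grouped.items()), reverse=True)

    term_by_len = by_len(term_entries)
    neg_by_len = by_len(neg_entries)

    lower = sentence.lower()
    time_spans = _find_time_spans(sentence)
    tokens: List[Token] = []
    other_start: Optional[int] = None

    def flush_other(upto: int) -> None:
        nonlocal other_start
        if other_start is None:
            return
        chunk = sentence[other_start:upto]
        # whitespace-delimited OTHER words; punctuation stays attached
        for m in re.finditer(r"\S+", chunk):
            tokens.append(Token(m.group(), "OTHER", other_start + m.start(), other_start + m.end()))
        other_start = None

    i = 0
    n = len(sentence)
    while i < n:
        tspan = next(((s, e) for s, e in time_spans if s == i), None)
        if tspan is not None:
            flush_other(i)
            tokens.append(Token(sentence[tspan[0] : tspan[1]], "TIME", tspan[0], tspan[1]))
            i = tspan[1]
            continue
        inside_time = any(s < i < e for s, e in time_spans)
        if not inside_time:
            term_end = _longest_match(lower, sentence, i, term_by_len)
            neg_end = _longest_match(lower, sentence, i, neg_by_len)
            # clip matches that would run into a TIME span
            for s, _e in time_spans:
                if term_end is not None and i < s < term_end:
                    term_end = None
                if neg_end is not None and i < s < neg_end:
                    neg_end = None
            if term_end is not None or neg_end is not None:
                if (neg_end or -1) > (term_end or -1):
                    end, pos_tag = neg_end, "NEG"
                else:
                    end, pos_tag = term_end, "TERM"
                flush_other(i)
                tokens.append(Token(sentence[i:end], pos_tag, i, end))
                i = end
                continue
        if not sentence[i].isspace() and other_start is None:
            other_start = i
        elif sentence[i].isspace():
            flush_other(i)
        i += 1
    flush_other(n)
    tokens.sort(key=lambda t: t.start)
    return tokens


def parse_time(token: Token | str, reference_date: date) -> Optional[date]:
    """Resolve a TIME token to a calendar date, or ``None``.

    Handles absolute month-name, ISO and CJK date patterns plus simple
    relative phrases ("3 days ago") resolved against
    ``reference_date``.  Malformed dates return ``None`` rather than
    raising.
    """
    text = token.surface if isinstance(token, Token) else token
    m = _RE_ISO.search(text)
    if m:
        parts = re.split(r"[-/]", m.group())
        return _safe_date(int(parts[0]), int(parts[1]), int(parts[2]))
    m = _RE_CJK.search(text)
    if m:
        nums = re.findall(r"\d+", m.group())
        return _safe_date(int(nums[0]), int(nums[1]), int(nums[2]))
    m = re.search(rf"({_MONTH_ALT})\s+(\d{{1,2}}),?\s+(\d{{4}})", text, re.IGNORECASE)
    if m:
        return _safe_date(int(m.group(3)), _MONTHS[m.group(1).lower()], int(m.group(2)))
    m = _RE_RELATIVE.search(text)
    if m:
        n, unit = int(m.group(1)), m.group(2).lower()
        if unit == "day":
            return reference_date - timedelta(days=n)
        if unit == "week":
            return reference_date - timedelta(weeks=n)
        return _months_before(reference_date, n)
    return None


def _safe_date(y: int, mth: int, d: int) -> Optional[date]:
    try:
        return date(y, mth, d)
    except ValueError:
        return None


def _months_before(ref: date, n: int) -> date:
    month = ref.month - n
    year = ref.year
    while month < 1:
        month += 12
        year -= 1
    day = ref.day
    while True:
        try:
            return date(year, month, day)
        except ValueError:
            day -= 1
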