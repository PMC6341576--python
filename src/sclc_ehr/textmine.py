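"""Negation-aware free-text string search for SCLC case ascertainment.

UK primary-care Read dictionaries of the study era had no dedicated code for
small cell lung cancer, so the deciding evidence often sits in the free-text
comment a practitioner attaches to a coded entry ("small cell ca confirmed on
biopsy", "non-small cell lung cancer").  This module implements the simple,
auditable string-matching layer used to split code-detected patients into
text strata: a case-insensitive substring search for SCLC-suggestive strings,
with a one-token negation rule ("non" immediately preceding the string marks
the mention as non-small cell) and a plain substring search for lung-cancer
strings.

Deliberately not a general clinical NLP engine: no stemming, no bidirectional
NegEx-style scope, no misspelling tolerance.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "PatternSet",
    "TextFlags",
    "match_text",
    "window_flags",
    "load_patterns",
    "save_patterns",
    "default_patterns",
]

# characters accepted between a negation prefix and the pattern it negates
_SEPARATORS = " -"


@dataclass(frozen=True)
class TextFlags:
    """Outcome of a text search: the three strata flags.

    ``has_sclc_text``  - an SCLC-suggestive string occurs un-negated.
    ``has_non_text``   - an SCLC-suggestive string occurs negated (or a
                         dedicated negated token such as "nsclc" occurs).
    ``has_lung_text``  - a lung-cancer string occurs.

    The flags are independent: one comment can raise several.
    """

    has_sclc_text: bool = False
    has_non_text: bool = False
    has_lung_text: bool = False

    def __or__(self, other: "TextFlags") -> "TextFlags":
        return TextFlags(
            self.has_sclc_text or other.has_sclc_text,
            self.has_non_text or other.has_non_text,
            self.has_lung_text or other.has_lung_text,
        )

    @property
    def any(self) -> bool:
        return self.has_sclc_text or self.has_non_text or self.has_lung_text


@dataclass(frozen=True)
class PatternSet:
    """Search strings for the free-text step, stored lower-case.

    ``sclc_patterns``     strings suggestive of small cell histology.
    ``negation_prefixes`` tokens that, immediately preceding an SCLC string
                          (at most one space or hyphen in between), mark the
                          mention as non-small cell.
    ``lung_patterns``     strings suggestive of lung cancer (group 2 search).
    ``negated_tokens``    stand-alone abbreviations that are inherently
                          negated mentions, e.g. "nsclc".
    """

    sclc_patterns: tuple[str, ...]
    negation_prefixes: tuple[str, ...]
    lung_patterns: tuple[str, ...]
    negated_tokens: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for name in ("sclc_patterns", "negation_prefixes", "lung_patterns"):
            vals = getattr(self, name)
            if not vals:
                raise ValueError(f"PatternSet.{name} must be non-empty")
        lowered = {
            name: tuple(v.lower() for v in getattr(self, name))
            for name in (
                "sclc_patterns",
                "negation_prefixes",
                "lung_patterns",
                "negated_tokens",
            )
        }
        for name, vals in lowered.items():
            object.__setattr__(self, name, vals)


def default_patterns() -> PatternSet:
    """Pattern set covering the spelling variants seen in UK free text."""
    return PatternSet(
        sclc_patterns=("small cell", "small-cell", "sclc", "oat cell"),
        negation_prefixes=("non",),
        lung_patterns=("lung cancer", "lung ca", "ca lung", "carcinoma of lung"),
        negated_tokens=("nsclc",),
    )


def _find_all(haystack: str, needle: str) -> Iterable[int]:
    start = 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return
        yield i
        start = i + 1


def _at_left_boundary(text: str, i: int) -> bool:
    # an occurrence buried inside a longer token ("sclc" in "nsclc") is not
    # a mention of the pattern itself
    return i == 0 or not text[i - 1].isalnum()


def _is_negated(text: str, i: int, prefixes: Sequence[str]) -> bool:
    """True if a negation prefix immediately precedes position ``i``,
    allowing at most one intervening space or hyphen."""
    j = i
    if j > 0 and text[j - 1] in _SEPARATORS:
        j -= 1
    for p in prefixes:
        if j >= len(p) and text[j - len(p):j] == p:
            k = j - len(p)
            if k == 0 or not text[k - 1].isalnum():
                return True
    return False


def match_text(text: str | None, patterns: PatternSet) -> TextFlags:
    """Classify one free-text comment.

    Matching is a case-insensitive substring scan over the raw text; an
    SCLC pattern occurrence raises ``has_non_text`` instead of
    ``has_sclc_text`` when a negation prefix is adjacent to its left
    (at most one space/hyphen in between).  Total function: ``None`` or
    empty text yields all-false flags.
    """
    if not text:
        return TextFlags()
    t = text.lower()
    has_sclc = has_non = False
    for pat in patterns.sclc_patterns:
        for i in _find_all(t, pat):
            if not _at_left_boundary(t, i):
                continue
            if _is_negated(t, i, patterns.negation_prefixes):
                has_non = True
            else:
                has_sclc = True
    for tok in patterns.negated_tokens:
        for i in _find_all(t, tok):
            if _at_left_boundary(t, i):
                has_non = True
                break
    has_lung = any(p in t for p in patterns.lung_patterns)
    return TextFlags(has_sclc, has_non, has_lung)


def window_flags(
    events: pd.DataFrame,
    anchor_date: date | pd.Timestamp,
    patterns: PatternSet,
    lo_days: int = -30,
    hi_days: int = 90,
) -> TextFlags:
    """OR-combine :func:`match_text` over one patient's comments in a window.

    Parameters
    ----------
    events : DataFrame with ``event_date`` (datetime-like) and ``free_text``
        columns; rows for a single patient.
    anchor_date : the index-code date anchoring the window.
    lo_days, hi_days : closed window bounds in days relative to the anchor;
        defaults are 30 days before to 90 days after the index code.
    """
    anchor = pd.Timestamp(anchor_date)
    lo = anchor + pd.Timedelta(days=lo_days)
    hi = anchor + pd.Timedelta(days=hi_days)
    flags = TextFlags()
    if len(events) == 0:
        return flags
    dates = pd.to_datetime(events["event_date"])
    in_win = (dates >= lo) & (dates <= hi)
    for text in events.loc[in_win, "free_text"]:
        if isinstance(text, str) and text:
            flags = flags | match_text(text, patterns)
            if flags.has_sclc_text and flags.has_non_text and flags.has_lung_text:
                break
    return flags


# ---------------------------------------------------------------------------
# pattern file I/O  (CSV: category,pattern — one pattern per line)

_CATEGORIES = {
    "sclc": "sclc_patterns",
    "negation_prefix": "negation_prefixes",
    "lung": "lung_patterns",
    "negated_token": "negated_tokens",
}


def load_patterns(path: str | Path) -> PatternSet:
    """Load a :class:`PatternSet` from a two-column CSV (category, pattern)."""
    path = Path(path)
    buckets: dict[str, list[str]] = {v: [] for v in _CATEGORIES.values()}
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            raise ValueError(f"empty pattern file: {path}")
        if [c.strip().lower() for c in header[:2]] != ["category", "pattern"]:
            raise ValueError(
                f"pattern file {path}: expected header 'category,pattern', got {header!r}"
            )
        for row in reader:
            if not row or not row[0].strip():
                continue
            cat, pat = row[0].strip().lower(), row[1]
            if cat not in _CATEGORIES:
                raise ValueError(f"pattern file {path}: unknown category {cat!r}")
            buckets[_CATEGORIES[cat]].append(pat)
    return PatternSet(
        sclc_patterns=tuple(buckets["sclc_patterns"]),
        negation_prefixes=tuple(buckets["negation_prefixes"]),
        lung_patterns=tuple(buckets["lung_patterns"]),
        negated_tokens=tuple(buckets["negated_tokens"]),
    )


def save_patterns(patterns: PatternSet, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["category", "pattern"])
        for cat, attr in _CATEGORIES.items():
            for pat in getattr(patterns, attr):
                writer.writerow([cat, pat])
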