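"""Report-time detection, table-region location, and line normalization.

These are the first three stages that run on the formed lines of a report:

1. *Time detection* scans every line for datetime patterns and takes the
   earliest instant as the report time (reports typically carry several
   timestamps — collection, reporting, printing — of which the earliest is
   the most meaningful anchor).
2. *Headline position* finds the table header line (via role keywords such
   as "name" / "result") and the end line (signature/notes region), bounding
   the region the entity recognizer should look at.
3. *Line normalization* repairs lines that the OCR stage split into
   fragments, by comparing fragment lengths against the report's mean line
   length and merging them back, then removing empty lines.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from datetime import datetime
from importlib import resources
from typing import Iterable, Sequence

import yaml

from .ocr import TextLine

__all__ = [
    "ReportTime",
    "TableRegion",
    "LineStats",
    "HeadlineKeywords",
    "NormalizationThresholds",
    "load_keyword_config",
    "detect_report_time",
    "locate_table_region",
    "normalize_lines",
    "line_stats",
]


@dataclass(frozen=True)
class ReportTime:
    """The earliest datetime found on a report."""

    value: datetime
    source_line: int
    raw_text: str


@dataclass(frozen=True)
class TableRegion:
    """Bounds of the test-result table within the document's lines.

    ``head_index`` is the header line, ``tail_index`` the end line (both
    inclusive document line indices); the table body lies strictly between
    them.  ``confident`` is False when no header keyword matched and the
    region fell back to the whole document.
    """

    head_index: int
    tail_index: int
    confident: bool
    tail_matched: bool = False

    def body_range(self) -> range:
        """Line indices of the table body (between header and end line).

        The tail line itself is excluded when it matched an endline keyword
        (it is signature/notes content, not table content).
        """
        start = self.head_index + 1 if self.confident else self.head_index
        stop = self.tail_index if self.tail_matched else self.tail_index + 1
        return range(start, stop)


@dataclass(frozen=True)
class LineStats:
    mean_length: float
    per_line_lengths: tuple[int, ...]


@dataclass
class HeadlineKeywords:
    """Keyword lists for header/endline role matching (case-insensitive)."""

    name: list[str]
    result: list[str]
    unit: list[str]
    range: list[str]
    endline: list[str]

    def header_roles(self) -> dict[str, list[str]]:
        return {
            "name": self.name,
            "result": self.result,
            "unit": self.unit,
            "range": self.range,
        }


@dataclass
class NormalizationThresholds:
    """Fractions of the mean line length L-bar driving fragment merging.

    ``short`` — a current line shorter than ``short * L-bar`` is a merge
    candidate; ``max_merged`` — a merge happens only if the merged length
    stays within ``max_merged * L-bar``; ``fragment`` — the next line must
    itself be shorter than ``fragment * L-bar`` before a two-line merge is
    attempted.
    """

    short: float = 0.6
    max_merged: float = 1.25
    fragment: float = 0.3


def load_keyword_config(
    path: str | None = None,
) -> tuple[HeadlineKeywords, NormalizationThresholds]:
    """Load header keywords and normalization thresholds from YAML.

    With no path, the packaged bilingual defaults (``data/keywords.yaml``)
    are used.
    """
    if path is None:
        text = (
            resources.files("labdigitize.data").joinpath("keywords.yaml").read_text(
                encoding="utf-8"
            )
        )
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    kw = raw.get("keywords", {})
    keywords = HeadlineKeywords(
        name=list(kw.get("name", [])),
        result=list(kw.get("result", [])),
        unit=list(kw.get("unit", [])),
        range=list(kw.get("range", [])),
        endline=list(kw.get("endline", [])),
    )
    th = raw.get("thresholds", {})
    thresholds = NormalizationThresholds(
        short=float(th.get("short", 0.6)),
        max_merged=float(th.get("max_merged", 1.25)),
        fragment=float(th.get("fragment", 0.3)),
    )
    return keywords, thresholds


# --------------------------------------------------------------------------
# Time detection
# --------------------------------------------------------------------------

# Three dialects: ISO-like, slash, and CJK.  Two-digit years are rejected to
# avoid century ambiguity; they do not occur in report headers.
_DT_PATTERNS = [
    re.compile(
        r"(?<!\d)(\d{4})-(\d{1,2})-(\d{1,2})"
        r"(?:[ T](\d{1,2}):(\d{2})(?::(\d{2}))?)?"
    ),
    re.compile(
        r"(?<!\d)(\d{4})/(\d{1,2})/(\d{1,2})"
        r"(?:[ T](\d{1,2}):(\d{2})(?::(\d{2}))?)?"
    ),
    re.compile(
        r"(?<!\d)(\d{4})年(\d{1,2})月(\d{1,2})日"
        r"(?:\s*(\d{1,2}):(\d{2})(?::(\d{2}))?)?"
    ),
]


def _parse_match(m: re.Match) -> datetime | None:
    y, mo, d = int(m.group(1)), int(m.group(2)), int(m.group(3))
    hh = int(m.group(4)) if m.group(4) else 0
    mm = int(m.group(5)) if m.group(5) else 0
    ss = int(m.group(6)) if m.group(6) else 0
    try:
        return datetime(y, mo, d, hh, mm, ss)
    except ValueError:
        return None  # e.g. month 13 from an OCR error


def detect_report_time(lines: Sequence[TextLine]) -> ReportTime | None:
    """Scan all lines for datetimes and return the earliest as report time.

    Datetimes lacking a time-of-day compare at 00:00.  Ties on equal
    instants are broken by the earliest line index.  Returns None when no
    line contains a parseable datetime.
    """
    best: ReportTime | None = None
    for i, line in enumerate(lines):
        for pat in _DT_PATTERNS:
            for m in pat.finditer(line.text):
                value = _parse_match(m)
                if value is None:
                    continue
                if best is None or value < best.value:
                    best = ReportTime(value=value, source_line=i, raw_text=m.group(0))
    return best


# --------------------------------------------------------------------------
# Headline position
# --------------------------------------------------------------------------


def locate_table_region(
    lines: Sequence[TextLine], keywords: HeadlineKeywords
) -> TableRegion:
    """Locate the table header and end line via role keywords.

    The header is the first line matching keywords from at least two
    distinct header roles (name/result/unit/range); the end line is the
    first subsequent line matching an endline keyword (signature/notes),
    else the last line.  When no header matches, the region falls back to
    the whole document with ``confident=False``.
    """
    if not lines:
        raise ValueError("cannot locate a table region in an empty document")
    roles = keywords.header_roles()
    if not roles["name"] or not roles["result"]:
        raise ValueError("keyword config must provide name and result roles")

    head_index = None
    for i, line in enumerate(lines):
        low = line.text.lower()
        hit_roles = sum(
            1
            for role_kws in roles.values()
            if any(kw.lower() in low for kw in role_kws)
        )
        if hit_roles >= 2:
            head_index = i
            break

    confident = head_index is not None
    if head_index is None:
        head_index = 0

    tail_index = len(lines) - 1
    tail_matched = False
    for j in range(head_index + 1, len(lines)):
        low = lines[j].text.lower()
        if any(kw.lower() in low for kw in keywords.endline):
            tail_index = j
            tail_matched = True
            break
    return TableRegion(
        head_index=head_index,
        tail_index=tail_index,
        confident=confident,
        tail_matched=tail_matched,
    )


# --------------------------------------------------------------------------
# Line normalization
# --------------------------------------------------------------------------


def line_stats(lines: Sequence[TextLine]) -> LineStats:
    """Mean line length over the non-empty lines."""
    lengths = tuple(len(ln.text) for ln in lines if ln.text.strip())
    mean = sum(lengths) / len(lengths) if lengths else 0.0
    return LineStats(mean_length=mean, per_line_lengths=lengths)


def _merge_pass(
    texts: list[str], th: NormalizationThresholds
) -> tuple[list[str], bool]:
    lengths = [len(t) for t in texts]
    lbar = sum(lengths) / len(lengths) if lengths else 0.0
    if lbar == 0.0:
        return texts, False
    out: list[str] = []
    i = 0
    changed = False
    while i < len(texts):
        c = len(texts[i])
        if c < th.short * lbar and i + 1 < len(texts):
            n1 = len(texts[i + 1])
            if c + n1 <= th.max_merged * lbar:
                if (
                    i + 2 < len(texts)
                    and n1 < th.fragment * lbar
                    and c + n1 + len(texts[i + 2]) <= th.max_merged * lbar
                ):
                    out.append(" ".join((texts[i], texts[i + 1], texts[i + 2])))
                    i += 3
                else:
                    out.append(" ".join((texts[i], texts[i + 1])))
                    i += 2
                changed = True
                continue
        out.append(texts[i])
        i += 1
    return out, changed


def normalize_lines(
    lines: Sequence[TextLine],
    thresholds: NormalizationThresholds | None = None,
) -> list[TextLine]:
    """Merge fragment lines back together and drop empty lines.

    Walks the document comparing each line's length (and its next one or
    two) against the mean line length; short lines absorb their following
    fragment(s) when the merged length stays plausible.  Passes repeat
    until a fixed point so the operation is idempotent.  The multiset and
    order of non-whitespace characters are preserved exactly.
    """
    th = thresholds or NormalizationThresholds()
    texts = [ln.text for ln in lines if ln.text.strip()]
    for _ in range(len(texts) + 1):  # each effective pass shrinks the list
        texts, changed = _merge_pass(texts, th)
        if not changed:
            break
    return [TextLine(text=t) for t in texts]
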