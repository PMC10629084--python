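"""Rule-based comparison arm for entity extraction.

The baseline types whitespace-delimited spans with character-class regular
expressions — reference ranges contain comparator symbols with digits,
units contain "/", "%" or Latin letters, results are unsigned numbers (the
decimal point excepted) or qualitative Chinese words, and names are mainly
Chinese characters — falling back to header-keyword column typing when a
span matches no pattern.  It exists as the comparison arm for the CRF
recognizer, not as a tuned competitor.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import yaml

from .iob import EntityCategory, LabEntity
from .layout import DigitalTable, assemble_table, detect_columns
from .ner import link_entities
from .ocr import TextLine
from .preprocess import HeadlineKeywords, ReportTime, TableRegion

__all__ = [
    "RuleSet",
    "load_rules",
    "rule_classify_span",
    "header_column_types",
    "rule_extract",
]

_ROLE_TO_CATEGORY = {
    "name": EntityCategory.LabName,
    "result": EntityCategory.LabResult,
    "unit": EntityCategory.LabUnit,
    "range": EntityCategory.LabRefRange,
}


@dataclass
class RuleSet:
    """Ordered per-category patterns plus header keywords and a priority.

    ``priority`` is the order in which categories are tried; the first
    category with a matching pattern wins (most-specific-first by default,
    since e.g. "-" with digits would otherwise match the number rule).
    """

    patterns: dict[EntityCategory, list[re.Pattern]]
    header_keywords: dict[str, list[str]]
    priority: tuple[EntityCategory, ...] = (
        EntityCategory.LabRefRange,
        EntityCategory.LabUnit,
        EntityCategory.LabResult,
        EntityCategory.LabName,
    )

    def __post_init__(self) -> None:
        missing = [c for c in EntityCategory if not self.patterns.get(c)]
        if missing:
            raise ValueError(f"no patterns for categories: {missing}")
        if sorted(self.priority) != sorted(EntityCategory):
            raise ValueError("priority must be a permutation of the categories")


def load_rules(path: str | None = None) -> RuleSet:
    """Load a RuleSet from YAML (packaged defaults when no path given)."""
    if path is None:
        text = (
            resources.files("labdigitize.data").joinpath("rules.yaml").read_text(
                encoding="utf-8"
            )
        )
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    patterns = {
        EntityCategory(cat): [re.compile(p) for p in pats]
        for cat, pats in raw["patterns"].items()
    }
    priority = tuple(EntityCategory(c) for c in raw.get("priority", []))
    kwargs = {"patterns": patterns, "header_keywords": raw.get("header_keywords", {})}
    if priority:
        kwargs["priority"] = priority
    return RuleSet(**kwargs)


def rule_classify_span(text: str, rules: RuleSet) -> EntityCategory | None:
    """Type one span: first matching category in priority order, else None."""
    text = text.strip()
    if not text:
        raise ValueError("cannot classify an empty span")
    for cat in rules.priority:
        if any(p.search(text) for p in rules.patterns[cat]):
            return cat
    return None


def header_column_types(
    header_line: TextLine | str, rules: RuleSet
) -> list[tuple[EntityCategory, int]]:
    """Map header keywords to (category, start offset), sorted by offset."""
    text = header_line.text if isinstance(header_line, TextLine) else header_line
    low = text.lower()
    hits: list[tuple[EntityCategory, int]] = []
    claimed: set[EntityCategory] = set()
    for role, cat in _ROLE_TO_CATEGORY.items():
        best = None
        for kw in rules.header_keywords.get(role, []):
            pos = low.find(kw.lower())
            if pos >= 0 and (best is None or pos < best):
                best = pos
        if best is not None and cat not in claimed:
            hits.append((cat, best))
            claimed.add(cat)
    hits.sort(key=lambda t: t[1])
    return hits


_SPAN_SPLIT = re.compile(r"\s{2,}")


def _spans(text: str) -> list[tuple[str, int, int]]:
    """Split a line on runs of >= 2 spaces; single spaces bind in a span."""
    out = []
    pos = 0
    for part in _SPAN_SPLIT.split(text):
        if part.strip():
            start = text.index(part, pos)
            out.append((part.strip(), start, start + len(part.strip())))
            pos = start + len(part)
        else:
            pos += len(part)
    return out


def rule_extract(
    lines: Sequence[TextLine],
    region: TableRegion,
    rules: RuleSet,
    report_time: ReportTime | None = None,
) -> DigitalTable:
    """Extract the table with rules only (no learned model).

    Within the located region, each line is split into spans on runs of
    two or more spaces; spans are typed by :func:`rule_classify_span`,
    untyped spans falling back to the nearest header column's category by
    offset; records are then assembled exactly as in the layout stage.
    """
    header_cols = (
        header_column_types(lines[region.head_index], rules)
        if region.confident
        else []
    )

    per_line_entities: list[list[LabEntity]] = []
    body_lines: list[TextLine] = []
    for li in region.body_range():
        line = lines[li]
        ents: list[LabEntity] = []
        for text, start, end in _spans(line.text):
            cat = rule_classify_span(text, rules)
            if cat is None and header_cols:
                cat = min(header_cols, key=lambda t: abs(t[1] - start))[0]
            if cat is None:
                continue
            ents.append(
                LabEntity(
                    category=cat,
                    text=text,
                    start=start,
                    end=end,
                    line_index=len(body_lines),
                )
            )
        per_line_entities.append(link_entities(line.text, ents))
        body_lines.append(line)

    layouts = [detect_columns(ents) for ents in per_line_entities]
    return assemble_table(
        body_lines, per_line_entities, layouts, report_time=report_time
    )
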