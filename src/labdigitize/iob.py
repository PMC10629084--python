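"""Entity categories, typed spans, and the IOB tag scheme.

Each token of a line carries a tag from ``{O} ∪ {B-c, I-c}`` over the four
entity categories of a lab-report table: LabName (test item name), LabResult
(test result), LabUnit (unit), and LabRefRange (reference value range).
``encode_iob``/``decode_iob`` convert between character-offset entity spans
and per-token tag sequences; ``repair_tags`` makes arbitrary tag sequences
well-formed deterministically before decoding.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Sequence

from .tokenization import Token

__all__ = [
    "EntityCategory",
    "LabEntity",
    "AnnotationError",
    "encode_iob",
    "decode_iob",
    "repair_tags",
    "valid_tags",
    "TAG_ALPHABET",
]


class EntityCategory(str, Enum):
    LabName = "LabName"
    LabResult = "LabResult"
    LabUnit = "LabUnit"
    LabRefRange = "LabRefRange"


TAG_ALPHABET: tuple[str, ...] = ("O",) + tuple(
    f"{p}-{c.value}" for c in EntityCategory for p in ("B", "I")
)


class AnnotationError(ValueError):
    """Raised for inconsistent entity annotations (e.g. overlapping spans)."""


@dataclass(frozen=True)
class LabEntity:
    """A typed span inside one report line.

    ``linked_alt_text`` carries the second half of a linked pair: the
    other-script name of a bilingual LabName, or the qualitative value of a
    dual LabResult.
    """

    category: EntityCategory
    text: str
    start: int
    end: int
    line_index: int = 0
    linked_alt_text: str | None = None

    def __post_init__(self) -> None:
        if self.linked_alt_text is not None and self.category not in (
            EntityCategory.LabName,
            EntityCategory.LabResult,
        ):
            raise AnnotationError(
                "linked_alt_text only applies to LabName or LabResult"
            )


def encode_iob(
    line_text: str, tokens: Sequence[Token], entities: Sequence[LabEntity]
) -> list[str]:
    """Tag tokens with B-/I- labels for the entities covering them.

    A token gets a label only when it lies fully inside an entity span; the
    first such token of an entity is B-, the rest I-.  Entities must not
    overlap.
    """
    spans = sorted(entities, key=lambda e: e.start)
    for a, b in zip(spans, spans[1:]):
        if b.start < a.end:
            raise AnnotationError(
                f"overlapping entities at [{a.start},{a.end}) and "
                f"[{b.start},{b.end}) in line {line_text!r}"
            )
    tags = ["O"] * len(tokens)
    for ent in spans:
        first = True
        for i, tok in enumerate(tokens):
            if tok.start >= ent.start and tok.end <= ent.end:
                tags[i] = f"{'B' if first else 'I'}-{ent.category.value}"
                first = False
    return tags


def repair_tags(tags: Sequence[str]) -> list[str]:
    """Make a tag sequence IOB-valid, deterministically.

    A leading I-c with no open B-c of the same category becomes B-c; an I-c
    following a different category closes the previous entity and opens a
    new one.  Valid sequences pass through unchanged; the repair is
    idempotent.
    """
    out: list[str] = []
    open_cat: str | None = None
    for tag in tags:
        if tag == "O":
            out.append(tag)
            open_cat = None
        elif tag.startswith("B-"):
            out.append(tag)
            open_cat = tag[2:]
        else:  # I-c
            cat = tag[2:]
            if open_cat == cat:
                out.append(tag)
            else:
                out.append(f"B-{cat}")
                open_cat = cat
    return out


def valid_tags(tags: Sequence[str]) -> bool:
    return list(tags) == repair_tags(tags)


def decode_iob(
    line_text: str,
    tokens: Sequence[Token],
    tags: Sequence[str],
    line_index: int = 0,
) -> list[LabEntity]:
    """Turn a per-token tag sequence back into entity spans.

    Invalid transitions are repaired first.  Each maximal ``B-c (I-c)*``
    run becomes one entity whose text is the original line substring
    between the run's first and last token.
    """
    if len(tokens) != len(tags):
        raise ValueError(
            f"token/tag length mismatch: {len(tokens)} vs {len(tags)}"
        )
    tags = repair_tags(tags)
    entities: list[LabEntity] = []
    i = 0
    while i < len(tags):
        tag = tags[i]
        if tag.startswith("B-"):
            cat = tag[2:]
            j = i + 1
            while j < len(tags) and tags[j] == f"I-{cat}":
                j += 1
            start = tokens[i].start
            end = tokens[j - 1].end
            entities.append(
                LabEntity(
                    category=EntityCategory(cat),
                    text=line_text[start:end],
                    start=start,
                    end=end,
                    line_index=line_index,
                )
            )
            i = j
        else:
            i += 1
    return entities
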