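"""Named entity recognition over report lines.

:class:`EntityRecognizer` is the user-facing estimator: it is fitted on
annotated lines (text + character-offset entity spans) and predicts the
four lab-report entity categories on new lines, one line at a time (the
sequence model never crosses line boundaries).  Internally each line is
tokenized, featurized, tagged by a linear-chain CRF, repaired/decoded back
into spans, and finally adjacent bilingual LabNames / dual LabResults are
linked into single logical entities.
"""

from __future__ import annotations

import json
from typing import Iterable, Sequence

from sklearn.base import BaseEstimator

from .crf import CrfTagger
from .features import extract_features
from .iob import EntityCategory, LabEntity, decode_iob, encode_iob
from .ocr import TextLine
from .tokenization import cjk_portion, is_cjk, tokenize

__all__ = [
    "EntityRecognizer",
    "link_entities",
    "read_annotated_lines",
    "write_annotated_lines",
]

# Characters allowed (besides spaces) in the gap between two entities that
# are linked into one logical entity.
_LINK_GAP_CHARS = set(" ()（）")
_LINK_MAX_GAP = 2


def _linkable_gap(line_text: str, left: LabEntity, right: LabEntity) -> bool:
    gap = line_text[left.end : right.start]
    return len(gap) <= _LINK_MAX_GAP and all(c in _LINK_GAP_CHARS for c in gap)


def link_entities(line_text: str, entities: Sequence[LabEntity]) -> list[LabEntity]:
    """Link adjacent bilingual LabNames and dual LabResults.

    Two adjacent LabName entities with nothing but a short neutral gap
    between them (no intervening entity) merge into one LabName: its text
    is the CJK half and ``linked_alt_text`` the other-script half.  Two
    adjacent LabResults merge likewise, the second value stored as
    ``linked_alt_text``.  Entities must be sorted by start offset.
    """
    out: list[LabEntity] = []
    i = 0
    ents = list(entities)
    while i < len(ents):
        cur = ents[i]
        if (
            i + 1 < len(ents)
            and cur.category == ents[i + 1].category
            and cur.category in (EntityCategory.LabName, EntityCategory.LabResult)
            and cur.linked_alt_text is None
            and ents[i + 1].linked_alt_text is None
            and _linkable_gap(line_text, cur, ents[i + 1])
        ):
            nxt = ents[i + 1]
            if cur.category == EntityCategory.LabName:
                # The CJK name is primary; the other script is the alternate.
                if cjk_portion(cur.text) or not cjk_portion(nxt.text):
                    primary, alt = cur, nxt
                else:
                    primary, alt = nxt, cur
            else:
                primary, alt = cur, nxt
            out.append(
                LabEntity(
                    category=cur.category,
                    text=primary.text,
                    start=primary.start,
                    end=primary.end,
                    line_index=cur.line_index,
                    linked_alt_text=alt.text,
                )
            )
            i += 2
        else:
            out.append(cur)
            i += 1
    return out


class EntityRecognizer(BaseEstimator):
    """Line-wise CRF entity recognizer for lab-report tables.

    Parameters
    ----------
    c1, c2 : float
        Elastic-net penalties of the underlying CRF.
    max_iterations : int
        L-BFGS iteration cap.
    window : int
        Context window (tokens on each side) for feature extraction.
    link : bool
        Whether to link bilingual/dual entities after decoding.

    Attributes
    ----------
    crf_ : CrfTagger
        The fitted sequence model.
    """

    def __init__(
        self,
        c1: float = 0.1,
        c2: float = 0.1,
        max_iterations: int = 100,
        window: int = 2,
        link: bool = True,
    ):
        self.c1 = c1
        self.c2 = c2
        self.max_iterations = max_iterations
        self.window = window
        self.link = link

    def fit(self, lines: Sequence[str | TextLine], entities: Sequence[Sequence[LabEntity]]):
        """Fit on annotated lines.

        Parameters
        ----------
        lines : sequence of str or TextLine
        entities : per-line entity span lists (character offsets)
        """
        texts = [ln.text if isinstance(ln, TextLine) else ln for ln in lines]
        X, y = [], []
        for text, ents in zip(texts, entities):
            toks = tokenize(text)
            if not toks:
                continue
            X.append(extract_features(toks, window=self.window))
            y.append(encode_iob(text, toks, ents))
        self.crf_ = CrfTagger(
            c1=self.c1, c2=self.c2, max_iterations=self.max_iterations
        ).fit(X, y)
        return self

    def predict(self, lines: Sequence[str | TextLine]) -> list[list[LabEntity]]:
        """Predict (and optionally link) entities for each line."""
        if not hasattr(self, "crf_"):
            raise ValueError("EntityRecognizer is not fitted")
        texts = [ln.text if isinstance(ln, TextLine) else ln for ln in lines]
        token_lists = [tokenize(t) for t in texts]
        X = [
            extract_features(toks, window=self.window) if toks else []
            for toks in token_lists
        ]
        tag_lists = self.crf_.predict(X)
        out: list[list[LabEntity]] = []
        for i, (text, toks, tags) in enumerate(zip(texts, token_lists, tag_lists)):
            ents = decode_iob(text, toks, tags, line_index=i)
            if self.link:
                ents = link_entities(text, ents)
            out.append(ents)
        return out

    def save(self, path: str) -> None:
        self.crf_.save(path)

    @classmethod
    def load_crf(cls, path: str, window: int = 2, link: bool = True) -> "EntityRecognizer":
        """Rebuild a recognizer around a persisted CRF model."""
        model = cls(window=window, link=link)
        model.crf_ = CrfTagger.load(path)
        p = model.crf_.get_params()
        model.c1, model.c2 = p["c1"], p["c2"]
        model.max_iterations = p["max_iterations"]
        return model


# --------------------------------------------------------------------------
# Annotated-corpus serialization (JSON Lines)
# --------------------------------------------------------------------------


def read_annotated_lines(path: str) -> tuple[list[str], list[list[LabEntity]]]:
    """Read a JSONL training corpus: one object per report line.

    Each record is ``{"text": str, "entities": [{"start", "end",
    "category"}]}`` with 0-based half-open character offsets.
    """
    texts: list[str] = []
    entities: list[list[LabEntity]] = []
    with open(path, encoding="utf-8") as fh:
        for i, raw in enumerate(fh):
            raw = raw.strip()
            if not raw:
                continue
            rec = json.loads(raw)
            text = rec["text"]
            ents = [
                LabEntity(
                    category=EntityCategory(e["category"]),
                    text=text[e["start"] : e["end"]],
                    start=e["start"],
                    end=e["end"],
                    line_index=len(texts),
                )
                for e in rec.get("entities", [])
            ]
            texts.append(text)
            entities.append(ents)
    return texts, entities


def write_annotated_lines(
    path: str, texts: Sequence[str], entities: Sequence[Sequence[LabEntity]]
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for text, ents in zip(texts, entities):
            fh.write(
                json.dumps(
                    {
                        "text": text,
                        "entities": [
                            {"start": e.start, "end": e.end, "category": e.category.value}
                            for e in ents
                        ],
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )
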