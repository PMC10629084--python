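"""Evaluation: entity-level precision/recall/F1 and OCR accuracies.

Two surfaces, matching how extraction pipelines of this kind are scored:

* **Entity-level P/R/F1** — a predicted entity counts as correct when both
  its category and its normalized text match a still-unmatched gold entity
  of the same report; for LabName, agreement of the Chinese portion alone
  suffices (bilingual names are scored on the Chinese name).  Matching is
  greedy in document order, one-to-one within each report and category;
  for small reports this provably coincides with maximum bipartite
  matching because the match relation is an equivalence on texts.
* **OCR accuracies** — character level (edit alignment of the recognized
  character stream against the gold stream), detection-box level (gold
  boxes that map one-to-one to an identical predicted box), and line
  formation (gold lines reproduced exactly), averaged into one overall
  score.
"""

from __future__ import annotations

import difflib
import json
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .iob import EntityCategory, LabEntity
from .layout import DigitalTable
from .tokenization import cjk_portion

__all__ = [
    "CategoryMetrics",
    "MetricsReport",
    "OcrAccuracyReport",
    "normalize_entity_text",
    "match_entity",
    "prf_from_counts",
    "f1_score",
    "table_entities",
    "entity_prf",
    "ocr_accuracy",
]

_WS = re.compile(r"\s+")


def normalize_entity_text(text: str) -> str:
    """Trim and collapse internal whitespace."""
    return _WS.sub(" ", text.strip())


def match_entity(pred: LabEntity, gold: LabEntity) -> bool:
    """True iff category and normalized text agree.

    For LabName, a correct Chinese portion alone counts as a match (the
    Latin half of a bilingual name is not penalized); names without any
    Chinese characters fall back to full text comparison.
    """
    if pred.category != gold.category:
        return False
    p = normalize_entity_text(pred.text)
    g = normalize_entity_text(gold.text)
    if pred.category == EntityCategory.LabName:
        pc, gc = cjk_portion(p), cjk_portion(g)
        if gc:
            return pc == gc
    return p == g


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


@dataclass(frozen=True)
class CategoryMetrics:
    correct: int
    predicted: int
    gold: int

    @property
    def precision(self) -> float:
        return self.correct / self.predicted if self.predicted else 0.0

    @property
    def recall(self) -> float:
        return self.correct / self.gold if self.gold else 0.0

    @property
    def f1(self) -> float:
        return f1_score(self.precision, self.recall)


def prf_from_counts(correct: int, predicted: int, gold: int) -> CategoryMetrics:
    """Precision/recall/F1 from raw entity counts."""
    return CategoryMetrics(correct=correct, predicted=predicted, gold=gold)


@dataclass
class MetricsReport:
    """Per-category and overall entity metrics.

    ``overall`` aggregates micro (summed counts); ``macro_*`` are plain
    averages of the per-category rates, reported alongside because the two
    conventions differ and should never be conflated.
    """

    per_category: dict[EntityCategory, CategoryMetrics]
    warnings: list[str] = field(default_factory=list)

    @property
    def overall(self) -> CategoryMetrics:
        cats = self.per_category.values()
        return CategoryMetrics(
            correct=sum(c.correct for c in cats),
            predicted=sum(c.predicted for c in cats),
            gold=sum(c.gold for c in cats),
        )

    @property
    def macro_precision(self) -> float:
        cats = self.per_category.values()
        return sum(c.precision for c in cats) / len(self.per_category)

    @property
    def macro_recall(self) -> float:
        cats = self.per_category.values()
        return sum(c.recall for c in cats) / len(self.per_category)

    def to_dict(self) -> dict:
        def cat_dict(m: CategoryMetrics) -> dict:
            return {
                "correct": m.correct,
                "predicted": m.predicted,
                "gold": m.gold,
                "precision": m.precision,
                "recall": m.recall,
                "f1": m.f1,
            }

        return {
            "per_category": {
                c.value: cat_dict(m) for c, m in self.per_category.items()
            },
            "overall_micro": cat_dict(self.overall),
            "macro": {
                "precision": self.macro_precision,
                "recall": self.macro_recall,
                "f1": f1_score(self.macro_precision, self.macro_recall),
            },
            "warnings": self.warnings,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), ensure_ascii=False, indent=2)

    def to_text(self) -> str:
        """Human-readable table, metrics rounded to 2 decimals."""
        rows = [f"{'Category':<14}{'P':>8}{'R':>8}{'F1':>8}{'Gold':>8}"]
        for cat in EntityCategory:
            m = self.per_category.get(cat)
            if m is None:
                continue
            rows.append(
                f"{cat.value:<14}{m.precision:>8.2f}{m.recall:>8.2f}"
                f"{m.f1:>8.2f}{m.gold:>8d}"
            )
        o = self.overall
        rows.append(
            f"{'Overall':<14}{o.precision:>8.2f}{o.recall:>8.2f}"
            f"{o.f1:>8.2f}{o.gold:>8d}"
        )
        return "\n".join(rows)


def table_entities(table: DigitalTable) -> list[LabEntity]:
    """Flatten a digitalized table into scoreable entities.

    Every non-empty field becomes one entity; a linked alternate is part
    of the same logical entity, appended to its text (for LabName the
    Chinese-portion matching rule makes the alternate inert).
    """
    ents: list[LabEntity] = []
    for i, rec in enumerate(table.records):
        def add(cat: EntityCategory, text: str, alt: str | None = None) -> None:
            if text:
                full = f"{text} {alt}" if alt else text
                ents.append(
                    LabEntity(category=cat, text=full, start=0, end=max(len(full), 1),
                              line_index=i)
                )

        add(EntityCategory.LabName, rec.lab_name, rec.lab_name_alt)
        add(EntityCategory.LabResult, rec.lab_result, rec.lab_result_alt)
        add(EntityCategory.LabUnit, rec.lab_unit)
        add(EntityCategory.LabRefRange, rec.lab_ref_range)
    return ents


def _as_entities(obj) -> list[LabEntity]:
    if isinstance(obj, DigitalTable):
        return table_entities(obj)
    return list(obj)


def entity_prf(
    pred: Mapping[str, DigitalTable | Sequence[LabEntity]],
    gold: Mapping[str, DigitalTable | Sequence[LabEntity]],
) -> MetricsReport:
    """Entity-level metrics over reports aligned by identifier.

    Within each report and category, predictions are matched greedily in
    document order, each gold entity consumed at most once.
    """
    if set(pred) != set(gold):
        raise ValueError(
            f"report identifiers differ: pred-only {sorted(set(pred) - set(gold))}, "
            f"gold-only {sorted(set(gold) - set(pred))}"
        )
    warnings: list[str] = []
    counts = {c: [0, 0, 0] for c in EntityCategory}  # correct, predicted, gold
    for rid in sorted(gold):
        p_ents = _as_entities(pred[rid])
        g_ents = _as_entities(gold[rid])
        if not p_ents and not g_ents:
            warnings.append(f"report {rid}: no gold and no predicted entities")
        for cat in EntityCategory:
            p_cat = [e for e in p_ents if e.category == cat]
            g_cat = [e for e in g_ents if e.category == cat]
            counts[cat][1] += len(p_cat)
            counts[cat][2] += len(g_cat)
            used = [False] * len(g_cat)
            for pe in p_cat:
                for j, ge in enumerate(g_cat):
                    if not used[j] and match_entity(pe, ge):
                        used[j] = True
                        counts[cat][0] += 1
                        break
    report = MetricsReport(
        per_category={
            c: CategoryMetrics(correct=v[0], predicted=v[1], gold=v[2])
            for c, v in counts.items()
        },
        warnings=warnings,
    )
    if report.overall.gold == 0 and report.overall.predicted == 0:
        # Perfect silence on empty reports is not penalized.
        report.warnings.append("no gold and no predicted entities overall; "
                              "metrics reported as 1.0 by convention")
        report.per_category = {
            c: CategoryMetrics(correct=1, predicted=1, gold=1) for c in EntityCategory
        }
    return report


# --------------------------------------------------------------------------
# OCR accuracies
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class OcrAccuracyReport:
    character_accuracy: float
    box_accuracy: float
    line_accuracy: float

    @property
    def overall(self) -> float:
        """Arithmetic mean of the three accuracies."""
        return (self.character_accuracy + self.box_accuracy + self.line_accuracy) / 3.0

    def to_dict(self) -> dict:
        return {
            "character_accuracy": self.character_accuracy,
            "box_accuracy": self.box_accuracy,
            "line_accuracy": self.line_accuracy,
            "overall": self.overall,
        }


def ocr_accuracy(
    pred_lines: Sequence[Sequence[str]],
    gold_lines: Sequence[Sequence[str]],
) -> OcrAccuracyReport:
    """Score an OCR product against gold at three levels.

    Inputs are per-line lists of box texts: ``gold_lines`` defines the
    reference characters, box segmentation, and line segmentation.

    * character accuracy — matched characters in an edit alignment of the
      two character streams, divided by the gold character count;
    * box accuracy — gold boxes mapped one-to-one to an identical
      predicted box (a merged prediction leaves both constituents
      unmatched), divided by the gold box count;
    * line accuracy — gold lines reproduced exactly (same boxes, same
      order), one-to-one, divided by the gold line count.
    """
    if not gold_lines or all(not ln for ln in gold_lines):
        raise ValueError("gold OCR reference is empty")

    gold_chars = "".join("".join(ln) for ln in gold_lines)
    pred_chars = "".join("".join(ln) for ln in pred_lines)
    matcher = difflib.SequenceMatcher(a=gold_chars, b=pred_chars, autojunk=False)
    matched = sum(size for _, _, size in matcher.get_matching_blocks())
    character_accuracy = matched / len(gold_chars)

    gold_boxes = Counter(b for ln in gold_lines for b in ln)
    pred_boxes = Counter(b for ln in pred_lines for b in ln)
    box_hits = sum((gold_boxes & pred_boxes).values())
    box_accuracy = box_hits / sum(gold_boxes.values())

    gold_texts = Counter(" ".join(ln) for ln in gold_lines if ln)
    pred_texts = Counter(" ".join(ln) for ln in pred_lines if ln)
    line_hits = sum((gold_texts & pred_texts).values())
    line_accuracy = line_hits / sum(gold_texts.values())

    return OcrAccuracyReport(
        character_accuracy=character_accuracy,
        box_accuracy=box_accuracy,
        line_accuracy=line_accuracy,
    )
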