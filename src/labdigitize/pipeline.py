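"""End-to-end extraction: formed lines in, digitalized table out.

Stage order mirrors the five information-extraction sub-modules: time
detection, headline position, line normalization (applied to the located
table body), line-wise NER, and step detection for multi-column layouts,
followed by table assembly.
"""

from __future__ import annotations

import time as _time
from dataclasses import dataclass, field
from typing import Sequence

from .baseline import RuleSet, load_rules, rule_extract
from .iob import LabEntity
from .layout import DigitalTable, assemble_table, detect_columns
from .ner import EntityRecognizer, link_entities
from .ocr import OcrPage, TextLine, form_lines
from .preprocess import (
    HeadlineKeywords,
    NormalizationThresholds,
    TableRegion,
    detect_report_time,
    load_keyword_config,
    locate_table_region,
    normalize_lines,
)

__all__ = ["LabReportPipeline", "StageTimings"]


@dataclass
class StageTimings:
    """Per-stage wall-clock seconds of the last extraction."""

    seconds: dict[str, float] = field(default_factory=dict)

    def format(self) -> str:
        total = sum(self.seconds.values())
        rows = [f"{k:<16}{v * 1000:>9.1f} ms" for k, v in self.seconds.items()]
        rows.append(f"{'total':<16}{total * 1000:>9.1f} ms")
        return "\n".join(rows)


class LabReportPipeline:
    """Wire the stages together around a fitted :class:`EntityRecognizer`."""

    def __init__(
        self,
        recognizer: EntityRecognizer | None = None,
        keywords: HeadlineKeywords | None = None,
        thresholds: NormalizationThresholds | None = None,
        rules: RuleSet | None = None,
        column_order: str = "row_major",
    ):
        if keywords is None or thresholds is None:
            kw, th = load_keyword_config()
            keywords = keywords or kw
            thresholds = thresholds or th
        self.recognizer = recognizer
        self.keywords = keywords
        self.thresholds = thresholds
        self.rules = rules
        self.column_order = column_order
        self.timings = StageTimings()

    # -- shared front half --------------------------------------------------

    def _prepare(self, lines_or_page):
        t0 = _time.perf_counter()
        if isinstance(lines_or_page, OcrPage):
            lines = form_lines(lines_or_page)
        else:
            lines = list(lines_or_page)
        t1 = _time.perf_counter()
        report_time = detect_report_time(lines)
        t2 = _time.perf_counter()
        region = locate_table_region(lines, self.keywords)
        t3 = _time.perf_counter()
        body = normalize_lines(
            [lines[i] for i in region.body_range()], self.thresholds
        )
        t4 = _time.perf_counter()
        self.timings.seconds = {
            "line_formation": t1 - t0,
            "time_detection": t2 - t1,
            "headline_position": t3 - t2,
            "line_normalization": t4 - t3,
        }
        return lines, report_time, region, body

    # -- extraction paths ---------------------------------------------------

    def extract(self, lines_or_page) -> DigitalTable:
        """CRF path: prepare, recognize entities per line, assemble."""
        if self.recognizer is None:
            raise ValueError("pipeline has no fitted EntityRecognizer")
        lines, report_time, region, body = self._prepare(lines_or_page)
        t0 = _time.perf_counter()
        entities = self.recognizer.predict(body)
        t1 = _time.perf_counter()
        layouts = [detect_columns(e) for e in entities]
        table = assemble_table(
            body, entities, layouts,
            report_time=report_time, column_order=self.column_order,
        )
        t2 = _time.perf_counter()
        self.timings.seconds["ner"] = t1 - t0
        self.timings.seconds["step_detection"] = t2 - t1
        return table

    def extract_with_annotations(
        self,
        lines: Sequence[TextLine],
        annotations: Sequence[Sequence[LabEntity]],
    ) -> DigitalTable:
        """Oracle path: gold annotations substituted for the NER output.

        Isolates preprocessing/layout correctness from sequence-model
        quality.  ``annotations`` are indexed per document line; lines are
        not normalized (the annotations refer to the given clean lines).
        """
        report_time = detect_report_time(lines)
        region = locate_table_region(lines, self.keywords)
        body, body_entities = [], []
        for bi, li in enumerate(region.body_range()):
            if not lines[li].text.strip():
                continue
            body.append(lines[li])
            linked = link_entities(lines[li].text, list(annotations[li]))
            body_entities.append([e for e in linked])
        layouts = [detect_columns(e) for e in body_entities]
        return assemble_table(
            body, body_entities, layouts,
            report_time=report_time, column_order=self.column_order,
        )

    def extract_rules(self, lines_or_page) -> DigitalTable:
        """Rule-based path: the comparison arm, sharing the front half."""
        rules = self.rules or load_rules()
        lines, report_time, region, body = self._prepare(lines_or_page)
        # Rebuild a region over header + normalized body so offsets align.
        if region.confident:
            all_lines = [lines[region.head_index]] + body
            body_region = TableRegion(
                head_index=0, tail_index=len(all_lines) - 1,
                confident=True, tail_matched=False,
            )
        else:
            all_lines = body
            body_region = TableRegion(
                head_index=0, tail_index=max(len(body) - 1, 0),
                confident=False, tail_matched=False,
            )
        return rule_extract(all_lines, body_region, rules, report_time=report_time)
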