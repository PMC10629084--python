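"""Multi-column step detection and final table assembly.

Many paper reports print the result table in two or three repeated column
groups.  Step detection infers the layout of each line from its recognized
entities alone: the second (third) LabName on a line marks the start of a
repeated column group, and its start offset is where the line is cut.  The
assembler then buckets each segment's entities into one table record and
emits records row-major, yielding the final single-column digitalized table
(LabName, LabResult, LabUnit, LabRefRange) plus the report time.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field
from typing import Sequence

from .iob import EntityCategory, LabEntity
from .ocr import TextLine
from .preprocess import ReportTime

__all__ = [
    "ColumnLayout",
    "LabRecord",
    "DigitalTable",
    "detect_columns",
    "assemble_table",
    "tables_match",
    "write_table_csv",
    "read_table_csv",
    "table_sidecar",
]


@dataclass(frozen=True)
class ColumnLayout:
    """Per-line column structure: cut offsets where repeated columns begin."""

    n_columns: int
    split_offsets: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.n_columns < 1:
            raise ValueError("n_columns must be >= 1")
        if len(self.split_offsets) != self.n_columns - 1:
            raise ValueError("split_offsets must have n_columns - 1 entries")
        if any(b <= a for a, b in zip(self.split_offsets, self.split_offsets[1:])):
            raise ValueError("split_offsets must be strictly increasing")


@dataclass(frozen=True)
class LabRecord:
    """One row of the digitalized table."""

    lab_name: str
    lab_result: str = ""
    lab_unit: str = ""
    lab_ref_range: str = ""
    lab_name_alt: str | None = None
    lab_result_alt: str | None = None
    source: tuple[int, int] = (0, 0)  # (line_index, column_index)

    def __post_init__(self) -> None:
        if not self.lab_name:
            raise ValueError("lab_name must be non-empty")


@dataclass
class DigitalTable:
    """The pipeline's final product: ordered records plus the report time."""

    report_time: ReportTime | None
    records: list[LabRecord]
    warnings: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)


def detect_columns(line_entities: Sequence[LabEntity]) -> ColumnLayout:
    """Infer the column layout of one line from its LabName entities.

    Entities must be sorted by start offset with bilingual names already
    linked, so each logical test item contributes exactly one LabName.
    """
    name_starts = [
        e.start for e in line_entities if e.category == EntityCategory.LabName
    ]
    if len(name_starts) <= 1:
        return ColumnLayout(n_columns=1)
    return ColumnLayout(
        n_columns=len(name_starts), split_offsets=tuple(name_starts[1:])
    )


def _segment_index(layout: ColumnLayout, offset: int) -> int:
    seg = 0
    for cut in layout.split_offsets:
        if offset >= cut:
            seg += 1
    return seg


def _majority_order(per_line_entities: Sequence[Sequence[LabEntity]]) -> str | None:
    """Report-wide majority ordering of Unit vs RefRange (diagnostic only)."""
    unit_first = range_first = 0
    for ents in per_line_entities:
        pos = {e.category: e.start for e in ents}
        if EntityCategory.LabUnit in pos and EntityCategory.LabRefRange in pos:
            if pos[EntityCategory.LabUnit] < pos[EntityCategory.LabRefRange]:
                unit_first += 1
            else:
                range_first += 1
    if unit_first == range_first == 0:
        return None
    return "unit_before_range" if unit_first >= range_first else "range_before_unit"


def assemble_table(
    lines: Sequence[TextLine],
    per_line_entities: Sequence[Sequence[LabEntity]],
    per_line_layouts: Sequence[ColumnLayout] | None = None,
    report_time: ReportTime | None = None,
    column_order: str = "row_major",
) -> DigitalTable:
    """Assemble per-line entities into the single-column digitalized table.

    Each line is cut at its layout's split offsets; within a segment the
    first entity of each category fills the record (extras are logged).
    Records are emitted row-major — all segments of line *i* left-to-right
    before line *i+1*; ``column_order="column_major"`` re-sorts records for
    sources known to be filled down each column first.  Segments without a
    LabName yield no record and are logged as orphans.
    """
    if column_order not in ("row_major", "column_major"):
        raise ValueError(f"unknown column_order {column_order!r}")
    if per_line_layouts is None:
        per_line_layouts = [detect_columns(ents) for ents in per_line_entities]

    records: list[LabRecord] = []
    warnings: list[str] = []
    for li, (ents, layout) in enumerate(zip(per_line_entities, per_line_layouts)):
        buckets: list[dict[EntityCategory, LabEntity]] = [
            {} for _ in range(layout.n_columns)
        ]
        for ent in ents:
            seg = _segment_index(layout, ent.start)
            if ent.category in buckets[seg]:
                warnings.append(
                    f"line {li} segment {seg}: extra {ent.category.value} "
                    f"{ent.text!r} ignored"
                )
            else:
                buckets[seg][ent.category] = ent
        for ci, bucket in enumerate(buckets):
            name = bucket.get(EntityCategory.LabName)
            if name is None:
                if bucket:
                    warnings.append(
                        f"line {li} segment {ci}: orphan entities without a LabName"
                    )
                continue
            result = bucket.get(EntityCategory.LabResult)
            records.append(
                LabRecord(
                    lab_name=name.text,
                    lab_name_alt=name.linked_alt_text,
                    lab_result=result.text if result else "",
                    lab_result_alt=result.linked_alt_text if result else None,
                    lab_unit=bucket.get(EntityCategory.LabUnit).text
                    if EntityCategory.LabUnit in bucket
                    else "",
                    lab_ref_range=bucket.get(EntityCategory.LabRefRange).text
                    if EntityCategory.LabRefRange in bucket
                    else "",
                    source=(li, ci),
                )
            )

    if column_order == "column_major":
        records.sort(key=lambda r: (r.source[1], r.source[0]))

    order = _majority_order(per_line_entities)
    if order is not None:
        warnings.append(f"majority column order: {order}")
    return DigitalTable(report_time=report_time, records=records, warnings=warnings)


def tables_match(a: DigitalTable, b: DigitalTable) -> bool:
    """Field-exact record equality (ignoring provenance) plus report time."""
    if len(a.records) != len(b.records):
        return False
    for ra, rb in zip(a.records, b.records):
        if (
            ra.lab_name, ra.lab_name_alt, ra.lab_result, ra.lab_result_alt,
            ra.lab_unit, ra.lab_ref_range,
        ) != (
            rb.lab_name, rb.lab_name_alt, rb.lab_result, rb.lab_result_alt,
            rb.lab_unit, rb.lab_ref_range,
        ):
            return False
    ta = a.report_time.value if a.report_time else None
    tb = b.report_time.value if b.report_time else None
    return ta == tb


# --------------------------------------------------------------------------
# Serialization
# --------------------------------------------------------------------------

_CSV_HEADER = ["LabName", "LabResult", "LabUnit", "LabRefRange"]


def write_table_csv(table: DigitalTable, path: str | None = None) -> str:
    """Write the four-column table as RFC-4180 CSV; return the CSV text.

    Linked alternates are appended in parentheses so the CSV remains
    four-column.
    """
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(_CSV_HEADER)
    for rec in table.records:
        name = rec.lab_name + (f" ({rec.lab_name_alt})" if rec.lab_name_alt else "")
        result = rec.lab_result + (
            f" ({rec.lab_result_alt})" if rec.lab_result_alt else ""
        )
        writer.writerow([name, result, rec.lab_unit, rec.lab_ref_range])
    text = buf.getvalue()
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text


def read_table_csv(path_or_text: str, is_path: bool = True) -> DigitalTable:
    """Read a four-column table CSV back into a DigitalTable."""
    text = (
        open(path_or_text, encoding="utf-8").read() if is_path else path_or_text
    )
    rows = list(csv.reader(io.StringIO(text)))
    records = []
    for i, row in enumerate(rows[1:]):
        name, result, unit, rng = (row + ["", "", "", ""])[:4]
        name_alt = result_alt = None
        if name.endswith(")") and " (" in name:
            name, name_alt = name.rsplit(" (", 1)
            name_alt = name_alt[:-1]
        if result.endswith(")") and " (" in result:
            result, result_alt = result.rsplit(" (", 1)
            result_alt = result_alt[:-1]
        records.append(
            LabRecord(
                lab_name=name,
                lab_result=result,
                lab_unit=unit,
                lab_ref_range=rng,
                lab_name_alt=name_alt,
                lab_result_alt=result_alt,
                source=(i, 0),
            )
        )
    return DigitalTable(report_time=None, records=records)


def table_sidecar(table: DigitalTable) -> str:
    """JSON sidecar carrying the report time and assembly warnings."""
    return json.dumps(
        {
            "report_time": table.report_time.value.isoformat()
            if table.report_time
            else None,
            "warnings": table.warnings,
        },
        ensure_ascii=False,
        indent=2,
    )
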