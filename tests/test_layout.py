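"""Step detection for multi-column layouts and table assembly."""

from dataclasses import replace

import pytest

from labdigitize.iob import EntityCategory, LabEntity
from labdigitize.layout import (
    ColumnLayout,
    DigitalTable,
    LabRecord,
    assemble_table,
    detect_columns,
    read_table_csv,
    write_table_csv,
)
from labdigitize.ocr import TextLine
from labdigitize.pipeline import LabReportPipeline
from labdigitize.synthetic import default_templates, generate_report
from conftest import tables_equal


def ent(cat, text, start, line_index=0):
    return LabEntity(
        category=cat, text=text, start=start, end=start + len(text),
        line_index=line_index,
    )


class TestDetectColumns:
    def test_single_name_single_column(self):
        layout = detect_columns([ent(EntityCategory.LabName, "白细胞", 0)])
        assert layout.n_columns == 1 and layout.split_offsets == ()

    def test_second_name_starts_second_column(self):
        layout = detect_columns(
            [
                ent(EntityCategory.LabName, "白细胞", 0),
                ent(EntityCategory.LabResult, "6.2", 10),
                ent(EntityCategory.LabName, "红细胞", 40),
            ]
        )
        assert layout.n_columns == 2 and layout.split_offsets == (40,)

    def test_triple_column_counts_begin_spans(self):
        ents = [
            ent(EntityCategory.LabName, "甲", 0),
            ent(EntityCategory.LabName, "乙", 30),
            ent(EntityCategory.LabName, "丙", 60),
        ]
        # independent scan: count LabName spans directly
        assert sum(1 for e in ents if e.category == EntityCategory.LabName) == 3
        layout = detect_columns(ents)
        assert layout.n_columns == 3 and layout.split_offsets == (30, 60)

    def test_invalid_layout_rejected(self):
        with pytest.raises(ValueError):
            ColumnLayout(n_columns=2, split_offsets=())
        with pytest.raises(ValueError):
            ColumnLayout(n_columns=3, split_offsets=(40, 40))


class TestAssembleTable:
    def line_ents(self, li, base=0):
        return [
            ent(EntityCategory.LabName, "白细胞", base + 0, li),
            ent(EntityCategory.LabResult, "6.2", base + 10, li),
            ent(EntityCategory.LabUnit, "g/L", base + 16, li),
            ent(EntityCategory.LabRefRange, "3.5-9.5", base + 22, li),
        ]

    def test_single_column_identity(self):
        lines = [TextLine(text="x" * 30)] * 3
        per_line = [self.line_ents(i) for i in range(3)]
        table = assemble_table(lines, per_line)
        assert len(table.records) == 3
        assert all(r.lab_name == "白细胞" and r.lab_result == "6.2" for r in table.records)

    def test_double_column_row_major(self):
        ents = self.line_ents(0) + [
            replace(e, start=e.start + 40, end=e.end + 40)
            for e in self.line_ents(0)
        ]
        ents[4] = replace(ents[4], text="红细胞")
        table = assemble_table([TextLine(text="x" * 80)], [ents])
        assert [r.lab_name for r in table.records] == ["白细胞", "红细胞"]
        assert [r.source for r in table.records] == [(0, 0), (0, 1)]

    def test_column_major_resort(self):
        per_line = [
            self.line_ents(0)
            + [replace(e, start=e.start + 40, end=e.end + 40) for e in self.line_ents(0)],
            self.line_ents(1)
            + [replace(e, start=e.start + 40, end=e.end + 40) for e in self.line_ents(1)],
        ]
        lines = [TextLine(text="x" * 80)] * 2
        table = assemble_table(lines, per_line, column_order="column_major")
        assert [r.source for r in table.records] == [(0, 0), (1, 0), (0, 1), (1, 1)]

    def test_orphan_segment_produces_no_record(self):
        ents = [
            ent(EntityCategory.LabResult, "6.2", 0),
            ent(EntityCategory.LabUnit, "g/L", 8),
        ]
        table = assemble_table([TextLine(text="x" * 20)], [ents])
        assert table.records == []
        assert any("orphan" in w for w in table.warnings)

    def test_name_without_result_still_yields_record(self):
        ents = [ent(EntityCategory.LabName, "白细胞", 0)]
        table = assemble_table([TextLine(text="白细胞")], [ents])
        assert len(table.records) == 1
        assert table.records[0].lab_result == ""

    def test_extra_entity_logged_first_wins(self):
        ents = [
            ent(EntityCategory.LabName, "白细胞", 0),
            ent(EntityCategory.LabResult, "6.2", 5),
            ent(EntityCategory.LabResult, "7.7", 12),
        ]
        table = assemble_table([TextLine(text="x" * 20)], [ents])
        assert table.records[0].lab_result == "6.2"
        assert any("extra" in w for w in table.warnings)

    def test_segments_never_split_entities(self):
        """Every (linked) entity lies wholly inside one segment of its line."""
        from labdigitize.ner import link_entities

        tpl = default_templates()["double_bilingual"]
        bundle = generate_report(replace(tpl, n_items=20), seed=11)
        for line, ents in zip(bundle.clean_lines, bundle.gold_annotations):
            linked = link_entities(line.text, ents)
            layout = detect_columns(linked)
            for e in linked:
                segs = {
                    sum(1 for cut in layout.split_offsets if off >= cut)
                    for off in (e.start, e.end - 1)
                }
                assert len(segs) == 1


class TestGeneratorOracle:
    def test_double_column_twenty_items_matches_gold(self):
        """Oracle-NER assembly reproduces the generator's gold table."""
        tpl = replace(default_templates()["double_bilingual"], n_items=20)
        bundle = generate_report(tpl, seed=11)
        pipe = LabReportPipeline()
        table = pipe.extract_with_annotations(bundle.clean_lines, bundle.gold_annotations)
        assert len(table.records) == 20
        assert tables_equal(table, bundle.gold_table)

    def test_record_count_equals_name_bearing_segments(self):
        tpl = replace(default_templates()["triple_plain"], n_items=10)
        bundle = generate_report(tpl, seed=4)
        pipe = LabReportPipeline()
        table = pipe.extract_with_annotations(bundle.clean_lines, bundle.gold_annotations)
        assert len(table.records) == 10


class TestCsv:
    def test_round_trip_with_alternates(self):
        table = DigitalTable(
            report_time=None,
            records=[
                LabRecord(
                    lab_name="癌胚抗原", lab_name_alt="CEA", lab_result="2.3",
                    lab_unit="ng/mL", lab_ref_range="<5.0",
                ),
                LabRecord(lab_name="尿蛋白", lab_result="阴性", lab_ref_range="阴性"),
            ],
        )
        text = write_table_csv(table)
        assert text.splitlines()[0] == "LabName,LabResult,LabUnit,LabRefRange"
        again = read_table_csv(text, is_path=False)
        assert again.records[0].lab_name == "癌胚抗原"
        assert again.records[0].lab_name_alt == "CEA"
        assert again.records[1].lab_result == "阴性"
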