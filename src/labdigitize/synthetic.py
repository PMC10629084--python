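"""Synthetic lab-report corpus generator with an OCR noise model.

Real annotated scans of laboratory reports cannot ship with a software
package, so this module fabricates them: structurally realistic Chinese
hospital lab reports (four parts top-to-bottom — report time and test type,
patient information, the result table, signature and notes) over a bank of
~95 fabricated but format-realistic test items.  Templates vary the layout
the way real reports do: single/double/triple repeated column groups,
bilingual (Chinese + Latin) item names, dual results (numeric value plus a
qualitative call), swapped unit/reference-range order, and extra method or
note columns that are not extraction targets.

Every generated report is a :class:`GoldBundle` carrying the clean lines,
the gold four-column table, and gold per-line entity annotations — so the
extraction pipeline can be trained and scored offline.  :func:`corrupt`
then emulates the textual failure modes of an OCR stage: adjacent-line
swaps (misplaced lines), line splits, merged text items (a lost column
gap), and character substitutions/deletions from a visual confusion map
(e.g. ``101.1`` read as ``01.1``).  Each corruption is recorded in a
replayable noise log; the gold truth always refers to the clean report.
"""

from __future__ import annotations

import json
import random
import re
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from pathlib import Path
from typing import Sequence

from .iob import EntityCategory, LabEntity
from .layout import DigitalTable, LabRecord, write_table_csv
from .ner import write_annotated_lines
from .ocr import TextLine
from .preprocess import ReportTime

__all__ = [
    "LabItem",
    "ITEM_BANK",
    "ReportTemplate",
    "NoiseConfig",
    "GoldBundle",
    "default_templates",
    "default_template_mix",
    "generate_report",
    "corrupt",
    "replay_noise",
    "generate_corpus",
    "sample_reports",
    "training_lines",
]


@dataclass(frozen=True)
class LabItem:
    """One fabricated test item: bilingual name, unit, plausible range."""

    cjk: str
    abbr: str
    unit: str
    low: float
    high: float
    decimals: int = 2
    kind: str = "quant"  # quant | serology | urine


# Fabricated, format-realistic item bank (names/units/ranges follow common
# report conventions; values are not a copy of any proprietary catalogue).
ITEM_BANK: tuple[LabItem, ...] = tuple(
    LabItem(*row)
    for row in [
        ("白细胞计数", "WBC", "10^9/L", 3.5, 9.5, 2),
        ("红细胞计数", "RBC", "10^12/L", 3.8, 5.1, 2),
        ("血红蛋白", "HGB", "g/L", 115, 150, 0),
        ("红细胞压积", "HCT", "%", 35, 45, 1),
        ("平均红细胞体积", "MCV", "fL", 82, 100, 1),
        ("平均血红蛋白量", "MCH", "pg", 27, 34, 1),
        ("平均血红蛋白浓度", "MCHC", "g/L", 316, 354, 0),
        ("血小板计数", "PLT", "10^9/L", 125, 350, 0),
        ("中性粒细胞绝对值", "NEUT", "10^9/L", 1.8, 6.3, 2),
        ("淋巴细胞绝对值", "LYMPH", "10^9/L", 1.1, 3.2, 2),
        ("单核细胞绝对值", "MONO", "10^9/L", 0.1, 0.6, 2),
        ("嗜酸性粒细胞绝对值", "EO", "10^9/L", 0.02, 0.52, 2),
        ("嗜碱性粒细胞绝对值", "BASO", "10^9/L", 0.0, 0.06, 2),
        ("中性粒细胞百分比", "NEUT%", "%", 40, 75, 1),
        ("淋巴细胞百分比", "LYMPH%", "%", 20, 50, 1),
        ("单核细胞百分比", "MONO%", "%", 3, 10, 1),
        ("红细胞分布宽度", "RDW", "%", 11.5, 14.5, 1),
        ("血小板压积", "PCT", "%", 0.1, 0.28, 2),
        ("平均血小板体积", "MPV", "fL", 7.4, 10.4, 1),
        ("网织红细胞百分比", "RET%", "%", 0.5, 1.5, 1),
        ("丙氨酸氨基转移酶", "ALT", "U/L", 9, 50, 0),
        ("天冬氨酸氨基转移酶", "AST", "U/L", 15, 40, 0),
        ("总蛋白", "TP", "g/L", 65, 85, 1),
        ("白蛋白", "ALB", "g/L", 40, 55, 1),
        ("球蛋白", "GLB", "g/L", 20, 40, 1),
        ("白球比值", "A/G", "", 1.2, 2.4, 2),
        ("总胆红素", "TBIL", "μmol/L", 3.4, 23.0, 1),
        ("直接胆红素", "DBIL", "μmol/L", 0.1, 8.0, 1),
        ("碱性磷酸酶", "ALP", "U/L", 45, 125, 0),
        ("谷氨酰转肽酶", "GGT", "U/L", 10, 60, 0),
        ("胆碱酯酶", "CHE", "U/L", 5000, 12000, 0),
        ("腺苷脱氨酶", "ADA", "U/L", 4, 18, 0),
        ("尿素", "UREA", "mmol/L", 3.1, 8.0, 1),
        ("肌酐", "CREA", "μmol/L", 57, 97, 0),
        ("尿酸", "UA", "μmol/L", 208, 428, 0),
        ("葡萄糖", "GLU", "mmol/L", 3.9, 6.1, 2),
        ("总胆固醇", "TC", "mmol/L", 2.8, 5.2, 2),
        ("甘油三酯", "TG", "mmol/L", 0.4, 1.7, 2),
        ("高密度脂蛋白胆固醇", "HDL-C", "mmol/L", 1.0, 1.6, 2),
        ("低密度脂蛋白胆固醇", "LDL-C", "mmol/L", 1.3, 3.4, 2),
        ("载脂蛋白A1", "ApoA1", "g/L", 1.0, 1.6, 2),
        ("载脂蛋白B", "ApoB", "g/L", 0.6, 1.1, 2),
        ("脂蛋白a", "Lp(a)", "mg/L", 1, 300, 0),
        ("钾", "K", "mmol/L", 3.5, 5.3, 2),
        ("钠", "Na", "mmol/L", 137, 147, 0),
        ("氯", "Cl", "mmol/L", 99, 110, 0),
        ("钙", "Ca", "mmol/L", 2.11, 2.52, 2),
        ("磷", "P", "mmol/L", 0.85, 1.51, 2),
        ("镁", "Mg", "mmol/L", 0.75, 1.02, 2),
        ("乳酸脱氢酶", "LDH", "U/L", 120, 250, 0),
        ("肌酸激酶", "CK", "U/L", 50, 310, 0),
        ("肌酸激酶同工酶", "CK-MB", "U/L", 0, 24, 0),
        ("淀粉酶", "AMY", "U/L", 35, 135, 0),
        ("脂肪酶", "LIP", "U/L", 13, 60, 0),
        ("乳酸", "LAC", "mmol/L", 0.5, 1.7, 2),
        ("二氧化碳结合力", "CO2CP", "mmol/L", 22, 29, 1),
        ("阴离子间隙", "AG", "mmol/L", 8, 16, 1),
        ("渗透压", "OSM", "mOsm/kg", 275, 300, 0),
        ("超敏C反应蛋白", "hs-CRP", "mg/L", 0.1, 3.0, 2),
        ("降钙素原", "PCT", "ng/mL", 0.01, 0.05, 3),
        ("红细胞沉降率", "ESR", "mm/h", 1, 15, 0),
        ("铁蛋白", "FER", "ng/mL", 30, 400, 1),
        ("维生素B12", "VB12", "pg/mL", 197, 771, 0),
        ("叶酸", "FOL", "ng/mL", 3.1, 20.5, 1),
        ("总前列腺特异性抗原", "TPSA", "ng/mL", 0.01, 4.0, 3),
        ("游离前列腺特异性抗原", "FPSA", "ng/mL", 0.01, 0.93, 3),
        ("癌胚抗原", "CEA", "ng/mL", 0.2, 5.0, 2),
        ("甲胎蛋白", "AFP", "ng/mL", 0.5, 7.0, 2),
        ("糖类抗原125", "CA125", "U/mL", 1, 35, 1),
        ("糖类抗原199", "CA199", "U/mL", 1, 27, 1),
        ("糖类抗原153", "CA153", "U/mL", 1, 25, 1),
        ("神经元特异性烯醇化酶", "NSE", "ng/mL", 1.0, 16.3, 2),
        ("细胞角蛋白19片段", "CYFRA21-1", "ng/mL", 0.1, 3.3, 2),
        ("鳞状细胞癌抗原", "SCC", "ng/mL", 0.1, 2.7, 2),
        ("促甲状腺激素", "TSH", "mIU/L", 0.27, 4.2, 2),
        ("游离三碘甲状腺原氨酸", "FT3", "pmol/L", 3.1, 6.8, 2),
        ("游离甲状腺素", "FT4", "pmol/L", 12, 22, 1),
        ("总三碘甲状腺原氨酸", "TT3", "nmol/L", 1.3, 3.1, 2),
        ("总甲状腺素", "TT4", "nmol/L", 66, 181, 0),
        ("糖化血红蛋白", "HbA1c", "%", 4.0, 6.0, 1),
        ("凝血酶原时间", "PT", "s", 9.4, 12.5, 1),
        ("活化部分凝血活酶时间", "APTT", "s", 25.1, 36.5, 1),
        ("凝血酶时间", "TT", "s", 10.3, 16.6, 1),
        ("纤维蛋白原", "FIB", "g/L", 2.38, 4.98, 2),
        ("D-二聚体", "D-Dimer", "mg/L", 0.01, 0.55, 2),
        ("国际标准化比值", "INR", "", 0.8, 1.2, 2),
        ("胱抑素C", "CysC", "mg/L", 0.59, 1.03, 2),
        ("肌红蛋白", "MYO", "ng/mL", 5, 70, 1),
        ("肌钙蛋白I", "cTnI", "ng/mL", 0.001, 0.04, 3),
        ("B型钠尿肽", "BNP", "pg/mL", 5, 100, 1),
        ("同型半胱氨酸", "HCY", "μmol/L", 5, 15, 1),
        ("乙肝表面抗原", "HBsAg", "S/CO", 0.0, 1.0, 2, "serology"),
        ("乙肝表面抗体", "HBsAb", "mIU/mL", 0.0, 10.0, 1, "serology"),
        ("乙肝e抗原", "HBeAg", "S/CO", 0.0, 1.0, 2, "serology"),
        ("乙肝核心抗体", "HBcAb", "S/CO", 0.0, 1.0, 2, "serology"),
        ("丙型肝炎病毒抗体", "HCV-Ab", "S/CO", 0.0, 1.0, 2, "serology"),
        ("梅毒螺旋体抗体", "TP-Ab", "S/CO", 0.0, 1.0, 2, "serology"),
        ("人免疫缺陷病毒抗体", "HIV-Ab", "S/CO", 0.0, 1.0, 2, "serology"),
        ("尿蛋白", "PRO", "", 0.0, 0.0, 0, "urine"),
        ("尿葡萄糖", "GLU-U", "", 0.0, 0.0, 0, "urine"),
        ("尿酮体", "KET", "", 0.0, 0.0, 0, "urine"),
        ("尿潜血", "BLD", "", 0.0, 0.0, 0, "urine"),
        ("尿亚硝酸盐", "NIT", "", 0.0, 0.0, 0, "urine"),
    ]
)


@dataclass(frozen=True)
class ReportTemplate:
    """Layout recipe for one family of generated reports."""

    name: str
    n_columns: int = 1
    column_order: tuple[str, ...] = ("result", "unit", "range")
    bilingual_names: bool = True
    dual_results: bool = False
    extra_columns: tuple[str, ...] = ()
    with_item_numbers: bool = False
    n_items: int = 12
    title: str = "综合医院检验报告单"
    test_type: str = "生化检验"

    def __post_init__(self) -> None:
        if self.n_items < 1:
            raise ValueError("n_items must be >= 1")
        if sorted(self.column_order) != ["range", "result", "unit"]:
            raise ValueError("column_order must permute (result, unit, range)")
        if self.n_columns not in (1, 2, 3):
            raise ValueError("n_columns must be 1, 2 or 3")


@dataclass(frozen=True)
class NoiseConfig:
    """Textual OCR corruption rates (all probabilities per opportunity)."""

    p_merge: float = 0.05
    p_line_split: float = 0.05
    p_line_swap: float = 0.03
    p_char_sub: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_merge", "p_line_split", "p_line_swap", "p_char_sub"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class GoldBundle:
    """A generated report with its ground truth and corruption history."""

    clean_lines: list[TextLine]
    noisy_lines: list[TextLine]
    gold_table: DigitalTable
    gold_annotations: list[list[LabEntity]]
    noise_log: list[tuple]
    template: ReportTemplate
    seed: int


def default_templates() -> dict[str, ReportTemplate]:
    """Layout presets covering the documented real-report variations."""
    return {
        "single_bilingual": ReportTemplate(
            name="single_bilingual", n_columns=1, bilingual_names=True
        ),
        "single_dual_results": ReportTemplate(
            name="single_dual_results",
            n_columns=1,
            bilingual_names=False,
            dual_results=True,
            test_type="病毒检验",
        ),
        "single_extras_swapped": ReportTemplate(
            name="single_extras_swapped",
            n_columns=1,
            column_order=("result", "range", "unit"),
            bilingual_names=True,
            extra_columns=("method", "note"),
            with_item_numbers=True,
            test_type="肿瘤标志物检验",
        ),
        "double_bilingual": ReportTemplate(
            name="double_bilingual", n_columns=2, bilingual_names=True,
            test_type="全血细胞分析",
        ),
        "triple_plain": ReportTemplate(
            name="triple_plain", n_columns=3, bilingual_names=False, n_items=18
        ),
    }


def default_template_mix() -> dict[str, float]:
    return {
        "single_bilingual": 0.25,
        "single_dual_results": 0.20,
        "single_extras_swapped": 0.20,
        "double_bilingual": 0.25,
        "triple_plain": 0.10,
    }


# --------------------------------------------------------------------------
# Clean report generation
# --------------------------------------------------------------------------

_HEADER_CELLS = {
    "number": "序号",
    "name": "项目名称",
    "result": "结果",
    "unit": "单位",
    "range": "参考范围",
    "method": "方法",
    "note": "提示",
}

_SURNAMES = "王李张刘陈杨赵黄周吴"


def _format_value(item: LabItem, rng: random.Random) -> tuple[str, str | None]:
    """Draw a result value; returns (value text, qualitative text or None)."""
    if item.kind == "urine":
        qual = rng.choices(["阴性", "阳性", "弱阳性"], weights=[0.8, 0.15, 0.05])[0]
        return qual, None
    out_of_range = rng.random() < 0.15
    if out_of_range and item.low > 0 and rng.random() < 0.5:
        v = item.low * rng.uniform(0.8, 0.95)
        marker = "↓"
    elif out_of_range:
        v = item.high * rng.uniform(1.05, 1.2)
        marker = "↑"
    else:
        v = rng.uniform(item.low, item.high)
        marker = ""
    text = f"{v:.{item.decimals}f}{marker}"
    if item.kind == "serology":
        qual = "阳性" if marker == "↑" else "阴性"
        return text, qual
    return text, None


def _range_text(item: LabItem) -> str:
    if item.kind == "urine":
        return "阴性"
    fmt = f"{{:.{item.decimals}f}}"
    if item.kind == "serology":
        return "<" + fmt.format(item.high)
    if item.low == 0.0:
        return "<" + fmt.format(item.high)
    return fmt.format(item.low) + "-" + fmt.format(item.high)


def _field_sequence(template: ReportTemplate) -> list[str]:
    fields = []
    if template.with_item_numbers:
        fields.append("number")
    fields.append("name")
    fields.extend(template.column_order)
    for extra in template.extra_columns:
        fields.append(extra)
    return fields


def _item_cells(
    item: LabItem,
    number: int,
    template: ReportTemplate,
    rng: random.Random,
) -> tuple[dict[str, tuple[str, list[tuple[int, int, EntityCategory]]]], LabRecord]:
    """Cell texts + relative entity spans for one item, plus its gold record."""
    cells: dict[str, tuple[str, list[tuple[int, int, EntityCategory]]]] = {}

    if template.with_item_numbers:
        cells["number"] = (str(number), [])

    name_alt = None
    if template.bilingual_names:
        text = f"{item.cjk} {item.abbr}"
        spans = [
            (0, len(item.cjk), EntityCategory.LabName),
            (len(item.cjk) + 1, len(text), EntityCategory.LabName),
        ]
        name_alt = item.abbr
    else:
        text = item.cjk
        spans = [(0, len(item.cjk), EntityCategory.LabName)]
    cells["name"] = (text, spans)

    value, qual = _format_value(item, rng)
    result_alt = None
    if qual is not None and template.dual_results:
        text = f"{value}  {qual}"
        spans = [
            (0, len(value), EntityCategory.LabResult),
            (len(value) + 2, len(text), EntityCategory.LabResult),
        ]
        result_alt = qual
    else:
        text = value
        spans = [(0, len(value), EntityCategory.LabResult)]
    cells["result"] = (text, spans)

    unit = item.unit
    cells["unit"] = (unit, [(0, len(unit), EntityCategory.LabUnit)] if unit else [])

    rng_text = _range_text(item)
    cells["range"] = (rng_text, [(0, len(rng_text), EntityCategory.LabRefRange)])

    if "method" in template.extra_columns:
        cells["method"] = (rng.choice(["化学发光法", "速率法", "比浊法", "电极法"]), [])
    if "note" in template.extra_columns:
        note = "偏高" if "↑" in value else ("偏低" if "↓" in value else "")
        cells["note"] = (note, [])

    record = LabRecord(
        lab_name=item.cjk,
        lab_name_alt=name_alt,
        lab_result=value,
        lab_result_alt=result_alt,
        lab_unit=unit,
        lab_ref_range=rng_text,
    )
    return cells, record


def generate_report(
    template: ReportTemplate,
    item_bank: Sequence[LabItem] = ITEM_BANK,
    seed: int = 0,
) -> GoldBundle:
    """Generate one clean report bundle, deterministic in ``seed``.

    The document follows the four-part structure of real reports: report
    time and test type, patient information, the result table, and
    signature/notes.  Items are drawn without replacement from the bank.
    """
    if len(item_bank) < template.n_items:
        raise ValueError(
            f"item bank has {len(item_bank)} entries, need {template.n_items}"
        )
    rng = random.Random(seed)

    if template.dual_results:
        pool = [it for it in item_bank if it.kind == "serology"]
        pool += [it for it in item_bank if it.kind != "serology"]
        items = pool[: template.n_items]
        rng.shuffle(items)
    else:
        items = rng.sample([it for it in item_bank if it.kind != "urine"],
                           template.n_items)

    # Part 1: title, test type, datetimes (collection earliest = report time).
    report_dt = datetime(
        rng.randint(2019, 2023), rng.randint(1, 12), rng.randint(1, 28),
        rng.randint(8, 18), rng.randint(0, 59),
    )
    collect_dt = report_dt - timedelta(hours=rng.randint(2, 30))
    fmt = "%Y-%m-%d %H:%M"
    lines_text: list[str] = [
        template.title,
        f"标本类型: 血清    检验类别: {template.test_type}",
        f"采集时间: {collect_dt.strftime(fmt)}    报告时间: {report_dt.strftime(fmt)}",
        "",
        f"姓名: {rng.choice(_SURNAMES)}某  性别: {rng.choice('男女')}  "
        f"年龄: {rng.randint(18, 88)}岁  病历号: {rng.randint(100000, 999999)}",
        "",
    ]
    annotations: list[list[LabEntity]] = [[] for _ in lines_text]

    # Part 3: table. Compute per-field cell data, then column widths.
    fields = _field_sequence(template)
    per_item = [
        _item_cells(item, i + 1, template, rng) for i, item in enumerate(items)
    ]
    widths = {
        f: max(
            [len(_HEADER_CELLS[f])]
            + [len(cells[f][0]) for cells, _ in per_item if f in cells]
        )
        + 2
        for f in fields
    }

    def compose(groups: list[dict]) -> tuple[str, list[LabEntity]]:
        text_parts: list[str] = []
        ents: list[LabEntity] = []
        cursor = 0
        for group in groups:
            for f in fields:
                cell_text, spans = group.get(f, ("", []))
                for s, e, cat in spans:
                    ents.append(
                        LabEntity(
                            category=cat,
                            text=cell_text[s:e],
                            start=cursor + s,
                            end=cursor + e,
                        )
                    )
                text_parts.append(cell_text.ljust(widths[f]))
                cursor += widths[f]
        line = "".join(text_parts).rstrip()
        return line, ents

    header_groups = [
        {f: (_HEADER_CELLS[f], []) for f in fields}
    ] * template.n_columns
    header_line, _ = compose(header_groups)
    lines_text.append(header_line)
    annotations.append([])

    # Row-major placement: consecutive items fill one physical line's
    # column groups left to right.
    records: list[LabRecord] = []
    line_index_base = len(lines_text)
    row = 0
    for start in range(0, len(per_item), template.n_columns):
        chunk = per_item[start : start + template.n_columns]
        line, ents = compose([cells for cells, _ in chunk])
        ents = [
            replace(e, line_index=line_index_base + row) for e in ents
        ]
        lines_text.append(line)
        annotations.append(ents)
        for ci, (_, rec) in enumerate(chunk):
            records.append(replace(rec, source=(row, ci)))
        row += 1

    # Part 4: signature and notes.
    lines_text += [
        "",
        f"检验者: {rng.choice(_SURNAMES)}技师    审核者: {rng.choice(_SURNAMES)}医师",
        "备注: 本结果仅对该标本负责",
    ]
    annotations += [[], [], []]

    clean_lines = [TextLine(text=t) for t in lines_text]
    gold_time = ReportTime(value=collect_dt, source_line=2, raw_text=collect_dt.strftime(fmt))
    gold_table = DigitalTable(report_time=gold_time, records=records)
    return GoldBundle(
        clean_lines=clean_lines,
        noisy_lines=list(clean_lines),
        gold_table=gold_table,
        gold_annotations=annotations,
        noise_log=[],
        template=template,
        seed=seed,
    )


# --------------------------------------------------------------------------
# Noise model
# --------------------------------------------------------------------------

# Visually confusable characters; "" entries model character loss (the
# leading-digit-drop error class).
_CONFUSION = {
    "0": ["O", ""],
    "1": ["l", ""],
    "2": ["Z"],
    "5": ["S"],
    "6": ["b"],
    "8": ["B"],
    "9": ["g"],
    "O": ["0"],
    "l": ["1"],
    "B": ["8"],
    ".": [""],
}


def _apply_event(texts: list[str], event: tuple) -> None:
    kind = event[0]
    if kind == "swap":
        i = event[1]
        texts[i], texts[i + 1] = texts[i + 1], texts[i]
    elif kind == "split":
        i, pos = event[1], event[2]
        left, right = texts[i][:pos].rstrip(), texts[i][pos:].lstrip()
        texts[i : i + 1] = [left, right]
    elif kind == "merge":
        i, gap_start, gap_len = event[1], event[2], event[3]
        t = texts[i]
        texts[i] = t[:gap_start] + t[gap_start + gap_len :]
    elif kind == "sub":
        i, pos, repl = event[1], event[2], event[3]
        t = texts[i]
        texts[i] = t[:pos] + repl + t[pos + 1 :]
    else:  # pragma: no cover
        raise ValueError(f"unknown noise event {kind!r}")


def replay_noise(clean_lines: Sequence[TextLine], noise_log: Sequence[tuple]) -> list[TextLine]:
    """Re-apply a recorded noise log to clean lines (exact reproduction)."""
    texts = [ln.text for ln in clean_lines]
    for event in noise_log:
        _apply_event(texts, event)
    return [TextLine(text=t) for t in texts]


def corrupt(bundle: GoldBundle, noise: NoiseConfig) -> GoldBundle:
    """Apply OCR-style corruption to a clean bundle.

    Events are drawn and applied in a fixed order — adjacent-line swaps,
    then line splits, then text-item merges, then character substitutions —
    so the recorded noise log replays unambiguously.  The gold table and
    annotations still describe the clean report.
    """
    rng = random.Random(noise.seed)
    texts = [ln.text for ln in bundle.clean_lines]
    log: list[tuple] = []

    def apply(event: tuple) -> None:
        _apply_event(texts, event)
        log.append(event)

    # 1) misplaced lines: swap adjacent non-empty pairs
    i = 0
    while i < len(texts) - 1:
        if texts[i].strip() and texts[i + 1].strip() and rng.random() < noise.p_line_swap:
            apply(("swap", i))
            i += 2
        else:
            i += 1

    # 2) line splits at an internal space
    i = 0
    while i < len(texts):
        t = texts[i]
        gaps = [j for j, ch in enumerate(t) if ch == " " and 0 < j < len(t) - 1]
        if gaps and rng.random() < noise.p_line_split:
            apply(("split", i, rng.choice(gaps)))
            i += 2
        else:
            i += 1

    # 3) merged text items: a multi-space gap collapses
    for i, t in enumerate(list(texts)):
        runs = [(m.start(), m.end() - m.start()) for m in re.finditer(r" {2,}", t)]
        if runs and rng.random() < noise.p_merge:
            gs, gl = rng.choice(runs)
            apply(("merge", i, gs, gl))

    # 4) character substitutions / deletions from the confusion map
    for i in range(len(texts)):
        # iterate right-to-left so recorded positions stay valid on deletion
        for pos in range(len(texts[i]) - 1, -1, -1):
            ch = texts[i][pos]
            if ch in _CONFUSION and rng.random() < noise.p_char_sub:
                apply(("sub", i, pos, rng.choice(_CONFUSION[ch])))

    return replace(
        bundle,
        noisy_lines=[TextLine(text=t) for t in texts],
        noise_log=log,
    )


def sample_reports(
    n: int,
    seed: int,
    noise: NoiseConfig | None = None,
    template_mix: dict[str, float] | None = None,
    n_items_range: tuple[int, int] = (8, 20),
) -> list[GoldBundle]:
    """Draw ``n`` in-memory report bundles from the template mix.

    Deterministic in ``seed``; per-report noise seeds are derived from it
    when a noise configuration is given.
    """
    templates = default_templates()
    mix = template_mix or default_template_mix()
    names = sorted(mix)
    weights = [mix[t] for t in names]
    rng = random.Random(seed)
    bundles = []
    for _ in range(n):
        tname = rng.choices(names, weights=weights)[0]
        tpl = replace(templates[tname], n_items=rng.randint(*n_items_range))
        bundle = generate_report(tpl, seed=rng.randrange(2**31))
        if noise is not None:
            bundle = corrupt(bundle, replace(noise, seed=rng.randrange(2**31)))
        bundles.append(bundle)
    return bundles


def training_lines(bundles: Sequence[GoldBundle]) -> tuple[list[str], list[list[LabEntity]]]:
    """Non-empty clean lines with their gold annotations, for NER training."""
    texts: list[str] = []
    ents: list[list[LabEntity]] = []
    for b in bundles:
        for ln, an in zip(b.clean_lines, b.gold_annotations):
            if ln.text.strip():
                texts.append(ln.text)
                ents.append(an)
    return texts, ents


# --------------------------------------------------------------------------
# Corpus generation
# --------------------------------------------------------------------------


def generate_corpus(
    n_reports: int,
    out_dir: str | Path,
    template_mix: dict[str, float] | None = None,
    noise: NoiseConfig | None = None,
    seed: int = 0,
    train_frac: float = 0.8,
    n_items_range: tuple[int, int] = (8, 20),
) -> dict:
    """Write a train/test corpus of paired noisy reports and gold truth.

    Each report lands in ``<out_dir>/{train,test}/NNN/`` with files
    ``clean.txt``, ``noisy.txt``, ``gold.csv``, ``gold.jsonl`` (per-line
    entity annotations over the clean lines) and ``meta.json``.  Returns
    the manifest (also written to ``manifest.json``).
    """
    if n_reports < 2:
        raise ValueError("n_reports must be >= 2")
    mix = template_mix or default_template_mix()
    total = sum(mix.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"template mix weights sum to {total}, expected 1")
    templates = default_templates()
    unknown = set(mix) - set(templates)
    if unknown:
        raise ValueError(f"unknown template names: {sorted(unknown)}")
    noise = noise or NoiseConfig()
    rng = random.Random(seed)

    out = Path(out_dir)
    names = sorted(mix)
    weights = [mix[n] for n in names]
    n_test = max(1, round(n_reports * (1.0 - train_frac)))
    split_flags = ["test"] * n_test + ["train"] * (n_reports - n_test)
    rng.shuffle(split_flags)

    manifest = {
        "n_reports": n_reports,
        "seed": seed,
        "noise": {
            "p_merge": noise.p_merge,
            "p_line_split": noise.p_line_split,
            "p_line_swap": noise.p_line_swap,
            "p_char_sub": noise.p_char_sub,
        },
        "template_mix": mix,
        "reports": [],
    }
    for r in range(n_reports):
        tname = rng.choices(names, weights=weights)[0]
        n_items = rng.randint(*n_items_range)
        template = replace(templates[tname], n_items=n_items)
        report_seed = rng.randrange(2**31)
        noise_seed = rng.randrange(2**31)
        bundle = generate_report(template, seed=report_seed)
        bundle = corrupt(bundle, replace(noise, seed=noise_seed))

        rid = f"{r:03d}"
        rdir = out / split_flags[r] / rid
        rdir.mkdir(parents=True, exist_ok=True)
        (rdir / "clean.txt").write_text(
            "\n".join(ln.text for ln in bundle.clean_lines), encoding="utf-8"
        )
        (rdir / "noisy.txt").write_text(
            "\n".join(ln.text for ln in bundle.noisy_lines), encoding="utf-8"
        )
        write_table_csv(bundle.gold_table, str(rdir / "gold.csv"))
        write_annotated_lines(
            str(rdir / "gold.jsonl"),
            [ln.text for ln in bundle.clean_lines],
            bundle.gold_annotations,
        )
        meta = {
            "id": rid,
            "split": split_flags[r],
            "template": tname,
            "n_items": n_items,
            "n_columns": template.n_columns,
            "report_seed": report_seed,
            "noise_seed": noise_seed,
            "report_time": bundle.gold_table.report_time.value.isoformat(),
            "n_noise_events": len(bundle.noise_log),
        }
        (rdir / "meta.json").write_text(
            json.dumps(meta, ensure_ascii=False, indent=2), encoding="utf-8"
        )
        manifest["reports"].append(meta)

    out.mkdir(parents=True, exist_ok=True)
    (out / "manifest.json").write_text(
        json.dumps(manifest, ensure_ascii=False, indent=2), encoding="utf-8"
    )
    return manifest
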