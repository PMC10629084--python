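"""Entity matching, P/R/F1 aggregation, and OCR accuracies."""

import random

import pytest
from scipy.optimize import linear_sum_assignment

from labdigitize.evaluation import (
    MetricsReport,
    OcrAccuracyReport,
    entity_prf,
    f1_score,
    match_entity,
    normalize_entity_text,
    ocr_accuracy,
    prf_from_counts,
)
from labdigitize.iob import EntityCategory, LabEntity


def ent(cat, text):
    return LabEntity(category=cat, text=text, start=0, end=max(len(text), 1))


class TestMatchEntity:
    def test_chinese_name_portion_suffices(self):
        assert match_entity(
            ent(EntityCategory.LabName, "白细胞"),
            ent(EntityCategory.LabName, "白细胞 WBC"),
        )

    def test_result_text_must_match(self):
        assert not match_entity(
            ent(EntityCategory.LabResult, "4.5"), ent(EntityCategory.LabResult, "4.6")
        )

    def test_category_must_match(self):
        assert not match_entity(
            ent(EntityCategory.LabUnit, "mmol/L"),
            ent(EntityCategory.LabRefRange, "mmol/L"),
        )

    def test_whitespace_normalized(self):
        assert normalize_entity_text("  3.5 - 9.5 ") == "3.5 - 9.5"
        assert match_entity(
            ent(EntityCategory.LabRefRange, "3.5  -  9.5"),
            ent(EntityCategory.LabRefRange, "3.5 - 9.5"),
        )

    def test_pure_latin_name_compared_fully(self):
        assert not match_entity(
            ent(EntityCategory.LabName, "WBC"), ent(EntityCategory.LabName, "RBC")
        )


class TestPrfAggregation:
    def test_perfect_prediction(self):
        gold = {"r": [ent(EntityCategory.LabName, "白细胞"), ent(EntityCategory.LabResult, "6.2")]}
        report = entity_prf(gold, gold)
        assert report.overall.precision == 1.0
        assert report.overall.recall == 1.0
        assert report.overall.f1 == 1.0

    def test_published_recall_arithmetic(self):
        # 1862 correct of 2140 annotated names -> recall 0.87 at 2 d.p.
        m = prf_from_counts(correct=1862, predicted=2000, gold=2140)
        assert round(m.recall, 2) == 0.87

    def test_harmonic_mean_examples(self):
        assert round(f1_score(0.90, 0.83), 2) == 0.86
        assert round(f1_score(0.84, 0.73), 2) == 0.78

    def test_mismatched_ids_rejected(self):
        with pytest.raises(ValueError, match="identifiers"):
            entity_prf({"a": []}, {"b": []})

    def test_no_predictions_zero_precision_convention(self):
        gold = {"r": [ent(EntityCategory.LabName, "白细胞")]}
        report = entity_prf({"r": []}, gold)
        assert report.overall.precision == 0.0
        assert report.overall.recall == 0.0

    def test_empty_gold_and_empty_pred_scores_one_with_warning(self):
        report = entity_prf({"r": []}, {"r": []})
        assert report.overall.f1 == 1.0
        assert report.warnings

    def test_f1_between_p_and_r(self):
        rng = random.Random(0)
        for _ in range(100):
            p, r = rng.random(), rng.random()
            f = f1_score(p, r)
            assert min(p, r) - 1e-12 <= f <= max(p, r) + 1e-12
        assert f1_score(1.0, 1.0) == 1.0

    @pytest.mark.parametrize("case", range(100))
    def test_greedy_matching_equals_maximum_bipartite(self, case):
        """For <= 5 entities per category, greedy count equals optimal."""
        rng = random.Random(5000 + case)
        vocab = ["白细胞", "红细胞", "6.2", "6.2 ", "mmol/L", "白细胞 WBC", "3.5-9.5"]
        cat = rng.choice(list(EntityCategory))
        pred = [ent(cat, rng.choice(vocab)) for _ in range(rng.randint(0, 5))]
        gold = [ent(cat, rng.choice(vocab)) for _ in range(rng.randint(0, 5))]
        report = entity_prf({"r": pred}, {"r": gold})
        if not pred and not gold:
            return
        greedy_correct = report.per_category[cat].correct

        # independent optimum via assignment on the match matrix
        if pred and gold:
            cost = [[0 if match_entity(p, g) else 1 for g in gold] for p in pred]
            rows, cols = linear_sum_assignment(cost)
            optimal = sum(1 for r_, c_ in zip(rows, cols) if cost[r_][c_] == 0)
        else:
            optimal = 0
        assert greedy_correct == optimal


class TestMetricsReport:
    def test_micro_counts_sum(self):
        report = MetricsReport(
            per_category={
                EntityCategory.LabName: prf_from_counts(1862, 2046, 2140),
                EntityCategory.LabResult: prf_from_counts(1786, 1941, 2140),
                EntityCategory.LabRefRange: prf_from_counts(1620, 1929, 2115),
                EntityCategory.LabUnit: prf_from_counts(1697, 1996, 2047),
            }
        )
        assert report.overall.correct == 1862 + 1786 + 1620 + 1697
        assert report.overall.gold == 8442
        assert round(report.overall.recall, 2) == 0.83

    def test_text_rendering_rounds_to_two_decimals(self):
        report = MetricsReport(
            per_category={EntityCategory.LabName: prf_from_counts(9, 10, 12)}
        )
        assert "0.90" in report.to_text()


class TestOcrAccuracy:
    def test_character_level_worked_example(self):
        """100 gold characters with 10 misrecognized -> 90%."""
        gold = [["ABCDEFGHIJ"]] * 10
        pred = [["ABCDEFGHIX"]] * 10  # one bad character per line
        report = ocr_accuracy(pred, gold)
        assert report.character_accuracy == pytest.approx(0.90)

    def test_box_level_merge_worked_example(self):
        """10 gold boxes, two merged into one prediction -> 80%."""
        gold = [["b1", "b2"], ["b3", "b4"], ["b5", "b6"], ["b7", "b8"], ["b9", "b10"]]
        pred = [["b1b2"], ["b3", "b4"], ["b5", "b6"], ["b7", "b8"], ["b9", "b10"]]
        report = ocr_accuracy(pred, gold)
        assert report.box_accuracy == pytest.approx(0.80)

    def test_line_level_split_worked_example(self):
        """10 gold lines, one split into two -> 90%."""
        gold = [[f"L{i}a", f"L{i}b"] for i in range(10)]
        pred = [[f"L{i}a", f"L{i}b"] for i in range(9)] + [["L9a"], ["L9b"]]
        report = ocr_accuracy(pred, gold)
        assert report.line_accuracy == pytest.approx(0.90)

    def test_overall_is_mean_of_three(self):
        report = OcrAccuracyReport(0.95, 0.93, 0.90)
        assert report.overall == pytest.approx((0.95 + 0.93 + 0.90) / 3)
        assert round(report.overall, 2) == 0.93

    def test_perfect_product(self):
        gold = [["甲", "乙"], ["丙"]]
        report = ocr_accuracy(gold, gold)
        assert report.overall == 1.0

    def test_empty_gold_rejected(self):
        with pytest.raises(ValueError):
            ocr_accuracy([[]], [[]])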