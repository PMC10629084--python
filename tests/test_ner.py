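"""Entity recognizer: features, linking, end-to-end recognition quality."""

import pytest

from labdigitize import NoiseConfig
from labdigitize.evaluation import entity_prf
from labdigitize.features import extract_features, token_features
from labdigitize.iob import EntityCategory, LabEntity
from labdigitize.ner import EntityRecognizer, link_entities, read_annotated_lines, write_annotated_lines
from labdigitize.pipeline import LabReportPipeline
from labdigitize.tokenization import Token, tokenize
from conftest import make_reports, tables_equal


class TestFeatures:
    def test_ascii_shape_and_suffixes(self):
        feats = token_features(Token("Hb", 0, 2, "ascii_run"))
        assert "shape=Aa" in feats
        assert "suf1=b" in feats and "suf2=hb" in feats

    def test_cjk_shape_and_kind(self):
        feats = token_features(Token("血", 0, 1, "cjk_char"))
        assert "shape=c" in feats and "kind=cjk_char" in feats

    def test_slash_flag(self):
        feats = token_features(Token("/", 4, 5, "punct"))
        assert "has_slash" in feats

    def test_window_context_markers(self):
        toks = tokenize("白 6.2")
        feats = extract_features(toks, window=2)
        assert "BOL" in feats[0]
        assert "EOL" in feats[-1]
        assert any(f.startswith("-1:") for f in feats[1])

    def test_negative_window_rejected(self):
        with pytest.raises(ValueError):
            extract_features(tokenize("ab"), window=-1)


def ent(cat, text, start, alt=None):
    return LabEntity(
        category=cat, text=text, start=start, end=start + len(text),
        linked_alt_text=alt,
    )


class TestLinkEntities:
    def test_bilingual_name_linked(self):
        line = "癌胚抗原 CEA  2.3"
        ents = [
            ent(EntityCategory.LabName, "癌胚抗原", 0),
            ent(EntityCategory.LabName, "CEA", 5),
            ent(EntityCategory.LabResult, "2.3", 10),
        ]
        linked = link_entities(line, ents)
        assert len(linked) == 2
        assert linked[0].text == "癌胚抗原" and linked[0].linked_alt_text == "CEA"
        assert linked[1].text == "2.3"

    def test_latin_first_still_prefers_cjk_text(self):
        line = "CEA 癌胚抗原"
        linked = link_entities(
            line,
            [
                ent(EntityCategory.LabName, "CEA", 0),
                ent(EntityCategory.LabName, "癌胚抗原", 4),
            ],
        )
        assert linked[0].text == "癌胚抗原" and linked[0].linked_alt_text == "CEA"

    def test_dual_result_linked(self):
        line = "0.02  阴性"
        linked = link_entities(
            line,
            [
                ent(EntityCategory.LabResult, "0.02", 0),
                ent(EntityCategory.LabResult, "阴性", 6),
            ],
        )
        assert len(linked) == 1
        assert linked[0].text == "0.02" and linked[0].linked_alt_text == "阴性"

    def test_single_name_unchanged(self):
        line = "白细胞"
        ents = [ent(EntityCategory.LabName, "白细胞", 0)]
        assert link_entities(line, ents) == ents

    def test_distant_pair_not_linked(self):
        line = "白细胞      红细胞"  # a column gap, not a bilingual pair
        ents = [
            ent(EntityCategory.LabName, "白细胞", 0),
            ent(EntityCategory.LabName, "红细胞", 9),
        ]
        assert len(link_entities(line, ents)) == 2

    def test_units_never_linked(self):
        line = "g/L mmol/L"
        ents = [
            ent(EntityCategory.LabUnit, "g/L", 0),
            ent(EntityCategory.LabUnit, "mmol/L", 4),
        ]
        assert len(link_entities(line, ents)) == 2


class TestEntityRecognizer:
    def test_empty_and_whitespace_lines(self, trained_recognizer):
        assert trained_recognizer.predict([]) == []
        assert trained_recognizer.predict(["   "]) == [[]]

    def test_clean_heldout_f1(self, trained_recognizer):
        """Entity-level F1 >= 0.95 on clean held-out reports."""
        test = make_reports(15, seed=202)
        pipe = LabReportPipeline(recognizer=trained_recognizer)
        pred = {str(i): pipe.extract(b.clean_lines) for i, b in enumerate(test)}
        gold = {str(i): b.gold_table for i, b in enumerate(test)}
        report = entity_prf(pred, gold)
        assert report.overall.f1 >= 0.95

    def test_noise_degrades_f1_monotonically(self, trained_recognizer):
        """F1 is non-increasing in the character-substitution rate."""
        pipe = LabReportPipeline(recognizer=trained_recognizer)
        f1s = []
        for p_sub in (0.0, 0.03, 0.10):
            noise = NoiseConfig(
                p_merge=0.0, p_line_split=0.0, p_line_swap=0.0, p_char_sub=p_sub
            )
            test = make_reports(12, seed=77, noise=noise)
            pred = {str(i): pipe.extract(b.noisy_lines) for i, b in enumerate(test)}
            gold = {str(i): b.gold_table for i, b in enumerate(test)}
            f1s.append(entity_prf(pred, gold).overall.f1)
        assert f1s[1] <= f1s[0] + 0.01
        assert f1s[2] <= f1s[1] + 0.01

    def test_model_file_round_trip(self, trained_recognizer, tmp_path):
        path = str(tmp_path / "ner.model")
        trained_recognizer.save(path)
        again = EntityRecognizer.load_crf(path)
        line = "白细胞计数 WBC   6.20   10^9/L   3.50-9.50"
        assert [
            (e.category, e.text) for e in again.predict([line])[0]
        ] == [(e.category, e.text) for e in trained_recognizer.predict([line])[0]]


class TestCorpusIO:
    def test_jsonl_round_trip(self, tmp_path):
        texts = ["白细胞 6.2", "没有实体"]
        ents = [
            [ent(EntityCategory.LabName, "白细胞", 0), ent(EntityCategory.LabResult, "6.2", 4)],
            [],
        ]
        path = str(tmp_path / "corpus.jsonl")
        write_annotated_lines(path, texts, ents)
        texts2, ents2 = read_annotated_lines(path)
        assert texts2 == texts
        assert [[(e.category, e.start, e.end) for e in row] for row in ents2] == [
            [(e.category, e.start, e.end) for e in row] for row in ents
        ]
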