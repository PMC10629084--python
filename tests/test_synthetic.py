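"""Generator determinism, gold consistency, and the noise model."""

import random
from dataclasses import replace
from pathlib import Path

import pytest

from labdigitize.iob import EntityCategory
from labdigitize.pipeline import LabReportPipeline
from labdigitize.synthetic import (
    ITEM_BANK,
    NoiseConfig,
    corrupt,
    default_template_mix,
    default_templates,
    generate_corpus,
    generate_report,
    replay_noise,
)
from conftest import tables_equal


def bundle_texts(bundle):
    return [ln.text for ln in bundle.clean_lines], [ln.text for ln in bundle.noisy_lines]


class TestGenerateReport:
    def test_seed_determinism(self):
        tpl = default_templates()["single_bilingual"]
        a = generate_report(tpl, seed=42)
        b = generate_report(tpl, seed=42)
        assert bundle_texts(a) == bundle_texts(b)
        assert tables_equal(a.gold_table, b.gold_table)

    def test_item_count(self):
        tpl = replace(default_templates()["single_bilingual"], n_items=5)
        bundle = generate_report(tpl, seed=0)
        assert len(bundle.gold_table.records) == 5

    def test_double_column_lines_carry_two_names(self):
        tpl = replace(default_templates()["double_bilingual"], n_items=20)
        bundle = generate_report(tpl, seed=0)
        table_lines = [ents for ents in bundle.gold_annotations if ents]
        assert len(table_lines) == 10
        for ents in table_lines:
            # bilingual: each logical item contributes two LabName spans
            names = [e for e in ents if e.category == EntityCategory.LabName]
            assert len(names) == 4

    def test_insufficient_item_bank_rejected(self):
        tpl = replace(default_templates()["triple_plain"], n_items=len(ITEM_BANK) + 1)
        with pytest.raises(ValueError, match="item bank"):
            generate_report(tpl, seed=0)

    @pytest.mark.parametrize("name", sorted(default_templates()))
    def test_gold_consistency_every_template(self, name):
        """Oracle-NER pipeline on clean lines reproduces the gold table."""
        tpl = default_templates()[name]
        pipe = LabReportPipeline()
        for seed in (0, 1, 2):
            bundle = generate_report(tpl, seed=seed)
            table = pipe.extract_with_annotations(
                bundle.clean_lines, bundle.gold_annotations
            )
            assert tables_equal(table, bundle.gold_table)

    def test_report_time_is_earliest_datetime(self):
        bundle = generate_report(default_templates()["single_bilingual"], seed=9)
        assert bundle.gold_table.report_time is not None
        # collection precedes reporting by construction
        texts = [ln.text for ln in bundle.clean_lines]
        assert any("采集时间" in t for t in texts)


class TestCorrupt:
    def test_zero_noise_is_identity(self):
        bundle = generate_report(default_templates()["single_bilingual"], seed=1)
        noisy = corrupt(bundle, NoiseConfig(0.0, 0.0, 0.0, 0.0, seed=5))
        assert [ln.text for ln in noisy.noisy_lines] == [
            ln.text for ln in bundle.clean_lines
        ]
        assert noisy.noise_log == []

    def test_forced_swap_logged(self):
        bundle = generate_report(
            replace(default_templates()["single_bilingual"], n_items=2), seed=1
        )
        noisy = corrupt(bundle, NoiseConfig(0.0, 0.0, 1.0, 0.0, seed=5))
        swaps = [e for e in noisy.noise_log if e[0] == "swap"]
        assert swaps, "p_line_swap=1 must produce swap events"

    def test_gold_untouched_by_noise(self):
        bundle = generate_report(default_templates()["double_bilingual"], seed=3)
        noisy = corrupt(bundle, NoiseConfig(0.3, 0.3, 0.3, 0.1, seed=8))
        assert tables_equal(noisy.gold_table, bundle.gold_table)
        assert [ln.text for ln in noisy.clean_lines] == [
            ln.text for ln in bundle.clean_lines
        ]

    @pytest.mark.parametrize("case", range(40))
    def test_noise_log_replay_identity(self, case):
        """Replaying the noise log on clean lines reproduces noisy lines."""
        master = random.Random(1234 + case)
        templates = default_templates()
        tpl = templates[master.choice(sorted(templates))]
        bundle = generate_report(tpl, seed=master.randrange(2**31))
        noise = NoiseConfig(
            p_merge=master.uniform(0, 0.5),
            p_line_split=master.uniform(0, 0.5),
            p_line_swap=master.uniform(0, 0.5),
            p_char_sub=master.uniform(0, 0.2),
            seed=master.randrange(2**31),
        )
        noisy = corrupt(bundle, noise)
        replayed = replay_noise(bundle.clean_lines, noisy.noise_log)
        assert [ln.text for ln in replayed] == [ln.text for ln in noisy.noisy_lines]

    def test_corrupt_determinism(self):
        bundle = generate_report(default_templates()["single_extras_swapped"], seed=6)
        n = NoiseConfig(0.2, 0.2, 0.2, 0.05, seed=77)
        a = corrupt(bundle, n)
        b = corrupt(bundle, n)
        assert [ln.text for ln in a.noisy_lines] == [ln.text for ln in b.noisy_lines]
        assert a.noise_log == b.noise_log


class TestGenerateCorpus:
    def test_rerun_identical_trees(self, tmp_path):
        d1, d2 = tmp_path / "c1", tmp_path / "c2"
        generate_corpus(6, d1, seed=3)
        generate_corpus(6, d2, seed=3)
        files1 = sorted(p.relative_to(d1) for p in d1.rglob("*") if p.is_file())
        files2 = sorted(p.relative_to(d2) for p in d2.rglob("*") if p.is_file())
        assert files1 == files2
        for rel in files1:
            assert (d1 / rel).read_bytes() == (d2 / rel).read_bytes()

    def test_pure_double_column_mix(self, tmp_path):
        manifest = generate_corpus(
            4, tmp_path / "c", template_mix={"double_bilingual": 1.0}, seed=1
        )
        assert all(r["n_columns"] == 2 for r in manifest["reports"])

    def test_too_few_reports_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            generate_corpus(1, tmp_path / "c", seed=0)

    def test_bad_mix_weights_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="sum"):
            generate_corpus(4, tmp_path / "c", template_mix={"triple_plain": 0.4}, seed=0)

    def test_category_marginals_match_template_expectation(self, tmp_path):
        """Gold entity category counts agree with template-implied counts.

        Every item carries exactly one reference range; bilingual
        templates contribute two LabName spans per item; dual results at
        most double LabResult spans; only the few unit-less items lack a
        LabUnit span.
        """
        import json

        from labdigitize.synthetic import default_templates

        manifest = generate_corpus(30, tmp_path / "c", seed=12)
        counts = {c: 0 for c in EntityCategory}
        for jsonl in Path(tmp_path / "c").rglob("gold.jsonl"):
            for raw in jsonl.read_text(encoding="utf-8").splitlines():
                rec = json.loads(raw)
                for e in rec["entities"]:
                    counts[EntityCategory(e["category"])] += 1

        templates = default_templates()
        n_records = sum(m["n_items"] for m in manifest["reports"])
        expected_names = sum(
            m["n_items"] * (2 if templates[m["template"]].bilingual_names else 1)
            for m in manifest["reports"]
        )
        assert counts[EntityCategory.LabRefRange] == n_records
        assert counts[EntityCategory.LabName] == expected_names
        assert n_records <= counts[EntityCategory.LabResult] <= 2 * n_records
        assert 0.7 * n_records <= counts[EntityCategory.LabUnit] <= n_records
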