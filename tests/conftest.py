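"""Shared fixtures: synthetic report sets and a session-trained recognizer."""

from __future__ import annotations

import pytest
from hypothesis import settings

from labdigitize import EntityRecognizer, GoldBundle
from labdigitize.layout import tables_match as tables_equal  # noqa: F401
from labdigitize.synthetic import sample_reports as make_reports  # noqa: F401
from labdigitize.synthetic import training_lines as annotated_lines  # noqa: F401

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_reports() -> list[GoldBundle]:
    """Training reports: roughly 500 annotated table lines (seed 7)."""
    return make_reports(35, seed=7)


@pytest.fixture(scope="session")
def trained_recognizer(fixture_reports) -> EntityRecognizer:
    texts, ents = annotated_lines(fixture_reports)
    return EntityRecognizer(max_iterations=80).fit(texts, ents)
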