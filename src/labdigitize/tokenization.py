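"""Line tokenization for sequence labeling.

Laboratory report lines mix CJK item names, Latin abbreviations, numeric
results and symbolic units.  The tokenizer therefore works at mixed
granularity: each CJK character is its own token (entity boundaries in
Chinese fall between characters), while maximal ASCII letter runs and digit
runs (with interior decimal points) are kept whole, and any other visible
character is a single punctuation token.  Spaces separate tokens but produce
none.  Offsets are 0-based half-open character spans into the line.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

__all__ = ["Token", "tokenize", "is_cjk", "cjk_portion"]

# CJK Unified Ideographs plus Extension A; covers lab-report Chinese text.
_CJK_RANGES = ((0x4E00, 0x9FFF), (0x3400, 0x4DBF))


def is_cjk(ch: str) -> bool:
    cp = ord(ch)
    return any(lo <= cp <= hi for lo, hi in _CJK_RANGES)


def cjk_portion(text: str) -> str:
    """Maximal subsequence of CJK characters of ``text``."""
    return "".join(ch for ch in text if is_cjk(ch))


@dataclass(frozen=True)
class Token:
    text: str
    start: int
    end: int
    kind: str  # cjk_char | ascii_run | digit_run | punct

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad token span [{self.start}, {self.end})")


# Order matters: digit runs (with interior '.') before single punctuation.
_TOKEN_RE = re.compile(
    r"(?P<digit_run>\d+(?:\.\d+)*)|(?P<ascii_run>[A-Za-z]+)|(?P<space>\s+)|(?P<other>.)",
    re.DOTALL,
)


def tokenize(text: str) -> list[Token]:
    """Split a line into tokens covering every non-space character once."""
    tokens: list[Token] = []
    for m in _TOKEN_RE.finditer(text):
        kind = m.lastgroup
        if kind == "space":
            continue
        s, e = m.span()
        if kind == "other":
            ch = m.group()
            if is_cjk(ch):
                tokens.append(Token(ch, s, e, "cjk_char"))
            else:
                tokens.append(Token(ch, s, e, "punct"))
        else:
            tokens.append(Token(m.group(), s, e, kind))
    return tokens
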