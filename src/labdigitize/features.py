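"""Per-token feature extraction for the sequence labeler.

Features follow the classic CRF recipe for mixed-script clinical text:
token identity, suffixes (for Latin-script runs), a word-shape string, and
a coarse lexical class standing in for a part-of-speech tag (a true POS is
ill-defined for isolated CJK characters), plus flags that matter for lab
tables — numeric content, slashes (units like mmol/L), percent signs, and
comparator characters (<, >, -) typical of reference ranges.  The same
features of neighboring tokens within a configurable window are included,
with begin/end-of-line markers at the boundaries.
"""

from __future__ import annotations

from typing import Sequence

from .tokenization import Token, is_cjk

__all__ = ["token_features", "extract_features"]

_COMPARATORS = set("<>-~≤≥")


def _shape(text: str) -> str:
    out = []
    for ch in text:
        if is_cjk(ch):
            out.append("c")
        elif ch.isdigit():
            out.append("d")
        elif ch.isalpha():
            out.append("A" if ch.isupper() else "a")
        else:
            out.append(ch)
    return "".join(out)


def token_features(tok: Token) -> list[str]:
    """Intrinsic (position-independent) features of one token."""
    feats = [
        f"w={tok.text.lower()}",
        f"kind={tok.kind}",
        f"shape={_shape(tok.text)}",
    ]
    if tok.kind == "ascii_run":
        for n in (1, 2, 3):
            if len(tok.text) >= n:
                feats.append(f"suf{n}={tok.text[-n:].lower()}")
    if tok.kind == "digit_run":
        feats.append("is_numeric")
    if "/" in tok.text:
        feats.append("has_slash")
    if "%" in tok.text:
        feats.append("has_percent")
    if any(ch in _COMPARATORS for ch in tok.text):
        feats.append("has_comparator")
    return feats


def extract_features(tokens: Sequence[Token], window: int = 2) -> list[list[str]]:
    """Feature sets for every token of a line, with a +/- ``window`` context.

    Neighbor features are the neighbor's intrinsic features prefixed with
    the signed offset; boundary positions add BOL/EOL markers.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    intrinsic = [token_features(t) for t in tokens]
    out: list[list[str]] = []
    for i in range(len(tokens)):
        feats = ["bias"] + list(intrinsic[i])
        for off in range(-window, window + 1):
            if off == 0:
                continue
            j = i + off
            if j < 0:
                if j == -1:
                    feats.append("BOL")
            elif j >= len(tokens):
                if j == len(tokens):
                    feats.append("EOL")
            else:
                feats.extend(f"{off:+d}:{f}" for f in intrinsic[j])
        out.append(feats)
    return out
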