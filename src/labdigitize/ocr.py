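"""OCR output ingestion and physical line formation.

The OCR engine itself (text detection + recognition) is out of scope: this
module consumes its product — a list of recognized text items, each with a
quadrilateral detection box and a recognition confidence — and turns it into
ordered physical lines of text, which is what the downstream information
extraction stages operate on.

Two input dialects are supported:

* ``box_json`` — a JSON array of ``{"text", "quad", "score"}`` objects, the
  raw per-box OCR product; lines are formed geometrically.
* ``lines_text`` — plain UTF-8 text, one physical line per record, for the
  case where line structure is already known (e.g. synthetic corpora).

An adapter registry lets callers plug a real OCR engine (e.g. PP-OCR) behind
:func:`run_ocr_engine` without this package depending on one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, IO, Iterable, Sequence

__all__ = [
    "OcrBox",
    "OcrPage",
    "TextLine",
    "OcrFormatError",
    "OcrEngineUnavailableError",
    "read_ocr_page",
    "write_ocr_page",
    "form_lines",
    "default_v_tolerance",
    "register_ocr_engine",
    "run_ocr_engine",
]


class OcrFormatError(ValueError):
    """Raised when an OCR input record cannot be parsed."""


class OcrEngineUnavailableError(RuntimeError):
    """Raised when no external OCR engine has been registered."""


@dataclass(frozen=True)
class OcrBox:
    """One recognized text item with its quadrilateral detection box.

    Parameters
    ----------
    text : str
        Recognized content; non-empty after whitespace trimming.
    quad : tuple of 4 (x, y) pairs
        Detection-box corners in image pixels.
    confidence : float
        Recognition confidence in ``[0, 1]``.
    """

    text: str
    quad: tuple[tuple[float, float], ...]
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if not self.text.strip():
            raise OcrFormatError("OcrBox text is empty after trimming")
        if len(self.quad) != 4:
            raise OcrFormatError(f"quad must have 4 points, got {len(self.quad)}")
        object.__setattr__(
            self, "quad", tuple((float(x), float(y)) for x, y in self.quad)
        )
        if not 0.0 <= self.confidence <= 1.0:
            raise OcrFormatError(f"confidence {self.confidence} outside [0, 1]")
        if any(x < 0 or y < 0 for x, y in self.quad):
            raise OcrFormatError("quad coordinates must be non-negative")

    @property
    def y_center(self) -> float:
        """Mean of the four corner y values; robust to mild skew."""
        return sum(y for _, y in self.quad) / 4.0

    @property
    def x_left(self) -> float:
        return min(x for x, _ in self.quad)

    @property
    def height(self) -> float:
        ys = [y for _, y in self.quad]
        return max(ys) - min(ys)


@dataclass(frozen=True)
class OcrPage:
    """The OCR product for one scanned page: an ordered set of boxes."""

    boxes: tuple[OcrBox, ...]
    image_size: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "boxes", tuple(self.boxes))
        if self.image_size is not None:
            w, h = self.image_size
            for b in self.boxes:
                if any(x > w or y > h for x, y in b.quad):
                    raise OcrFormatError("box coordinates exceed image_size")

    def __len__(self) -> int:
        return len(self.boxes)


@dataclass(frozen=True)
class TextLine:
    """One ordered physical line of report text.

    ``text`` is the left-to-right concatenation of the source boxes' texts
    separated by single spaces.  ``source_boxes`` holds indices into the
    originating :class:`OcrPage` (empty when the line came from plain text),
    and ``y_center`` the mean of those boxes' vertical centers.
    """

    text: str
    source_boxes: tuple[int, ...] = ()
    y_center: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "source_boxes", tuple(self.source_boxes))


def read_ocr_page(
    stream: IO | str, format_tag: str
) -> OcrPage | list[TextLine]:
    """Read OCR output from ``stream`` in the named dialect.

    Parameters
    ----------
    stream : file-like or str
        Input text (a string is treated as the content itself).
    format_tag : {"box_json", "lines_text"}
        Input dialect.

    Returns
    -------
    OcrPage for ``box_json``; list of TextLine for ``lines_text``.
    """
    data = stream if isinstance(stream, str) else stream.read()
    if isinstance(data, bytes):
        data = data.decode("utf-8")

    if format_tag == "box_json":
        try:
            records = json.loads(data)
        except json.JSONDecodeError as exc:
            raise OcrFormatError(f"invalid box_json document: {exc}") from exc
        if not isinstance(records, list):
            raise OcrFormatError("box_json top level must be an array")
        boxes = []
        for i, rec in enumerate(records):
            try:
                boxes.append(
                    OcrBox(
                        text=rec["text"],
                        quad=tuple((p[0], p[1]) for p in rec["quad"]),
                        confidence=float(rec.get("score", 1.0)),
                    )
                )
            except (KeyError, TypeError, IndexError, OcrFormatError) as exc:
                raise OcrFormatError(f"malformed box_json record {i}: {exc}") from exc
        return OcrPage(boxes=tuple(boxes))

    if format_tag == "lines_text":
        # Empty lines are preserved; line normalization removes them later.
        return [TextLine(text=ln) for ln in data.split("\n")]

    raise ValueError(f"unknown format_tag {format_tag!r}")


def write_ocr_page(page: OcrPage) -> str:
    """Serialize a page back to the ``box_json`` dialect (round-trippable)."""
    return json.dumps(
        [
            {"text": b.text, "quad": [list(p) for p in b.quad], "score": b.confidence}
            for b in page.boxes
        ],
        ensure_ascii=False,
    )


def default_v_tolerance(page: OcrPage) -> float:
    """Half the median box height — scale-free across scan resolutions."""
    if not page.boxes:
        return 1.0
    heights = sorted(b.height for b in page.boxes)
    mid = len(heights) // 2
    med = heights[mid] if len(heights) % 2 else 0.5 * (heights[mid - 1] + heights[mid])
    return max(0.5 * med, 1e-6)


def form_lines(page: OcrPage, v_tolerance: float | None = None) -> list[TextLine]:
    """Group detection boxes with similar vertical coordinates into lines.

    Boxes are partitioned by single-linkage clustering of their vertical
    centers: two boxes share a line when a chain of pairwise-close centers
    (each gap ``<= v_tolerance``) connects them.  Within a line boxes are
    ordered by left x; lines are ordered top-to-bottom by mean y_center,
    ties broken by the left x of the first box.

    Parameters
    ----------
    page : OcrPage
    v_tolerance : float, optional
        Maximum vertical-center gap joining two boxes into the same line.
        Defaults to half the median box height on the page.
    """
    if v_tolerance is None:
        v_tolerance = default_v_tolerance(page)
    if v_tolerance <= 0:
        raise ValueError(f"v_tolerance must be positive, got {v_tolerance}")
    if not page.boxes:
        return []

    # Single-linkage over a single coordinate: sort by y_center and cut the
    # chain wherever consecutive gaps exceed the tolerance.
    order = sorted(range(len(page.boxes)), key=lambda i: page.boxes[i].y_center)
    groups: list[list[int]] = [[order[0]]]
    for idx in order[1:]:
        prev = groups[-1][-1]
        if page.boxes[idx].y_center - page.boxes[prev].y_center <= v_tolerance:
            groups[-1].append(idx)
        else:
            groups.append([idx])

    lines = []
    for grp in groups:
        grp.sort(key=lambda i: (page.boxes[i].x_left, i))
        text = " ".join(page.boxes[i].text for i in grp)
        y = sum(page.boxes[i].y_center for i in grp) / len(grp)
        lines.append(TextLine(text=text, source_boxes=tuple(grp), y_center=y))
    lines.sort(key=lambda ln: (ln.y_center, page.boxes[ln.source_boxes[0]].x_left))
    return lines


_OCR_ENGINE: Callable[[str], OcrPage] | None = None


def register_ocr_engine(engine: Callable[[str], OcrPage] | None) -> None:
    """Register (or clear, with ``None``) an external OCR engine adapter.

    The engine is any callable mapping an image path to an :class:`OcrPage`.
    """
    global _OCR_ENGINE
    _OCR_ENGINE = engine


def run_ocr_engine(image_path: str) -> OcrPage:
    """Run the registered OCR engine on an image.

    Raises
    ------
    OcrEngineUnavailableError
        When no engine is registered; use ``box_json`` input instead.
    """
    if _OCR_ENGINE is None:
        raise OcrEngineUnavailableError(
            "no OCR engine registered; provide box_json input via read_ocr_page "
            "or register an engine with register_ocr_engine()"
        )
    page = _OCR_ENGINE(image_path)
    if not isinstance(page, OcrPage):
        page = OcrPage(boxes=tuple(page))
    return page
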