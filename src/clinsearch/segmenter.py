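"""Report segmentation by header patterns with lexical variants.

Hospitalization-style reports are split into up to 19 labeled sections.
A header must be line-initial (case- and diacritic-insensitive) and be
followed by ':' or the end of its line; each header opens a segment that
runs to the next header or the end of the document. Text before the
first header is unsegmented. Consultation reports typically contain no
headers and legitimately yield zero segments.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import yaml

from ._text import fold
from .corpus import Segment

__all__ = [
    "SegmentRule",
    "load_segment_rules",
    "default_segment_rules",
    "segment_document",
]

N_SEGMENT_LABELS = 19


@dataclass(frozen=True)
class SegmentRule:
    label: str
    header_patterns: tuple[str, ...]
    canonical: str = ""


class SegmentRuleError(ValueError):
    pass


def load_segment_rules(path: str | Path) -> list[SegmentRule]:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    rules = [
        SegmentRule(
            label=e["label"],
            header_patterns=tuple(e["patterns"]),
            canonical=e.get("canonical", e["label"]),
        )
        for e in data["segments"]
    ]
    labels = [r.label for r in rules]
    if len(set(labels)) != len(labels):
        raise SegmentRuleError("duplicate segment labels")
    for r in rules:
        for p in r.header_patterns:
            try:
                re.compile(p)
            except re.error as exc:
                raise SegmentRuleError(f"{r.label}: bad pattern {p!r}: {exc}") from exc
    return rules


def default_segment_rules() -> list[SegmentRule]:
    path = resources.files("clinsearch.data") / "segments.yaml"
    return load_segment_rules(str(path))


def _match_header(folded_line: str, rules: Sequence[SegmentRule]) -> str | None:
    """Label of the first rule whose pattern spans a header on this line."""
    for rule in rules:  # file order breaks ties
        for pat in rule.header_patterns:
            m = re.match(r"\s*(?:" + pat + r")\s*(?::|$)", folded_line)
            if m:
                return rule.label
    return None


def segment_document(
    text: str, rules: Sequence[SegmentRule] | None = None
) -> list[Segment]:
    """Split a document into labeled segments (sorted, non-overlapping).

    Each segment starts at its header-line start; concatenating the
    unsegmented prefix with all segment texts reproduces the document.
    """
    if rules is None:
        rules = default_segment_rules()
    folded = fold(text)
    headers: list[tuple[int, str]] = []  # (char offset of line start, label)
    pos = 0
    for raw in folded.split("\n"):
        label = _match_header(raw, rules) if raw.strip() else None
        if label is not None:
            headers.append((pos, label))
        pos += len(raw) + 1
    segments = []
    for i, (start, label) in enumerate(headers):
        end = headers[i + 1][0] if i + 1 < len(headers) else len(text)
        if start < end:
            segments.append(Segment(label, start, end))
    return segments
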