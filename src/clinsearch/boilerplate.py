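"""Corpus-wide detection of repeated header/footer lines.

The detector counts each normalized document line at its line index and
flags, per document, the lines whose count aggregated over nearby line
indices (a ± ``window`` bucket tolerance absorbs small layout shifts)
reaches a threshold. The more often the same line recurs across documents
at roughly the same position, the less patient-specific it is. Flagged
lines are excluded from indexing but stay visible in the stored text.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from ._text import normalize_line
from .corpus import BoilerplateReason, BoilerplateSpan

__all__ = [
    "FrequencyTable",
    "BoilerplateConfig",
    "build_frequency_table",
    "detect_boilerplate",
]


@dataclass
class FrequencyTable:
    counts: Counter[tuple[str, int]]
    corpus_size: int

    def save_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("line\tbucket\tcount\n")
            for (line, bucket), count in sorted(self.counts.items()):
                fh.write(f"{line}\t{bucket}\t{count}\n")

    @classmethod
    def load_tsv(cls, path: str | Path, corpus_size: int) -> "FrequencyTable":
        counts: Counter[tuple[str, int]] = Counter()
        with open(path, encoding="utf-8") as fh:
            next(fh)
            for row in fh:
                line, bucket, count = row.rstrip("\n").split("\t")
                counts[(line, int(bucket))] = int(count)
        return cls(counts, corpus_size)


@dataclass
class BoilerplateConfig:
    """Flagging rules.

    ``threshold`` is the absolute repeat count the original deployment
    uses on its multi-million-document corpus (default 500);
    ``threshold_fraction``, when set, overrides it with a fraction of the
    corpus size so the same logic applies to small corpora. Lines on
    ``force_list`` are always flagged; lines containing a protected term
    from ``unforce_list`` (e.g. *hypertension*, a common clinical sign
    that also appears in unit letterheads) are never auto-flagged.
    """

    threshold: int = 500
    window: int = 7
    force_list: frozenset[str] = frozenset()
    unforce_list: frozenset[str] = frozenset()
    threshold_fraction: float | None = None

    def __post_init__(self) -> None:
        self.force_list = frozenset(normalize_line(s) for s in self.force_list)
        self.unforce_list = frozenset(normalize_line(s) for s in self.unforce_list)
        if self.force_list & self.unforce_list:
            raise ValueError("force_list and unforce_list overlap")
        if self.window < 0 or self.threshold <= 0:
            raise ValueError("window must be >= 0 and threshold > 0")

    def effective_threshold(self, corpus_size: int) -> int:
        if self.threshold_fraction is not None:
            return max(2, math.ceil(self.threshold_fraction * corpus_size))
        return self.threshold


def _doc_lines(text: str) -> list[tuple[str, int, int]]:
    """(normalized line, char start, char end) for every line of a text."""
    out = []
    pos = 0
    for raw in text.split("\n"):
        out.append((normalize_line(raw), pos, pos + len(raw)))
        pos += len(raw) + 1
    return out


def build_frequency_table(texts: Sequence[str]) -> FrequencyTable:
    """Count each (normalized line, line index) pair once per document."""
    if not texts:
        raise ValueError("cannot build a frequency table from an empty corpus")
    counts: Counter[tuple[str, int]] = Counter()
    for text in texts:
        seen: set[tuple[str, int]] = set()
        for idx, (norm, _s, _e) in enumerate(_doc_lines(text)):
            if norm:
                seen.add((norm, idx))
        counts.update(seen)
    return FrequencyTable(counts, len(texts))


def detect_boilerplate(
    text: str, table: FrequencyTable, cfg: BoilerplateConfig
) -> list[BoilerplateSpan]:
    """Flag boilerplate lines of one document against the corpus table."""
    threshold = cfg.effective_threshold(table.corpus_size)
    spans: list[BoilerplateSpan] = []
    for idx, (norm, start, end) in enumerate(_doc_lines(text)):
        if not norm:
            continue
        if norm in cfg.force_list:
            spans.append(BoilerplateSpan(start, end, BoilerplateReason.FORCED))
            continue
        if any(term in norm for term in cfg.unforce_list):
            continue
        total = sum(
            table.counts.get((norm, j), 0)
            for j in range(max(0, idx - cfg.window), idx + cfg.window + 1)
        )
        if total >= threshold:
            spans.append(BoilerplateSpan(start, end, BoilerplateReason.FREQUENT_LINE))
    return spans
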