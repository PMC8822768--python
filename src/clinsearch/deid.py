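"""De-identification: masking of patient names and identifiers.

Names are matched token-bounded, case- and diacritic-insensitively; every
hit (plus every match of the configured ID patterns) is replaced by a
fixed mask token, which keeps sentence structure intact for the context
tagger downstream. Because the mask rarely has the same length as what it
replaces, :func:`deidentify` also returns an :class:`OffsetMap` so that
annotations expressed on the original text can be projected onto the
masked text and vice versa.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from ._text import fold
from .corpus import ClinicalDocument

__all__ = ["DeidConfig", "DeidResult", "OffsetMap", "deidentify", "find_leaks"]

DEFAULT_MASK = "[MASQUE]"

#: Placeholder identifier shapes (long digit runs, record-number style);
#: deployments tune these to their own local identifier formats.
DEFAULT_ID_PATTERNS = (
    r"\b\d{8,}\b",
    r"\b[A-Z]{2}\d{6,}\b",
)


@dataclass
class DeidConfig:
    name_list_per_patient: dict[str, list[str]] = field(default_factory=dict)
    id_patterns: tuple[str, ...] = DEFAULT_ID_PATTERNS
    mask_token: str = DEFAULT_MASK

    def __post_init__(self) -> None:
        for pat in self.id_patterns:
            if re.search(pat, self.mask_token):
                raise ValueError(
                    f"mask token {self.mask_token!r} matches id pattern {pat!r}"
                )


class OffsetMap:
    """Piecewise map between original and masked character offsets.

    Built from the sorted list of replaced regions; spans that do not
    straddle a replacement boundary project cleanly.
    """

    def __init__(
        self, replacements: list[tuple[int, int]], mask_len: int, orig_len: int
    ) -> None:
        self._repl = replacements
        self._mask_len = mask_len
        self._orig_len = orig_len

    def project(self, offset: int) -> int:
        """Map an original-text offset to the masked text."""
        delta = 0
        for start, end in self._repl:
            if offset <= start:
                break
            if offset < end:
                # inside a masked region: snap to the mask start
                return start + delta
            delta += self._mask_len - (end - start)
        return offset + delta

    def project_span(self, start: int, end: int) -> tuple[int, int]:
        return self.project(start), self.project(end)


@dataclass
class DeidResult:
    text: str
    n_masked: int
    offset_map: OffsetMap


def _name_pattern(name: str) -> re.Pattern[str] | None:
    folded = fold(name).strip()
    if len(folded) < 2:  # single letters would over-mask catastrophically
        return None
    return re.compile(r"(?<![a-z0-9])" + re.escape(folded) + r"(?![a-z0-9])")


def deidentify(doc: ClinicalDocument, cfg: DeidConfig) -> DeidResult:
    """Mask listed patient names and identifier patterns in a document.

    Idempotent: masked text contains no residual matches, so a second
    pass is a no-op.
    """
    text = doc.raw_text
    folded = fold(text)
    spans: list[tuple[int, int]] = []
    for name in cfg.name_list_per_patient.get(doc.patient_id, []):
        pat = _name_pattern(name)
        if pat is None:
            continue
        spans.extend(m.span() for m in pat.finditer(folded))
    for raw_pat in cfg.id_patterns:
        spans.extend(m.span() for m in re.finditer(raw_pat, text))
    # merge overlapping/adjacent hits into maximal regions
    spans.sort()
    merged: list[tuple[int, int]] = []
    for start, end in spans:
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    pieces: list[str] = []
    cursor = 0
    for start, end in merged:
        pieces.append(text[cursor:start])
        pieces.append(cfg.mask_token)
        cursor = end
    pieces.append(text[cursor:])
    return DeidResult(
        text="".join(pieces),
        n_masked=len(merged),
        offset_map=OffsetMap(merged, len(cfg.mask_token), len(text)),
    )


def find_leaks(text: str, names: list[str]) -> list[str]:
    """Independent audit scan: listed names still findable in a text."""
    folded = fold(text)
    leaks = []
    for name in names:
        pat = _name_pattern(name)
        if pat is not None and pat.search(folded):
            leaks.append(name)
    return leaks
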