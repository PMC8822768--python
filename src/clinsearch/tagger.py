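"""Context tagging: negation, hypothesis/future and family medical history.

Lexical triggers (regular expressions over folded text) open a scope that
extends forward, backward or both ways from the trigger until a stop
character, a stop word, a segment boundary, or the per-rule token budget.
The emitted :class:`~clinsearch.corpus.TagSpan` covers the scoped content
only; the trigger surface form is recorded on the span.

A guard suppresses negation triggers on numeric laboratory-result lines
("Préalbumine : 0,16"), a known false-positive shape for trigger-based
negation detection.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from ._text import analyze, fold
from .corpus import BoilerplateSpan, Segment, Tag, TagSpan

__all__ = [
    "TriggerRule",
    "ScopeConfig",
    "load_trigger_rules",
    "default_trigger_rules",
    "tag_document",
    "split_patient_family_content",
]


class LexiconError(ValueError):
    """Raised at load time for an invalid trigger lexicon."""


@dataclass(frozen=True)
class TriggerRule:
    pattern: str
    tag: Tag
    direction: str  # FORWARD | BACKWARD | BIDIRECTIONAL
    max_scope_tokens: int = 10

    def compile(self) -> re.Pattern[str]:
        try:
            return re.compile(self.pattern)
        except re.error as exc:
            raise LexiconError(f"bad trigger pattern {self.pattern!r}: {exc}") from exc


@dataclass
class ScopeConfig:
    stop_characters: frozenset[str] = frozenset({".", ",", ";", ":", "\n"})
    stop_words: frozenset[str] = frozenset({"mais"})
    merge_overlaps: bool = True

    def __post_init__(self) -> None:
        if not self.stop_characters or not self.stop_words:
            raise ValueError("stop character and stop word sets must be non-empty")
        # post-posed result triggers routinely follow "label : value", so
        # ':' does not terminate a backward scope
        self.backward_stop_characters = frozenset(self.stop_characters - {":"})


def load_trigger_rules(path: str | Path) -> list[TriggerRule]:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    default_scope = int(data.get("defaults", {}).get("max_scope_tokens", 10))
    rules = []
    for entry in data["rules"]:
        rule = TriggerRule(
            pattern=entry["pattern"],
            tag=Tag(entry["tag"]),
            direction=entry.get("direction", "FORWARD"),
            max_scope_tokens=int(entry.get("max_scope_tokens", default_scope)),
        )
        if rule.direction not in {"FORWARD", "BACKWARD", "BIDIRECTIONAL"}:
            raise LexiconError(f"bad direction {rule.direction!r}")
        rule.compile()  # fail now, not at tag time
        rules.append(rule)
    for tag in Tag:
        if not any(r.tag is tag for r in rules):
            raise LexiconError(f"lexicon has no rule for tag {tag.value}")
    return rules


def default_trigger_rules() -> list[TriggerRule]:
    path = resources.files("clinsearch.data") / "triggers.yaml"
    return load_trigger_rules(str(path))


# "label : 0.16"-style numeric result, optionally with a short unit
_NUMERIC_RESULT_RE = re.compile(r":\s*[<>]?\s*\d[\d.,]*(?:\s*\S{1,6})?\s*$")


def _line_bounds(text: str, pos: int) -> tuple[int, int]:
    start = text.rfind("\n", 0, pos) + 1
    end = text.find("\n", pos)
    return start, len(text) if end == -1 else end


def _inside(pos: int, spans: Sequence[tuple[int, int]]) -> bool:
    return any(s <= pos < e for s, e in spans)


def _scope_span(
    text: str,
    folded: str,
    trig_start: int,
    trig_end: int,
    rule: TriggerRule,
    cfg: ScopeConfig,
    forward: bool,
    bounds: tuple[int, int],
) -> tuple[int, int] | None:
    """Character span of the scoped content, or None if empty."""
    lo, hi = bounds
    if forward:
        limit = trig_end
        while limit < hi and folded[limit] not in cfg.stop_characters:
            limit += 1
        region = (trig_end, limit)
    else:
        limit = trig_start
        while limit > lo and folded[limit - 1] not in cfg.backward_stop_characters:
            limit -= 1
        region = (limit, trig_start)
    if region[0] >= region[1]:
        return None
    tokens = analyze(text[region[0] : region[1]])
    if not tokens:
        return None
    if not forward:
        tokens.reverse()
    kept: list = []
    n_content = 0
    for tok in tokens:
        if tok.text in cfg.stop_words:
            break
        if not tok.is_stop:
            n_content += 1
            if n_content > rule.max_scope_tokens:
                break
        kept.append(tok)
    # trim leading/trailing analyzer stop tokens so the span hugs content
    while kept and kept[-1].is_stop:
        kept.pop()
    while kept and kept[0].is_stop:
        kept.pop(0)
    if not kept:
        return None
    if not forward:
        kept.reverse()
    return region[0] + kept[0].start, region[0] + kept[-1].end


def tag_document(
    text: str,
    rules: Sequence[TriggerRule] | None = None,
    cfg: ScopeConfig | None = None,
    segments: Sequence[Segment] | None = None,
    boilerplate: Sequence[BoilerplateSpan] | None = None,
) -> list[TagSpan]:
    """Apply the trigger lexicon to one document text.

    Deterministic: rules apply in file order, and a trigger match fully
    contained in another same-tag trigger match is dropped
    (leftmost-longest wins). Overlapping same-type spans are merged.
    Spans never cross a segment boundary when segments are supplied, and
    triggers inside boilerplate lines are ignored.
    """
    if rules is None:
        rules = default_trigger_rules()
    if cfg is None:
        cfg = ScopeConfig()
    folded = fold(text)
    boiler = [(b.start, b.end) for b in (boilerplate or [])]
    seg_bounds = [(s.start, s.end) for s in (segments or [])]

    matches: list[tuple[int, int, TriggerRule]] = []
    for rule in rules:
        pat = rule.compile()
        for m in pat.finditer(folded):
            if m.start() == m.end():
                continue
            if _inside(m.start(), boiler):
                continue
            if rule.tag is Tag.NEGATION:
                ls, le = _line_bounds(folded, m.start())
                if _NUMERIC_RESULT_RE.search(folded[ls:le]):
                    continue
            matches.append((m.start(), m.end(), rule))
    # leftmost-longest suppression of nested same-tag trigger matches
    kept_matches = [
        (s, e, rule)
        for s, e, rule in matches
        if not any(
            (s2 <= s and e <= e2) and (s2, e2) != (s, e) and rule2.tag is rule.tag
            for s2, e2, rule2 in matches
        )
    ]

    spans: list[TagSpan] = []
    for s, e, rule in kept_matches:
        seg = next(((ss, se) for ss, se in seg_bounds if ss <= s < se), None)
        bounds = seg if seg is not None else (0, len(text))
        directions = (
            [True]
            if rule.direction == "FORWARD"
            else [False]
            if rule.direction == "BACKWARD"
            else [True, False]
        )
        for forward in directions:
            span = _scope_span(text, folded, s, e, rule, cfg, forward, bounds)
            if span is not None:
                spans.append(TagSpan(span[0], span[1], rule.tag, text[s:e]))

    spans.sort(key=lambda sp: (sp.start, sp.end))
    if not cfg.merge_overlaps:
        return spans
    merged: list[TagSpan] = []
    for sp in spans:
        if merged and merged[-1].tag is sp.tag and sp.start <= merged[-1].end:
            prev = merged[-1]
            merged[-1] = TagSpan(
                prev.start, max(prev.end, sp.end), prev.tag, prev.trigger
            )
        else:
            merged.append(sp)
    return merged


def split_patient_family_content(
    text: str,
    tags: Sequence[TagSpan],
    boilerplate: Sequence[BoilerplateSpan] | None = None,
) -> tuple[str, str]:
    """Separate patient content from family-medical-history content.

    ``family_text`` concatenates the FAMILY spans; ``patient_text`` is the
    document minus FAMILY spans and boilerplate. Negation/hypothesis spans
    remain in the patient text (their polarity is carried by the index
    fields, not by this split). Token content is conserved: the token
    multiset of patient + family + boilerplate equals that of the input.
    """
    for sp in tags:
        if sp.end > len(text):
            raise ValueError(f"tag span [{sp.start}, {sp.end}) out of bounds")
    removed = sorted(
        [(sp.start, sp.end) for sp in tags if sp.tag is Tag.FAMILY]
        + [(b.start, b.end) for b in (boilerplate or [])]
    )
    family_parts = [
        text[sp.start : sp.end] for sp in tags if sp.tag is Tag.FAMILY
    ]
    pieces: list[str] = []
    cursor = 0
    for s, e in removed:
        s = max(s, cursor)
        if s < e:
            pieces.append(text[cursor:s])
            pieces.append("\n")  # separator prevents token gluing
            cursor = e
    pieces.append(text[cursor:])
    return "".join(pieces), "\n".join(family_parts)
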