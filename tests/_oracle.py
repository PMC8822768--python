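"""Independent brute-force query evaluator and random query generator.

The evaluator never touches the inverted index: for every document it
re-derives token contexts directly from the standoff annotations and
answers leaf queries by explicit scans over the token list. It exists to
cross-check the index's set semantics on small corpora.
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass
from typing import Mapping, Sequence

from clinsearch._text import analyze, fold
from clinsearch.corpus import ClinicalDocument, DocumentAnnotations, Tag
from clinsearch.query import (
    And, AttrFilter, Not, Or, Phrase, Proximity, QueryNode, SegmentScope,
    TagScope, Term, Wildcard,
)


@dataclass
class _Tok:
    term: str
    is_stop: bool
    fam: bool
    neg: bool
    hyp: bool
    seg: str | None


def _doc_tokens(text: str, ann: DocumentAnnotations) -> list[_Tok]:
    def overlaps(spans, s, e):
        return any(a < e and s < b for a, b in spans)

    boiler = [(b.start, b.end) for b in ann.boilerplate]
    by_tag = {
        t: [(sp.start, sp.end) for sp in ann.tags if sp.tag is t] for t in Tag
    }
    toks = []
    for tok in analyze(text):
        if overlaps(boiler, tok.start, tok.end):
            continue
        seg = None
        for sg in ann.segments:
            if sg.start <= tok.start and tok.end <= sg.end:
                seg = sg.label
                break
        toks.append(
            _Tok(
                tok.text, tok.is_stop,
                overlaps(by_tag[Tag.FAMILY], tok.start, tok.end),
                overlaps(by_tag[Tag.NEGATION], tok.start, tok.end),
                overlaps(by_tag[Tag.HYPOTHESIS], tok.start, tok.end),
                seg,
            )
        )
    return toks


def _admits(tok: _Tok, tag: Tag | None, seg: str | None) -> bool:
    if seg is not None and tok.seg != seg:
        return False
    if tag is Tag.NEGATION:
        return tok.neg
    if tag is Tag.HYPOTHESIS:
        return tok.hyp
    if tag is Tag.FAMILY:
        return tok.fam
    return not (tok.fam or tok.neg or tok.hyp)


def _query_terms(words: Sequence[str]) -> list[str]:
    out = []
    for w in words:
        out.extend(t.text for t in analyze(w) if not t.is_stop)
    return out


def _leaf_match(
    node: QueryNode, toks: list[_Tok], tag: Tag | None, seg: str | None
) -> bool:
    if isinstance(node, Term):
        terms = _query_terms([node.word])
        if len(terms) != 1:
            return _leaf_match(Phrase(tuple(node.word.split())), toks, tag, seg)
        return any(
            t.term == terms[0] and _admits(t, tag, seg) for t in toks
        )
    if isinstance(node, Wildcard):
        rx = re.compile(
            "^" + ".*".join(re.escape(p) for p in fold(node.pattern).split("*")) + "$"
        )
        return any(
            rx.match(t.term) and not t.is_stop and _admits(t, tag, seg) for t in toks
        )
    if isinstance(node, Phrase):
        terms = _query_terms(node.words)
        if not terms:
            return False
        nonstop = [i for i, t in enumerate(toks) if not t.is_stop]
        for j in range(len(nonstop) - len(terms) + 1):
            window = nonstop[j : j + len(terms)]
            if all(
                toks[p].term == w and _admits(toks[p], tag, seg)
                for p, w in zip(window, terms)
            ):
                return True
        return False
    if isinstance(node, Proximity):
        terms = _query_terms(node.words)
        if not terms:
            return False
        if len(terms) == 1:
            return _leaf_match(Term(terms[0]), toks, tag, seg)
        rank = []
        r = 0
        for t in toks:
            rank.append(r)
            if not t.is_stop:
                r += 1
        occ = [
            [i for i, t in enumerate(toks) if t.term == w and _admits(t, tag, seg)]
            for w in terms
        ]
        import itertools

        for combo in itertools.product(*occ):
            if len(set(combo)) != len(terms):
                continue
            lo, hi = min(combo), max(combo)
            between = rank[hi] - rank[lo] - 1
            inside = sum(1 for p in combo if lo < p < hi)
            if between - inside <= node.slope:
                return True
        return False
    raise TypeError(node)


def oracle_search(
    node: QueryNode,
    docs: Sequence[ClinicalDocument],
    annotations: Mapping[str, DocumentAnnotations],
    texts: Mapping[str, str] | None = None,
) -> set[str]:
    token_cache = {
        d.doc_id: _doc_tokens(
            texts[d.doc_id] if texts else d.raw_text, annotations[d.doc_id]
        )
        for d in docs
    }
    by_id = {d.doc_id: d for d in docs}

    def ev(n: QueryNode, tag: Tag | None, seg: str | None) -> set[str]:
        if isinstance(n, And):
            sets = [ev(c, tag, seg) for c in n.children]
            return set.intersection(*sets)
        if isinstance(n, Or):
            out: set[str] = set()
            for c in n.children:
                out |= ev(c, tag, seg)
            return out
        if isinstance(n, Not):
            return set(by_id) - ev(n.child, tag, seg)
        if isinstance(n, TagScope):
            return ev(n.child, n.tag, seg)
        if isinstance(n, SegmentScope):
            return ev(n.child, tag, n.label)
        if isinstance(n, AttrFilter):
            return {d for d in by_id if _attr_match(by_id[d], n)}
        return {
            d for d, toks in token_cache.items() if _leaf_match(n, toks, tag, seg)
        }

    return ev(node, None, None)


def _attr_match(doc: ClinicalDocument, n: AttrFilter) -> bool:
    attr = {"type": "doc_type", "date": "doc_date"}.get(n.attribute, n.attribute)
    v = n.value
    if attr == "age":
        if "-" in v:
            lo, hi = v.split("-", 1)
            return int(lo) <= doc.age_years <= int(hi)
        return doc.age_years == int(v)
    if attr == "sex":
        return doc.sex.value == v.upper()
    if attr == "doc_date":
        iso = doc.doc_date.isoformat()
        if ".." in v:
            lo, hi = v.split("..", 1)
            return (not lo or iso >= lo) and (not hi or iso <= hi + "￿")
        return iso.startswith(v)
    if attr == "doc_type":
        return doc.doc_type.lower() == v.lower()
    if attr == "unit":
        return doc.unit.lower() == v.lower()
    if attr == "icd10":
        return any(c.startswith(v.upper()) for c in doc.icd10_codes)
    if attr == "ccam":
        return any(c.upper().startswith(v.upper()) for c in doc.ccam_codes)
    raise ValueError(attr)


# ---------------------------------------------------------------------------
# Random query trees


def random_query(
    rng: random.Random,
    vocab: Sequence[str],
    segment_labels: Sequence[str],
    depth: int = 4,
) -> QueryNode:
    """A random well-formed query tree of bounded depth."""
    if depth <= 0 or rng.random() < 0.35:
        kind = rng.random()
        word = rng.choice(vocab)
        if kind < 0.5:
            return Term(word)
        if kind < 0.65:
            return Phrase((rng.choice(vocab), rng.choice(vocab)))
        if kind < 0.8:
            return Proximity((rng.choice(vocab), rng.choice(vocab)), rng.randrange(4))
        if kind < 0.9:
            return Wildcard(word[: max(2, len(word) // 2)] + "*")
        return AttrFilter(
            *rng.choice(
                [
                    ("age", f"{rng.randrange(0, 60)}-{rng.randrange(60, 100)}"),
                    ("sex", rng.choice("MF")),
                    ("unit", "cardiologie"),
                    ("icd10", rng.choice(["I48", "J45", "E11"])),
                ]
            )
        )
    kind = rng.random()
    if kind < 0.3:
        return And(
            tuple(
                random_query(rng, vocab, segment_labels, depth - 1)
                for _ in range(rng.randrange(2, 4))
            )
        )
    if kind < 0.6:
        return Or(
            tuple(
                random_query(rng, vocab, segment_labels, depth - 1)
                for _ in range(rng.randrange(2, 4))
            )
        )
    if kind < 0.75:
        return Not(random_query(rng, vocab, segment_labels, depth - 1))
    if kind < 0.9:
        tag = rng.choice(list(Tag))
        return TagScope(tag, random_query(rng, vocab, segment_labels, depth - 1))
    return SegmentScope(
        rng.choice(list(segment_labels)),
        random_query(rng, vocab, segment_labels, depth - 1),
    )
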