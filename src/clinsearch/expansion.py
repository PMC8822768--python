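"""Lexicon-driven query expansion with live document counts.

A local terminology lexicon (concept → preferred term, synonyms,
hyponyms, related concepts) stands in for a remote terminology server;
the interface is pluggable so a web service could back it later. For a
concept, expansion collects the preferred term, synonyms, and the terms
of direct hyponym/related concepts, attaching each term's document
frequency in the index so callers (or users) can drop terms that match
nothing.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

from .index import SearchIndex
from .query import Or, Phrase, QueryNode, Term

__all__ = [
    "Concept", "TermLexicon", "ExpandedTerm",
    "load_lexicon", "demo_lexicon", "expand_concept", "build_subquery",
]


@dataclass
class Concept:
    concept_id: str
    preferred_term: str = ""
    synonyms: list[str] = field(default_factory=list)
    hyponyms: list[str] = field(default_factory=list)  # concept ids
    related: list[str] = field(default_factory=list)  # concept ids


class LexiconIntegrityError(ValueError):
    pass


@dataclass
class TermLexicon:
    concepts: dict[str, Concept]

    def validate(self) -> None:
        for c in self.concepts.values():
            for ref in [*c.hyponyms, *c.related]:
                if ref not in self.concepts:
                    raise LexiconIntegrityError(
                        f"{c.concept_id}: unresolved reference {ref!r}"
                    )
        # hyponym graph must be acyclic (no concept is its own ancestor)
        WHITE, GREY, BLACK = 0, 1, 2
        color = {cid: WHITE for cid in self.concepts}

        def visit(cid: str) -> None:
            color[cid] = GREY
            for child in self.concepts[cid].hyponyms:
                if color[child] == GREY:
                    raise LexiconIntegrityError(f"hyponym cycle through {child!r}")
                if color[child] == WHITE:
                    visit(child)
            color[cid] = BLACK

        for cid in self.concepts:
            if color[cid] == WHITE:
                visit(cid)

    def terms_of(self, concept_id: str) -> list[str]:
        c = self.concepts[concept_id]
        out = [c.preferred_term] if c.preferred_term else []
        out.extend(c.synonyms)
        return out


def load_lexicon(path: str | Path) -> TermLexicon:
    """Read a TSV lexicon: concept_id, relation, term-or-target-id.

    Relations: PREF (preferred term), SYN (synonym), HYPONYM_OF (this
    concept is a hyponym of the target concept), RELATED (target id).
    """
    concepts: dict[str, Concept] = {}

    def get(cid: str) -> Concept:
        return concepts.setdefault(cid, Concept(cid))

    with open(path, encoding="utf-8") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            cid, relation, value = row[0], row[1], row[2]
            if relation == "PREF":
                get(cid).preferred_term = value
            elif relation == "SYN":
                get(cid).synonyms.append(value)
            elif relation == "HYPONYM_OF":
                get(value).hyponyms.append(cid)
                get(cid)
            elif relation == "RELATED":  # relatedness is symmetric
                get(cid).related.append(value)
                get(value).related.append(cid)
            else:
                raise LexiconIntegrityError(f"unknown relation {relation!r}")
    lex = TermLexicon(concepts)
    lex.validate()
    return lex


def demo_lexicon() -> TermLexicon:
    path = resources.files("clinsearch.data") / "demo_lexicon.tsv"
    return load_lexicon(str(path))


@dataclass(frozen=True)
class ExpandedTerm:
    term: str
    n_documents: int
    #: True when the term matches no document (caller may drop it)
    zero_flagged: bool


def expand_concept(
    concept_id: str,
    lexicon: TermLexicon,
    index: Optional[SearchIndex] = None,
    depth: int = 1,
) -> list[ExpandedTerm]:
    """Terms for a concept with their document frequencies.

    Collects the preferred term and synonyms, plus the terms of hyponym
    and related concepts expanded ``depth`` levels deep (1 = direct
    children only). Without an index, counts are reported as 0/flagged.
    """
    if concept_id not in lexicon.concepts:
        raise KeyError(f"unknown concept {concept_id!r}")
    terms: list[str] = []
    seen_terms: set[str] = set()
    seen_concepts: set[str] = set()

    def collect(cid: str, remaining: int) -> None:
        if cid in seen_concepts:
            return
        seen_concepts.add(cid)
        for t in lexicon.terms_of(cid):
            if t not in seen_terms:
                seen_terms.add(t)
                terms.append(t)
        if remaining > 0:
            c = lexicon.concepts[cid]
            for child in [*c.hyponyms, *c.related]:
                collect(child, remaining - 1)

    collect(concept_id, depth)
    out = []
    for t in terms:
        df = index.document_frequency(t) if index is not None else 0
        out.append(ExpandedTerm(t, df, df == 0))
    return out


def build_subquery(expanded: list[ExpandedTerm]) -> QueryNode:
    """OR of term/phrase nodes over the selected expansion terms."""
    if not expanded:
        raise ValueError("cannot build a subquery from an empty term selection")
    nodes: list[QueryNode] = []
    for et in expanded:
        words = et.term.split()
        nodes.append(Phrase(tuple(words)) if len(words) > 1 else Term(et.term))
    return nodes[0] if len(nodes) == 1 else Or(tuple(nodes))
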