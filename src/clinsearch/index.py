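"""Tag- and segment-aware inverted index and search semantics.

Every document contributes one analyzed token stream (boilerplate lines
are dropped before tokenization, so positions run over indexable tokens
only). Each position carries the context derived from the standoff
annotations: inside a FAMILY span, inside a NEGATION span, inside a
HYPOTHESIS span, and the enclosing segment label. Logical index fields
(``patient_content``, ``family_content``, ``seg:<label>``,
``neg:patient``, ``neg:seg:<label>``, ``hyp:...``) are views over these
per-position flags.

Search semantics follow the R1/R2/R3 contract: a bare term is "true"
when it occurs outside NEGATION and HYPOTHESIS spans (and outside family
content); ``NEG(C)`` matches documents where C occurs inside a negation
span at least once; ``C NOT NEG(C)`` therefore selects documents where C
is asserted at least once and never negated.
"""

from __future__ import annotations

import itertools
import json
import re
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from ._text import analyze
from .corpus import (
    ClinicalDocument,
    CorpusError,
    DocumentAnnotations,
    Tag,
)
from .query import (
    And,
    AttrFilter,
    Not,
    Or,
    Phrase,
    Proximity,
    QueryNode,
    SegmentScope,
    TagScope,
    Term,
    Wildcard,
)

__all__ = ["SearchIndex", "SearchResult", "build_index", "IndexConfig"]


@dataclass
class IndexConfig:
    allow_leading_wildcard: bool = False
    #: when True, bare terms also match inside negation/hypothesis spans
    include_uncertain: bool = False
    ordered_proximity: bool = False


@dataclass(frozen=True)
class SearchResult:
    doc_ids: tuple[str, ...]
    n_documents: int
    n_patients: int


@dataclass
class _DocEntry:
    doc_id: str
    patient_id: str
    sex: str
    age: int
    doc_date: str
    doc_type: str
    unit: str
    icd10: frozenset[str]
    ccam: frozenset[str]
    terms: list[str]
    stop: list[bool]
    fam: list[bool]
    neg: list[bool]
    hyp: list[bool]
    seg: list[Optional[str]]
    nonstop_rank: list[int] = field(default_factory=list)  # rank of non-stop prefix

    def finish(self) -> None:
        rank = 0
        self.nonstop_rank = []
        for is_stop in self.stop:
            self.nonstop_rank.append(rank)
            if not is_stop:
                rank += 1


@dataclass(frozen=True)
class _Ctx:
    tag: Optional[Tag] = None
    segment: Optional[str] = None
    include_uncertain: bool = False

    def admits(self, doc: _DocEntry, pos: int) -> bool:
        if self.segment is not None and doc.seg[pos] != self.segment:
            return False
        if self.tag is Tag.NEGATION:
            return doc.neg[pos]
        if self.tag is Tag.HYPOTHESIS:
            return doc.hyp[pos]
        if self.tag is Tag.FAMILY:
            return doc.fam[pos]
        if doc.fam[pos]:
            return False
        if not self.include_uncertain and (doc.neg[pos] or doc.hyp[pos]):
            return False
        return True


class SearchIndex:
    """In-memory inverted index over a processed corpus."""

    def __init__(self, config: IndexConfig | None = None) -> None:
        self.config = config or IndexConfig()
        self._docs: dict[str, _DocEntry] = {}
        self._postings: dict[str, dict[str, list[int]]] = {}
        self.segment_labels: set[str] = set()

    # -- construction -------------------------------------------------------

    def add_document(
        self,
        doc: ClinicalDocument,
        text: str,
        annotations: DocumentAnnotations,
    ) -> None:
        if annotations.doc_id != doc.doc_id:
            raise CorpusError(
                f"annotations for {annotations.doc_id!r} given with {doc.doc_id!r}"
            )
        for sp in [*annotations.tags, *annotations.segments, *annotations.boilerplate]:
            if sp.end > len(text):
                raise CorpusError(f"{doc.doc_id}: annotation beyond text end")
        boiler = sorted((b.start, b.end) for b in annotations.boilerplate)
        fam_spans = [(t.start, t.end) for t in annotations.tags if t.tag is Tag.FAMILY]
        neg_spans = [(t.start, t.end) for t in annotations.tags if t.tag is Tag.NEGATION]
        hyp_spans = [
            (t.start, t.end) for t in annotations.tags if t.tag is Tag.HYPOTHESIS
        ]
        segs = [(s.start, s.end, s.label) for s in annotations.segments]

        def covered(spans: list[tuple[int, int]], s: int, e: int) -> bool:
            return any(a < e and s < b for a, b in spans)

        entry = _DocEntry(
            doc_id=doc.doc_id,
            patient_id=doc.patient_id,
            sex=doc.sex.value,
            age=doc.age_years,
            doc_date=doc.doc_date.isoformat(),
            doc_type=doc.doc_type,
            unit=doc.unit,
            icd10=doc.icd10_codes,
            ccam=doc.ccam_codes,
            terms=[], stop=[], fam=[], neg=[], hyp=[], seg=[],
        )
        pos = 0
        for tok in analyze(text):
            if covered(boiler, tok.start, tok.end):
                continue  # boilerplate is never indexed
            entry.terms.append(tok.text)
            entry.stop.append(tok.is_stop)
            entry.fam.append(covered(fam_spans, tok.start, tok.end))
            entry.neg.append(covered(neg_spans, tok.start, tok.end))
            entry.hyp.append(covered(hyp_spans, tok.start, tok.end))
            label = next(
                (lb for s, e, lb in segs if s <= tok.start and tok.end <= e), None
            )
            entry.seg.append(label)
            self._postings.setdefault(tok.text, {}).setdefault(
                doc.doc_id, []
            ).append(pos)
            pos += 1
        entry.finish()
        if doc.doc_id in self._docs:
            raise CorpusError(f"duplicate doc_id {doc.doc_id!r} in index")
        self._docs[doc.doc_id] = entry
        self.segment_labels.update(lb for _s, _e, lb in segs)

    # -- introspection ------------------------------------------------------

    @property
    def doc_ids(self) -> list[str]:
        return sorted(self._docs)

    def __len__(self) -> int:
        return len(self._docs)

    def vocabulary(self) -> list[str]:
        return sorted(self._postings)

    def document_frequency(self, word: str, ctx_tag: Optional[Tag] = None) -> int:
        """Number of documents containing ``word`` under default semantics."""
        node: QueryNode = Phrase(tuple(word.split())) if " " in word else Term(word)
        if ctx_tag is not None:
            node = TagScope(ctx_tag, node)
        return self.search(node).n_documents

    # -- search -------------------------------------------------------------

    def search(self, node: QueryNode) -> SearchResult:
        ctx = _Ctx(include_uncertain=self.config.include_uncertain)
        ids = sorted(self._eval(node, ctx))
        patients = {self._docs[d].patient_id for d in ids}
        return SearchResult(tuple(ids), len(ids), len(patients))

    def _eval(self, node: QueryNode, ctx: _Ctx) -> set[str]:
        if isinstance(node, Term):
            return self._eval_terms([node.word], ctx, kind="term")
        if isinstance(node, Wildcard):
            return self._eval_wildcard(node.pattern, ctx)
        if isinstance(node, Phrase):
            return self._eval_terms(list(node.words), ctx, kind="phrase")
        if isinstance(node, Proximity):
            return self._eval_terms(
                list(node.words), ctx, kind="proximity", slope=node.slope,
                ordered=node.ordered or self.config.ordered_proximity,
            )
        if isinstance(node, And):
            sets = [self._eval(c, ctx) for c in node.children]
            return set.intersection(*sets) if sets else set()
        if isinstance(node, Or):
            out: set[str] = set()
            for c in node.children:
                out |= self._eval(c, ctx)
            return out
        if isinstance(node, Not):
            return set(self._docs) - self._eval(node.child, ctx)
        if isinstance(node, TagScope):
            return self._eval(node.child, _Ctx(node.tag, ctx.segment, True))
        if isinstance(node, SegmentScope):
            return self._eval(
                node.child, _Ctx(ctx.tag, node.label, ctx.include_uncertain)
            )
        if isinstance(node, AttrFilter):
            return self._eval_attr(node)
        raise TypeError(f"unknown query node {node!r}")

    def _analyzed_query_terms(self, words: Sequence[str]) -> list[str]:
        """Analyze query words, dropping stop words (phrase/slope contract)."""
        out = []
        for w in words:
            for tok in analyze(w):
                if not tok.is_stop:
                    out.append(tok.text)
        return out

    def _eval_terms(
        self,
        words: Sequence[str],
        ctx: _Ctx,
        kind: str,
        slope: int = 0,
        ordered: bool = False,
    ) -> set[str]:
        terms = self._analyzed_query_terms(words)
        if not terms:
            return set()
        if kind == "term" and len(terms) > 1:
            kind = "phrase"  # a multi-token surface form behaves as a phrase
        doc_sets = []
        for t in terms:
            if t not in self._postings:
                return set()
            doc_sets.append(set(self._postings[t]))
        candidates = set.intersection(*doc_sets)
        out = set()
        for doc_id in candidates:
            doc = self._docs[doc_id]
            if len(terms) == 1:
                positions = self._postings[terms[0]][doc_id]
                if any(ctx.admits(doc, p) for p in positions):
                    out.add(doc_id)
            elif kind == "phrase":
                if self._phrase_in_doc(terms, doc, ctx):
                    out.add(doc_id)
            else:
                if self._proximity_in_doc(terms, doc, ctx, slope, ordered):
                    out.add(doc_id)
        return out

    def _phrase_in_doc(self, terms: list[str], doc: _DocEntry, ctx: _Ctx) -> bool:
        """Exact sequence over the document's non-stop token stream."""
        nonstop = [i for i, s in enumerate(doc.stop) if not s]
        k = len(terms)
        for j in range(len(nonstop) - k + 1):
            window = nonstop[j : j + k]
            if all(
                doc.terms[p] == t and ctx.admits(doc, p)
                for p, t in zip(window, terms)
            ):
                return True
        return False

    def _proximity_in_doc(
        self, terms: list[str], doc: _DocEntry, ctx: _Ctx, slope: int, ordered: bool
    ) -> bool:
        occs = []
        for t in terms:
            positions = [
                p for p in self._postings[t][doc.doc_id] if ctx.admits(doc, p)
            ]
            if not positions:
                return False
            occs.append(positions)
        k = len(terms)
        for combo in itertools.product(*occs):
            if len(set(combo)) != k:
                continue
            if ordered and list(combo) != sorted(combo):
                continue
            lo, hi = min(combo), max(combo)
            between = doc.nonstop_rank[hi] - doc.nonstop_rank[lo] - 1
            # chosen terms strictly inside the window are not "separators"
            inside = sum(1 for p in combo if lo < p < hi)
            if between - inside <= slope:
                return True
        return False

    def _eval_wildcard(self, pattern: str, ctx: _Ctx) -> set[str]:
        if pattern.startswith("*") and not self.config.allow_leading_wildcard:
            raise ValueError(
                "leading wildcards are disabled (IndexConfig.allow_leading_wildcard)"
            )
        from ._text import FRENCH_STOP_WORDS, fold

        regex = re.compile(
            "^" + ".*".join(re.escape(part) for part in fold(pattern).split("*")) + "$"
        )
        out: set[str] = set()
        for term in self._postings:
            # wildcards expand over content words only
            if term not in FRENCH_STOP_WORDS and regex.match(term):
                out |= self._eval_terms([term], ctx, kind="term")
        return out

    def _eval_attr(self, node: AttrFilter) -> set[str]:
        attr = {"type": "doc_type", "date": "doc_date"}.get(
            node.attribute, node.attribute
        )
        value = node.value

        def match(doc: _DocEntry) -> bool:
            if attr == "age":
                if "-" in value:
                    lo, hi = value.split("-", 1)
                    return int(lo) <= doc.age <= int(hi)
                return doc.age == int(value)
            if attr == "sex":
                return doc.sex == value.upper()
            if attr == "doc_date":
                if ".." in value:
                    lo, hi = value.split("..", 1)
                    return (not lo or doc.doc_date >= lo) and (
                        not hi or doc.doc_date <= hi + "￿"
                    )
                return doc.doc_date.startswith(value)
            if attr == "doc_type":
                return doc.doc_type.lower() == value.lower()
            if attr == "unit":
                return doc.unit.lower() == value.lower()
            if attr == "icd10":
                return any(c.startswith(value.upper()) for c in doc.icd10)
            if attr == "ccam":
                return any(c.upper().startswith(value.upper()) for c in doc.ccam)
            raise ValueError(f"unsupported attribute {attr!r}")

        return {d for d, e in self._docs.items() if match(e)}

    # -- persistence --------------------------------------------------------

    def field_postings(self) -> dict[str, dict[str, dict[str, list[int]]]]:
        """Materialize the logical fields as term → doc → positions maps."""
        fields: dict[str, dict[str, dict[str, list[int]]]] = {}

        def put(fname: str, term: str, doc_id: str, pos: int) -> None:
            fields.setdefault(fname, {}).setdefault(term, {}).setdefault(
                doc_id, []
            ).append(pos)

        for doc_id, e in self._docs.items():
            for p, term in enumerate(e.terms):
                if e.fam[p]:
                    put("family_content", term, doc_id, p)
                else:
                    put("patient_content", term, doc_id, p)
                if e.seg[p]:
                    put(f"seg:{e.seg[p]}", term, doc_id, p)
                for flag, prefix in ((e.neg[p], "neg"), (e.hyp[p], "hyp")):
                    if flag:
                        put(f"{prefix}:patient", term, doc_id, p)
                        if e.seg[p]:
                            put(f"{prefix}:seg:{e.seg[p]}", term, doc_id, p)
        return fields

    def save(self, directory: str | Path) -> None:
        """Persist as a documented directory of per-field postings files."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        docs_payload = {
            doc_id: {
                "patient_id": e.patient_id, "sex": e.sex, "age": e.age,
                "doc_date": e.doc_date, "doc_type": e.doc_type, "unit": e.unit,
                "icd10": sorted(e.icd10), "ccam": sorted(e.ccam),
                "terms": e.terms, "stop": [int(s) for s in e.stop],
            }
            for doc_id, e in self._docs.items()
        }
        (directory / "documents.json").write_text(
            json.dumps(docs_payload, ensure_ascii=False), encoding="utf-8"
        )
        fields = self.field_postings()
        manifest = {}
        fdir = directory / "fields"
        fdir.mkdir(exist_ok=True)
        for fname, postings in fields.items():
            safe = fname.replace(":", "__")
            manifest[fname] = f"fields/{safe}.json"
            (fdir / f"{safe}.json").write_text(
                json.dumps(postings, ensure_ascii=False), encoding="utf-8"
            )
        (directory / "manifest.json").write_text(
            json.dumps({"fields": manifest, "n_documents": len(self._docs)}),
            encoding="utf-8",
        )

    @classmethod
    def load(cls, directory: str | Path, config: IndexConfig | None = None
             ) -> "SearchIndex":
        directory = Path(directory)
        idx = cls(config)
        docs_payload = json.loads(
            (directory / "documents.json").read_text(encoding="utf-8")
        )
        manifest = json.loads((directory / "manifest.json").read_text())
        fields: dict[str, dict[str, dict[str, list[int]]]] = {}
        for fname, rel in manifest["fields"].items():
            fields[fname] = json.loads((directory / rel).read_text(encoding="utf-8"))
        for doc_id, d in docs_payload.items():
            n = len(d["terms"])
            e = _DocEntry(
                doc_id=doc_id, patient_id=d["patient_id"], sex=d["sex"],
                age=d["age"], doc_date=d["doc_date"], doc_type=d["doc_type"],
                unit=d["unit"], icd10=frozenset(d["icd10"]),
                ccam=frozenset(d["ccam"]), terms=d["terms"],
                stop=[bool(s) for s in d["stop"]],
                fam=[False] * n, neg=[False] * n, hyp=[False] * n,
                seg=[None] * n,
            )
            e.finish()
            idx._docs[doc_id] = e
            for p, term in enumerate(e.terms):
                idx._postings.setdefault(term, {}).setdefault(doc_id, []).append(p)
        for fname, postings in fields.items():
            if fname == "family_content":
                flag = "fam"
            elif fname.startswith("neg:"):
                flag = "neg"
            elif fname.startswith("hyp:"):
                flag = "hyp"
            elif fname.startswith("seg:"):
                flag = None
            else:
                continue
            label = fname.split("seg:", 1)[1] if "seg:" in fname else None
            for term, docmap in postings.items():
                for doc_id, positions in docmap.items():
                    e = idx._docs[doc_id]
                    for p in positions:
                        if flag is not None:
                            getattr(e, flag)[p] = True
                        if label is not None:
                            e.seg[p] = label
                            idx.segment_labels.add(label)
        return idx


def build_index(
    docs: Sequence[ClinicalDocument],
    annotations: Mapping[str, DocumentAnnotations],
    texts: Optional[Mapping[str, str]] = None,
    config: IndexConfig | None = None,
) -> SearchIndex:
    """Build a :class:`SearchIndex` from documents and their annotations.

    ``texts`` supplies the processed (de-identified) text per document;
    when omitted, ``raw_text`` is indexed as-is.
    """
    idx = SearchIndex(config)
    for doc in docs:
        if doc.doc_id not in annotations:
            raise CorpusError(f"no annotations for document {doc.doc_id!r}")
        text = texts[doc.doc_id] if texts is not None else doc.raw_text
        idx.add_document(doc, text, annotations[doc.doc_id])
    return idx
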