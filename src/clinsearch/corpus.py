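"""Document and annotation model, plus corpus/annotation readers and writers.

The corpus is a JSON Lines file, one clinical document per line, carrying
the narrative text and the structured attributes used as search filters
(patient, sex, dates, document type, producing unit, ICD-10 diagnoses and
CCAM procedure codes, hospital stay). Annotations are standoff: they
reference ``raw_text`` by 0-based half-open character offsets and are
serialized separately, one JSON object per document.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence


class Sex(str, enum.Enum):
    M = "M"
    F = "F"
    U = "U"  # unknown; excluded from sex-stratified analytics


class Tag(str, enum.Enum):
    """Context tag types attached to narrative spans."""

    NEGATION = "NEGATION"
    HYPOTHESIS = "HYPOTHESIS"
    FAMILY = "FAMILY"


class CorpusError(ValueError):
    """Raised for malformed corpus files or invalid document sets."""


def compute_age(birth_date: dt.date, doc_date: dt.date) -> int:
    """Completed years between birth and document date (floor convention).

    A birthday not yet reached at ``doc_date`` decrements the age; the
    leap-day birthday (Feb 29) counts as completed on Feb 28 of common
    years only once the full year has elapsed.
    """
    if doc_date < birth_date:
        raise CorpusError(
            f"document date {doc_date} precedes birth date {birth_date}"
        )
    years = doc_date.year - birth_date.year
    anniversary = (doc_date.month, doc_date.day) < (birth_date.month, birth_date.day)
    return years - int(anniversary)


@dataclass(frozen=True)
class TagSpan:
    """A context-tagged span of ``raw_text`` (scope content only).

    ``trigger`` records the surface form of the lexical cue that opened
    the scope; the span itself covers the scoped content, which is what
    exact-match evaluation compares against concept ranges.
    """

    start: int
    end: int
    tag: Tag
    trigger: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise CorpusError(f"invalid span [{self.start}, {self.end})")


@dataclass(frozen=True)
class Segment:
    """A labeled report section, offsets including its header line."""

    label: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise CorpusError(f"invalid segment [{self.start}, {self.end})")


class BoilerplateReason(str, enum.Enum):
    FREQUENT_LINE = "FREQUENT_LINE"
    FORCED = "FORCED"


@dataclass(frozen=True)
class BoilerplateSpan:
    """A line flagged as repeated header/footer content.

    Excluded from indexing but kept in ``raw_text`` for display.
    """

    start: int
    end: int
    reason: BoilerplateReason = BoilerplateReason.FREQUENT_LINE


@dataclass
class ClinicalDocument:
    doc_id: str
    patient_id: str
    sex: Sex
    birth_date: dt.date
    doc_date: dt.date
    doc_type: str
    unit: str
    raw_text: str
    icd10_codes: frozenset[str] = field(default_factory=frozenset)
    ccam_codes: frozenset[str] = field(default_factory=frozenset)
    stay_id: str = ""

    def __post_init__(self) -> None:
        self.sex = Sex(self.sex)
        self.icd10_codes = frozenset(self.icd10_codes)
        self.ccam_codes = frozenset(self.ccam_codes)
        if self.doc_date < self.birth_date:
            raise CorpusError(
                f"{self.doc_id}: doc_date {self.doc_date} precedes "
                f"birth_date {self.birth_date}"
            )

    @property
    def age_years(self) -> int:
        """Patient age at the document date, in completed years."""
        return compute_age(self.birth_date, self.doc_date)

    def validate_span(self, start: int, end: int) -> None:
        if not (0 <= start < end <= len(self.raw_text)):
            raise CorpusError(
                f"{self.doc_id}: span [{start}, {end}) outside text of "
                f"length {len(self.raw_text)}"
            )


@dataclass
class DocumentAnnotations:
    """Standoff annotations for one document (offsets into its text)."""

    doc_id: str
    tags: list[TagSpan] = field(default_factory=list)
    segments: list[Segment] = field(default_factory=list)
    boilerplate: list[BoilerplateSpan] = field(default_factory=list)


# ---------------------------------------------------------------------------
# JSON Lines corpus I/O


_DATE_FIELDS = ("birth_date", "doc_date")


def _doc_to_json(doc: ClinicalDocument) -> dict:
    d = dataclasses.asdict(doc)
    d["sex"] = doc.sex.value
    d["icd10_codes"] = sorted(doc.icd10_codes)
    d["ccam_codes"] = sorted(doc.ccam_codes)
    for k in _DATE_FIELDS:
        d[k] = d[k].isoformat()
    return d


def _doc_from_json(obj: dict) -> ClinicalDocument:
    known = {f.name for f in dataclasses.fields(ClinicalDocument)}
    kwargs = {k: v for k, v in obj.items() if k in known}
    for k in _DATE_FIELDS:
        kwargs[k] = dt.date.fromisoformat(kwargs[k])
    return ClinicalDocument(**kwargs)


def read_corpus(path: str | Path) -> list[ClinicalDocument]:
    """Read a JSON Lines corpus, enforcing doc_id uniqueness.

    Unknown fields are ignored; a malformed line raises :class:`CorpusError`
    naming the line number.
    """
    docs: list[ClinicalDocument] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
                doc = _doc_from_json(obj)
            except CorpusError:
                raise
            except Exception as exc:
                raise CorpusError(f"{path}: malformed line {lineno}: {exc}") from exc
            if doc.doc_id in seen:
                raise CorpusError(
                    f"{path}: duplicate doc_id {doc.doc_id!r} at line {lineno}"
                )
            seen.add(doc.doc_id)
            docs.append(doc)
    return docs


def write_corpus(docs: Iterable[ClinicalDocument], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for doc in docs:
            fh.write(json.dumps(_doc_to_json(doc), ensure_ascii=False, sort_keys=True))
            fh.write("\n")


# ---------------------------------------------------------------------------
# Standoff annotation I/O


def _ann_to_json(ann: DocumentAnnotations) -> dict:
    return {
        "doc_id": ann.doc_id,
        "tags": [
            {"start": t.start, "end": t.end, "tag": t.tag.value, "trigger": t.trigger}
            for t in ann.tags
        ],
        "segments": [
            {"label": s.label, "start": s.start, "end": s.end} for s in ann.segments
        ],
        "boilerplate": [
            {"start": b.start, "end": b.end, "reason": b.reason.value}
            for b in ann.boilerplate
        ],
    }


def _ann_from_json(obj: dict) -> DocumentAnnotations:
    return DocumentAnnotations(
        doc_id=obj["doc_id"],
        tags=[
            TagSpan(t["start"], t["end"], Tag(t["tag"]), t.get("trigger", ""))
            for t in obj.get("tags", [])
        ],
        segments=[
            Segment(s["label"], s["start"], s["end"]) for s in obj.get("segments", [])
        ],
        boilerplate=[
            BoilerplateSpan(b["start"], b["end"], BoilerplateReason(b["reason"]))
            for b in obj.get("boilerplate", [])
        ],
    )


def read_annotations(path: str | Path) -> dict[str, DocumentAnnotations]:
    """Read standoff annotations (JSON Lines, one object per document)."""
    out: dict[str, DocumentAnnotations] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            ann = _ann_from_json(json.loads(line))
            out[ann.doc_id] = ann
    return out


def write_annotations(
    annotations: Iterable[DocumentAnnotations], path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for ann in annotations:
            fh.write(json.dumps(_ann_to_json(ann), ensure_ascii=False, sort_keys=True))
            fh.write("\n")


def validate_annotations(
    doc: ClinicalDocument, ann: DocumentAnnotations
) -> None:
    """Check every annotation's offsets against the document text."""
    if ann.doc_id != doc.doc_id:
        raise CorpusError(f"annotation doc_id {ann.doc_id!r} != {doc.doc_id!r}")
    for span in [*ann.tags, *ann.segments, *ann.boilerplate]:
        doc.validate_span(span.start, span.end)
    prev_end = 0
    for seg in ann.segments:
        if seg.start < prev_end:
            raise CorpusError(f"{doc.doc_id}: overlapping segments")
        prev_end = seg.end
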