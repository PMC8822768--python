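"""End-to-end document processing: deid → boilerplate → segment → tag → index.

The pipeline mirrors how documents flow into the search engine: names and
identifiers are masked first (all downstream offsets refer to the masked
text), repeated header/footer lines are detected corpus-wide, reports are
segmented, context tags are applied (skipping boilerplate, clipped to
segments), and everything is handed to the index builder.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .boilerplate import BoilerplateConfig, build_frequency_table, detect_boilerplate
from .corpus import ClinicalDocument, DocumentAnnotations
from .deid import DeidConfig, OffsetMap, deidentify
from .index import IndexConfig, SearchIndex, build_index
from .segmenter import SegmentRule, segment_document
from .tagger import ScopeConfig, TriggerRule, tag_document

__all__ = ["PipelineConfig", "ProcessedDocument", "process_corpus", "index_corpus"]


@dataclass
class PipelineConfig:
    deid: DeidConfig = field(default_factory=DeidConfig)
    boilerplate: BoilerplateConfig = field(default_factory=BoilerplateConfig)
    trigger_rules: Optional[Sequence[TriggerRule]] = None  # None = shipped lexicon
    scope: ScopeConfig = field(default_factory=ScopeConfig)
    segment_rules: Optional[Sequence[SegmentRule]] = None  # None = shipped catalogue
    index: IndexConfig = field(default_factory=IndexConfig)


@dataclass
class ProcessedDocument:
    doc: ClinicalDocument
    text: str  # masked text; all annotation offsets refer to it
    offset_map: OffsetMap
    n_masked: int
    annotations: DocumentAnnotations


def process_corpus(
    docs: Sequence[ClinicalDocument], cfg: PipelineConfig | None = None
) -> list[ProcessedDocument]:
    cfg = cfg or PipelineConfig()
    masked = [deidentify(doc, cfg.deid) for doc in docs]
    table = build_frequency_table([m.text for m in masked])
    out: list[ProcessedDocument] = []
    for doc, m in zip(docs, masked):
        boiler = detect_boilerplate(m.text, table, cfg.boilerplate)
        segments = segment_document(m.text, cfg.segment_rules)
        tags = tag_document(
            m.text, cfg.trigger_rules, cfg.scope, segments=segments,
            boilerplate=boiler,
        )
        out.append(
            ProcessedDocument(
                doc=doc,
                text=m.text,
                offset_map=m.offset_map,
                n_masked=m.n_masked,
                annotations=DocumentAnnotations(
                    doc_id=doc.doc_id, tags=tags, segments=segments,
                    boilerplate=boiler,
                ),
            )
        )
    return out


def index_corpus(
    docs: Sequence[ClinicalDocument], cfg: PipelineConfig | None = None
) -> tuple[SearchIndex, list[ProcessedDocument]]:
    """Process a corpus and build its search index."""
    cfg = cfg or PipelineConfig()
    processed = process_corpus(docs, cfg)
    idx = build_index(
        [p.doc for p in processed],
        {p.doc.doc_id: p.annotations for p in processed},
        texts={p.doc.doc_id: p.text for p in processed},
        config=cfg.index,
    )
    return idx, processed
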