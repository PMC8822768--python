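import datetime as dt

import pytest

from clinsearch.corpus import ClinicalDocument, DocumentAnnotations, Sex
from clinsearch.index import build_index
from clinsearch.pipeline import PipelineConfig, index_corpus
from clinsearch.segmenter import segment_document
from clinsearch.synthetic import GeneratorConfig, generate
from clinsearch.tagger import tag_document


def make_doc(i, text, *, pid=None, sex=Sex.M, birth=dt.date(1950, 1, 1),
             date=dt.date(2020, 6, 1), doc_type="consultation",
             unit="cardiologie", icd10=(), ccam=()):
    return ClinicalDocument(
        doc_id=f"D{i}", patient_id=pid or f"P{i}", sex=sex, birth_date=birth,
        doc_date=date, doc_type=doc_type, unit=unit, raw_text=text,
        icd10_codes=frozenset(icd10), ccam_codes=frozenset(ccam),
    )


def annotate(doc):
    segs = segment_document(doc.raw_text)
    tags = tag_document(doc.raw_text, segments=segs)
    return DocumentAnnotations(doc.doc_id, tags=tags, segments=segs)


@pytest.fixture(scope="session")
def micro_corpus():
    """Six hand-written documents exercising every search feature."""
    texts = [
        "traitement par quinine pour paludisme",
        "quinine seule",
        "palu ancien",
        "abcès de la marge anale opéré",
        "psoriasis étendu et rhumatisme psoriasique",
        "Histoire de la maladie :\nPas d'asthme connu.\n"
        "Examen clinique :\nasthme équilibré.",
    ]
    docs = [make_doc(i + 1, t) for i, t in enumerate(texts)]
    anns = {d.doc_id: annotate(d) for d in docs}
    return docs, anns, build_index(docs, anns)


@pytest.fixture(scope="session")
def synthetic_indexed():
    """A processed-and-indexed synthetic corpus with its gold record."""
    cfg = GeneratorConfig(
        n_documents=60, n_patients=25, seed=11,
        boilerplate_lines=(("Hôpital Universitaire - Secrétariat", 40),),
    )
    sc = generate(cfg)
    pcfg = PipelineConfig(
        deid=sc.deid_config(), boilerplate=sc.boilerplate_config(0.5)
    )
    idx, processed = index_corpus(sc.documents, pcfg)
    return sc, pcfg, idx, processed
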