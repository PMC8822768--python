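"""Index construction and search semantics, cross-checked brute force."""

import random

import pytest

from clinsearch.corpus import DocumentAnnotations, Tag
from clinsearch.index import IndexConfig, SearchIndex, build_index
from clinsearch.query import Or, Term, parse_query
from clinsearch.tagger import tag_document

from _oracle import oracle_search, random_query
from conftest import annotate, make_doc


def run(idx, q):
    return set(idx.search(parse_query(q)).doc_ids)


def test_boolean_retrieval_micro_corpus(micro_corpus):
    docs, anns, idx = micro_corpus
    assert run(idx, '(paludisme OR "accès palustre" OR palu) AND quinine') == {"D1"}


def test_proximity_counts_non_stop_separators(micro_corpus):
    _docs, _anns, idx = micro_corpus
    # "abcès de la marge anale": only "marge" separates the terms
    assert run(idx, '"abcès anal"~2') == {"D4"}
    assert run(idx, '"abcès anal"~1') == {"D4"}
    assert run(idx, '"abcès anal"~0') == set()


def test_wildcard_expansion(micro_corpus):
    _docs, _anns, idx = micro_corpus
    assert run(idx, "pso*") == {"D5"}  # psoriasis + psoriasique
    assert run(idx, "palu*") == {"D1", "D3"}


def test_leading_wildcard_disabled_by_default(micro_corpus):
    _docs, _anns, idx = micro_corpus
    with pytest.raises(ValueError, match="leading wildcard"):
        run(idx, "*isme")


def test_r1_r2_r3_semantics(micro_corpus):
    _docs, _anns, idx = micro_corpus
    r1 = run(idx, "asthme")
    r2 = run(idx, "NEG(asthme)")
    r3 = run(idx, "asthme NOT NEG(asthme)")
    assert r1 == {"D6"} and r2 == {"D6"}
    assert r3 == r1 - r2 == set()


def test_negated_token_present_in_patient_content_and_neg_fields(micro_corpus):
    docs, anns, idx = micro_corpus
    # D6: "asthme" negated in anamnesis, asserted in clinical examination
    assert run(idx, "SEG(anamnesis, NEG(asthme))") == {"D6"}
    assert run(idx, "SEG(anamnesis, asthme)") == set()
    assert run(idx, "SEG(clinical_examination, asthme)") == {"D6"}


def test_family_content_separated_from_patient_search():
    doc = make_doc(
        1, "Antécédents familiaux d'infarctus du myocarde. Pas d'angor."
    )
    idx = build_index([doc], {"D1": annotate(doc)})
    assert run(idx, "infarctus") == set()
    assert run(idx, "FAM(infarctus)") == {"D1"}
    assert run(idx, "NEG(angor)") == {"D1"}


def test_boilerplate_tokens_never_indexed():
    from clinsearch.corpus import BoilerplateSpan

    text = "Secrétariat ouvert du lundi au vendredi\nasthme équilibré"
    doc = make_doc(1, text)
    ann = DocumentAnnotations(
        "D1", boilerplate=[BoilerplateSpan(0, text.index("\n"))]
    )
    idx = build_index([doc], {"D1": ann})
    assert run(idx, "secrétariat") == set()
    assert run(idx, "asthme") == {"D1"}


def test_attribute_filters_combine_with_text():
    docs = [
        make_doc(1, "asthme", sex="F", icd10=("J45",)),
        make_doc(2, "asthme", sex="M"),
    ]
    idx = build_index([d for d in docs], {d.doc_id: annotate(d) for d in docs})
    assert run(idx, "asthme AND sex:F") == {"D1"}
    assert run(idx, "asthme AND icd10:J45") == {"D1"}
    assert run(idx, "asthme AND age:60-80") == {"D1", "D2"}
    assert run(idx, "asthme AND date:2020") == {"D1", "D2"}


def test_n_patients_counts_distinct_patients():
    docs = [
        make_doc(1, "asthme", pid="P1"),
        make_doc(2, "asthme ancien", pid="P1"),
        make_doc(3, "asthme", pid="P2"),
    ]
    idx = build_index(list(docs), {d.doc_id: annotate(d) for d in docs})
    res = idx.search(parse_query("asthme"))
    assert res.n_documents == 3 and res.n_patients == 2


def test_unknown_segment_label_in_corpus_returns_empty(micro_corpus):
    _docs, _anns, idx = micro_corpus
    # label valid in the catalogue but absent from this corpus
    assert run(idx, "SEG(geriatric_assessment, asthme)") == set()


def test_phrase_roundtrip_every_document(synthetic_indexed):
    sc, _cfg, idx, processed = synthetic_indexed
    for p in processed[:20]:
        g = sc.gold[p.doc.doc_id]
        plain = [
            c for c, t in zip(g.concepts, [c.tags for c in g.concepts]) if not t
        ]
        if not plain:
            continue
        concept = plain[0]
        q = f'"{concept.concept}"'
        assert p.doc.doc_id in run(idx, q)


def test_or_and_monotonicity(micro_corpus):
    _docs, _anns, idx = micro_corpus
    base = idx.search(Term("asthme")).doc_ids
    widened = idx.search(Or((Term("asthme"), Term("quinine")))).doc_ids
    assert set(base) <= set(widened)
    from clinsearch.query import And

    narrowed = idx.search(And((Term("asthme"), Term("quinine")))).doc_ids
    assert set(narrowed) <= set(base)


def test_results_sorted_and_counts_consistent(synthetic_indexed):
    _sc, _cfg, idx, _processed = synthetic_indexed
    res = idx.search(parse_query("pneumopathie OR asthme OR sinusite"))
    assert list(res.doc_ids) == sorted(res.doc_ids)
    assert res.n_documents == len(res.doc_ids)
    assert res.n_patients <= res.n_documents


def test_random_queries_match_brute_force_oracle(synthetic_indexed):
    sc, _cfg, idx, processed = synthetic_indexed
    anns = {p.doc.doc_id: p.annotations for p in processed}
    texts = {p.doc.doc_id: p.text for p in processed}
    vocab = sorted(
        {t for e in idx._docs.values() for t in e.terms if not t.isdigit()}
    )[:120] + ["introuvable"]
    labels = sorted(idx.segment_labels)
    rng = random.Random(1234)
    for _ in range(200):
        node = random_query(rng, vocab, labels, depth=4)
        got = set(idx.search(node).doc_ids)
        expected = oracle_search(node, sc.documents, anns, texts)
        assert got == expected, f"mismatch for {node!r}"


def test_save_load_roundtrip_preserves_search(tmp_path, micro_corpus):
    _docs, _anns, idx = micro_corpus
    idx.save(tmp_path / "idx")
    back = SearchIndex.load(tmp_path / "idx")
    for q in ["asthme", "NEG(asthme)", '"abcès anal"~2', "pso*",
              "SEG(clinical_examination, asthme)", "asthme AND sex:M"]:
        assert run(back, q) == run(idx, q), q
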