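"""Boilerplate detection: frequency table, thresholds, exceptions."""

import random
from collections import Counter

import pytest

from clinsearch.boilerplate import (
    BoilerplateConfig,
    build_frequency_table,
    detect_boilerplate,
)
from clinsearch.corpus import BoilerplateReason


HEADER = "Service de Cardiologie"


def corpus_with_header(n_with, n_without, line_index=0, filler="ligne banale"):
    docs = []
    for i in range(n_with):
        lines = [f"{filler} {i}"] * line_index + [HEADER, f"contenu du patient {i}"]
        docs.append("\n".join(lines))
    for i in range(n_without):
        docs.append(f"texte libre {i}\nsuite {i}")
    return docs


def test_frequency_table_counts_line_at_position():
    texts = corpus_with_header(600, 0, line_index=2)
    table = build_frequency_table(texts)
    assert table.counts[("service de cardiologie", 2)] == 600
    assert table.corpus_size == 600


def test_line_unique_to_one_document_counts_once():
    table = build_frequency_table(["unique ici\nautre", "rien\nvoir"])
    assert table.counts[("unique ici", 0)] == 1


def test_duplicate_line_within_one_document_counts_once_per_doc():
    table = build_frequency_table(["même ligne\nmême ligne"])
    assert table.counts[("meme ligne", 0)] == 1
    assert table.counts[("meme ligne", 1)] == 1


def test_frequency_table_matches_independent_two_pass_count():
    rng = random.Random(4)
    lines_pool = [f"ligne {i}" for i in range(6)]
    texts = [
        "\n".join(rng.choice(lines_pool) for _ in range(rng.randrange(1, 6)))
        for _ in range(50)
    ]
    table = build_frequency_table(texts)
    expected = Counter()
    for text in texts:
        for pair in {(l, i) for i, l in enumerate(text.split("\n")) if l}:
            expected[pair] += 1
    assert table.counts == expected


def test_empty_corpus_rejected():
    with pytest.raises(ValueError):
        build_frequency_table([])


def test_header_above_threshold_flagged_in_every_document():
    texts = corpus_with_header(600, 400)
    table = build_frequency_table(texts)
    cfg = BoilerplateConfig(threshold=500)
    for text in texts[:600]:
        spans = detect_boilerplate(text, table, cfg)
        assert [text[s.start : s.end] for s in spans] == [HEADER]
        assert spans[0].reason is BoilerplateReason.FREQUENT_LINE
    assert detect_boilerplate(texts[-1], table, cfg) == []


def test_window_aggregates_nearby_line_positions():
    # the same header drifts between line 0 and line 5: individually each
    # bucket is under threshold, together they are over
    texts = []
    for i in range(600):
        pad = ["pad"] * (i % 6)
        texts.append("\n".join(pad + [HEADER, f"texte {i}"]))
    table = build_frequency_table(texts)
    assert max(table.counts[("service de cardiologie", j)] for j in range(6)) == 100
    spans = detect_boilerplate(texts[0], table, BoilerplateConfig(threshold=500))
    assert [texts[0][s.start : s.end] for s in spans] == [HEADER]
    # window 0 sees only the single bucket
    assert (
        detect_boilerplate(texts[0], table, BoilerplateConfig(threshold=500, window=0))
        == []
    )


def test_protected_term_prevents_flagging():
    header = "Unité hypertension et maladies vasculaires"
    texts = ["\n".join([header, f"contenu {i}"]) for i in range(600)]
    table = build_frequency_table(texts)
    cfg = BoilerplateConfig(threshold=500, unforce_list=frozenset({"hypertension"}))
    assert detect_boilerplate(texts[0], table, cfg) == []
    # without protection the same line is flagged
    assert detect_boilerplate(texts[0], table, BoilerplateConfig(threshold=500))


def test_force_list_flags_rare_line():
    texts = ["ligne forcée unique\ncontenu", "autre\ndocument"]
    table = build_frequency_table(texts)
    cfg = BoilerplateConfig(force_list=frozenset({"Ligne forcée unique"}))
    spans = detect_boilerplate(texts[0], table, cfg)
    assert len(spans) == 1 and spans[0].reason is BoilerplateReason.FORCED


def test_threshold_monotonicity():
    texts = corpus_with_header(300, 300)
    table = build_frequency_table(texts)
    flagged = {}
    for threshold in (100, 200, 300, 301):
        spans = detect_boilerplate(texts[0], table, BoilerplateConfig(threshold=threshold))
        flagged[threshold] = {(s.start, s.end) for s in spans}
    assert flagged[301] <= flagged[300] <= flagged[200] <= flagged[100]
    assert flagged[300] and not flagged[301]


def test_force_and_unforce_must_be_disjoint():
    with pytest.raises(ValueError):
        BoilerplateConfig(
            force_list=frozenset({"x"}), unforce_list=frozenset({"x"})
        )


def test_table_tsv_roundtrip(tmp_path):
    table = build_frequency_table(corpus_with_header(10, 5))
    path = tmp_path / "freq.tsv"
    table.save_tsv(path)
    from clinsearch.boilerplate import FrequencyTable

    back = FrequencyTable.load_tsv(path, table.corpus_size)
    assert back.counts == table.counts
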