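"""Context tagging: triggers, scopes, stop characters, content split."""

import pytest

from clinsearch._text import analyze
from clinsearch.corpus import Segment, Tag
from clinsearch.tagger import (
    LexiconError,
    ScopeConfig,
    TriggerRule,
    default_trigger_rules,
    split_patient_family_content,
    tag_document,
)


def spans_of(text, tag=None, **kw):
    return [
        (s.tag, text[s.start : s.end])
        for s in tag_document(text, **kw)
        if tag is None or s.tag is tag
    ]


@pytest.mark.parametrize(
    "text, expected",
    [
        ("Pas de complication.", [(Tag.NEGATION, "complication")]),
        ("Absence de fièvre ce jour.", [(Tag.NEGATION, "fièvre ce jour")]),
        ("Recherche de BK : négatif", [(Tag.NEGATION, "Recherche de BK")]),
        ("L'endocardite a été exclue.", [(Tag.NEGATION, "endocardite")]),
        ("lésion suspecte", [(Tag.HYPOTHESIS, "lésion")]),
        ("Suspicion de pneumopathie.", [(Tag.HYPOTHESIS, "pneumopathie")]),
        ("", []),
        ("Texte sans aucun contenu pertinent, euh si.", None),  # just no crash
    ],
)
def test_trigger_examples(text, expected):
    got = spans_of(text)
    if expected is not None:
        assert got == expected


def test_discontinuous_ne_pas_negation_covers_object():
    got = spans_of("Dit ne pas faire de fausses routes")
    assert len(got) == 1 and got[0][0] is Tag.NEGATION
    assert "fausses routes" in got[0][1]


def test_numeric_result_line_not_tagged_negative():
    assert spans_of("Prealbumin: 0.16", tag=Tag.NEGATION) == []
    assert spans_of("Préalbumine : 0,16 g/l", tag=Tag.NEGATION) == []
    # the guard is specific: a textual result still tags
    assert spans_of("Protéinurie : négative", tag=Tag.NEGATION) == [
        (Tag.NEGATION, "Protéinurie")
    ]


def test_scope_stops_at_stop_characters():
    got = spans_of("Pas de dyspnée, toux grasse présente.")
    assert got == [(Tag.NEGATION, "dyspnée")]


def test_scope_stops_at_stop_word():
    got = spans_of("Pas de dyspnée mais toux fébrile")
    assert got == [(Tag.NEGATION, "dyspnée")]


def test_scope_clipped_by_token_budget():
    words = " ".join(f"mot{i}" for i in range(20))
    rules = [TriggerRule(r"\bpas d[e']", Tag.NEGATION, "FORWARD", max_scope_tokens=3)]
    got = spans_of(f"pas de {words}", rules=rules)
    assert got == [(Tag.NEGATION, "mot0 mot1 mot2")]


def test_span_does_not_cross_segment_boundary():
    text = "Antécédents :\npas de diabète\nTraitement habituel :\naspirine"
    segments = [
        Segment("medical_history", 0, text.index("Traitement")),
        Segment("usual_treatments", text.index("Traitement"), len(text)),
    ]
    got = spans_of(text, segments=segments)
    assert got == [(Tag.NEGATION, "diabète")]


def test_triggers_inside_boilerplate_ignored():
    from clinsearch.corpus import BoilerplateSpan

    text = "pas de publicité\ncontenu réel"
    got = spans_of(text, boilerplate=[BoilerplateSpan(0, 16)])
    assert got == []


def test_family_trigger_scopes_relative_content():
    text = "son père a eu un infarctus du myocarde."
    got = spans_of(text, tag=Tag.FAMILY)
    assert len(got) == 1 and "infarctus du myocarde" in got[0][1]


def test_determinism_identical_inputs_identical_spans():
    text = "Pas de fièvre. Suspicion d'embolie. Antécédents familiaux de diabète."
    assert tag_document(text) == tag_document(text)


def test_uncompilable_rule_fails_at_load_time():
    with pytest.raises(LexiconError):
        TriggerRule("([", Tag.NEGATION, "FORWARD").compile()


def test_shipped_lexicon_covers_every_tag():
    rules = default_trigger_rules()
    assert {r.tag for r in rules} == set(Tag)


def test_split_separates_family_from_patient_text():
    text = "Antécédents familiaux d'infarctus. Pas d'angor personnel."
    tags = tag_document(text)
    patient, family = split_patient_family_content(text, tags)
    assert "infarctus" in family and "infarctus" not in patient
    assert "angor" in patient


def test_split_without_tags_is_identity():
    patient, family = split_patient_family_content("texte simple", [])
    assert patient == "texte simple" and family == ""


def test_split_conserves_token_multiset():
    from collections import Counter

    text = (
        "En-tête répétée\nAntécédents familiaux de diabète. "
        "Pas de fièvre. Texte libre final."
    )
    from clinsearch.corpus import BoilerplateSpan

    boiler = [BoilerplateSpan(0, len("En-tête répétée"))]
    tags = tag_document(text, boilerplate=boiler)
    patient, family = split_patient_family_content(text, tags, boiler)
    boiler_text = " ".join(text[b.start : b.end] for b in boiler)

    def toks(s):
        return Counter(t.text for t in analyze(s))

    assert toks(patient) + toks(family) + toks(boiler_text) == toks(text)


def test_stop_sets_must_be_non_empty():
    with pytest.raises(ValueError):
        ScopeConfig(stop_characters=frozenset())
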