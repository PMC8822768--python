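"""Evaluation statistics: metrics, kappa, prevalence, exact matching."""

import random
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clinsearch.corpus import Tag, TagSpan
from clinsearch.evaluation import (
    AgreementTable,
    ConceptRecord,
    ConfusionMatrix,
    GoldConceptSpan,
    cohen_kappa,
    confusion_from_records,
    evaluate_tagger,
    metrics,
    prevalence,
    truncate2,
    well_segmented_proportion,
    write_records_tsv,
)

# Published audit tables for a French clinical negation/hypothesis tagger:
# concept-level confusion counts and the two-reader agreement tables
# (categories FN, FP, TN, TP; both agreement subsets total 2000 concepts).
NEGATION_CM = ConfusionMatrix(tp=551, fp=60, fn=68, tn=4598)
HYPOTHESIS_CM = ConfusionMatrix(tp=116, fp=41, fn=128, tn=4992)
NEGATION_AGREEMENT = (
    (14, 0, 7, 0), (0, 14, 6, 2), (14, 5, 1711, 4), (2, 7, 10, 204),
)
HYPOTHESIS_AGREEMENT = (
    (14, 0, 23, 2), (0, 15, 0, 3), (19, 0, 1886, 0), (0, 1, 4, 33),
)


def test_truncation_not_rounding():
    assert truncate2(0.7389) == 0.73
    assert truncate2(0.4754) == 0.47
    assert truncate2(0.5785) == 0.57
    assert truncate2(0.999) == 0.99


def test_negation_audit_metrics_display():
    m = metrics(NEGATION_CM)
    assert m["precision"].display == "0.90"
    assert m["recall"].display == "0.89"
    assert m["f_measure"].display == "0.89"
    assert m["precision"].exact == Fraction(551, 611)


def test_hypothesis_audit_metrics_display():
    m = metrics(HYPOTHESIS_CM)
    assert m["precision"].display == "0.73"
    assert m["recall"].display == "0.47"
    assert m["f_measure"].display == "0.57"


def test_zero_denominator_metric_is_undefined_not_zero():
    m = metrics(ConfusionMatrix(tp=0, fp=0, fn=5, tn=5))
    assert not m["precision"].defined
    assert m["precision"].display == "undefined"
    assert m["recall"].exact == 0
    assert m["recall"].display == "0.00"


def test_metrics_agree_with_sklearn_on_random_matrices():
    from sklearn.metrics import precision_score, recall_score, f1_score

    rng = random.Random(2)
    for _ in range(30):
        tp, fp, fn, tn = (rng.randrange(1, 50) for _ in range(4))
        cm = ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)
        y_true = [1] * tp + [0] * fp + [1] * fn + [0] * tn
        y_pred = [1] * tp + [1] * fp + [0] * fn + [0] * tn
        m = metrics(cm)
        assert float(m["precision"].exact) == pytest.approx(
            precision_score(y_true, y_pred)
        )
        assert float(m["recall"].exact) == pytest.approx(recall_score(y_true, y_pred))
        assert float(m["f_measure"].exact) == pytest.approx(f1_score(y_true, y_pred))


@settings(max_examples=60, derandomize=True)
@given(st.tuples(*[st.integers(1, 200)] * 4))
def test_f_between_precision_and_recall(counts):
    tp, fp, fn, tn = counts
    m = metrics(ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn))
    p, r, f = (float(m[k].exact) for k in ("precision", "recall", "f_measure"))
    assert min(p, r) - 1e-12 <= f <= max(p, r) + 1e-12


def test_precision_recall_have_wilson_intervals():
    m = metrics(NEGATION_CM)
    assert m["precision"].ci_low < float(m["precision"].exact) < m["precision"].ci_high
    # the audit reports precision 0.90 [0.87; 0.92]: the Wilson bounds
    # under the same truncation convention as the point estimates
    assert truncate2(m["precision"].ci_low) == 0.87
    assert truncate2(m["precision"].ci_high) == 0.92
    r = metrics(NEGATION_CM)["recall"]  # reported as 0.89 [0.86; 0.91]
    assert truncate2(r.ci_low) == 0.86
    assert truncate2(r.ci_high) == 0.91


def test_kappa_perfect_agreement_is_one():
    t = AgreementTable(((5, 0), (0, 7)), categories=("A", "B"))
    assert cohen_kappa(t) == 1


def test_kappa_all_cells_equal_is_zero():
    t = AgreementTable(((3, 3), (3, 3)), categories=("A", "B"))
    assert cohen_kappa(t) == 0


def test_kappa_degenerate_single_category_undefined():
    t = AgreementTable(((8, 0), (0, 0)), categories=("A", "B"))
    assert cohen_kappa(t) is None


def test_kappa_on_published_agreement_tables():
    k_neg = float(cohen_kappa(AgreementTable(NEGATION_AGREEMENT)))
    k_hyp = float(cohen_kappa(AgreementTable(HYPOTHESIS_AGREEMENT)))
    assert k_neg == pytest.approx(0.8794, abs=1e-4)
    assert k_hyp == pytest.approx(0.7051, abs=1e-4)


def test_kappa_matches_sklearn_on_random_tables():
    from sklearn.metrics import cohen_kappa_score

    rng = np.random.default_rng(3)
    for _ in range(20):
        table = rng.integers(0, 8, size=(4, 4))
        if table.sum() == 0 or table.trace() == table.sum():
            continue
        r1, r2 = [], []
        for i in range(4):
            for j in range(4):
                r1 += [i] * int(table[i, j])
                r2 += [j] * int(table[i, j])
        ours = cohen_kappa(AgreementTable(tuple(map(tuple, table.tolist()))))
        theirs = cohen_kappa_score(r1, r2)
        assert float(ours) == pytest.approx(theirs)


def test_kappa_invariant_under_category_permutation():
    rng = np.random.default_rng(5)
    table = rng.integers(1, 9, size=(4, 4))
    base = cohen_kappa(AgreementTable(tuple(map(tuple, table.tolist()))))
    perm = [2, 0, 3, 1]
    permuted = table[np.ix_(perm, perm)]
    assert cohen_kappa(
        AgreementTable(tuple(map(tuple, permuted.tolist())))
    ) == base


def records_from_counts(tag_attr, tp, fp, fn, tn):
    recs = []
    for cat, n in (("TP", tp), ("FP", fp), ("FN", fn), ("TN", tn)):
        recs += [ConceptRecord("c", **{tag_attr: cat}) for _ in range(n)]
    return recs


def test_prevalence_from_audit_counts():
    recs = records_from_counts("negation", 551, 60, 68, 4598)
    p = prevalence(recs, Tag.NEGATION)
    assert p.exact == Fraction(619, 5277)
    assert round(float(p.exact) * 100, 1) == 11.7
    recs = records_from_counts("hypothesis", 116, 41, 128, 4992)
    p = prevalence(recs, Tag.HYPOTHESIS)
    assert round(float(p.exact) * 100, 1) == 4.6


def test_prevalence_all_negative_is_zero_and_empty_rejected():
    recs = [ConceptRecord("c") for _ in range(10)]
    assert prevalence(recs, Tag.NEGATION).exact == 0
    with pytest.raises(ValueError):
        prevalence([], Tag.NEGATION)


def test_well_segmented_proportion_with_wilson_ci():
    recs = [ConceptRecord("c", well_segmented=True)] * 84 + [
        ConceptRecord("c", well_segmented=False)
    ] * 16 + [ConceptRecord("c")]  # unassessed record excluded
    m = well_segmented_proportion(recs)
    assert m.exact == Fraction(84, 100)
    assert m.ci_low < 0.84 < m.ci_high


def test_evaluate_tagger_exact_match_rule():
    text = "Pas de complication."
    s, e = text.index("complication"), text.index("complication") + 12
    gold = {"D1": [GoldConceptSpan("complication", s, e, frozenset({Tag.NEGATION}))]}
    exact = {"D1": [TagSpan(s, e, Tag.NEGATION)]}
    cm = evaluate_tagger(gold, exact)[Tag.NEGATION]
    assert (cm.tp, cm.fp, cm.fn, cm.tn) == (1, 0, 0, 0)


def test_evaluate_tagger_partial_overlap_counts_fn():
    gold = {"D1": [GoldConceptSpan("insuffisance cardiaque", 10, 32,
                                   frozenset({Tag.NEGATION}))]}
    half = {"D1": [TagSpan(10, 22, Tag.NEGATION)]}
    cm = evaluate_tagger(gold, half)[Tag.NEGATION]
    assert cm.fn == 1 and cm.tp == 0


def test_evaluate_tagger_stray_prediction_is_fp_on_untagged_concept():
    gold = {"D1": [GoldConceptSpan("asthme", 5, 11, frozenset())]}
    stray = {"D1": [TagSpan(5, 11, Tag.NEGATION)]}
    cm = evaluate_tagger(gold, stray)[Tag.NEGATION]
    assert cm.fp == 1 and cm.tn == 0


def test_evaluate_tagger_document_mismatch_rejected():
    with pytest.raises(ValueError):
        evaluate_tagger({"D1": []}, {"D2": []})


def test_confusion_from_records_and_tsv(tmp_path):
    recs = records_from_counts("negation", 2, 1, 1, 3)
    cm = confusion_from_records(recs, Tag.NEGATION)
    assert (cm.tp, cm.fp, cm.fn, cm.tn) == (2, 1, 1, 3)
    path = tmp_path / "records.tsv"
    write_records_tsv(recs, path)
    lines = path.read_text().strip().split("\n")
    assert lines[0].split("\t") == [
        "concept", "negation", "hypothesis", "family", "well_segmented",
    ]
    assert len(lines) == 8
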