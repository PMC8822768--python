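"""Descriptive analytics over a search result, and a bag-of-words
concept annotator.

``summarize_result`` reproduces the analysis-panel numbers: sex counts
and male/female ratio, the age distribution at document date (five-number
summary, mean, 5-year histogram bins stratified by sex), ICD-10/CCAM code
frequencies, document types, producing units, and the document-date
range. ``annotate_concepts`` is a greedy longest-match annotator over
analyzed tokens, enabling frequent-concept tables for a corpus.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from ._text import analyze
from .corpus import ClinicalDocument, Sex
from .expansion import TermLexicon
from .index import SearchResult

__all__ = ["summarize_result", "annotate_concepts", "concept_frequencies"]

AGE_BIN_WIDTH = 5  # years; bin k covers [5k, 5k+5)


def _median(sorted_vals: Sequence[float]) -> float:
    n = len(sorted_vals)
    mid = n // 2
    if n % 2:
        return float(sorted_vals[mid])
    return (sorted_vals[mid - 1] + sorted_vals[mid]) / 2.0


def _quartiles(values: Sequence[float]) -> tuple[float, float, float]:
    """Median-of-halves (Tukey hinge) convention.

    The lower/upper halves exclude the overall median element when the
    count is odd.
    """
    vals = sorted(values)
    n = len(vals)
    med = _median(vals)
    half = n // 2
    lower = vals[:half]
    upper = vals[n - half:]
    return _median(lower), med, _median(upper)


def summarize_result(
    result: SearchResult, corpus: Mapping[str, ClinicalDocument]
) -> dict:
    """Aggregate statistics for the documents of a search result.

    Ages are computed at each document's date. Documents whose sex is
    unknown (U) are excluded from sex-stratified tables but counted in
    the totals. An empty result yields zeroed counts, not an error.
    """
    docs = [corpus[d] for d in result.doc_ids]
    summary: dict = {
        "n_documents": len(docs),
        "n_patients": len({d.patient_id for d in docs}),
        "sex_counts": {"M": 0, "F": 0, "U": 0},
        "male_female_ratio": None,
        "age": None,
        "age_histogram": {},
        "age_histogram_by_sex": {"M": {}, "F": {}},
        "icd10_counts": {},
        "ccam_counts": {},
        "doc_type_counts": {},
        "unit_counts": {},
        "date_range": None,
    }
    if not docs:
        return summary
    by_patient_sex = {d.patient_id: d.sex for d in docs}
    for sex in by_patient_sex.values():
        summary["sex_counts"][sex.value] += 1
    m, f = summary["sex_counts"]["M"], summary["sex_counts"]["F"]
    summary["male_female_ratio"] = (m / f) if f else None

    ages = [d.age_years for d in docs]
    q1, med, q3 = _quartiles(ages)
    summary["age"] = {
        "min": min(ages), "q1": q1, "median": med, "q3": q3,
        "max": max(ages), "mean": sum(ages) / len(ages),
    }
    hist: Counter[int] = Counter()
    hist_by_sex: dict[str, Counter[int]] = {"M": Counter(), "F": Counter()}
    for d in docs:
        b = (d.age_years // AGE_BIN_WIDTH) * AGE_BIN_WIDTH
        hist[b] += 1
        if d.sex is not Sex.U:
            hist_by_sex[d.sex.value][b] += 1
    summary["age_histogram"] = dict(sorted(hist.items()))
    summary["age_histogram_by_sex"] = {
        s: dict(sorted(c.items())) for s, c in hist_by_sex.items()
    }
    summary["icd10_counts"] = dict(
        Counter(code for d in docs for code in d.icd10_codes).most_common()
    )
    summary["ccam_counts"] = dict(
        Counter(code for d in docs for code in d.ccam_codes).most_common()
    )
    summary["doc_type_counts"] = dict(Counter(d.doc_type for d in docs).most_common())
    summary["unit_counts"] = dict(Counter(d.unit for d in docs).most_common())
    dates = sorted(d.doc_date for d in docs)
    summary["date_range"] = (dates[0].isoformat(), dates[-1].isoformat())
    return summary


def _lexicon_token_terms(lexicon: TermLexicon) -> dict[tuple[str, ...], str]:
    """Map analyzed token tuples of every lexicon term to a concept id.

    When several concepts share a surface form, the first concept id in
    sorted order wins (deterministic).
    """
    out: dict[tuple[str, ...], str] = {}
    for cid in sorted(lexicon.concepts):
        for term in lexicon.terms_of(cid):
            key = tuple(t.text for t in analyze(term) if not t.is_stop)
            if key and key not in out:
                out[key] = cid
    return out


def annotate_concepts(
    text: str, lexicon: TermLexicon
) -> list[tuple[str, tuple[int, int]]]:
    """Greedy longest-match concept annotation over analyzed tokens.

    Returns (concept_id, (char_start, char_end)) pairs; overlapping
    candidates are resolved longest-first, left to right.
    """
    table = _lexicon_token_terms(lexicon)
    if not table:
        return []
    max_len = max(len(k) for k in table)
    tokens = [t for t in analyze(text) if not t.is_stop]
    out: list[tuple[str, tuple[int, int]]] = []
    i = 0
    while i < len(tokens):
        matched = False
        for k in range(min(max_len, len(tokens) - i), 0, -1):
            key = tuple(t.text for t in tokens[i : i + k])
            cid = table.get(key)
            if cid is not None:
                out.append((cid, (tokens[i].start, tokens[i + k - 1].end)))
                i += k
                matched = True
                break
        if not matched:
            i += 1
    return out


def concept_frequencies(
    texts: Sequence[str], lexicon: TermLexicon
) -> Counter[str]:
    """Concept occurrence counts over a collection of texts."""
    counts: Counter[str] = Counter()
    for text in texts:
        counts.update(cid for cid, _span in annotate_concepts(text, lexicon))
    return counts
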