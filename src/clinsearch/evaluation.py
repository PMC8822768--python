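"""Formal-evaluation statistics for tagging and segmentation.

Implements the confusion-matrix metrics used to audit context tagging
(precision, recall, F-measure, negative predictive value, specificity),
Cohen's kappa for two-reader agreement over the {FN, FP, TN, TP}
categories, tag prevalence among collected concepts, and the
concept-record data frame linking gold annotations to tagger output.

Displayed values are truncated (not rounded) to two decimals — the
convention the audited report tables follow — while exact rationals stay
available on every metric. Confidence intervals use the Wilson score
method.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from fractions import Fraction
from math import floor
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .corpus import Tag, TagSpan

__all__ = [
    "ConfusionMatrix", "Metric", "metrics", "cohen_kappa",
    "AgreementTable", "ConceptRecord", "prevalence", "evaluate_tagger",
    "well_segmented_proportion", "truncate2", "write_records_tsv",
]

CATEGORIES = ("FN", "FP", "TN", "TP")


def truncate2(x: float | Fraction) -> float:
    """Truncate to 2 decimals (floor of |x|·100 / 100, sign preserved)."""
    sign = -1 if x < 0 else 1
    return sign * floor(abs(x) * 100) / 100


@dataclass(frozen=True)
class Metric:
    """One evaluation metric: exact value plus its 2-decimal display."""

    exact: Optional[Fraction]
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None

    @property
    def defined(self) -> bool:
        return self.exact is not None

    @property
    def value(self) -> Optional[float]:
        return None if self.exact is None else float(self.exact)

    @property
    def display(self) -> str:
        if self.exact is None:
            return "undefined"
        return f"{truncate2(self.exact):.2f}"


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")
        if self.total == 0:
            raise ValueError("confusion matrix is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _ratio(num: int, den: int, with_ci: bool = False) -> Metric:
    if den == 0:
        return Metric(None)
    exact = Fraction(num, den)
    if not with_ci:
        return Metric(exact)
    low, high = proportion_confint(num, den, alpha=0.05, method="wilson")
    return Metric(exact, float(low), float(high))


def metrics(cm: ConfusionMatrix) -> dict[str, Metric]:
    """Precision, recall, F-measure, NPV and specificity.

    Zero-denominator metrics are reported as undefined, never as 0.
    Precision and recall carry Wilson 95% confidence intervals.
    F = TP / (TP + (FP+FN)/2), the harmonic mean of precision and recall.
    """
    f: Metric
    if 2 * cm.tp + cm.fp + cm.fn == 0:
        f = Metric(None)
    else:
        f = Metric(Fraction(2 * cm.tp, 2 * cm.tp + cm.fp + cm.fn))
    return {
        "precision": _ratio(cm.tp, cm.tp + cm.fp, with_ci=True),
        "recall": _ratio(cm.tp, cm.tp + cm.fn, with_ci=True),
        "f_measure": f,
        "npv": _ratio(cm.tn, cm.tn + cm.fn),
        "specificity": _ratio(cm.tn, cm.tn + cm.fp),
    }


@dataclass(frozen=True)
class AgreementTable:
    """k×k reader-1 × reader-2 category counts (default categories
    FN/FP/TN/TP)."""

    counts: tuple[tuple[int, ...], ...]
    categories: tuple[str, ...] = CATEGORIES

    def __post_init__(self) -> None:
        k = len(self.categories)
        arr = np.asarray(self.counts)
        if arr.shape != (k, k):
            raise ValueError(f"agreement table must be {k}x{k}")
        if (arr < 0).any() or arr.sum() == 0:
            raise ValueError("counts must be >= 0 with a positive total")

    @property
    def total(self) -> int:
        return int(np.asarray(self.counts).sum())


def cohen_kappa(table: AgreementTable) -> Optional[Fraction]:
    """Chance-corrected agreement κ = (Po − Pe) / (1 − Pe), exact.

    Po is the observed agreement (trace / total), Pe the chance
    agreement from the marginals. A degenerate table with Pe = 1 has no
    defined kappa and returns None.
    """
    arr = np.asarray(table.counts, dtype=object)
    n = int(arr.sum())
    po = Fraction(int(np.trace(arr)), n)
    pe = Fraction(
        int(sum(int(arr[i, :].sum()) * int(arr[:, i].sum()) for i in range(len(arr)))),
        n * n,
    )
    if pe == 1:
        return None
    return (po - pe) / (1 - pe)


@dataclass(frozen=True)
class ConceptRecord:
    """One manually collected concept with its per-tag audit category.

    ``negation``/``hypothesis``/``family`` take values in FN/FP/TN/TP;
    ``well_segmented`` is a single binary (None when segmentation was
    not assessable, e.g. consultation reports).
    """

    concept: str
    negation: str = "TN"
    hypothesis: str = "TN"
    family: str = "TN"
    well_segmented: Optional[bool] = None

    def __post_init__(self) -> None:
        for v in (self.negation, self.hypothesis, self.family):
            if v not in CATEGORIES:
                raise ValueError(f"bad category {v!r}")

    def category(self, tag: Tag) -> str:
        return {
            Tag.NEGATION: self.negation,
            Tag.HYPOTHESIS: self.hypothesis,
            Tag.FAMILY: self.family,
        }[tag]


def confusion_from_records(records: Sequence[ConceptRecord], tag: Tag
                           ) -> ConfusionMatrix:
    c = Counter(r.category(tag) for r in records)
    return ConfusionMatrix(tp=c["TP"], fp=c["FP"], fn=c["FN"], tn=c["TN"])


def prevalence(records: Sequence[ConceptRecord], tag: Tag) -> Metric:
    """Fraction of concepts truly carrying the tag (TP + FN over all).

    The reader ground truth is positive for TP (system agreed) and FN
    (system missed) records. Wilson 95% CI attached.
    """
    if not records:
        raise ValueError("prevalence needs at least one concept record")
    positive = sum(1 for r in records if r.category(tag) in ("TP", "FN"))
    return _ratio(positive, len(records), with_ci=True)


def well_segmented_proportion(records: Sequence[ConceptRecord]) -> Metric:
    """Proportion of assessable concepts falling in their correct segment."""
    assessed = [r for r in records if r.well_segmented is not None]
    if not assessed:
        return Metric(None)
    good = sum(1 for r in assessed if r.well_segmented)
    return _ratio(good, len(assessed), with_ci=True)


@dataclass(frozen=True)
class GoldConceptSpan:
    """A gold concept occurrence: its text span and true tag polarity."""

    concept: str
    start: int
    end: int
    tags: frozenset[Tag] = frozenset()


def evaluate_tagger(
    gold: Mapping[str, Sequence[GoldConceptSpan]],
    predicted: Mapping[str, Sequence[TagSpan]],
) -> dict[Tag, ConfusionMatrix]:
    """Concept-level confusion matrices per tag, exact-match rule.

    A gold-positive concept counts TP only when a predicted span of that
    tag exactly covers the concept's character range; a partial overlap
    leaves the concept FN (and the stray prediction is an FP on any
    gold-negative concept it touches). Gold and predictions must cover
    the same document set.
    """
    if set(gold) != set(predicted):
        raise ValueError("gold and predicted annotations cover different documents")
    counts: dict[Tag, Counter[str]] = {t: Counter() for t in Tag}
    for doc_id, concepts in gold.items():
        spans_by_tag: dict[Tag, list[TagSpan]] = {t: [] for t in Tag}
        for sp in predicted[doc_id]:
            spans_by_tag[sp.tag].append(sp)
        for concept in concepts:
            for tag in Tag:
                exact = any(
                    sp.start == concept.start and sp.end == concept.end
                    for sp in spans_by_tag[tag]
                )
                overlap = any(
                    sp.start < concept.end and concept.start < sp.end
                    for sp in spans_by_tag[tag]
                )
                if tag in concept.tags:
                    counts[tag]["TP" if exact else "FN"] += 1
                else:
                    counts[tag]["FP" if overlap else "TN"] += 1
    return {
        t: ConfusionMatrix(tp=c["TP"], fp=c["FP"], fn=c["FN"], tn=c["TN"])
        for t, c in counts.items()
    }


def write_records_tsv(records: Iterable[ConceptRecord], path: str | Path) -> None:
    """Write the evaluation data frame (one row per concept)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("concept\tnegation\thypothesis\tfamily\twell_segmented\n")
        for r in records:
            ws = "" if r.well_segmented is None else ("Y" if r.well_segmented else "N")
            fh.write(f"{r.concept}\t{r.negation}\t{r.hypothesis}\t{r.family}\t{ws}\n")
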