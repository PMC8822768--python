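"""Synthetic French-like clinical corpora with gold annotations.

The generator produces fixture corpora whose *statistical* structure —
tag prevalences among concepts, mean concepts per document, the
one-hospitalization-to-two-consultation/procedure document-type ratio,
repeated boilerplate lines, planted patient names — mirrors the study
conditions of a hospital document warehouse, while the language itself is
template-built and makes no claim to clinical realism. Every planted
fact is recorded as gold: concept spans with their true tag polarity and
segment, tag scopes, segment extents, boilerplate lines and names.

Default statistical parameters: 35.9 concepts per document on average
(the per-document count is drawn from an exponential law, whose standard
deviation equals its mean, matching the heavily dispersed counts seen in
real reports), and tag prevalences 11.7% negation, 4.6% hypothesis,
0.3% family medical history.
"""

from __future__ import annotations

import datetime as dt
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .boilerplate import BoilerplateConfig
from .corpus import (
    BoilerplateReason,
    BoilerplateSpan,
    ClinicalDocument,
    DocumentAnnotations,
    Segment,
    Sex,
    Tag,
    TagSpan,
    write_annotations,
    write_corpus,
)
from .deid import DeidConfig
from .evaluation import GoldConceptSpan
from .segmenter import default_segment_rules

__all__ = ["GeneratorConfig", "GoldDocument", "SyntheticCorpus", "generate"]


DEFAULT_TAG_PREVALENCE = {Tag.NEGATION: 0.117, Tag.HYPOTHESIS: 0.046,
                          Tag.FAMILY: 0.003}

CONCEPT_VOCABULARY = (
    "asthme", "pneumopathie", "embolie pulmonaire", "insuffisance rénale",
    "anémie", "fibrillation auriculaire", "infarctus du myocarde",
    "diabète de type 2", "accident vasculaire cérébral", "épilepsie",
    "migraine", "ulcère gastrique", "appendicite", "cholécystite",
    "fracture du col fémoral", "ostéoporose", "mélanome", "psoriasis",
    "eczéma", "polyarthrite rhumatoïde", "gonarthrose", "hypothyroïdie",
    "glaucome", "cataracte", "otite moyenne", "sinusite", "paludisme",
    "endocardite", "péricardite", "sarcoïdose",
)

# sentence templates; triggers drawn from the shipped lexicon so that the
# tagger's scope (up to the sentence stop character) is exactly the concept
_PLAIN_TEMPLATES = ("Présence de {c}.", "On retrouve {c}.", "Bilan retrouve {c}.")
_TAG_TEMPLATES = {
    Tag.NEGATION: ("Pas de {c}.", "Absence de {c}.", "{C} : négatif."),
    Tag.HYPOTHESIS: ("Suspicion de {c}.", "{C} probable."),
    Tag.FAMILY: ("Antécédents familiaux de {c}.", "Notion familiale de {c}."),
}

_FILLER_TEMPLATES = (
    "Consultation de suivi ce jour.",
    "Poids stable à {n} kg.",
    "Tension artérielle {n2}/{n3}.",
    "État général conservé.",
    "Prochain rendez-vous fixé.",
)

PLANTED_SURNAMES = (
    "DURAND", "LEFEBVRE", "MOREAU", "FOURNIER", "GIRARD", "BONNET",
    "ROUSSEL", "VIDAL", "CHEVALIER", "GAUTHIER", "PERRIN", "MARCHAND",
)
PLANTED_FORENAMES = (
    "Claire", "Julien", "Sophie", "Antoine", "Camille", "Hugo",
    "Manon", "Louis", "Inès", "Victor",
)

_UNITS = ("cardiologie", "pneumologie", "neurologie", "gériatrie", "urologie")
_ICD10 = ("I48", "I50.1", "J45", "E11", "G40", "N18", "K25", "M05", "C43")
_CCAM = ("DEQP003", "GLQP012", "ZBQK001", "HHFA016", "NEMA020")

DEFAULT_SEGMENT_LAYOUT = (
    "hospitalization_indication", "medical_history", "usual_treatments",
    "anamnesis", "clinical_examination", "lab_imaging_results",
    "hospital_course", "conclusion",
)


@dataclass
class GeneratorConfig:
    n_documents: int = 100
    n_patients: int = 40
    seed: int = 0
    mean_concepts_per_doc: float = 35.9
    tag_prevalence: dict[Tag, float] = field(
        default_factory=lambda: dict(DEFAULT_TAG_PREVALENCE)
    )
    #: (line text, number of documents carrying it near the top)
    boilerplate_lines: tuple[tuple[str, int], ...] = ()
    segment_layout: tuple[str, ...] = DEFAULT_SEGMENT_LAYOUT
    planted_names: tuple[tuple[str, str], ...] = tuple(
        (s, f) for s, f in zip(PLANTED_SURNAMES * 4, PLANTED_FORENAMES * 5)
    )
    filler_rate: float = 0.12  # filler sentences per concept sentence

    def __post_init__(self) -> None:
        total = sum(self.tag_prevalence.values())
        if any(p < 0 or p > 1 for p in self.tag_prevalence.values()) or total > 1:
            raise ValueError("tag prevalences must lie in [0,1] and sum to <= 1")
        if self.n_patients > self.n_documents:
            raise ValueError("n_patients cannot exceed n_documents")
        if self.n_documents <= 0:
            raise ValueError("need at least one document")


@dataclass
class GoldDocument:
    doc_id: str
    tags: list[TagSpan] = field(default_factory=list)
    segments: list[Segment] = field(default_factory=list)
    boilerplate: list[BoilerplateSpan] = field(default_factory=list)
    concepts: list[GoldConceptSpan] = field(default_factory=list)
    #: gold segment label per concept (index-aligned), None outside segments
    concept_segments: list[Optional[str]] = field(default_factory=list)

    def annotations(self) -> DocumentAnnotations:
        return DocumentAnnotations(
            doc_id=self.doc_id, tags=list(self.tags),
            segments=list(self.segments), boilerplate=list(self.boilerplate),
        )


@dataclass
class SyntheticCorpus:
    documents: list[ClinicalDocument]
    gold: dict[str, GoldDocument]
    names_per_patient: dict[str, list[str]]
    config: GeneratorConfig

    def deid_config(self) -> DeidConfig:
        return DeidConfig(
            name_list_per_patient={
                pid: list(names) for pid, names in self.names_per_patient.items()
            }
        )

    def boilerplate_config(
        self, threshold_fraction: float = 0.5
    ) -> BoilerplateConfig:
        return BoilerplateConfig(threshold_fraction=threshold_fraction)

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_corpus(self.documents, directory / "corpus.jsonl")
        write_annotations(
            (g.annotations() for g in self.gold.values()),
            directory / "gold_annotations.jsonl",
        )
        (directory / "metadata.txt").write_text(
            f"seed={self.config.seed}\nn_documents={self.config.n_documents}\n",
            encoding="utf-8",
        )


class _DocBuilder:
    """Accumulates lines while tracking character offsets."""

    def __init__(self) -> None:
        self.parts: list[str] = []
        self.pos = 0

    def add_line(self, line: str) -> tuple[int, int]:
        start = self.pos
        self.parts.append(line + "\n")
        self.pos += len(line) + 1
        return start, start + len(line)

    def text(self) -> str:
        return "".join(self.parts)


def _draw_tag(rng: random.Random, prevalence: dict[Tag, float]) -> Optional[Tag]:
    r = rng.random()
    acc = 0.0
    for tag in (Tag.NEGATION, Tag.HYPOTHESIS, Tag.FAMILY):
        acc += prevalence.get(tag, 0.0)
        if r < acc:
            return tag
    return None


def _concept_sentence(
    rng: random.Random, concept: str, tag: Optional[Tag]
) -> tuple[str, int]:
    """Render a sentence; returns (line, char offset of the concept)."""
    if tag is None:
        template = rng.choice(_PLAIN_TEMPLATES)
    else:
        template = rng.choice(_TAG_TEMPLATES[tag])
    if "{C}" in template:
        surface = concept[0].upper() + concept[1:]
        return template.replace("{C}", surface), template.index("{C}")
    return template.replace("{c}", concept), template.index("{c}")


def generate(cfg: GeneratorConfig) -> SyntheticCorpus:
    """Build a deterministic synthetic corpus with gold annotations."""
    rng = random.Random(cfg.seed)
    seg_rules = {r.label: r for r in default_segment_rules()}
    for label in cfg.segment_layout:
        if label not in seg_rules:
            raise ValueError(f"unknown segment label {label!r} in layout")

    patients = []
    names_per_patient: dict[str, list[str]] = {}
    for i in range(cfg.n_patients):
        pid = f"P{i:05d}"
        surname, forename = cfg.planted_names[i % len(cfg.planted_names)]
        names_per_patient[pid] = [surname, forename]
        birth = dt.date(1930 + rng.randrange(70), 1 + rng.randrange(12),
                        1 + rng.randrange(28))
        patients.append((pid, rng.choice((Sex.M, Sex.F)), birth, surname, forename))

    # which documents carry each boilerplate line (deterministic sample)
    boiler_membership: list[set[int]] = []
    for _line, n_docs in cfg.boilerplate_lines:
        n = min(n_docs, cfg.n_documents)
        boiler_membership.append(set(rng.sample(range(cfg.n_documents), n)))

    documents: list[ClinicalDocument] = []
    gold: dict[str, GoldDocument] = {}
    for d in range(cfg.n_documents):
        doc_id = f"D{d:06d}"
        pid, sex, birth, surname, forename = patients[d % cfg.n_patients]
        doc_date = dt.date(2016 + rng.randrange(5), 1 + rng.randrange(12),
                           1 + rng.randrange(28))
        if doc_date <= birth:
            doc_date = birth.replace(year=birth.year + 20)
        doc_type = rng.choice(
            ("hospitalization report", "consultation", "procedure report")
        )
        g = GoldDocument(doc_id)
        b = _DocBuilder()

        for (line, _n), members in zip(cfg.boilerplate_lines, boiler_membership):
            if d in members:
                s, e = b.add_line(line)
                g.boilerplate.append(BoilerplateSpan(s, e))
        civility = "Mme" if sex is Sex.F else "M."
        b.add_line(f"Patient : {civility} {surname} {forename}")
        b.add_line(f"Dossier : 8{rng.randrange(10**9):09d}")

        n_concepts = max(1, round(rng.expovariate(1.0 / cfg.mean_concepts_per_doc)))
        is_hosp = doc_type == "hospitalization report"
        if is_hosp:
            n_segs = rng.randrange(3, len(cfg.segment_layout) + 1)
            layout = cfg.segment_layout[:n_segs]
            per_seg = [n_concepts // n_segs] * n_segs
            for i in range(n_concepts % n_segs):
                per_seg[i] += 1
            seg_starts: list[tuple[int, str]] = []
            for label, quota in zip(layout, per_seg):
                hs, _he = b.add_line(seg_rules[label].canonical + " :")
                seg_starts.append((hs, label))
                _emit_sentences(rng, cfg, b, g, quota, label)
            for i, (hs, label) in enumerate(seg_starts):
                end = seg_starts[i + 1][0] if i + 1 < len(seg_starts) else b.pos
                g.segments.append(Segment(label, hs, end))
        else:
            _emit_sentences(rng, cfg, b, g, n_concepts, None)

        raw_text = b.text()
        documents.append(
            ClinicalDocument(
                doc_id=doc_id, patient_id=pid, sex=sex, birth_date=birth,
                doc_date=doc_date, doc_type=doc_type,
                unit=rng.choice(_UNITS), raw_text=raw_text,
                icd10_codes=frozenset(rng.sample(_ICD10, rng.randrange(1, 4))),
                ccam_codes=frozenset(rng.sample(_CCAM, rng.randrange(0, 3))),
                stay_id=f"S{d:06d}",
            )
        )
        gold[doc_id] = g
    return SyntheticCorpus(documents, gold, names_per_patient, cfg)


def _emit_sentences(
    rng: random.Random,
    cfg: GeneratorConfig,
    b: _DocBuilder,
    g: GoldDocument,
    n_concepts: int,
    segment_label: Optional[str],
) -> None:
    for _ in range(n_concepts):
        if rng.random() < cfg.filler_rate:
            filler = rng.choice(_FILLER_TEMPLATES)
            filler = (
                filler.replace("{n2}", str(rng.randrange(9, 16)))
                .replace("{n3}", str(rng.randrange(5, 10)))
                .replace("{n}", str(rng.randrange(45, 110)))
            )
            b.add_line(filler)
        concept = rng.choice(CONCEPT_VOCABULARY)
        tag = _draw_tag(rng, cfg.tag_prevalence)
        line, rel = _concept_sentence(rng, concept, tag)
        ls, _le = b.add_line(line)
        start, end = ls + rel, ls + rel + len(concept)
        g.concepts.append(
            GoldConceptSpan(
                concept=concept, start=start, end=end,
                tags=frozenset([tag]) if tag else frozenset(),
            )
        )
        g.concept_segments.append(segment_label)
        if tag is not None:
            g.tags.append(TagSpan(start, end, tag, trigger=""))
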