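# Methods

This note records how `clinsearch` models the problem, the conventions
and parameters it adopts, what the synthetic-data generator does and
does not emulate, and the design choices made where the design was
genuinely open.

## Corpus model

A corpus is a JSON Lines file of documents; each document carries a
narrative (`raw_text`) and the structured attributes used as filters:
patient id, sex (M/F/U), birth date, document date, document type,
producing unit, ICD-10 diagnosis codes, CCAM procedure codes, stay id.
Age is derived at the document date by the completed-years (floor)
convention: the day before a birthday still counts the previous age,
and a Feb-29 birthday completes a year only on Mar 1 of common years.
Annotations are standoff — 0-based half-open character offsets over
Unicode code points into the (processed) text — serialized separately,
one JSON object per document. Sex `U` (unknown) is admitted because
real extracts have gaps; such documents are excluded from
sex-stratified analytics but counted in totals. A document carries a
single unit and stay id.

## Text folding and the analyzer

All text comparison goes through one folding function: lowercase plus
diacritic stripping, implemented length-preservingly (ligatures œ/æ map
to a single base letter) so that character offsets survive folding.
The index analyzer splits on non-alphanumerics, resolves French
elisions (l', d', qu', …) keeping the clitic as a stop token so
positions stay aligned, marks ~70 French stop words, and applies light
gender/number conflation: the longest of the suffixes -es/-s/-e is
stripped when at least 4 characters remain, iterated to a fixpoint so
the map is idempotent. This merges *anal/anale/anales* and
*psoriasis/psoriasique* prefixes while protecting short stems
(*abcès* keeps its ending). The conflation deliberately over-stems
nouns whose final -e is not a suffix (*marge* → *marg*); this is
harmless for retrieval because queries and documents pass through the
same analyzer.

## De-identification

Listed patient names (length ≥ 2; single letters would over-mask
catastrophically) are matched token-bounded, case- and
diacritic-insensitively; identifier regular expressions (defaults:
digit runs of 8+, two letters + 6 digits — placeholders to be tuned
per deployment) are matched on the raw text. All hits are merged and
replaced by a fixed mask token (`[MASQUE]`), which keeps sentence
structure for the tagger; masking with deletion would glue tokens and
move triggers next to unrelated words. Because the mask length differs
from what it replaces, the function returns a piecewise offset map;
spans that do not straddle a replacement boundary project exactly.
Masking is idempotent (the mask matches neither names nor identifier
patterns — enforced at configuration time). Known limitation: a
patient surnamed like a common word (e.g. "Blanc") is masked anyway;
over-masking is preferred to leakage.

## Boilerplate detection

A corpus-wide table counts each whitespace-normalized, folded line once
per document at its line index. A line of a document is flagged when
the sum of its counts over line indices within ± `window` (default 7 —
absorbing small layout shifts) reaches the threshold, unless the line
contains a protected term (`unforce_list`, e.g. *hypertension*, which
is both a common clinical sign and a frequent letterhead word); lines
on `force_list` are always flagged. The production threshold is an
absolute 500 repeats; an optional `threshold_fraction` mode re-expresses
it as a fraction of corpus size so the same logic is exercisable on
small corpora (tests use 0.5). Aggregation across nearby line indices
is our reading of "line position ± 7"; the window is configurable.
Flagged lines are excluded from indexing but remain in the stored text.

## Context tagging

Trigger rules are regular expressions over folded text, shipped as an
editable YAML lexicon (the original deployment's lists are not public;
ours covers the standard French forms: *pas de*, *absence de*,
*aucun(e)*, *sans*, discontinuous *ne … pas*, post-posed
*négatif/exclu/éliminé* for negation; *suspicion*, *suspect(e)*,
*probable*, *possible*, *doute*, *évoque*, *à prévoir*,
*prévu/programmé*, *prévention*, future auxiliaries for hypothesis;
kinship nouns, *familial(e)*, *antécédents familiaux de* for family
history). Each rule scopes FORWARD (pre-posed triggers), BACKWARD
(post-posed results and adjectives) or both; the scope runs to the
nearest stop character (default `. , ; :` and newline), stop word
(default *mais*), segment boundary, or `max_scope_tokens` non-stop
tokens (default 10). Two asymmetries matter:

- backward scopes ignore `:` as a stop so that result lines
  ("Recherche de BK : négatif") tag their left-hand label;
- negation triggers are suppressed on numeric laboratory-result lines
  (`label : 0.16`-shaped), a classic false-positive of trigger-based
  negation detection.

The emitted span covers the scoped content only (trimmed of stop
tokens at the edges); the trigger surface is stored on the span. Rules
apply in file order; a trigger match nested inside another same-tag
match is dropped (leftmost-longest), and overlapping same-type spans
are merged. A span may carry several tag types via separate spans.
Patient/family content split: family spans (and boilerplate) are
removed from the patient text and concatenated into a family text;
token content is conserved across the split. Negated content inside
family spans is indexed symmetrically in the family fields.

## Segmentation

A 19-label section catalogue ships as YAML (17 canonical labels plus
`conclusion` and `lifestyle`, local names for the two sections the
source catalogue leaves unnamed), each with header-pattern variants
(*antécédents*, *ATCD*, …). A header must be line-initial and followed
by `:` or end-of-line — this requirement, not pattern priority, does
most disambiguation (bare *évolution* is a header only as a full line).
Each header opens a segment at its own start; segments run to the next
header or end of text; ties at the same position resolve in rule-file
order (specific variants are listed before generic ones). Text before
the first header is unsegmented; consultation reports legitimately
yield zero segments. No recovery is attempted for headers clinicians
phrase unusually — on real text this is the dominant error source, and
the generator does not emulate it.

## Index and query semantics

Each document contributes one analyzed token stream (boilerplate
dropped before tokenization); every position carries its contexts
(family / negation / hypothesis membership, enclosing segment). The
logical fields — `patient_content`, `family_content`, `seg:<label>`,
`neg:patient`, `neg:seg:<label>`, `hyp:…` — are views over these flags
and are what the on-disk format (a manifest plus one postings JSON per
field) persists. A bare term is *true* when it occurs outside negation
and hypothesis scopes and outside family content; `NEG/HYP/FAM(...)`
re-scope evaluation to the corresponding flags, `SEG(label, ...)`
intersects with a segment, and the two compose (negated content within
a specific segment). An index flag restores inclusion of uncertain
content in bare-term search. Phrases match contiguous runs of the
document's non-stop token sequence; proximity `"a b"~N` matches when at
most N non-stop tokens separate the terms, unordered by default
(ordered mode by flag). Wildcards expand over the content-word
vocabulary; leading wildcards are disabled by default (cost) but can be
enabled. Attribute filters cover age (value or range), sex, date
(prefix or range), document type, unit, and ICD-10/CCAM by code prefix.
Results are doc-id-ordered sets with a distinct-patient count; there is
no relevance ranking, matching the count-oriented cohort-screening use
case. A query naming a segment absent from the corpus returns an empty
result, not an error.

## Expansion, analytics

The terminology lexicon is a local TSV (concept, PREF/SYN/HYPONYM_OF/
RELATED rows; relatedness is treated as symmetric); the interface is
pluggable for a remote terminology server. Expansion returns the
preferred term, synonyms and the terms of hyponym/related concepts one
level deep by default (depth configurable), each with its document
frequency under default search semantics; zero-hit terms are flagged
rather than silently dropped. Result analytics compute ages at
document date, quartiles by the median-of-halves (Tukey hinge)
convention, and 5-year age bins `[5k, 5k+5)` — the bin width is a
documented default, not a reproduction of any particular chart. The
concept annotator is greedy longest-match over non-stop analyzed
tokens; numeric-value pattern matching is out of scope.

## Evaluation statistics

Metrics are exact rationals; the display form truncates to two
decimals. Truncation is deliberate: the audited report's printed
precision/recall/F triplets (0.73/0.47/0.57 from 116/41/128/4992) are
consistent only with truncation, and its printed precision interval
[0.87; 0.92] is exactly the truncated Wilson interval. (The same
source prints a kappa of 0.88 for an exact 0.8794, i.e. rounded — the
printed tables mix conventions, which no single display rule can
reproduce; ours follows the majority and keeps exact values
available.) Zero-denominator metrics are reported as undefined, never
as 0. Cohen's kappa is computed exactly from the k×k reader table and
is undefined for degenerate single-category tables. Prevalence of a
tag is (TP+FN)/total over concept records — the reader's ground truth
— with a Wilson 95% interval; all intervals use Wilson (the audited
report does not name its method, so interval reproductions are close
but not guaranteed exact). Concept-level tagger scoring follows the
exact-match rule: a gold-positive concept is TP only when a predicted
span of that tag covers exactly the concept's character range; partial
overlap leaves it FN, and a prediction touching a gold-negative
concept makes that concept FP. Segmentation is scored as a single
binary per concept (well segmented or not); per-label precision/recall
are intentionally not computed.

## Synthetic corpus generator

The generator emulates the statistical structure of a hospital
document warehouse: tag prevalences among concepts (defaults 11.7%
negation, 4.6% hypothesis, 0.3% family history), 35.9 concepts per
document on average with the per-document count drawn from an
exponential law (its standard deviation equals its mean, matching the
heavy dispersion of real reports), a 1:2 ratio of hospitalization
reports to consultation/procedure reports, segment layouts for
hospitalization reports, boilerplate lines planted in a configured
number of documents, and per-patient names planted in a header line.
Sentences are template-built from a 30-concept vocabulary and triggers
drawn from the shipped lexicon, placed so that the trigger's scope is
exactly the concept. All randomness flows from one seed; identical
configurations produce byte-identical corpora.

What the generator does **not** emulate — and what closed-loop results
therefore do not show about real text: misspellings, unlisted trigger
phrasings, headers clinicians write unusually, line-broken headers,
concepts spanning stop characters, nested or conflicting scopes, and
OCR noise. Closed-loop perfection (precision = recall = 1 per tag,
100% well segmented) validates the *mechanics* — scoping, offsets,
masking projection, indexing — not real-world accuracy, which on real
French reports was measured near F 0.89 for negation and F 0.57 for
hypothesis by the published audit this package's evaluation module
recomputes.

## Problem sizes and numerical choices

The acceptance script runs the closed loop on 600 generated documents
(≈ 22,000 concepts), checks index-vs-oracle agreement on 300 random
query trees of depth ≤ 4 over a 100-document corpus (8 concepts per
document on average — query semantics do not need long documents), and
verifies the R1/R2/R3 identity over the full concept vocabulary; the
test suite additionally runs 1,000 random trees and a 1,000-document
closed loop. Determinism: rules apply in file order everywhere;
results are doc-id-sorted; generator output is seed-reproducible;
hypothesis-based property tests run derandomized.
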