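# French context-trigger lexicon.
#
# Patterns are regular expressions matched against *folded* text
# (lowercased, diacritics stripped), so write "negatif" not "négatif".
# direction says where the scope extends relative to the trigger:
#   FORWARD   pre-posed trigger, scope runs to the next stop character/word
#   BACKWARD  post-posed trigger (exam results, adjectives), scope runs back
#   BIDIRECTIONAL  both sides
# max_scope_tokens bounds the non-stop-word token count of the scope.
#
# This file is data, not code: deployments extend it without a release.

defaults:
  max_scope_tokens: 10

rules:
  # --- negation -----------------------------------------------------------
  - pattern: "\\bpas d[e']"
    tag: NEGATION
    direction: FORWARD
  - pattern: "\\babsence d[e']"
    tag: NEGATION
    direction: FORWARD
  - pattern: "\\baucune?s?\\b(?: signe d[e'])?"
    tag: NEGATION
    direction: FORWARD
  - pattern: "\\bsans\\b"
    tag: NEGATION
    direction: FORWARD
  # discontinuous "ne ... pas" (also elided "n'... pas"), scope after "pas"
  - pattern: "\\bn(?:e\\s+|' ?)(?:\\w+\\s+){0,3}?pas\\b(?: d[e'])?"
    tag: NEGATION
    direction: FORWARD
  - pattern: "\\bnegati(?:f|ve)s?\\b"
    tag: NEGATION
    direction: BACKWARD
  - pattern: "\\bexclue?s?\\b"
    tag: NEGATION
    direction: BACKWARD
  - pattern: "\\beliminee?s?\\b"
    tag: NEGATION
    direction: BACKWARD

  # --- hypothesis / future ------------------------------------------------
  - pattern: "\\bsuspicion d[e']"
    tag: HYPOTHESIS
    direction: FORWARD
  - pattern: "\\bsuspecte?s?\\b"
    tag: HYPOTHESIS
    direction: BACKWARD
  - pattern: "\\bprobables?\\b"
    tag: HYPOTHESIS
    direction: BACKWARD
  - pattern: "\\bpossibles?\\b"
    tag: HYPOTHESIS
    direction: BACKWARD
  - pattern: "\\bdoute (?:sur|d[e'])"
    tag: HYPOTHESIS
    direction: FORWARD
  - pattern: "\\bevoquant\\b|\\bevoque\\b"
    tag: HYPOTHESIS
    direction: FORWARD
  - pattern: "\\ba prevoir\\b"
    tag: HYPOTHESIS
    direction: BACKWARD
  - pattern: "\\bprevue?s?\\b|\\bprogrammee?s?\\b"
    tag: HYPOTHESIS
    direction: BACKWARD
  - pattern: "\\bprevention d[e']"
    tag: HYPOTHESIS
    direction: FORWARD
  # future auxiliaries
  - pattern: "\\bsera\\b|\\bseront\\b|\\bdevra\\b|\\bdevront\\b"
    tag: HYPOTHESIS
    direction: FORWARD

  # --- family medical history --------------------------------------------
  - pattern: "\\bantecedents familiaux d[e']"
    tag: FAMILY
    direction: FORWARD
  - pattern: "\\bnotion familiale d[e']"
    tag: FAMILY
    direction: FORWARD
  - pattern: "\\bfamilial(?:e?s?|aux)\\b"
    tag: FAMILY
    direction: BACKWARD
  - pattern: "\\b(?:son|sa|ses|le|la|les|un|une) (?:pere|mere|frere|soeur|fils|fille|oncle|tante|cousin|cousine|grand[- ]pere|grand[- ]mere|parent)s?\\b"
    tag: FAMILY
    direction: FORWARD
  - pattern: "\\bchez (?:le|la|son|sa|les|ses) (?:pere|mere|frere|soeur|parent)s?\\b"
    tag: FAMILY
    direction: FORWARD
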