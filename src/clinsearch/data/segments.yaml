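# Report segment catalogue: 19 labels with header-pattern variants.
#
# Patterns are regular expressions over folded text (lowercase, no
# diacritics). A header must be line-initial and followed by ':' or the
# end of the line. `canonical` is a printable header surface used by the
# synthetic-corpus generator. Rule order breaks exact ties.
#
# The source catalogue names 17 of its 19 sections; `conclusion` and
# `lifestyle` are local choices for the two unnamed ones.

segments:
  - label: hospitalization_indication
    canonical: "Motif d'hospitalisation"
    patterns: ["motif d'hospitalisation", "indication d'hospitalisation", "motif d'admission", "motif"]
  - label: medical_history
    canonical: "Antécédents"
    patterns: ["antecedents(?: personnels| medicaux)?", "atcd"]
  - label: allergies
    canonical: "Allergies"
    patterns: ["allergies?"]
  - label: usual_treatments
    canonical: "Traitement habituel"
    patterns: ["traitements? habituels?", "traitement a l'entree"]
  - label: anamnesis
    canonical: "Histoire de la maladie"
    patterns: ["anamnese", "histoire de la maladie", "histoire recente"]
  - label: clinical_examination
    canonical: "Examen clinique"
    patterns: ["examens? cliniques?", "a l'examen"]
  - label: lab_imaging_results
    canonical: "Examens complémentaires"
    patterns: ["examens complementaires", "biologie", "resultats biologiques", "imagerie", "resultats des examens"]
  - label: posttransplant_course
    canonical: "Évolution post-greffe"
    patterns: ["evolution post[- ]greffe", "suivi de greffe", "post[- ]transplantation"]
  - label: hospital_course
    canonical: "Évolution dans le service"
    patterns: ["evolution(?: dans le service)?"]
  - label: diagnosis
    canonical: "Diagnostic retenu"
    patterns: ["diagnostics?(?: retenus?)?", "conclusion diagnostique"]
  - label: treatments_received
    canonical: "Traitements reçus"
    patterns: ["traitements? recus?", "traitement dans le service"]
  - label: discharge_treatments
    canonical: "Traitement de sortie"
    patterns: ["traitements? de sortie", "ordonnance de sortie", "traitement a la sortie"]
  - label: discharge_recommendations
    canonical: "Recommandations à la sortie"
    patterns: ["recommandations(?: a la sortie)?", "consignes de sortie"]
  - label: procedures
    canonical: "Geste réalisé"
    patterns: ["gestes? realises?", "intervention", "procedure", "compte rendu operatoire", "technique"]
  - label: postoperative_care
    canonical: "Suites opératoires"
    patterns: ["suites operatoires", "soins post[- ]operatoires", "post[- ]operatoire"]
  - label: geriatric_assessment
    canonical: "Évaluation gériatrique"
    patterns: ["evaluation geriatrique", "bilan geriatrique"]
  - label: monitoring
    canonical: "Surveillance"
    patterns: ["surveillance", "suivi"]
  - label: conclusion
    canonical: "Conclusion"
    patterns: ["conclusion", "synthese"]
  - label: lifestyle
    canonical: "Mode de vie"
    patterns: ["mode de vie", "habitus"]
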