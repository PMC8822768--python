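# Small demonstration terminology lexicon (synthetic; illustrative only).
# Columns: concept_id <TAB> relation <TAB> term-or-target-id
C001	PREF	paludisme
C001	SYN	malaria
C001	SYN	accès palustre
C002	PREF	paludisme à plasmodium falciparum
C002	HYPONYM_OF	C001
C003	PREF	quinine
C003	RELATED	C001
C010	PREF	psoriasis
C010	SYN	dermatose psoriasique
C011	PREF	rhumatisme psoriasique
C011	HYPONYM_OF	C010
C020	PREF	insuffisance cardiaque
C020	SYN	défaillance cardiaque
C021	PREF	insuffisance cardiaque gauche
C021	HYPONYM_OF	C020
C022	PREF	fibrillation auriculaire
C022	RELATED	C020
C030	PREF	ostéogenèse imparfaite
C030	SYN	maladie des os de verre
C031	PREF	fracture
C031	RELATED	C030
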