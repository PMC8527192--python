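# Reconstructed heparin/heparan-sulfate PUL model. Core: the unsaturated
# glucuronyl hydrolase GH88, the exo-processive lyase PL15, the (antisense)
# PL13 lyase, and a sulfatase for the highly sulfated regions.
fiber: heparin
description: >-
  Reconstructed model of the heparin utilization locus; glycosaminoglycan
  lyases PL15 and PL13 with the unsaturated-disaccharide hydrolase GH88 and
  a sulfatase, flanked by a susC/susD pair and a regulator.
gap_threshold_bp: 5000
slots:
  - {family_label: GH88, hmm_id: GH88, is_core: true, min_copies: 1}
  - {family_label: PL15, hmm_id: PL15, is_core: true, min_copies: 1}
  - {family_label: PL13, hmm_id: PL13, is_core: true, min_copies: 1}
  - {family_label: sulfatase, hmm_id: Sulfatase, is_core: true, min_copies: 1}
  - {family_label: susC-like, hmm_id: SusC, is_core: false, min_copies: 1}
  - {family_label: susD-like, hmm_id: SusD, is_core: false, min_copies: 1}
  - {family_label: regulator, hmm_id: Regulator, is_core: false, min_copies: 1}
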