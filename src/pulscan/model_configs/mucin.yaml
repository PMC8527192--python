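# Reconstructed mucin O-glycan PUL model: 11 gene slots. Core: GH18, GH16
# and GH92 (the families anchoring the model); the remaining hexosaminidase,
# fucosidase, galactosidase, sialidase, sulfatase, transporter pair and
# regulator slots are accessory.
fiber: mucin
description: >-
  Reconstructed model of the mucin utilization locus; GH18, GH16 and GH92
  with hexosaminidase GH20, fucosidase GH29, galactosidase GH2, sialidase
  GH33, a sulfatase, the susC/susD pair and a regulator (11 genes).
gap_threshold_bp: 5000
slots:
  - {family_label: GH18, hmm_id: GH18, is_core: true, min_copies: 1}
  - {family_label: GH16, hmm_id: GH16, is_core: true, min_copies: 1}
  - {family_label: GH92, hmm_id: GH92, is_core: true, min_copies: 1}
  - {family_label: GH20, hmm_id: GH20, is_core: false, min_copies: 1}
  - {family_label: GH29, hmm_id: GH29, is_core: false, min_copies: 1}
  - {family_label: GH2, hmm_id: GH2, is_core: false, min_copies: 1}
  - {family_label: GH33, hmm_id: GH33, is_core: false, min_copies: 1}
  - {family_label: sulfatase, hmm_id: Sulfatase, is_core: false, min_copies: 1}
  - {family_label: susC-like, hmm_id: SusC, is_core: false, min_copies: 1}
  - {family_label: susD-like, hmm_id: SusD, is_core: false, min_copies: 1}
  - {family_label: regulator, hmm_id: Regulator, is_core: false, min_copies: 1}
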