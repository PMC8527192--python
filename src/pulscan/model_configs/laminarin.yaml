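# Reconstructed laminarin (beta-1,3/1,6 glucan) PUL model. Core: the
# endo-beta-1,3-glucanase GH16 and the beta-glucosidase GH3; GH158, a CBM6
# binding module, the susC/susD pair and a surface glycan-binding protein
# are accessory.
fiber: laminarin
description: >-
  Reconstructed model of the laminarin utilization locus; GH16 endoglucanase
  and GH3 glucosidase with GH158, CBM6 and the susC/susD transporter pair.
gap_threshold_bp: 5000
slots:
  - {family_label: GH16, hmm_id: GH16, is_core: true, min_copies: 1}
  - {family_label: GH3, hmm_id: GH3, is_core: true, min_copies: 1}
  - {family_label: GH158, hmm_id: GH158, is_core: false, min_copies: 1}
  - {family_label: CBM6, hmm_id: CBM6, is_core: false, min_copies: 1}
  - {family_label: susC-like, hmm_id: SusC, is_core: false, min_copies: 1}
  - {family_label: susD-like, hmm_id: SusD, is_core: false, min_copies: 1}
  - {family_label: SGBP, hmm_id: SGBP, is_core: false, min_copies: 1}
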