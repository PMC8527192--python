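# Reconstructed arabinoxylan PUL model (Bacteroides ovatus xylan large locus).
# 10 gene slots including the hybrid two-component-system regulator of the
# operon. Core: the endoxylanase, arabinofuranosidase and glucuronidase
# activities plus the susC/susD transporter pair.
fiber: arabinoxylan
description: >-
  Reconstructed model of the arabinoxylan utilization locus; endoxylanase
  GH10 with arabinose- and glucuronate-debranching enzymes, the hallmark
  susC/susD pair, esterases and a hybrid two-component-system regulator.
gap_threshold_bp: 5000
slots:
  - {family_label: GH10, hmm_id: GH10, is_core: true, min_copies: 1}
  - {family_label: GH43, hmm_id: GH43, is_core: true, min_copies: 1}
  - {family_label: GH115, hmm_id: GH115, is_core: true, min_copies: 1}
  - {family_label: GH67, hmm_id: GH67, is_core: false, min_copies: 1}
  - {family_label: CE1, hmm_id: CE1, is_core: false, min_copies: 1}
  - {family_label: CE6, hmm_id: CE6, is_core: false, min_copies: 1}
  - {family_label: susC-like, hmm_id: SusC, is_core: true, min_copies: 1}
  - {family_label: susD-like, hmm_id: SusD, is_core: true, min_copies: 1}
  - {family_label: SGBP, hmm_id: SGBP, is_core: false, min_copies: 1}
  - {family_label: HTCS-regulator, hmm_id: HTCS, is_core: false, min_copies: 1}
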