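# Reconstructed starch (Sus operon) PUL model: the amylases GH13 and GH17
# with susD-RagB, susF-SusE, susR, TonB and the periplasmic susA. Core:
# the two amylases and the TonB-dependent transporter; binding proteins and
# the regulator are accessory.
fiber: starch
description: >-
  Reconstructed model of the starch utilization (Sus) locus; amylases GH13
  and GH17 with the TonB-dependent transporter, the susD-RagB and susF-SusE
  binding proteins, the susR regulator and periplasmic susA.
gap_threshold_bp: 5000
slots:
  - {family_label: GH13, hmm_id: GH13, is_core: true, min_copies: 1}
  - {family_label: GH17, hmm_id: GH17, is_core: true, min_copies: 1}
  - {family_label: TonB, hmm_id: TonB, is_core: true, min_copies: 1}
  - {family_label: susD-RagB, hmm_id: SusD-RagB, is_core: false, min_copies: 1}
  - {family_label: susF-SusE, hmm_id: SusF-SusE, is_core: false, min_copies: 1}
  - {family_label: susR, hmm_id: SusR, is_core: false, min_copies: 1}
  - {family_label: susA, hmm_id: SusA, is_core: false, min_copies: 1}
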