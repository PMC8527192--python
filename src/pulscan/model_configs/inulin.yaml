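# Reconstructed inulin (beta-2,1 fructan) PUL model. The locus is described
# by a short gene list: GH32 fructofuranosidase, a fructokinase domain, a
# transporter, the susC/susD homolog pair and a susHT domain. Core: GH32 and
# the susC/susD pair.
fiber: inulin
description: >-
  Reconstructed model of the inulin utilization locus; GH32
  fructofuranosidase with fructokinase, an inner-membrane transporter, the
  susC/susD homolog pair and a susHT domain.
gap_threshold_bp: 5000
slots:
  - {family_label: GH32, hmm_id: GH32, is_core: true, min_copies: 1}
  - {family_label: fructokinase, hmm_id: Fructokinase, is_core: false, min_copies: 1}
  - {family_label: transporter, hmm_id: Transporter, is_core: false, min_copies: 1}
  - {family_label: susC-like, hmm_id: SusC, is_core: true, min_copies: 1}
  - {family_label: susD-like, hmm_id: SusD, is_core: true, min_copies: 1}
  - {family_label: susHT, hmm_id: SusHT, is_core: false, min_copies: 1}
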