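# Reconstructed levan (beta-2,6 fructan) PUL model. Core: three distinct
# GH32 gene copies plus a cell-surface endo-levanase (gene copies, not
# domains on one gene).
fiber: levan
description: >-
  Reconstructed model of the levan utilization locus; three GH32 gene copies
  and a cell-surface endo-levanase with a surface glycan-binding protein,
  fructokinase and the susC/susD pair.
gap_threshold_bp: 5000
slots:
  - {family_label: GH32, hmm_id: GH32, is_core: true, min_copies: 3}
  - {family_label: levanase, hmm_id: Levanase, is_core: true, min_copies: 1}
  - {family_label: SGBP, hmm_id: SGBP, is_core: false, min_copies: 1}
  - {family_label: fructokinase, hmm_id: Fructokinase, is_core: false, min_copies: 1}
  - {family_label: susC-like, hmm_id: SusC, is_core: false, min_copies: 1}
  - {family_label: susD-like, hmm_id: SusD, is_core: false, min_copies: 1}
  - {family_label: regulator, hmm_id: Regulator, is_core: false, min_copies: 1}
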