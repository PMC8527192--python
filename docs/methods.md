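# Methods

## Model and procedure

pulscan treats fiber-specific growth capability as a genome-structure
question: a *Bacteroidetes* strain is predicted to grow on a fiber when its
genome carries a spatially clustered, core-complete instance of that
fiber's polysaccharide utilization locus (PUL) model.

A PUL model is an ordered list of gene-family slots. Each slot names a
family (CAZy style — GH32, PL15 — or a locus-specific label such as
susC-like or sulfatase), the profile identifier its hits carry, whether the
family is *core*, and the minimum number of **distinct genes** that must
match it within one candidate locus (`min_copies`; copies are genes, never
multiple domains on one gene). Growth requires every core slot; accessory
slots influence candidate ranking and completeness only.

The detection procedure per fiber:

1. **Hit assignment.** Per-domain profile-HMM hits (independent E-value,
   alignment coordinates) are filtered to the model's profile identifiers
   at E ≤ `e_value_max`. One assigned gene per gene with surviving hits;
   the best E-value per family is retained. A gene matching several slots
   counts toward each, but supplies at most one copy of any one slot.
2. **Clustering.** Assigned genes are clustered per contig by
   single-linkage hierarchical clustering on a 1-D gene position with the
   tree cut at the model's `gap_threshold_bp` (default 5,000 bp): clusters
   merge while the linkage distance is strictly below the threshold; a gap
   of exactly the threshold splits. In one dimension this is provably the
   partition of sorted positions split at adjacent gaps ≥ threshold, which
   is how it is computed (O(n log n)); the equivalence is enforced in the
   test suite against both a naive O(n³) dendrogram construction and
   scipy's single-linkage implementation. Clusters never span contigs.
   Unannotated genes between assigned genes are irrelevant to the
   partition, and candidates have no span limit.
3. **Scoring.** Completeness = mean over core slots of
   min(distinct matching genes, min_copies) / min_copies; a candidate is
   core-complete iff completeness = 1. Candidates are ranked by
   completeness (desc), distinct family count (desc), span (asc), leftmost
   start (asc) — a deterministic total order.
4. **Call.** growth = true iff some candidate is core-complete; the
   top-ranked complete candidate is the supporting locus.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `gap_threshold_bp` | 5,000 bp | dendrogram cut / maximum intra-locus gene gap |
| `e_value_max` | 1e-5 | per-domain independent E-value acceptance cutoff |
| `position_mode` | `start` | gene coordinate clustered (`start` or `midpoint`) |
| growth threshold | 0.01 | normalized-growth binarization, strictly above |
| `min_copies` | per slot | distinct genes required per core family |

The 5-kb gap and the 0.01 growth threshold are the method's defining
constants. The E-value cutoff is the conventional profile-search
stringency and is exposed (`--evalue`); gene *start* is used for
clustering because it is deterministic and convention-free, with midpoint
available (`--position`). A historical 0.1 OD-style binarization remains
available through `--growth-threshold`. Strand is ignored during
clustering: antisense members are legitimate locus members (the heparin
model's PL13 is the canonical example).

## Shipped models

Seven models ship as editable YAML (one file per fiber, schema:
`fiber`, `gap_threshold_bp`, `slots[family_label, hmm_id, is_core,
min_copies]`; unknown fields rejected). They are *reconstructed*: the
slot lists follow the families that are publicly anchored for each locus
(inulin: GH32 + fructokinase + transporter + susC/susD + susHT; levan:
3 × GH32 + levanase; heparin: GH88 + PL15 + PL13 + sulfatase; mucin: 11
genes including GH18/GH16/GH92; starch: GH13/GH17/susD-RagB/susF-SusE/
susR/TonB; arabinoxylan: 10 genes including a hybrid two-component-system
regulator; laminarin: GH16/GH3 with GH158/CBM6), with accessory fillers
drawn from standard *Bacteroidetes* locus composition. Core flags follow
the rule: families anchored as necessary are core; regulators and binding
proteins default to accessory. For starch no family is anchored as core,
so the enzymes plus the TonB-dependent transporter were chosen. Users with
better locus knowledge should edit the YAML — that is the point of the
declarative schema. Note the inulin model has 6 slots while the other
models span 7–13; published inulin locus descriptions are simply shorter.

## Evaluation machinery

Experimental growth matrices (strain × substrate, unitless normalized
OD-derived values, blank = missing) are binarized strictly above the
threshold; missing values stay missing and are excluded pairwise from
confusion tallies (the dropped count is reported). TPR = TP/(TP+FN),
FPR = FP/(FP+TN), precision = TP/(TP+FP), recall = TPR. Any
zero-denominator metric is **undefined** and rendered NA — never coerced
to 0, which would fabricate perfect scores on empty classes. Rendered
tables round to 2 decimals half-up; raw full-precision tables are written
alongside. Where differently rounded variants of the same rate circulate
(e.g. a 0.75 vs 0.73 sensitivity for starch in different summaries of the
same external benchmark), the tabulated 2-dp value is treated as canonical.

The full 28-genome external benchmark is **not** reproducible here: it
requires the type-strain genome sequences, the Pfam-derived profile HMMs
and an unpublished growth matrix. The evaluation path is instead exercised
on (a) worked examples whose confusion counts are fully determined by
their published summary (arabinoxylan: 9/28 growers, one false negative,
zero false positives; inulin: the *unique* integer matrix with 22/28
growers matching the printed 2-dp metrics, found by exhaustive
enumeration), and (b) synthetic matrices with known truth.

## Synthetic study conditions

The generator plants, per scenario, one contig with: every core slot at
its copy count plus one gene per accessory slot (`complete`); the same
minus exactly one core slot (`missing_core`); the same with one ≥ 12-kb
gap inserted inside the core gene run (`split_gap` — because exactly
`min_copies` genes are planted per core slot, any interior split leaves
both sides incomplete); or scattered accessory-family hits only
(`decoy_only`). Intergenic gaps are sampled at 200–2,000 bp, planted
proteins at 100–250 aa so consecutive assigned-gene start distances stay
below the 5-kb cut even when an unannotated gene is interleaved
(probability 0.3 per planted gene). Background contigs carry hit-free
genes at roughly prodigal-like density (~1 gene/kb). Hits are emitted
directly with E-values ≤ 1e-10 as exact powers of ten (so text round-trips
are bit-identical); protein sequences are random amino-acid strings.

What this does **not** emulate: real sequence homology (no profile search
is run — the external-scanner path is an adapter exercised only when the
tool is present), fragmented assemblies splitting loci across contigs,
partial-domain hits near the E-value cutoff, or biased gene spacing.
Passing tests therefore demonstrate the correctness of the detection
logic under the stated spatial model, not annotation robustness on real
genomes — that depends on the quality of the profile HMMs supplied.

Growth matrices derive from truth labels: growers at 0.2, non-growers at
0.0, plus Gaussian noise; with zero noise binarization recovers truth
exactly, and the label-flip rate under noise matches the Gaussian tail
probability (asserted empirically).

## Numerical and design choices

- Coordinates are GFF3-style 1-based inclusive everywhere.
- Exact-threshold gaps split (merge condition is strictly `< cut`); the
  scipy cross-check expresses this with a cut of `t − 0.5` on integer
  coordinates.
- Completeness of 1.0 is exact (a mean of exact ones), so the
  `core_complete ⇔ completeness = 1` invariant is safe under floating
  point.
- The multi-algorithm annotation consensus operates per (gene, family)
  pair, not per gene: one gene can carry several CAZyme modules, and
  per-gene voting would conflate families. GH richness counts pairs for
  the same reason (a gene with two GH families counts twice); this is an
  assumption, flagged here.
- Subfamily normalization applies only to CAZy-class labels
  (GH/PL/CE/CBM/GT/AA followed by digits); locus-specific labels pass
  through.
- Empty input partitions, empty candidate lists and zero-denominator
  metrics are all defined, non-raising cases.
- External tools are optional adapters (prodigal for gene calling,
  hmmscan for scanning) behind narrow file-in/record-out contracts; the
  default test suite never invokes them, and their absence produces
  actionable errors naming the bypass (`--gff`/`--proteins`, `--hits`).

## Problem sizes

The test and acceptance workloads use genomes of a few dozen genes and
position vectors of n ≤ 50 with 1,000 random trials, 280 planted-locus
genomes (7 models × 4 modes × 10 seeds) and a 28-strain evaluation
example; the full suite completes in well under a minute.

## Known limitations

- The shipped models are reconstructions; per-gene core flags beyond the
  anchored families are editorial choices, and prediction quality on real
  genomes is bounded by model fidelity and HMM quality.
- Growth is a boolean on locus completeness; partial loci never yield
  probabilistic calls.
- No susC/susD tandem-pair heuristic, no regulator-based boundary
  refinement, no metagenomic (fragmented-assembly) mode.
- The prodigal adapter passes files through untouched; prodigal's GFF ID
  and FASTA header conventions may require harmonization upstream for
  some versions.
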