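"""Compare CAZyme annotation methods and build a 2-of-3 consensus.

Two annotation sources (say, a manually curated database and an automated
pipeline) are compared gene-by-gene at the family level after collapsing
subfamily labels (GH43_1 -> GH43); a third algorithm joins for the
majority-consensus call: a (gene, family) pair is accepted when at least
two of the three algorithms report it.
"""

from pulscan import (
    AnnotationSet,
    compare_annotations,
    gh_richness,
    majority_consensus,
)

curated = AnnotationSet.from_pairs(
    [("g1", "GH32"), ("g2", "GH43_1"), ("g3", "GH13"), ("g4", "PL15")],
    "curated",
)
automated = AnnotationSet.from_pairs(
    [("g1", "GH32"), ("g2", "GH43"), ("g5", "GH99")], "automated"
)
peptide = AnnotationSet.from_pairs(
    [("g1", "GH32"), ("g2", "GH43"), ("g3", "GH13")], "peptide"
)

a, b, c = (s.normalized() for s in (curated, automated, peptide))

venn = compare_annotations(a, b)
print(
    f"curated vs automated: {venn.both} shared pairs, "
    f"{venn.only_a} curated-only, {venn.only_b} automated-only "
    f"(union {venn.union})"
)

consensus = majority_consensus([a, b, c])
print(f"2-of-3 consensus: {sorted(consensus.pairs())}")

genes, families = gh_richness(consensus)
print(f"consensus GH richness: {genes} GH gene annotations, {families} families")
print(
    "\nSubfamily normalization makes g2's GH43_1 and GH43 agree; g4/g5 "
    "are single-\nmethod calls and drop out of the consensus."
)
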