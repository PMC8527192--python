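"""CAZyme annotation evidence: HMM domain hits, multi-algorithm consensus,
subfamily normalization and annotation-set comparison.

Annotation pipelines for carbohydrate-active enzymes typically combine
several algorithms (profile HMM search, sequence alignment, short-peptide
recognition). This module holds the per-domain hit record produced by an
HMMER3 scan, the two-of-three majority-consensus rule used to call a gene a
CAZyme, family-level normalization of subfamily labels (GH43_1 -> GH43), and
set arithmetic for comparing two annotation methods gene-by-gene.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping, Sequence

from .errors import ParseError

# HMMER3 per-domain tabular output ("domtblout") fixed column order:
# 0 target name, 1 target accession, 2 tlen, 3 query name, 4 query accession,
# 5 qlen, 6 full-seq E-value, 7 full-seq score, 8 full-seq bias, 9 dom #,
# 10 dom total, 11 c-Evalue, 12 i-Evalue, 13 dom score, 14 dom bias,
# 15-16 hmm from/to, 17-18 ali from/to, 19-20 env from/to, 21 acc,
# 22+ description of target.
_DOMTBL_MIN_COLS = 23


@dataclass(frozen=True)
class DomainHit:
    """One profile-HMM-vs-protein domain match.

    ``e_value`` is the per-domain independent E-value (i-Evalue);
    ``ali_from``/``ali_to`` are 1-based inclusive positions on the protein.
    ``source`` tags the producing algorithm (``"hmm"``, ``"alignment"``,
    ``"peptide"`` ...).
    """

    gene_id: str
    family_label: str
    e_value: float
    bit_score: float
    ali_from: int
    ali_to: int
    source: str = "hmm"

    def __post_init__(self):
        if self.e_value < 0:
            raise ValueError(f"e_value must be >= 0, got {self.e_value}")
        if self.ali_from > self.ali_to:
            raise ValueError(
                f"ali_from ({self.ali_from}) > ali_to ({self.ali_to})"
            )


def parse_domtblout(source: str | Path | IO[str]) -> list[DomainHit]:
    """Parse an HMMER3 per-domain table (hmmscan ``--domtblout``).

    In hmmscan orientation the *target* is the profile (family) and the
    *query* is the protein/gene. Comment lines (``#``) are skipped. Raises
    :class:`ParseError` with the line number on short rows, unparseable
    numeric fields, or inverted alignment coordinates.
    """
    if isinstance(source, (str, Path)):
        with open(source) as handle:
            return parse_domtblout(handle)
    hits: list[DomainHit] = []
    for lineno, line in enumerate(source, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split()
        if len(cols) < _DOMTBL_MIN_COLS:
            raise ParseError(
                f"expected >= {_DOMTBL_MIN_COLS} columns, found {len(cols)}",
                line_number=lineno,
            )
        try:
            e_value = float(cols[12])
            bit_score = float(cols[13])
            ali_from = int(cols[17])
            ali_to = int(cols[18])
        except ValueError as exc:
            raise ParseError(f"unparseable numeric field: {exc}", lineno)
        try:
            hits.append(
                DomainHit(
                    gene_id=cols[3],
                    family_label=cols[0],
                    e_value=e_value,
                    bit_score=bit_score,
                    ali_from=ali_from,
                    ali_to=ali_to,
                    source="hmm",
                )
            )
        except ValueError as exc:
            raise ParseError(str(exc), lineno)
    return hits


def write_domtblout(hits: Iterable[DomainHit], path: str | Path,
                    protein_lengths: Mapping[str, int] | None = None) -> None:
    """Write hits as an HMMER3-dialect per-domain table.

    Only the fields the package consumes are meaningful; the remaining
    columns are filled with plausible placeholders so that standard
    domtblout readers accept the file.
    """
    protein_lengths = protein_lengths or {}
    lines = [
        "#                                                               "
        "--- full sequence --- -------------- this domain -------------   "
        "hmm coord   ali coord   env coord",
        "# target name        accession   tlen query name           "
        "accession   qlen   E-value  score  bias   #  of  c-Evalue  "
        "i-Evalue  score  bias  from    to  from    to  from    to  acc "
        "description of target",
        "#------------------- ---------- ----- -------------------- "
        "---------- ----- --------- ------ ----- --- --- --------- "
        "--------- ------ ----- ----- ----- ----- ----- ----- ----- ---- "
        "---------------------",
    ]
    for h in hits:
        qlen = protein_lengths.get(h.gene_id, h.ali_to)
        lines.append(
            f"{h.family_label:<20} -          {h.ali_to - h.ali_from + 1:>5} "
            f"{h.gene_id:<20} -          {qlen:>5} {h.e_value:>9.3g} "
            f"{h.bit_score:>6.1f}   0.0   1   1 {h.e_value:>9.3g} "
            f"{h.e_value:>9.3g} {h.bit_score:>6.1f}   0.0     1 "
            f"{h.ali_to - h.ali_from + 1:>5} {h.ali_from:>5} {h.ali_to:>5} "
            f"{h.ali_from:>5} {h.ali_to:>5} 0.99 -"
        )
    Path(path).write_text("\n".join(lines) + "\n")


class AnnotationSet:
    """A gene -> set-of-family-labels mapping from one annotation method."""

    def __init__(self, families: Mapping[str, Iterable[str]], provenance: str):
        cleaned: dict[str, frozenset[str]] = {}
        for gene, fams in families.items():
            fams = frozenset(fams)
            if not fams:
                raise ValueError(
                    f"gene '{gene}' has an empty family set in '{provenance}'"
                )
            cleaned[gene] = fams
        self.families: dict[str, frozenset[str]] = cleaned
        self.provenance = provenance

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]],
                   provenance: str) -> "AnnotationSet":
        mapping: dict[str, set[str]] = {}
        for gene, fam in pairs:
            mapping.setdefault(gene, set()).add(fam)
        return cls(mapping, provenance)

    @classmethod
    def from_hits(cls, hits: Iterable[DomainHit],
                  provenance: str) -> "AnnotationSet":
        return cls.from_pairs(
            ((h.gene_id, h.family_label) for h in hits), provenance
        )

    def pairs(self) -> frozenset[tuple[str, str]]:
        return frozenset(
            (g, f) for g, fams in self.families.items() for f in fams
        )

    def normalized(self) -> "AnnotationSet":
        """Collapse subfamily labels to the family level (GH43_1 -> GH43)."""
        return AnnotationSet.from_pairs(
            ((g, normalize_family(f)) for g, f in self.pairs()),
            provenance=self.provenance,
        )

    def __len__(self) -> int:
        return len(self.pairs())

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, AnnotationSet)
            and self.families == other.families
        )

    def __repr__(self) -> str:
        return (
            f"AnnotationSet({len(self.families)} genes, "
            f"{len(self)} pairs, provenance={self.provenance!r})"
        )


@dataclass(frozen=True)
class VennCounts:
    """Pairwise overlap of two annotation sets over (gene, family) pairs."""

    both: int
    only_a: int
    only_b: int

    @property
    def union(self) -> int:
        return self.both + self.only_a + self.only_b


_SUBFAMILY_RE = re.compile(r"^(?:GH|PL|CE|GT|AA|CBM)\d+_\d+$")


def normalize_family(label: str) -> str:
    """Strip a trailing subfamily suffix from a CAZy family label.

    ``GH43_1`` becomes ``GH43``; labels without a subfamily suffix, and
    non-CAZy labels such as ``susC-like``, are returned unchanged. The
    operation is idempotent.
    """
    if not label:
        raise ValueError("family label must be non-empty")
    if _SUBFAMILY_RE.match(label):
        return label.rsplit("_", 1)[0]
    return label


def majority_consensus(sets: Sequence[AnnotationSet]) -> AnnotationSet:
    """Two-of-three consensus over per-algorithm annotation sets.

    A (gene, family) pair is kept iff at least two of the three input sets
    contain it. Applied at pair granularity because one gene may carry
    several CAZyme modules.
    """
    if len(sets) != 3:
        raise ValueError(
            f"majority consensus requires exactly 3 annotation sets, "
            f"got {len(sets)}"
        )
    tags = [s.provenance for s in sets]
    if len(set(tags)) != 3:
        raise ValueError(f"annotation-set tags must be distinct, got {tags}")
    counts: dict[tuple[str, str], int] = {}
    for s in sets:
        for pair in s.pairs():
            counts[pair] = counts.get(pair, 0) + 1
    kept = [pair for pair, n in counts.items() if n >= 2]
    return AnnotationSet.from_pairs(
        kept, provenance="consensus(" + "+".join(sorted(tags)) + ")"
    )


def compare_annotations(a: AnnotationSet, b: AnnotationSet) -> VennCounts:
    """Venn counts of two annotation sets over distinct (gene, family) pairs."""
    pa, pb = a.pairs(), b.pairs()
    return VennCounts(
        both=len(pa & pb), only_a=len(pa - pb), only_b=len(pb - pa)
    )


def gh_richness(a: AnnotationSet) -> tuple[int, int]:
    """(total GH gene-annotation count, distinct GH family count).

    Counted over (gene, family) pairs restricted to labels beginning
    ``GH`` — a gene annotated with two different GH families contributes
    two to the total.
    """
    gh_pairs = [(g, f) for g, f in a.pairs() if f.startswith("GH")]
    return len(gh_pairs), len({f for _, f in gh_pairs})


def read_hit_table(path: str | Path, provenance: str | None = None) -> AnnotationSet:
    """Read a 3-column TSV (gene_id, family_label, source) into an AnnotationSet."""
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    tag = provenance
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if lineno == 1 and cols[0].lower() in ("gene_id", "gene"):
                continue  # header
            if len(cols) < 2:
                raise ParseError(
                    f"expected >= 2 tab-separated columns, found {len(cols)}",
                    lineno,
                )
            pairs.append((cols[0], cols[1]))
            if tag is None and len(cols) >= 3:
                tag = cols[2]
    return AnnotationSet.from_pairs(pairs, provenance=tag or str(path))


def write_hit_table(aset: AnnotationSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tfamily_label\tsource\n")
        for gene, fam in sorted(aset.pairs()):
            fh.write(f"{gene}\t{fam}\t{aset.provenance}\n")
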