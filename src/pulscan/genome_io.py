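"""Genome input/output: gene coordinates (GFF3) and protein sequences (FASTA).

The pipeline consumes a *gene-annotated* genome: CDS coordinates from a GFF3
file plus the corresponding amino-acid sequences. All coordinates follow the
GFF3 convention (1-based, inclusive) throughout the package — no half-open
conversion anywhere.

External tools (a gene caller for raw nucleotide FASTA input, a profile-HMM
scanner for hit generation) plug in behind narrow adapter contracts and are
never required: precomputed GFF+FASTA and domtblout files are first-class
inputs.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Protocol

import gffutils
from Bio import SeqIO

from . import annotation
from .annotation import DomainHit
from .errors import AdapterMissingError, InputError, PulscanWarning

_AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY" + "X*")


@dataclass(frozen=True, order=True)
class GeneRecord:
    """One called gene: contig, 1-based inclusive coordinates, strand."""

    contig_id: str
    start: int
    end: int
    strand: str
    gene_id: str
    protein_id: str

    def __post_init__(self):
        if self.start > self.end:
            raise InputError(
                f"gene '{self.gene_id}': start ({self.start}) > end "
                f"({self.end})"
            )
        if self.strand not in ("+", "-"):
            raise InputError(
                f"gene '{self.gene_id}': strand must be '+' or '-', "
                f"got {self.strand!r}"
            )

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass
class GenomeBundle:
    """Genes plus their protein sequences for one genome."""

    genes: tuple[GeneRecord, ...]
    proteins: dict[str, str]
    source_label: str = ""

    def __post_init__(self):
        self.genes = tuple(
            sorted(self.genes, key=lambda g: (g.contig_id, g.start, g.end))
        )
        self._validate()

    def _validate(self) -> None:
        seen_ids: set[str] = set()
        seen_loci: set[tuple[str, int, int, str]] = set()
        missing: list[str] = []
        for g in self.genes:
            if g.gene_id in seen_ids:
                raise InputError(f"duplicate gene_id '{g.gene_id}'")
            seen_ids.add(g.gene_id)
            locus = (g.contig_id, g.start, g.end, g.strand)
            if locus in seen_loci:
                raise InputError(
                    f"two genes share locus {locus} on contig "
                    f"'{g.contig_id}'"
                )
            seen_loci.add(locus)
            if g.protein_id not in self.proteins:
                missing.append(g.protein_id)
        if missing:
            raise InputError(
                "gene(s) without a protein sequence: "
                + ", ".join(sorted(missing))
            )
        for pid, seq in self.proteins.items():
            bad = set(seq.upper()) - _AA_ALPHABET
            if bad:
                raise InputError(
                    f"protein '{pid}' contains non-amino-acid "
                    f"characters {sorted(bad)}"
                )

    def gene(self, gene_id: str) -> GeneRecord:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def by_contig(self) -> dict[str, list[GeneRecord]]:
        out: dict[str, list[GeneRecord]] = {}
        for g in self.genes:
            out.setdefault(g.contig_id, []).append(g)
        return out

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GenomeBundle)
            and self.genes == other.genes
            and self.proteins == other.proteins
        )


def read_gff_and_proteins(
    gff: str | Path,
    faa: str | Path,
    source_label: str | None = None,
) -> GenomeBundle:
    """Build a :class:`GenomeBundle` from a GFF3 file and a protein FASTA.

    Only ``CDS`` features are used; each must carry an ``ID`` attribute whose
    value matches the first token of a FASTA header. Unreferenced FASTA
    sequences trigger a :class:`PulscanWarning` and are dropped; referenced
    but absent sequences are an error.
    """
    gff, faa = Path(gff), Path(faa)
    proteins = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(faa), "fasta")}
    genes: list[GeneRecord] = []
    for feat in gffutils.DataIterator(str(gff)):
        if feat.featuretype != "CDS":
            continue
        ids = feat.attributes.get("ID")
        if not ids:
            raise InputError(
                f"{gff}: CDS at {feat.seqid}:{feat.start}-{feat.end} has "
                "no ID attribute"
            )
        gene_id = ids[0]
        genes.append(
            GeneRecord(
                contig_id=feat.seqid,
                start=int(feat.start),
                end=int(feat.end),
                strand=feat.strand,
                gene_id=gene_id,
                protein_id=gene_id,
            )
        )
    referenced = {g.protein_id for g in genes}
    missing = sorted(referenced - set(proteins))
    if missing:
        raise InputError(
            f"{faa}: no protein sequence for gene ID(s): " + ", ".join(missing)
        )
    extra = sorted(set(proteins) - referenced)
    if extra:
        warnings.warn(
            f"{faa}: {len(extra)} unreferenced protein sequence(s) ignored: "
            + ", ".join(extra[:5]) + ("..." if len(extra) > 5 else ""),
            PulscanWarning,
            stacklevel=2,
        )
        proteins = {k: v for k, v in proteins.items() if k in referenced}
    return GenomeBundle(
        genes=tuple(genes),
        proteins=proteins,
        source_label=source_label or gff.stem,
    )


def write_gff(bundle: GenomeBundle, path: str | Path) -> None:
    """Write the bundle's genes as GFF3 CDS features (round-trips)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in bundle.genes:
            fh.write(
                f"{g.contig_id}\tpulscan\tCDS\t{g.start}\t{g.end}\t.\t"
                f"{g.strand}\t0\tID={g.gene_id}\n"
            )


def write_proteins(bundle: GenomeBundle, path: str | Path) -> None:
    """Write the bundle's protein sequences as FASTA (60-column wrap)."""
    with open(path, "w") as fh:
        for pid in sorted(bundle.proteins):
            seq = bundle.proteins[pid]
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


class GeneCallerAdapter(Protocol):
    """Contract for external gene callers: nucleotide FASTA in, files out."""

    def call(self, genome_fasta: Path, workdir: Path) -> tuple[Path, Path]:
        """Run the caller; return (gff_path, protein_faa_path)."""
        ...


class ProdigalAdapter:
    """Adapter around the ``prodigal`` gene caller executable.

    ``mode`` is passed through to prodigal's ``-p`` flag when given
    (``"single"`` or ``"meta"``); no default is imposed.
    """

    def __init__(self, executable: str = "prodigal", mode: str | None = None):
        self.executable = executable
        self.mode = mode

    def available(self) -> bool:
        return shutil.which(self.executable) is not None

    def call(self, genome_fasta: Path, workdir: Path) -> tuple[Path, Path]:
        if not self.available():
            raise AdapterMissingError(
                f"gene caller '{self.executable}' not found on PATH; "
                "provide a GFF3 file and protein FASTA instead "
                "(--gff/--proteins)"
            )
        gff = workdir / "genes.gff"
        faa = workdir / "proteins.faa"
        cmd = [
            self.executable, "-i", str(genome_fasta), "-f", "gff",
            "-o", str(gff), "-a", str(faa),
        ]
        if self.mode:
            cmd += ["-p", self.mode]
        proc = subprocess.run(cmd, capture_output=True, text=True)
        if proc.returncode != 0:
            raise InputError(
                f"gene caller failed (exit {proc.returncode}): {proc.stderr}"
            )
        return gff, faa


def call_genes_external(
    genome_fasta: str | Path,
    tool: GeneCallerAdapter | None = None,
    workdir: str | Path | None = None,
) -> GenomeBundle:
    """Predict genes on a raw nucleotide FASTA via an external caller.

    Entirely optional: when precomputed GFF+proteins exist, use
    :func:`read_gff_and_proteins` directly.
    """
    tool = tool or ProdigalAdapter()
    workdir = Path(workdir) if workdir else Path(tempfile.mkdtemp(prefix="pulscan_"))
    gff, faa = tool.call(Path(genome_fasta), workdir)
    return read_gff_and_proteins(gff, faa, source_label=Path(genome_fasta).stem)


class ScannerAdapter(Protocol):
    """Contract for external profile-HMM scanners."""

    def scan(self, faa: Path, hmm_db: Path, workdir: Path) -> Path:
        """Run the scanner; return the per-domain table (domtblout) path."""
        ...


class HmmscanAdapter:
    """Adapter around the ``hmmscan`` executable (HMMER3)."""

    def __init__(self, executable: str = "hmmscan"):
        self.executable = executable

    def available(self) -> bool:
        return shutil.which(self.executable) is not None

    def scan(self, faa: Path, hmm_db: Path, workdir: Path) -> Path:
        if not self.available():
            raise AdapterMissingError(
                f"scanner '{self.executable}' not found on PATH; supply a "
                "precomputed per-domain table with --hits instead"
            )
        out = workdir / "hits.domtblout"
        proc = subprocess.run(
            [self.executable, "--domtblout", str(out), str(hmm_db), str(faa)],
            capture_output=True, text=True,
        )
        if proc.returncode != 0:
            raise InputError(
                f"scanner failed (exit {proc.returncode}): {proc.stderr}"
            )
        return out


def scan_proteins_external(
    bundle: GenomeBundle,
    hmm_db: str | Path,
    tool: ScannerAdapter | None = None,
    workdir: str | Path | None = None,
) -> list[DomainHit]:
    """Scan the bundle's proteins against a profile database.

    Optional: a precomputed domtblout parsed with
    :func:`pulscan.annotation.parse_domtblout` is the equivalent bypass.
    Returns an empty list for an empty protein set without invoking the tool.
    """
    if not bundle.proteins:
        return []
    tool = tool or HmmscanAdapter()
    workdir = Path(workdir) if workdir else Path(tempfile.mkdtemp(prefix="pulscan_"))
    faa = workdir / "proteins.faa"
    write_proteins(bundle, faa)
    table = tool.scan(faa, Path(hmm_db), workdir)
    return annotation.parse_domtblout(table)
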