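"""Seeded synthetic genomes, hit tables and growth matrices with planted
polysaccharide utilization loci.

The generator emulates the pipeline's detection scenarios so every stage is
testable without external data or tools:

``complete``
    every core slot of the model planted at its required distinct-gene copy
    count (plus one gene per accessory slot), intergenic gaps sampled well
    below the clustering threshold — ground truth: growth.
``missing_core``
    as ``complete`` but with exactly one core slot omitted entirely —
    truth: no growth.
``split_gap``
    as ``complete`` but with one gap >= ``split_gap_bp`` (default 12 kb)
    inserted inside the core gene run, splitting it into two incomplete
    clusters — truth: no growth.
``decoy_only``
    accessory-family hits scattered along the contig, no core families —
    truth: no growth.

Planted contigs also carry interleaved unannotated genes (the clustering
must tolerate them), and background contigs carry hit-free genes at roughly
prodigal-like density (~1 gene/kb). Protein sequences are random amino-acid
strings; hits are emitted directly with E-values <= 1e-10 rather than via a
real profile search, keeping the suite hermetic. All outputs are pure
functions of (spec, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotation import DomainHit, write_domtblout
from .errors import InputError
from .genome_io import GeneRecord, GenomeBundle, write_gff, write_proteins
from .growth import GrowthMatrix
from .models import PULModel

MODES = ("complete", "missing_core", "split_gap", "decoy_only")

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass
class PlantSpec:
    """Recipe for one contig bearing a planted locus scenario."""

    model: PULModel
    mode: str = "complete"
    intergenic_gap_bp: tuple[int, int] = (200, 2000)
    split_gap_bp: int = 12000
    seed: int | None = None

    def __post_init__(self):
        if self.mode not in MODES:
            raise InputError(
                f"mode must be one of {MODES}, got {self.mode!r}"
            )
        lo, hi = self.intergenic_gap_bp
        if lo <= 0 or hi < lo:
            raise InputError(
                f"intergenic gap range must be positive, got "
                f"{self.intergenic_gap_bp}"
            )
        if self.split_gap_bp < self.model.gap_threshold_bp:
            raise InputError(
                f"split_gap_bp ({self.split_gap_bp}) must be >= the model "
                f"gap threshold ({self.model.gap_threshold_bp})"
            )


def _random_protein(rng: np.random.Generator, lo: int, hi: int) -> str:
    n = int(rng.integers(lo, hi + 1))
    return "".join(rng.choice(_AA, size=n))


def _emit_hit(
    rng: np.random.Generator, gene_id: str, hmm_id: str, protein_len: int
) -> DomainHit:
    # exact powers of ten survive text round-trips bit-identically
    e_value = float(f"1e-{int(rng.integers(10, 50))}")
    bit_score = round(float(rng.uniform(50, 500)), 1)
    ali_from = int(rng.integers(1, 10))
    ali_to = min(protein_len, ali_from + int(rng.integers(50, 90)))
    return DomainHit(
        gene_id=gene_id,
        family_label=hmm_id,
        e_value=e_value,
        bit_score=bit_score,
        ali_from=ali_from,
        ali_to=ali_to,
        source="hmm",
    )


def _planted_slot_sequence(
    spec: PlantSpec, rng: np.random.Generator
) -> tuple[list, int | None]:
    """Ordered list of slot assignments and the core index after which the
    split gap goes (None unless mode == split_gap)."""
    model = spec.model
    core_genes = [
        slot for slot in model.core_slots for _ in range(slot.min_copies)
    ]
    accessory = [s for s in model.slots if not s.is_core]
    if spec.mode == "decoy_only":
        return list(accessory), None
    if spec.mode == "missing_core":
        dropped = model.core_slots[int(rng.integers(len(model.core_slots)))]
        core_genes = [s for s in core_genes if s is not dropped]
        return core_genes + accessory, None
    if spec.mode == "split_gap":
        # a split strictly inside the core run leaves each side short of at
        # least one core requirement (exactly min_copies are planted)
        k = int(rng.integers(1, len(core_genes)))
        return core_genes + accessory, k
    return core_genes + accessory, None


def make_genome(
    specs: Sequence[PlantSpec],
    n_background_genes: int = 30,
    seed: int = 0,
) -> tuple[GenomeBundle, list[DomainHit], dict[str, bool]]:
    """Build one synthetic genome: one contig per spec + background contigs.

    Returns the genome bundle, the emitted domain hits, and ground-truth
    growth labels per planted fiber (True only for ``complete`` plants).
    Deterministic in (specs, seed): same inputs give identical objects.
    """
    rng = np.random.default_rng(seed)
    genes: list[GeneRecord] = []
    proteins: dict[str, str] = {}
    hits: list[DomainHit] = []
    truth: dict[str, bool] = {}

    for i, spec in enumerate(specs):
        sub_rng = (
            np.random.default_rng(spec.seed)
            if spec.seed is not None
            else rng
        )
        contig = f"ctg_{spec.model.fiber_name}_{spec.mode}_{i}"
        slots, split_after = _planted_slot_sequence(spec, sub_rng)
        lo_gap, hi_gap = spec.intergenic_gap_bp
        pos = int(sub_rng.integers(500, 5000))
        core_seen = 0
        for j, slot in enumerate(slots):
            # short proteins + tight gaps keep start-to-start distances of
            # consecutive planted genes below the clustering threshold
            protein = _random_protein(sub_rng, 100, 250)
            gene_len = 3 * len(protein) + 3
            gid = f"{contig}_g{j:02d}"
            strand = "+" if sub_rng.random() < 0.8 else "-"
            genes.append(
                GeneRecord(contig, pos, pos + gene_len - 1, strand, gid, gid)
            )
            proteins[gid] = protein
            hits.append(_emit_hit(sub_rng, gid, slot.hmm_id, len(protein)))
            pos += gene_len
            if slot.is_core:
                core_seen += 1
            if split_after is not None and core_seen == split_after and slot.is_core:
                pos += spec.split_gap_bp + int(sub_rng.integers(0, 3000))
                core_seen = -len(slots)  # insert the big gap only once
            elif sub_rng.random() < 0.3:
                # interleave an unannotated gene without breaking the cluster
                upr = _random_protein(sub_rng, 100, 250)
                ulen = 3 * len(upr) + 3
                ugid = f"{contig}_u{j:02d}"
                pos += int(sub_rng.integers(100, 400))
                genes.append(
                    GeneRecord(contig, pos, pos + ulen - 1, "+", ugid, ugid)
                )
                proteins[ugid] = upr
                pos += ulen + int(sub_rng.integers(100, 400))
            else:
                pos += int(sub_rng.integers(lo_gap, hi_gap + 1))
        grew = spec.mode == "complete"
        truth[spec.model.fiber_name] = truth.get(spec.model.fiber_name, False) or grew

    if n_background_genes > 0:
        contig = "ctg_background"
        pos = int(rng.integers(500, 2000))
        for j in range(n_background_genes):
            protein = _random_protein(rng, 150, 250)
            gene_len = 3 * len(protein) + 3
            gid = f"{contig}_g{j:03d}"
            genes.append(
                GeneRecord(contig, pos, pos + gene_len - 1, "+", gid, gid)
            )
            proteins[gid] = protein
            pos += gene_len + int(rng.integers(200, 600))

    bundle = GenomeBundle(
        genes=tuple(genes), proteins=proteins, source_label=f"synthetic_seed{seed}"
    )
    return bundle, hits, truth


def make_growth_table(
    truth: pd.DataFrame,
    noise_sd: float = 0.0,
    seed: int = 0,
    grower_level: float = 0.2,
) -> GrowthMatrix:
    """Normalized-growth matrix from boolean truth labels.

    ``truth`` is a strains x fibers boolean DataFrame. Growers sit at
    ``grower_level`` (well above the 0.01 binarization threshold),
    non-growers at 0, plus Gaussian noise of standard deviation
    ``noise_sd``. With ``noise_sd = 0`` binarization recovers the truth
    exactly.
    """
    if noise_sd < 0:
        raise InputError(f"noise_sd must be >= 0, got {noise_sd}")
    rng = np.random.default_rng(seed)
    base = truth.astype(float) * grower_level
    noise = rng.normal(0.0, noise_sd, size=base.shape) if noise_sd else 0.0
    return GrowthMatrix(base + noise)


def write_fixture(
    outdir: str | Path,
    bundle: GenomeBundle,
    hits: Iterable[DomainHit],
    truth: dict[str, bool],
    growth: GrowthMatrix | None = None,
) -> dict[str, Path]:
    """Write a fixture directory: GFF3, protein FASTA, domtblout, truth JSON
    and (optionally) a growth TSV. Output bytes depend only on the inputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "gff": outdir / "genes.gff",
        "faa": outdir / "proteins.faa",
        "domtblout": outdir / "hits.domtblout",
        "truth": outdir / "truth.json",
    }
    write_gff(bundle, paths["gff"])
    write_proteins(bundle, paths["faa"])
    write_domtblout(
        hits, paths["domtblout"],
        protein_lengths={k: len(v) for k, v in bundle.proteins.items()},
    )
    paths["truth"].write_text(
        json.dumps(dict(sorted(truth.items())), indent=2) + "\n"
    )
    if growth is not None:
        paths["growth"] = outdir / "growth.tsv"
        growth.to_tsv(paths["growth"])
    return paths
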