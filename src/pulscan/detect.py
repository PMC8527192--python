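"""Core PUL detection: hit filtering, 1-D spatial clustering, candidate
scoring and per-fiber growth calls.

The algorithm: genes carrying a profile hit against any family slot of the
active fiber model are clustered along each contig by single-linkage
hierarchical clustering on gene position with the dendrogram cut at the
model's gap threshold (default 5 kb). In one dimension this is exactly the
partition of sorted positions split at every adjacent gap >= the threshold
(a gap strictly below the threshold merges; an exact-threshold gap splits).
Unannotated genes lying between hit genes neither block nor join a cluster.
Each cluster becomes a candidate locus scored for completeness against the
model's core slots; a genome is called growth-positive for a fiber iff some
candidate carries every required core family at its required distinct-gene
copy count. Candidate span is unbounded — only inter-gene gaps matter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

from .annotation import DomainHit
from .errors import InputError
from .genome_io import GeneRecord, GenomeBundle
from .models import PULModel

DEFAULT_EVALUE_MAX = 1e-5

PositionMode = Literal["start", "midpoint"]


@dataclass(frozen=True)
class AssignedGene:
    """A gene with at least one accepted hit against the active model."""

    gene: GeneRecord
    families: frozenset[str]
    best_e_value: dict[str, float] = field(compare=False, default_factory=dict)

    def __post_init__(self):
        if not self.families:
            raise ValueError(
                f"AssignedGene '{self.gene.gene_id}' has no families"
            )


@dataclass
class PULCandidate:
    """A detected spatial cluster of model-family genes on one contig."""

    fiber_name: str
    contig_id: str
    members: tuple[AssignedGene, ...]
    core_complete: bool
    completeness: float

    def __post_init__(self):
        self.members = tuple(
            sorted(self.members, key=lambda m: m.gene.start)
        )

    @property
    def span_bp(self) -> int:
        return self.members[-1].gene.end - self.members[0].gene.start + 1

    @property
    def start(self) -> int:
        return self.members[0].gene.start

    @property
    def families_present(self) -> list[str]:
        """Multiset of matched family labels over member genes."""
        out: list[str] = []
        for m in self.members:
            out.extend(sorted(m.families))
        return out

    @property
    def n_distinct_families(self) -> int:
        return len(set().union(*(m.families for m in self.members)))

    def to_dict(self) -> dict:
        return {
            "fiber": self.fiber_name,
            "contig": self.contig_id,
            "start": self.start,
            "end": self.members[-1].gene.end,
            "span_bp": self.span_bp,
            "core_complete": self.core_complete,
            "completeness": self.completeness,
            "members": [
                {
                    "gene_id": m.gene.gene_id,
                    "start": m.gene.start,
                    "end": m.gene.end,
                    "strand": m.gene.strand,
                    "families": sorted(m.families),
                    "best_e_value": {
                        k: m.best_e_value[k] for k in sorted(m.best_e_value)
                    },
                }
                for m in self.members
            ],
        }


@dataclass
class Prediction:
    """Per-fiber growth call with its supporting evidence."""

    fiber_name: str
    growth: bool
    supporting_candidate: PULCandidate | None
    all_candidates: list[PULCandidate]


def assign_hits(
    hits: Iterable[DomainHit],
    bundle: GenomeBundle,
    model: PULModel,
    e_value_max: float = DEFAULT_EVALUE_MAX,
) -> list[AssignedGene]:
    """Keep hits matching a model slot at or below the E-value cutoff.

    Returns one :class:`AssignedGene` per gene with >= 1 surviving hit,
    recording each matched family's best (lowest) E-value.
    """
    model_hmms = set(model.hmm_ids)
    per_gene: dict[str, dict[str, float]] = {}
    for h in hits:
        if h.family_label not in model_hmms or h.e_value > e_value_max:
            continue
        try:
            bundle.gene(h.gene_id)
        except KeyError:
            raise InputError(
                f"hit references unknown gene_id '{h.gene_id}'"
            ) from None
        best = per_gene.setdefault(h.gene_id, {})
        if h.family_label not in best or h.e_value < best[h.family_label]:
            best[h.family_label] = h.e_value
    out = [
        AssignedGene(
            gene=bundle.gene(gid),
            families=frozenset(best),
            best_e_value=dict(best),
        )
        for gid, best in per_gene.items()
    ]
    out.sort(key=lambda a: (a.gene.contig_id, a.gene.start))
    return out


def cluster_positions(
    positions: Sequence[float], cut_bp: int
) -> list[list[int]]:
    """1-D single-linkage clustering with the dendrogram cut at ``cut_bp``.

    Clusters merge while the linkage distance is strictly below ``cut_bp``;
    in one dimension this equals splitting the sorted positions at every
    adjacent gap >= ``cut_bp``. Returns a partition as lists of input
    indices; empty input yields an empty partition. Invariant under
    translation of all positions and permutation of the input order.
    """
    if cut_bp <= 0:
        raise ValueError(f"cut_bp must be positive, got {cut_bp}")
    n = len(positions)
    if n == 0:
        return []
    order = sorted(range(n), key=lambda i: positions[i])
    clusters: list[list[int]] = [[order[0]]]
    for prev, cur in zip(order, order[1:]):
        if positions[cur] - positions[prev] >= cut_bp:
            clusters.append([cur])
        else:
            clusters[-1].append(cur)
    return clusters


def _gene_position(gene: GeneRecord, mode: PositionMode) -> float:
    return float(gene.start) if mode == "start" else gene.midpoint


def _score_cluster(
    members: Sequence[AssignedGene], model: PULModel
) -> tuple[bool, float]:
    """Copy-aware core completeness of one cluster.

    Per core slot: min(distinct member genes matching the slot, min_copies)
    / min_copies, averaged over core slots. A gene matching several slots
    counts toward each, but one gene supplies at most one copy of any one
    slot (copy counting is over distinct genes).
    """
    core = model.core_slots
    if not core:
        return False, 0.0
    fractions = []
    for slot in core:
        n_genes = sum(1 for m in members if slot.hmm_id in m.families)
        fractions.append(min(n_genes, slot.min_copies) / slot.min_copies)
    completeness = sum(fractions) / len(fractions)
    return completeness == 1.0, completeness


def find_candidates(
    assigned: Sequence[AssignedGene],
    model: PULModel,
    position_mode: PositionMode = "start",
) -> list[PULCandidate]:
    """Cluster assigned genes per contig and score each cluster.

    Clustering runs on assigned genes only: intervening unannotated genes
    neither block nor join a cluster. Every cluster (even a singleton)
    becomes a candidate.
    """
    by_contig: dict[str, list[AssignedGene]] = {}
    for a in assigned:
        by_contig.setdefault(a.gene.contig_id, []).append(a)
    candidates: list[PULCandidate] = []
    for contig in sorted(by_contig):
        genes = by_contig[contig]
        positions = [_gene_position(a.gene, position_mode) for a in genes]
        for idx_cluster in cluster_positions(positions, model.gap_threshold_bp):
            members = tuple(genes[i] for i in idx_cluster)
            complete, completeness = _score_cluster(members, model)
            candidates.append(
                PULCandidate(
                    fiber_name=model.fiber_name,
                    contig_id=contig,
                    members=members,
                    core_complete=complete,
                    completeness=completeness,
                )
            )
    return candidates


def rank_candidates(candidates: Sequence[PULCandidate]) -> list[PULCandidate]:
    """Deterministic total order: most complete first.

    Sort key: completeness desc, distinct family count desc, span asc,
    leftmost start asc (contig id as final tie-break).
    """
    return sorted(
        candidates,
        key=lambda c: (
            -c.completeness,
            -c.n_distinct_families,
            c.span_bp,
            c.start,
            c.contig_id,
        ),
    )


def predict_growth(
    bundle: GenomeBundle,
    hits: Iterable[DomainHit],
    models: Sequence[PULModel],
    e_value_max: float = DEFAULT_EVALUE_MAX,
    position_mode: PositionMode = "start",
) -> list[Prediction]:
    """One growth call per fiber model.

    ``growth`` is true iff at least one candidate is core-complete; the
    supporting candidate is the top-ranked complete one. Accessory slots
    affect ranking and completeness only, never the growth boolean.
    """
    hits = list(hits)
    predictions: list[Prediction] = []
    for model in models:
        assigned = assign_hits(hits, bundle, model, e_value_max)
        candidates = rank_candidates(find_candidates(assigned, model, position_mode))
        complete = [c for c in candidates if c.core_complete]
        predictions.append(
            Prediction(
                fiber_name=model.fiber_name,
                growth=bool(complete),
                supporting_candidate=complete[0] if complete else None,
                all_candidates=candidates,
            )
        )
    return predictions


def predictions_to_rows(predictions: Sequence[Prediction]) -> list[dict]:
    """Flatten predictions to the per-fiber table written by the CLI."""
    rows = []
    for p in predictions:
        best = (
            rank_candidates(p.all_candidates)[0] if p.all_candidates else None
        )
        rows.append(
            {
                "fiber": p.fiber_name,
                "growth": int(p.growth),
                "n_candidates": len(p.all_candidates),
                "best_completeness": round(best.completeness, 4) if best else 0.0,
                "contig": best.contig_id if best else "",
                "span_bp": best.span_bp if best else 0,
            }
        )
    return rows
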