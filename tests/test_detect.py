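"""Core detection: hit assignment, 1-D clustering, candidate scoring,
growth calls."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pulscan import (
    DomainHit,
    GeneRecord,
    GenomeBundle,
    InputError,
    assign_hits,
    cluster_positions,
    find_candidates,
    get_model,
    predict_growth,
    rank_candidates,
)
from pulscan.detect import AssignedGene, PULCandidate

from conftest import canonical, naive_single_linkage


def hit(gene, family, e=1e-30):
    return DomainHit(gene, family, e, 100.0, 1, 50)


def make_bundle(loci):
    """loci: list of (contig, start, end, gene_id)."""
    genes = tuple(
        GeneRecord(c, s, e, "+", gid, gid) for c, s, e, gid in loci
    )
    return GenomeBundle(genes, {g.gene_id: "MKLV" * 30 for g in genes})


@pytest.fixture
def inulin(models_by_fiber):
    return models_by_fiber["inulin"]


class TestAssignHits:
    def test_no_hits(self, inulin):
        bundle = make_bundle([("c", 1, 300, "g1")])
        assert assign_hits([], bundle, inulin) == []

    def test_accepted_hit(self, inulin):
        bundle = make_bundle([("c", 1, 300, "g1")])
        (a,) = assign_hits([hit("g1", "GH32", 1e-30)], bundle, inulin, 1e-5)
        assert a.families == {"GH32"}
        assert a.best_e_value["GH32"] == 1e-30

    def test_weak_hit_filtered(self, inulin):
        bundle = make_bundle([("c", 1, 300, "g1")])
        assert assign_hits([hit("g1", "GH32", 1e-3)], bundle, inulin, 1e-5) == []

    def test_non_model_family_filtered(self, inulin):
        bundle = make_bundle([("c", 1, 300, "g1")])
        assert assign_hits([hit("g1", "PL99")], bundle, inulin) == []

    def test_unknown_gene_rejected(self, inulin):
        bundle = make_bundle([("c", 1, 300, "g1")])
        with pytest.raises(InputError, match="ghost"):
            assign_hits([hit("ghost", "GH32")], bundle, inulin)

    def test_best_e_value_kept_per_family(self, inulin):
        bundle = make_bundle([("c", 1, 300, "g1")])
        (a,) = assign_hits(
            [hit("g1", "GH32", 1e-10), hit("g1", "GH32", 1e-40)],
            bundle, inulin,
        )
        assert a.best_e_value["GH32"] == 1e-40


class TestClusterPositions:
    def test_empty(self):
        assert cluster_positions([], 5000) == []

    def test_singleton(self):
        assert cluster_positions([100], 5000) == [[0]]

    def test_two_clusters(self):
        # oracle: explicit naive single-linkage dendrogram construction
        pos = [1000, 3000, 9500]
        expect = canonical(naive_single_linkage(pos, 5000))
        assert canonical(cluster_positions(pos, 5000)) == expect
        assert expect == [(0, 1), (2,)]

    def test_chaining_across_successive_gaps(self):
        pos = [0, 4000, 8000, 16000]
        expect = canonical(naive_single_linkage(pos, 5000))
        assert canonical(cluster_positions(pos, 5000)) == expect
        assert expect == [(0, 1, 2), (3,)]

    def test_exact_threshold_gap_splits(self):
        assert canonical(cluster_positions([0, 5000], 5000)) == [(0,), (1,)]
        assert canonical(cluster_positions([0, 4999], 5000)) == [(0, 1)]

    @given(
        st.lists(st.integers(0, 200_000), min_size=1, max_size=50),
        st.integers(1, 20_000),
    )
    @settings(derandomize=True, max_examples=150)
    def test_equals_naive_single_linkage(self, pos, cut):
        assert canonical(cluster_positions(pos, cut)) == canonical(
            naive_single_linkage(pos, cut)
        )

    @given(
        st.lists(st.integers(0, 100_000), min_size=1, max_size=30),
        st.integers(1, 10_000),
        st.integers(-5000, 5000),
    )
    @settings(derandomize=True, max_examples=100)
    def test_translation_and_permutation_invariance(self, pos, cut, shift):
        base = canonical(cluster_positions(pos, cut))
        shifted = canonical(cluster_positions([p + shift for p in pos], cut))
        assert shifted == base
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(pos))
        permuted = cluster_positions([pos[i] for i in perm], cut)
        relabeled = canonical([[int(perm[i]) for i in c] for c in permuted])
        assert relabeled == base

    @given(
        st.lists(st.integers(0, 100_000), min_size=1, max_size=30),
        st.integers(1, 10_000),
        st.integers(1, 10_000),
    )
    @settings(derandomize=True, max_examples=100)
    def test_growing_cut_never_increases_cluster_count(self, pos, c1, c2):
        lo, hi = min(c1, c2), max(c1, c2)
        assert len(cluster_positions(pos, hi)) <= len(
            cluster_positions(pos, lo)
        )

    def test_scipy_linkage_cross_check(self):
        """Second independent oracle: scipy single linkage + fcluster."""
        from scipy.cluster.hierarchy import fcluster, linkage

        rng = np.random.default_rng(42)
        for _ in range(50):
            n = int(rng.integers(2, 40))
            pos = rng.integers(0, 100_000, size=n)
            cut = int(rng.integers(1, 20_000))
            Z = linkage(pos.reshape(-1, 1).astype(float), method="single")
            # strict "< cut merges": integer coordinates let t = cut - 0.5
            labels = fcluster(Z, t=cut - 0.5, criterion="distance")
            scipy_part = {}
            for i, lab in enumerate(labels):
                scipy_part.setdefault(lab, []).append(i)
            assert canonical(scipy_part.values()) == canonical(
                cluster_positions(list(pos), cut)
            )


def inulin_core_genes(start=1000, gap=1500):
    """Assigned-gene layout carrying all inulin core families in one run."""
    loci, fams = [], ["GH32", "SusC", "SusD"]
    pos = start
    out = []
    for i, fam in enumerate(fams):
        g = GeneRecord("c1", pos, pos + 900, "+", f"g{i}", f"g{i}")
        out.append(AssignedGene(g, frozenset({fam}), {fam: 1e-30}))
        pos += 900 + gap
    return out


class TestFindCandidates:
    def test_complete_neighborhood(self, inulin):
        cands = find_candidates(inulin_core_genes(), inulin)
        assert len(cands) == 1
        assert cands[0].core_complete
        assert cands[0].completeness == 1.0

    def test_missing_susc_incomplete(self, inulin):
        genes = [
            a for a in inulin_core_genes() if "SusC" not in a.families
        ]
        (c,) = find_candidates(genes, inulin)
        assert not c.core_complete
        assert c.completeness == pytest.approx(2 / 3)

    def test_split_by_12kb_gap(self, inulin):
        """Core run cut by a 12-kb gap: oracle = exhaustive window scan."""
        genes = inulin_core_genes()
        # move the third core gene 12 kb downstream
        far = genes[2]
        moved = AssignedGene(
            GeneRecord("c1", far.gene.start + 12_000,
                       far.gene.end + 12_000, "+", far.gene.gene_id,
                       far.gene.gene_id),
            far.families, far.best_e_value,
        )
        genes = genes[:2] + [moved]
        cands = find_candidates(genes, inulin)
        assert len(cands) == 2
        assert not any(c.core_complete for c in cands)
        # oracle: no contiguous window satisfying the gap rule has all cores
        starts = sorted(a.gene.start for a in genes)
        assert any(b - a >= 5000 for a, b in zip(starts, starts[1:]))

    def test_unannotated_genes_do_not_block(self, inulin):
        # assigned genes only are clustered; nothing else is passed in,
        # mirroring a locus interleaved with unannotated genes
        cands = find_candidates(inulin_core_genes(gap=3000), inulin)
        assert len(cands) == 1 and cands[0].core_complete

    def test_clusters_never_span_contigs(self, inulin):
        a, b, c = inulin_core_genes(gap=500)
        moved = AssignedGene(
            GeneRecord("c2", c.gene.start, c.gene.end, "+",
                       c.gene.gene_id, c.gene.gene_id),
            c.families, c.best_e_value,
        )
        cands = find_candidates([a, b, moved], inulin)
        assert {c.contig_id for c in cands} == {"c1", "c2"}
        assert not any(c.core_complete for c in cands)


def make_candidate(completeness, n_families, span, start, complete=False):
    genes = tuple(
        AssignedGene(
            GeneRecord("c", start + i * (span // max(n_families, 1)),
                       start + i * (span // max(n_families, 1)) + 10,
                       "+", f"m{start}_{i}", f"m{start}_{i}"),
            frozenset({f"F{i}"}), {f"F{i}": 1e-20},
        )
        for i in range(n_families)
    )
    c = PULCandidate("x", "c", genes, complete, completeness)
    return c


class TestRankCandidates:
    def test_complete_first(self):
        full = make_candidate(1.0, 3, 3000, 100, complete=True)
        half = make_candidate(0.5, 3, 3000, 9000)
        assert rank_candidates([half, full])[0] is full

    def test_span_tie_break(self):
        tight = make_candidate(0.5, 2, 6000, 100)
        loose = make_candidate(0.5, 2, 10_000, 100_000)
        assert rank_candidates([loose, tight])[0] is tight

    def test_empty(self):
        assert rank_candidates([]) == []


class TestPredictGrowth:
    def test_planted_complete_pul_detected(self, models_by_fiber):
        from pulscan import PlantSpec, make_genome

        model = models_by_fiber["inulin"]
        bundle, hits, truth = make_genome(
            [PlantSpec(model=model)], n_background_genes=10, seed=11
        )
        (pred,) = predict_growth(bundle, hits, [model])
        assert pred.growth is True
        assert pred.supporting_candidate.core_complete

    def test_absent_families_predict_no_growth(self, models_by_fiber):
        from pulscan import PlantSpec, make_genome

        bundle, hits, _ = make_genome(
            [PlantSpec(model=models_by_fiber["inulin"])],
            n_background_genes=5, seed=11,
        )
        (pred,) = predict_growth(bundle, hits, [models_by_fiber["heparin"]])
        assert pred.growth is False

    def test_levan_copy_count_enforced(self, models_by_fiber):
        """Two distinct GH32 genes cannot satisfy min_copies = 3."""
        levan = models_by_fiber["levan"]
        loci = [("c", 1000 + i * 2000, 1900 + i * 2000, f"g{i}") for i in range(3)]
        bundle = make_bundle(loci)
        hits = [
            hit("g0", "GH32"), hit("g1", "GH32"),  # only 2 distinct genes
            hit("g1", "GH32", 1e-50),  # second domain on the same gene
            hit("g2", "Levanase"),
        ]
        (pred,) = predict_growth(bundle, hits, [levan])
        assert pred.growth is False
        # direct multiset oracle: distinct GH32 genes = 2 < 3
        assert len({h.gene_id for h in hits if h.family_label == "GH32"}) == 2

    def test_adding_hits_never_flips_growth_off(self, models_by_fiber):
        from pulscan import PlantSpec, make_genome

        model = models_by_fiber["laminarin"]
        bundle, hits, _ = make_genome(
            [PlantSpec(model=model)], n_background_genes=5, seed=3
        )
        (before,) = predict_growth(bundle, hits, [model])
        extra = hits + [hit(bundle.genes[0].gene_id, "GH16", 1e-40)]
        (after,) = predict_growth(bundle, extra, [model])
        assert before.growth is True
        assert after.growth is True
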