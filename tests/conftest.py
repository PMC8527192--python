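import pytest

from pulscan import load_shipped_models


@pytest.fixture(scope="session")
def shipped_models():
    return load_shipped_models()


@pytest.fixture(scope="session")
def models_by_fiber(shipped_models):
    return {m.fiber_name: m for m in shipped_models}


def naive_single_linkage(positions, cut):
    """Independent O(n^3) single-linkage oracle: grow the dendrogram by
    repeatedly merging the closest pair of clusters while the linkage
    distance is strictly below the cut."""
    clusters = [[i] for i in range(len(positions))]
    while len(clusters) > 1:
        best = None
        best_d = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = min(
                    abs(positions[i] - positions[j])
                    for i in clusters[a]
                    for j in clusters[b]
                )
                if best_d is None or d < best_d:
                    best_d, best = d, (a, b)
        if best_d >= cut:
            break
        a, b = best
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return clusters


def canonical(partition):
    """Order-free canonical form of a partition (for comparing oracles)."""
    return sorted(tuple(sorted(c)) for c in partition)
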