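"""Single-linkage clusters, identity, greedy OTUs and neighbour joining."""

import itertools

import dendropy
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from coiaudit.clustering import (
    greedy_centroid_cluster,
    nj_tree,
    pairwise_identity,
    semiglobal_identity,
    single_linkage_clusters,
)
from coiaudit.distances import DistanceMatrix


def _matrix(ids, entries):
    n = len(ids)
    d = np.zeros((n, n))
    for (a, b), value in entries.items():
        i, j = ids.index(a), ids.index(b)
        d[i, j] = d[j, i] = value
    return DistanceMatrix(ids=list(ids), d=d)


def oracle_single_linkage(matrix, threshold):
    """Transitive closure by repeated sweeping — independent oracle."""
    groups = [{rid} for rid in matrix.ids]
    changed = True
    while changed:
        changed = False
        for g1, g2 in itertools.combinations(groups, 2):
            linked = any(
                matrix.get(a, b) < threshold for a in g1 for b in g2
            )
            if linked:
                g1 |= g2
                groups.remove(g2)
                changed = True
                break
    return {frozenset(g) for g in groups}


def test_single_linkage_zero_distances_one_cluster():
    m = _matrix(["a", "b", "c"], {})
    result = single_linkage_clusters(m, threshold=0.022)
    assert list(result.clusters) == ["C000001"]
    assert sorted(result.clusters["C000001"]) == ["a", "b", "c"]


def test_single_linkage_chain_and_strict_boundary():
    m = _matrix(["a", "b", "c"], {
        ("a", "b"): 0.01, ("b", "c"): 0.01, ("a", "c"): 0.03,
    })
    result = single_linkage_clusters(m, threshold=0.022)
    assert len(result.clusters) == 1  # chained through b

    m2 = _matrix(["a", "b"], {("a", "b"): 0.022})
    result2 = single_linkage_clusters(m2, threshold=0.022)
    assert len(result2.clusters) == 2  # strict <: boundary pair stays apart


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(min_value=0, max_value=10_000))
def test_single_linkage_matches_transitive_closure_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 20))
    d = rng.uniform(0, 0.05, size=(n, n))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    matrix = DistanceMatrix(ids=[f"r{i:02d}" for i in range(n)], d=d)
    result = single_linkage_clusters(matrix, threshold=0.022)
    assert {frozenset(ms) for ms in result.clusters.values()} == \
        oracle_single_linkage(matrix, 0.022)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(min_value=0, max_value=10_000))
def test_single_linkage_monotone_in_threshold(seed):
    rng = np.random.default_rng(seed)
    n = 12
    d = rng.uniform(0, 0.05, size=(n, n))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    matrix = DistanceMatrix(ids=[f"r{i:02d}" for i in range(n)], d=d)
    fine = single_linkage_clusters(matrix, threshold=0.01)
    coarse = single_linkage_clusters(matrix, threshold=0.03)
    coarse_of = coarse.member_to_cluster
    for members in fine.clusters.values():
        assert len({coarse_of[m] for m in members}) == 1  # only merges


def test_pairwise_identity_examples():
    assert pairwise_identity("ACGT", "ACGT") == 1.0
    assert pairwise_identity("ACGTACGT", "ACGAACGT") == pytest.approx(7 / 8)
    assert pairwise_identity("ACGT", "ACG") == pytest.approx(3 / 4)
    with pytest.raises(ValueError):
        pairwise_identity("", "ACGT")


def test_semiglobal_identity_ignores_terminal_gaps():
    insert = "ACGTTGCA" * 12
    assert semiglobal_identity(insert, "TTTT" + insert + "GG") == 1.0
    mutated = "T" + insert[1:]
    assert semiglobal_identity(mutated, "AAAA" + insert) == pytest.approx(
        (len(insert) - 1) / len(insert)
    )


def _mutate_at(seq, positions):
    swap = {"A": "C", "C": "G", "G": "T", "T": "A"}
    out = list(seq)
    for pos in positions:
        out[pos] = swap[out[pos]]
    return "".join(out)


def test_greedy_centroid_replays_the_greedy_rule():
    u1 = "ACGT" * 25  # 100 bp
    u2 = _mutate_at(u1, [10, 50])        # 98% to u1
    u3 = _mutate_at(u1, range(0, 40, 4))  # 90% to u1, ~88% to u2
    result = greedy_centroid_cluster([(u1, 10), (u2, 5), (u3, 3)],
                                     identity_threshold=0.97)
    members = {cid: set(ms) for cid, ms in result.clusters.items()}
    assert members["OTU000001"] == {u1, u2}
    assert members["OTU000002"] == {u3}
    assert result.centroids["OTU000001"] == u1


def test_greedy_centroid_singleton_and_abundance_tie_rule():
    single = greedy_centroid_cluster([("ACGT" * 30, 4)])
    assert list(single.clusters) == ["OTU000001"]

    a = "A" * 50 + "ACGT" * 20
    b = "T" * 50 + "TGCA" * 20  # far from a; both seed centroids
    result = greedy_centroid_cluster([(b, 5), (a, 5)], identity_threshold=0.97)
    # tie at abundance 5: lexicographically smaller sequence processed (and
    # here also ranked) first
    assert result.centroids["OTU000001"] == min(a, b)


def test_greedy_members_within_threshold_of_centroid_and_prefilter_noop():
    rng = np.random.default_rng(3)
    base = "".join("ACGT"[i] for i in rng.integers(0, 4, size=200))
    uniques = []
    for i in range(30):
        n_mut = int(rng.integers(0, 12))
        positions = rng.choice(200, size=n_mut, replace=False)
        uniques.append((_mutate_at(base, positions), int(rng.integers(1, 50))))
    uniques = list({seq: ab for seq, ab in uniques}.items())
    plain = greedy_centroid_cluster(uniques, identity_threshold=0.97)
    fast = greedy_centroid_cluster(uniques, identity_threshold=0.97,
                                   prefilter=True)
    assert plain.clusters == fast.clusters
    for otu_id, members in plain.clusters.items():
        for member in members:
            assert pairwise_identity(member, plain.centroids[otu_id]) >= 0.97


# ---------------------------------------------------------------------------
# Neighbour joining

def _patristic(newick):
    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    return lambda a, b: pdm.distance(taxa[a], taxa[b])


def test_nj_three_leaves_closed_form():
    m = _matrix(["A", "B", "C"], {
        ("A", "B"): 3.0, ("A", "C"): 4.0, ("B", "C"): 5.0,
    })
    tree = nj_tree(m)
    dist = _patristic(tree.newick)
    assert dist("A", "B") == pytest.approx(3.0, abs=1e-9)
    assert dist("A", "C") == pytest.approx(4.0, abs=1e-9)
    assert dist("B", "C") == pytest.approx(5.0, abs=1e-9)


def test_nj_recovers_additive_four_leaf_matrix():
    # distances from the tree ((A:1,B:2):1,(C:3,D:4))
    m = _matrix(["A", "B", "C", "D"], {
        ("A", "B"): 3, ("A", "C"): 5, ("A", "D"): 6,
        ("B", "C"): 6, ("B", "D"): 7, ("C", "D"): 7,
    })
    tree = nj_tree(m)
    dist = _patristic(tree.newick)
    for a, b in itertools.combinations("ABCD", 2):
        assert dist(a, b) == pytest.approx(m.get(a, b), abs=1e-9)


def test_nj_matches_reference_implementation_on_random_additive_matrix():
    skbio = pytest.importorskip("skbio")
    rng = np.random.default_rng(5)
    # build an additive matrix from a random tree via dendropy
    taxa = [f"T{i}" for i in range(8)]
    newick = "((T0:0.1,T1:0.2):0.05,((T2:0.3,T3:0.1):0.2,(T4:0.15,"
    newick += "(T5:0.1,(T6:0.2,T7:0.05):0.1):0.05):0.1):0.02);"
    dist = _patristic(newick)
    d = np.array([[0.0 if a == b else dist(a, b) for b in taxa] for a in taxa])
    matrix = DistanceMatrix(ids=taxa, d=d)
    ours = nj_tree(matrix)
    ours_dist = _patristic(ours.newick)

    ref = skbio.tree.nj(skbio.DistanceMatrix(d, ids=taxa))
    for a, b in itertools.combinations(taxa, 2):
        assert ours_dist(a, b) == pytest.approx(dist(a, b), abs=1e-9)
        assert ref.find(a).distance(ref.find(b)) == pytest.approx(
            ours_dist(a, b), abs=1e-6
        )


def test_nj_deterministic_under_symmetric_ties():
    d = np.array([
        [0, 2, 4, 4.0],
        [2, 0, 4, 4],
        [4, 4, 0, 2],
        [4, 4, 2, 0],
    ])
    matrix = DistanceMatrix(ids=["A", "B", "C", "D"], d=d)
    assert nj_tree(matrix).newick == nj_tree(matrix).newick
    with pytest.raises(ValueError):
        nj_tree(_matrix(["A", "B"], {("A", "B"): 1.0}))
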