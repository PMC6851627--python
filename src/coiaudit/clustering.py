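"""Sequence clustering: BIN-proxy single linkage, greedy centroid OTUs,
pairwise identity and neighbour-joining trees.

BOLD's RESL algorithm that mints real BINs is proprietary; the BIN proxy
here is single-linkage clustering of the K2P matrix at a 2.2% threshold (a
published RESL seed value).  Outputs are labelled "cluster", never claimed
to equal BOLD BIN ids.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from Bio import Align
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .distances import DistanceMatrix

__all__ = [
    "ClusterAssignment",
    "Tree",
    "single_linkage_clusters",
    "pairwise_identity",
    "greedy_centroid_cluster",
    "nj_tree",
]

logger = logging.getLogger(__name__)

SINGLE_LINKAGE_THRESHOLD = 0.022  # K2P, BIN-proxy seed threshold
OTU_IDENTITY_THRESHOLD = 0.97


@dataclass
class ClusterAssignment:
    """A partition of record ids into clusters.

    ``clusters`` maps cluster id -> member record ids (file order preserved
    within a cluster).  ``centroids`` maps cluster id -> centroid sequence
    for greedy clustering, empty for single linkage.
    """

    clusters: dict
    method: str
    threshold: float
    centroids: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        members = [m for ms in self.clusters.values() for m in ms]
        if len(members) != len(set(members)):
            raise ValueError("clusters do not partition the input ids")
        if any(not ms for ms in self.clusters.values()):
            raise ValueError("empty cluster")

    @property
    def member_to_cluster(self) -> dict:
        return {m: cid for cid, ms in self.clusters.items() for m in ms}

    def to_rows(self) -> list:
        return [
            {"record_id": m, "cluster_id": cid, "method": self.method,
             "threshold": self.threshold}
            for cid, ms in sorted(self.clusters.items())
            for m in ms
        ]


def single_linkage_clusters(
    matrix: DistanceMatrix, threshold: float = SINGLE_LINKAGE_THRESHOLD
) -> ClusterAssignment:
    """Single-linkage clusters: ids chained by pairs with d < threshold.

    The comparison is strict; a pair at exactly the threshold does not link.
    NaN (saturated, dropped) entries never link.  Cluster ids are assigned
    deterministically: clusters ordered by their smallest member id and
    numbered ``C000001``, ``C000002``, ...
    """
    with np.errstate(invalid="ignore"):
        adjacency = matrix.d < threshold
    np.fill_diagonal(adjacency, True)
    n_comp, labels = connected_components(csr_matrix(adjacency), directed=False)
    groups: dict = {}
    for rid, lab in zip(matrix.ids, labels):
        groups.setdefault(lab, []).append(rid)
    ordered = sorted(groups.values(), key=lambda ms: min(ms))
    clusters = {f"C{i:06d}": ms for i, ms in enumerate(ordered, 1)}
    return ClusterAssignment(
        clusters=clusters, method="single_linkage", threshold=threshold
    )


# ---------------------------------------------------------------------------
# Pairwise identity (global end-to-end alignment)

_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 1
_aligner.mismatch_score = -1
_aligner.open_gap_score = -2
_aligner.extend_gap_score = -2

# same scores, but terminal gaps free (semiglobal / overlap alignment)
_semi_aligner = Align.PairwiseAligner()
_semi_aligner.mode = "global"
_semi_aligner.match_score = 1
_semi_aligner.mismatch_score = -1
_semi_aligner.open_gap_score = -2
_semi_aligner.extend_gap_score = -2
try:
    _semi_aligner.open_end_insertion_score = 0
    _semi_aligner.extend_end_insertion_score = 0
    _semi_aligner.open_end_deletion_score = 0
    _semi_aligner.extend_end_deletion_score = 0
except AttributeError:  # older Biopython naming
    _semi_aligner.target_end_open_gap_score = 0
    _semi_aligner.target_end_extend_gap_score = 0
    _semi_aligner.query_end_open_gap_score = 0
    _semi_aligner.query_end_extend_gap_score = 0


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment identity: matches / alignment columns.

    Needleman-Wunsch with match +1, mismatch -1, linear gap -2; terminal
    gaps are scored and counted, so the denominator is the full end-to-end
    alignment length.
    """
    if not seq_a or not seq_b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    if seq_a == seq_b:
        return 1.0
    alignment = _aligner.align(seq_a.upper(), seq_b.upper())[0]
    counts = alignment.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    return counts.identities / columns


def semiglobal_identity(query: str, target: str) -> float:
    """Best-hit identity with free terminal gaps: matches / aligned columns.

    Same scoring as :func:`pairwise_identity` inside the aligned region but
    terminal gaps are neither scored nor counted, so a short amplicon can
    match a full-length barcode at up to 100%.  This is the Hit-%-ID-style
    statistic used for taxonomy assignment.
    """
    if not query or not target:
        raise ValueError("semiglobal_identity requires non-empty sequences")
    alignment = _semi_aligner.align(query.upper(), target.upper())[0]
    counts = alignment.counts()
    identities, mismatches = counts.identities, counts.mismatches
    # internal gaps only: subtract the unaligned overhangs at both ends
    qa, ta = alignment.aligned[0], alignment.aligned[1]
    span_q = int(qa[-1][1] - qa[0][0]) if len(qa) else 0
    span_t = int(ta[-1][1] - ta[0][0]) if len(ta) else 0
    internal_gaps = (span_q - identities - mismatches) + \
        (span_t - identities - mismatches)
    columns = identities + mismatches + internal_gaps
    return identities / columns if columns else 0.0


KMER_SIZE = 12
KMER_MIN_SHARED = 0.5  # of the smaller k-mer set


def kmer_set(seq: str, k: int = KMER_SIZE) -> frozenset:
    return frozenset(seq[i:i + k] for i in range(len(seq) - k + 1))


def kmer_shared_fraction(kmers_a: frozenset, kmers_b: frozenset) -> float:
    smaller = min(len(kmers_a), len(kmers_b))
    if smaller == 0:
        return 0.0
    return len(kmers_a & kmers_b) / smaller


def greedy_centroid_cluster(
    uniques: Sequence[tuple],
    identity_threshold: float = OTU_IDENTITY_THRESHOLD,
    prefilter: bool = False,
) -> ClusterAssignment:
    """Greedy centroid OTU clustering of (sequence, abundance) pairs.

    Uniques are processed in decreasing abundance (ties: lexicographically
    smaller sequence first).  Each is joined to the first existing centroid
    with identity >= threshold, else it seeds a new centroid.  Final OTU ids
    ``OTU000001``... are assigned in decreasing total (member-summed)
    abundance, ties by centroid sequence.

    ``prefilter=True`` skips the alignment against centroids sharing fewer
    than half their 12-mers with the query; at a 97% identity threshold at
    most ~10 edits separate joinable pairs, which can destroy far fewer
    than half of the k-mers, so the prescreen cannot change the result.
    """
    for seq, abundance in uniques:
        if abundance < 1:
            raise ValueError(f"abundance must be >= 1, got {abundance} for {seq[:20]}")
    order = sorted(uniques, key=lambda u: (-u[1], u[0]))
    centroids: list = []          # centroid sequences in creation order
    members: list = []            # parallel list of member sequence lists
    totals: list = []
    kmers: list = []
    for seq, abundance in order:
        query_kmers = kmer_set(seq) if prefilter else None
        joined = False
        for idx, centroid in enumerate(centroids):
            if prefilter and kmer_shared_fraction(
                query_kmers, kmers[idx]
            ) < KMER_MIN_SHARED:
                continue
            if pairwise_identity(seq, centroid) >= identity_threshold:
                members[idx].append(seq)
                totals[idx] += abundance
                joined = True
                break
        if not joined:
            centroids.append(seq)
            members.append([seq])
            totals.append(abundance)
            kmers.append(query_kmers if prefilter else kmer_set(seq))
    ranked = sorted(
        range(len(centroids)), key=lambda i: (-totals[i], centroids[i])
    )
    clusters = {}
    cents = {}
    for rank, idx in enumerate(ranked, 1):
        otu_id = f"OTU{rank:06d}"
        clusters[otu_id] = members[idx]
        cents[otu_id] = centroids[idx]
    return ClusterAssignment(
        clusters=clusters,
        method="greedy_centroid",
        threshold=identity_threshold,
        centroids=cents,
    )


# ---------------------------------------------------------------------------
# Neighbour joining

@dataclass
class Tree:
    """An unrooted tree as a Newick string plus its leaf set."""

    newick: str
    leaf_ids: list

    def write(self, path) -> None:
        with open(path, "w") as handle:
            handle.write(self.newick + "\n")


def _fmt(length: float) -> str:
    return f"{max(length, 0.0):.6f}"


def nj_tree(matrix: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbour joining on a distance matrix.

    Pair selection minimises Q(i,j) = (r-2) d(i,j) - R_i - R_j; ties are
    broken by the lexicographically smallest (sorted) pair of node keys,
    where a node's key is its smallest leaf id.  Negative branch-length
    estimates are clamped to zero (logged).  Requires >= 3 leaves.
    """
    n = len(matrix.ids)
    if n < 3:
        raise ValueError("neighbour joining requires at least 3 leaves")
    if not np.isfinite(matrix.d).all():
        raise ValueError("nj_tree requires a complete (finite) matrix")
    d = matrix.d.astype(float).copy()
    newicks = list(matrix.ids)
    keys = list(matrix.ids)  # smallest leaf id under each active node
    active = list(range(n))

    def clamp(length: float, context: str) -> float:
        if length < 0:
            logger.debug("clamping negative NJ branch length %.6g (%s)", length, context)
            return 0.0
        return length

    while len(active) > 3:
        r = len(active)
        sub = d[np.ix_(active, active)]
        row_sums = sub.sum(axis=1)
        q = (r - 2) * sub - row_sums[:, None] - row_sums[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        ties = np.argwhere(np.isclose(q, qmin, rtol=0, atol=1e-12))
        best = min(
            (tuple(sorted((keys[active[i]], keys[active[j]]))), i, j)
            for i, j in ties if i < j
        )
        _, ai, aj = best
        i_glob, j_glob = active[ai], active[aj]
        dij = d[i_glob, j_glob]
        li = 0.5 * dij + (row_sums[ai] - row_sums[aj]) / (2 * (r - 2))
        lj = dij - li
        li = clamp(li, f"{keys[i_glob]}|{keys[j_glob]}")
        lj = clamp(lj, f"{keys[i_glob]}|{keys[j_glob]}")
        new_newick = f"({newicks[i_glob]}:{_fmt(li)},{newicks[j_glob]}:{_fmt(lj)})"
        new_key = min(keys[i_glob], keys[j_glob])
        # distances from the new node to the remaining active nodes
        new_row = np.zeros(d.shape[0])
        for ak in active:
            if ak in (i_glob, j_glob):
                continue
            new_row[ak] = 0.5 * (d[i_glob, ak] + d[j_glob, ak] - dij)
        d = np.vstack([d, new_row])
        new_col = np.append(new_row, 0.0)
        d = np.hstack([d, new_col[:, None]])
        newicks.append(new_newick)
        keys.append(new_key)
        active = [a for a in active if a not in (i_glob, j_glob)] + [d.shape[0] - 1]

    a, b, c = active
    # closed-form terminal branch lengths for the final three nodes
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    la, lb, lc = (clamp(x, "final join") for x in (la, lb, lc))
    newick = (
        f"({newicks[a]}:{_fmt(la)},{newicks[b]}:{_fmt(lb)},{newicks[c]}:{_fmt(lc)});"
    )
    return Tree(newick=newick, leaf_ids=list(matrix.ids))
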