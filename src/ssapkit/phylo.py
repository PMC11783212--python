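"""Structural / sequence dendrograms and representative selection.

Distances are ``1 - similarity`` where similarity is either the mean of
the two TM-score normalizations (structure mode) or identity x coverage
from a local BLOSUM62 alignment (sequence mode).  Trees are built by
UPGMA (average linkage) with deterministic tie-breaking, and cluster
representatives are medoids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structio import StructureSet
from .superpose import align_structures

__all__ = [
    "SimilarityMatrix",
    "TreeNode",
    "ClusterTree",
    "RepresentativeSet",
    "similarity_matrix",
    "average_linkage",
    "to_newick",
    "cut_tree",
    "select_representatives",
    "sequence_similarity_matrix",
]


@dataclass
class SimilarityMatrix:
    """Symmetric similarity matrix in [0, 1] with unit diagonal."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError("matrix shape does not match id count")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("similarity matrix must be symmetric")
        if np.any(v < -1e-12) or np.any(v > 1 + 1e-12):
            raise ValueError("similarities must lie in [0, 1]")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("diagonal must be exactly 1")
        self.values = v

    def get(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.values[i, j])

    def distances(self) -> np.ndarray:
        return 1.0 - self.values


@dataclass
class TreeNode:
    """Binary dendrogram node; leaves carry ids, internals merge heights."""

    label: str | None = None
    children: list["TreeNode"] = field(default_factory=list)
    height: float = 0.0
    merge_index: int = -1  # order of the merge that created this node

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return [leaf for c in self.children for leaf in c.leaves()]

    def leaf_labels(self) -> list[str]:
        return [leaf.label for leaf in self.leaves()]


@dataclass
class ClusterTree:
    root: TreeNode

    def leaf_labels(self) -> list[str]:
        return self.root.leaf_labels()

    def n_leaves(self) -> int:
        return len(self.root.leaves())


@dataclass
class RepresentativeSet:
    representatives: list[str]
    clusters: dict[str, int]  # member id -> cluster index

    def members_of(self, cluster: int) -> list[str]:
        return [i for i, c in self.clusters.items() if c == cluster]


def similarity_matrix(s: StructureSet) -> SimilarityMatrix:
    """All-vs-all structural similarity: mean of both TM normalizations.

    Each unordered pair is aligned exactly once, which makes the matrix
    symmetric by construction.
    """
    if len(s) < 2:
        raise ValueError("need at least 2 structures")
    members = s.members
    n = len(members)
    v = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            res = align_structures(members[i], members[j])
            sim = 0.5 * (res.tm_norm_a + res.tm_norm_b)
            v[i, j] = v[j, i] = min(1.0, max(0.0, sim))
    return SimilarityMatrix(ids=[m.id for m in members], values=v)


def average_linkage(sim: SimilarityMatrix) -> ClusterTree:
    """UPGMA dendrogram on distances ``1 - similarity``.

    At each step the pair of clusters with minimal average distance is
    merged; ties are broken by the lexicographically smallest pair of
    cluster ids (a cluster is identified by its smallest leaf id).  The
    new node's height is the merge distance.
    """
    D = sim.distances()
    n = len(sim.ids)
    nodes: dict[int, TreeNode] = {
        i: TreeNode(label=sim.ids[i]) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    reps = {i: sim.ids[i] for i in range(n)}  # lexicographic representative
    dist: dict[tuple[int, int], float] = {
        (i, j): float(D[i, j]) for i in range(n) for j in range(i + 1, n)}
    next_id = n
    for merge_index in range(n - 1):
        best_key = None
        best_d = np.inf
        for (i, j), d in dist.items():
            pair_ids = tuple(sorted((reps[i], reps[j])))
            key = (d, pair_ids)
            if best_key is None or key < (best_d, best_key[1]):
                best_key = (d, pair_ids)
                best_d = d
                best_pair = (i, j)
        i, j = best_pair
        node = TreeNode(children=[nodes[i], nodes[j]], height=best_d,
                        merge_index=merge_index)
        nodes.pop(i), nodes.pop(j)
        new_dist = {}
        for k in nodes:
            dik = dist.pop((min(i, k), max(i, k)))
            djk = dist.pop((min(j, k), max(j, k)))
            new_dist[k] = (sizes[i] * dik + sizes[j] * djk) / (
                sizes[i] + sizes[j])
        dist.pop((i, j))
        nodes[next_id] = node
        sizes[next_id] = sizes.pop(i) + sizes.pop(j)
        reps[next_id] = min(reps.pop(i), reps.pop(j))
        for k, d in new_dist.items():
            dist[(min(k, next_id), max(k, next_id))] = d
        next_id += 1
    root = next(iter(nodes.values()))
    return ClusterTree(root=root)


def _newick_node(node: TreeNode, parent_height: float | None) -> str:
    if node.is_leaf:
        body = node.label
    else:
        body = "(" + ",".join(
            _newick_node(c, node.height) for c in node.children) + ")"
    if parent_height is None:
        return body
    # ultrametric layout: leaves sit at depth height/2 below a merge
    length = (parent_height - node.height) / 2.0
    return f"{body}:{length:.10g}"


def to_newick(t: ClusterTree) -> str:
    """Newick string with branch lengths from merge-height differences."""
    return _newick_node(t.root, None) + ";"


def cut_tree(t: ClusterTree, k: int) -> list[list[str]]:
    """Cut at the k-1 highest (latest) merges into k leaf-label groups."""
    n = t.n_leaves()
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    cutoff = (n - 1) - (k - 1)  # merges with index >= cutoff are removed

    groups: list[list[str]] = []

    def walk(node: TreeNode) -> None:
        if not node.is_leaf and node.merge_index >= cutoff:
            for c in node.children:
                walk(c)
        else:
            groups.append(node.leaf_labels())

    walk(t.root)
    return sorted(groups, key=lambda g: min(g))


def select_representatives(t: ClusterTree, sim: SimilarityMatrix,
                           k: int) -> RepresentativeSet:
    """Cut into k clusters and pick each cluster's medoid.

    The medoid maximizes mean similarity to its cluster co-members
    (ties broken by smallest id); singletons represent themselves.
    """
    groups = cut_tree(t, k)
    idx = {id_: i for i, id_ in enumerate(sim.ids)}
    representatives: list[str] = []
    clusters: dict[str, int] = {}
    for ci, group in enumerate(groups):
        for gid in group:
            clusters[gid] = ci
        if len(group) == 1:
            representatives.append(group[0])
            continue
        best_id = None
        best_score = -np.inf
        for gid in sorted(group):
            others = [idx[o] for o in group if o != gid]
            score = float(np.mean(sim.values[idx[gid], others]))
            if score > best_score + 1e-15:
                best_score = score
                best_id = gid
        representatives.append(best_id)
    return RepresentativeSet(representatives=representatives,
                             clusters=clusters)


def _identity_coverage(aligner, query: str, subject: str) -> float:
    aln = aligner.align(query, subject)[0]
    counts = aln.counts()
    length = aln.length
    if length == 0:
        return 0.0
    identity = counts.identities / length
    coverage = min(1.0, length / len(query))
    return identity * coverage


def sequence_similarity_matrix(
    seqs: list[tuple[str, str]],
) -> SimilarityMatrix:
    """Pairwise identity x coverage scores from local BLOSUM62 alignment.

    Gap open 11, extend 1; identity is identical columns over alignment
    length, coverage is alignment length over query length (capped at
    1), and the matrix is symmetrized by averaging both query choices.
    """
    from Bio import Align
    from Bio.Align import substitution_matrices

    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    for sid, seq in seqs:
        if not seq:
            raise ValueError(f"empty sequence: {sid}")

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0

    valid = set("ACDEFGHIKLMNPQRSTVWYBZX*")
    cleaned = [(sid, "".join(c if c in valid else "X" for c in seq.upper()))
               for sid, seq in seqs]
    n = len(cleaned)
    v = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            sij = _identity_coverage(aligner, cleaned[i][1], cleaned[j][1])
            sji = _identity_coverage(aligner, cleaned[j][1], cleaned[i][1])
            v[i, j] = v[j, i] = min(1.0, 0.5 * (sij + sji))
    return SimilarityMatrix(ids=[sid for sid, _ in cleaned], values=v)
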