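"""Chord-distance phylogeny from multilocus microsatellite genotypes.

Genetic distance between two strains is the Cavalli-Sforza & Edwards
chord distance computed per locus from the strains' allele-frequency
vectors and averaged over the loci shared by both strains
(pairwise deletion of missing loci):

    d_l = (2/pi) * sqrt( 2 * (1 - sum_a sqrt(p1(a) * p2(a))) )

Strains are treated as diploid by default (a homozygote contributes a
single allele at frequency 1, a heterozygote two alleles at 0.5 each); a
haploid mode is provided since yeast ploidy varies. The distance matrix
feeds a re-implemented Saitou-Nei neighbor-joining with deterministic
tie-breaking, and the resulting unrooted tree is rooted at the midpoint
of its longest leaf-to-leaf path.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence as TypingSequence

import numpy as np
from skbio import DistanceMatrix

from .datamodel_io import MultilocusGenotype, PhyloNode, PhyloTree

__all__ = [
    "CHORD_MAX",
    "MissingLocusError",
    "allele_freqs",
    "chord_distance",
    "distance_matrix",
    "neighbor_joining",
    "midpoint_root",
    "cluster_separation",
]

#: Upper bound of the per-locus chord distance, attained when the two
#: strains share no alleles at the locus.
CHORD_MAX = (2.0 / math.pi) * math.sqrt(2.0)


class MissingLocusError(KeyError):
    """Raised when a genotype lacks a requested locus (distinct from empty)."""


def allele_freqs(g: MultilocusGenotype, locus: str,
                 mode: str = "diploid") -> dict[int, float]:
    """Within-strain allele frequencies at one locus.

    Diploid mode: homozygote -> {a: 1.0}, heterozygote -> {a: 0.5, b: 0.5}.
    Haploid mode: the first recorded allele at frequency 1.
    """
    if locus not in g.genotype:
        raise MissingLocusError(f"{g.strain_id}: locus {locus!r} not recorded")
    a, b = g.genotype[locus]
    if mode == "haploid":
        return {a: 1.0}
    if mode != "diploid":
        raise ValueError(f"unknown ploidy mode {mode!r}")
    return {a: 1.0} if a == b else {a: 0.5, b: 0.5}


def chord_distance(g1: MultilocusGenotype, g2: MultilocusGenotype,
                   panel: TypingSequence[str], mode: str = "diploid") -> float:
    """Cavalli-Sforza-Edwards chord distance averaged over shared loci."""
    shared = [l for l in panel if l in g1.genotype and l in g2.genotype]
    if not shared:
        raise ValueError(
            f"{g1.strain_id} and {g2.strain_id} share no non-missing loci"
        )
    total = 0.0
    for locus in shared:
        p1 = allele_freqs(g1, locus, mode)
        p2 = allele_freqs(g2, locus, mode)
        s = sum(math.sqrt(p1[a] * p2[a]) for a in p1.keys() & p2.keys())
        total += (2.0 / math.pi) * math.sqrt(max(0.0, 2.0 * (1.0 - s)))
    return total / len(shared)


def distance_matrix(genos: TypingSequence[MultilocusGenotype],
                    panel: TypingSequence[str],
                    mode: str = "diploid") -> DistanceMatrix:
    """All-pairs chord distances as a labelled symmetric matrix."""
    if len(genos) < 2:
        raise ValueError("need at least 2 genotypes")
    ids = [g.strain_id for g in genos]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate strain ids")
    n = len(genos)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = chord_distance(genos[i], genos[j], panel, mode)
    return DistanceMatrix(d, ids)


# --------------------------------------------------------------------------
# neighbor joining
# --------------------------------------------------------------------------

def neighbor_joining(d: DistanceMatrix | np.ndarray,
                     ids: TypingSequence[str] | None = None) -> PhyloTree:
    """Saitou-Nei neighbor joining; deterministic, unrooted.

    At each step the pair minimizing the Q-criterion is joined (ties break
    toward the smallest (row, col) index pair); branch lengths follow the
    standard closed forms, with negative estimates clamped to zero and the
    excess transferred to the sister branch. On an additive matrix the
    generating tree is recovered exactly.
    """
    if not isinstance(d, DistanceMatrix):
        d = DistanceMatrix(np.asarray(d, dtype=float), ids)  # validates
    if np.any(d.data < 0):
        raise ValueError("distance matrix has negative entries")
    n = d.shape[0]
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")

    D = d.data.astype(float).copy()
    nodes: list[PhyloNode] = [PhyloNode(name) for name in d.ids]

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        q[np.tril_indices(m)] = np.inf
        i, j = np.unravel_index(int(np.argmin(q)), q.shape)  # row-major: lowest pair

        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            li, lj = 0.0, dij
        elif lj < 0:
            li, lj = dij, 0.0
        parent = PhyloNode()
        child_i, child_j = nodes[i], nodes[j]
        child_i.length, child_j.length = li, lj
        parent.add_child(child_i)
        parent.add_child(child_j)

        new_row = 0.5 * (D[i, :] + D[j, :] - dij)
        new_row = np.maximum(new_row, 0.0)
        D[i, :] = new_row
        D[:, i] = new_row
        D[i, i] = 0.0
        keep = [k for k in range(m) if k != j]
        D = D[np.ix_(keep, keep)]
        nodes[i] = parent
        del nodes[j]

    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    la = max(0.0, 0.5 * (dab + dac - dbc))
    lb = max(0.0, 0.5 * (dab + dbc - dac))
    lc = max(0.0, 0.5 * (dac + dbc - dab))
    root = PhyloNode()
    for node, length in zip(nodes, (la, lb, lc)):
        node.length = length
        root.add_child(node)
    return PhyloTree(root, rooted=False)


# --------------------------------------------------------------------------
# midpoint rooting
# --------------------------------------------------------------------------

def _path_between(a: PhyloNode, b: PhyloNode) -> list[PhyloNode]:
    anc_a = []
    node = a
    while node is not None:
        anc_a.append(node)
        node = node.parent
    seen = {id(x): k for k, x in enumerate(anc_a)}
    chain_b = []
    node = b
    while id(node) not in seen:
        chain_b.append(node)
        node = node.parent
    lca_idx = seen[id(node)]
    return anc_a[: lca_idx + 1] + list(reversed(chain_b))


def _edge_length(u: PhyloNode, v: PhyloNode) -> float:
    return v.length if v.parent is u else u.length


def _splice_unary(node: PhyloNode) -> None:
    """Remove a degree-2 pass-through node, merging branch lengths."""
    if node.parent is not None and len(node.children) == 1:
        child = node.children[0]
        child.length += node.length
        parent = node.parent
        pos = parent.children.index(node)
        parent.children[pos] = child
        child.parent = parent
        node.children = []
        node.parent = None


def _reroot_at(tree: PhyloTree, new_root: PhyloNode) -> PhyloTree:
    if new_root is tree.root:
        return PhyloTree(new_root, rooted=True)
    chain = []
    node = new_root
    while node is not None:
        chain.append(node)
        node = node.parent
    lengths = [c.length for c in chain[:-1]]  # chain[i] -> chain[i+1] edge
    for child, parent in zip(chain, chain[1:]):
        parent.children.remove(child)
        child.parent = None
    for i in range(len(chain) - 1):
        chain[i].add_child(chain[i + 1])
        chain[i + 1].length = lengths[i]
    new_root.length = 0.0
    new_root.parent = None
    for node in chain[1:]:
        _splice_unary(node)
    return PhyloTree(new_root, rooted=True)


def midpoint_root(tree: PhyloTree) -> PhyloTree:
    """Root the tree at the midpoint of its longest leaf-to-leaf path.

    The two farthest leaves end up equidistant from the root; when the
    midpoint falls exactly on an existing node, that node becomes the root
    without introducing a zero-length edge. A zero-diameter tree is rooted
    at its current top node and flagged degenerate.
    """
    if len(tree.leaves()) < 2:
        raise ValueError("midpoint rooting needs at least 2 leaves")
    work = tree.copy()
    names, dmat = work.leaf_distances()
    diameter = float(dmat.values.max())
    if diameter == 0.0:
        out = PhyloTree(work.root, rooted=True, degenerate=True)
        return out
    # deterministic farthest pair: smallest (i, j) among the maxima
    i, j = np.unravel_index(int(np.argmax(dmat.values)), dmat.values.shape)
    if i > j:
        i, j = j, i
    by_name = {leaf.name: leaf for leaf in work.leaves()}
    a, b = by_name[names[i]], by_name[names[j]]

    path = _path_between(a, b)
    target = diameter / 2.0
    cum = 0.0
    for k in range(len(path) - 1):
        edge = _edge_length(path[k], path[k + 1])
        if abs(cum - target) < 1e-12:
            return _reroot_at(work, path[k])
        if cum + edge > target:
            s = target - cum  # distance from path[k] into this edge
            u, v = path[k], path[k + 1]
            if v.parent is u:
                u.children.remove(v)
                mid = PhyloNode(length=s)
                u.add_child(mid)
                mid.add_child(v)
                v.length = edge - s
            else:
                v.children.remove(u)
                mid = PhyloNode(length=edge - s)
                v.add_child(mid)
                mid.add_child(u)
                u.length = s
            return _reroot_at(work, mid)
        cum += edge
    return _reroot_at(work, path[-1])


# --------------------------------------------------------------------------
# cluster separation (monophyly report)
# --------------------------------------------------------------------------

def cluster_separation(tree: PhyloTree,
                       group_labels: Mapping[str, str]) -> dict[str, dict]:
    """Per label: do its leaves form a connected subtree under the root?

    Returns ``label -> {monophyletic, n_leaves, clade_size}`` where
    ``clade_size`` is the leaf count of the smallest clade containing all
    leaves of the label.
    """
    leaves = tree.leaves()
    missing = [l.name for l in leaves if l.name not in group_labels]
    if missing:
        raise ValueError(f"unlabeled leaves: {missing}")

    def ancestors(node: PhyloNode) -> list[PhyloNode]:
        out = []
        while node is not None:
            out.append(node)
            node = node.parent
        return out

    def leafset(node: PhyloNode) -> set[str]:
        return {l.name for l in PhyloTree(node).leaves()} if node.children \
            else {node.name}

    report: dict[str, dict] = {}
    for label in dict.fromkeys(group_labels.values()):
        members = [l for l in leaves if group_labels[l.name] == label]
        chains = [ancestors(l) for l in members]
        common = set(id(n) for n in chains[0])
        for chain in chains[1:]:
            common &= {id(n) for n in chain}
        # lowest common ancestor = first ancestor of members[0] shared by all
        lca = next(n for n in chains[0] if id(n) in common)
        clade = leafset(lca)
        report[label] = {
            "monophyletic": clade == {m.name for m in members},
            "n_leaves": len(members),
            "clade_size": len(clade),
        }
    return report
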