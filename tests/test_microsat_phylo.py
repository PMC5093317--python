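"""Chord distances, neighbor joining, midpoint rooting, monophyly."""

import math

import numpy as np
import pytest
import skbio
import io

from fermentype.datamodel_io import MultilocusGenotype, PhyloNode, PhyloTree
from fermentype.microsat_phylo import (
    CHORD_MAX,
    MissingLocusError,
    allele_freqs,
    chord_distance,
    cluster_separation,
    distance_matrix,
    midpoint_root,
    neighbor_joining,
)
from fermentype.synthetic_data import GeneratorConfig, gen_microsat

from conftest import random_additive_tree


def chord_oracle(g1, g2, panel):
    """Straightforward re-implementation summing over the allele union."""
    shared = [l for l in panel if l in g1.genotype and l in g2.genotype]
    vals = []
    for locus in shared:
        def freqs(g):
            a, b = g.genotype[locus]
            out = {}
            for x in (a, b):
                out[x] = out.get(x, 0.0) + 0.5
            return out
        p, q = freqs(g1), freqs(g2)
        s = sum(math.sqrt(p.get(a, 0.0) * q.get(a, 0.0))
                for a in set(p) | set(q))
        vals.append((2 / math.pi) * math.sqrt(2 * (1 - s)))
    return sum(vals) / len(vals)


def random_genotype(rng, sid, panel, allele_range=(100, 140)):
    return MultilocusGenotype(sid, {
        locus: (int(rng.integers(*allele_range)), int(rng.integers(*allele_range)))
        for locus in panel
    })


class TestChordDistance:
    def test_allele_freqs(self):
        g = MultilocusGenotype("s", {"C3": (180, 180), "C4": (180, 186)})
        assert allele_freqs(g, "C3") == {180: 1.0}
        assert allele_freqs(g, "C4") == {180: 0.5, 186: 0.5}
        assert allele_freqs(g, "C3", mode="haploid") == {180: 1.0}
        with pytest.raises(MissingLocusError):
            allele_freqs(g, "C5")

    def test_identical_genotypes_distance_zero(self):
        g = MultilocusGenotype("s", {"C3": (180, 184), "C4": (200, 200)})
        h = MultilocusGenotype("t", dict(g.genotype))
        assert chord_distance(g, h, ["C3", "C4"]) == 0.0

    def test_disjoint_homozygotes_attain_closed_form_maximum(self):
        g = MultilocusGenotype("s", {"C3": (180, 180)})
        h = MultilocusGenotype("t", {"C3": (190, 190)})
        d = chord_distance(g, h, ["C3"])
        assert d == pytest.approx((2 / math.pi) * math.sqrt(2), abs=1e-12)
        assert d == pytest.approx(CHORD_MAX)

    def test_matches_union_oracle_on_random_genotypes(self):
        rng = np.random.default_rng(11)
        panel = ["C3", "C4", "C5", "C6"]
        for _ in range(200):
            g1 = random_genotype(rng, "a", panel)
            g2 = random_genotype(rng, "b", panel)
            assert chord_distance(g1, g2, panel) == \
                pytest.approx(chord_oracle(g1, g2, panel), abs=1e-12)

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(12)
        panel = ["C3", "C4"]
        for _ in range(50):
            g1 = random_genotype(rng, "a", panel)
            g2 = random_genotype(rng, "b", panel)
            d = chord_distance(g1, g2, panel)
            assert d == chord_distance(g2, g1, panel)
            assert 0.0 <= d <= CHORD_MAX + 1e-12

    def test_pairwise_deletion_and_no_shared_loci(self):
        g1 = MultilocusGenotype("a", {"C3": (100, 100), "C4": (100, 100)})
        g2 = MultilocusGenotype("b", {"C4": (100, 100)})
        assert chord_distance(g1, g2, ["C3", "C4"]) == 0.0
        g3 = MultilocusGenotype("c", {"C3": (100, 100)})
        with pytest.raises(ValueError, match="share no"):
            chord_distance(g2, g3, ["C3", "C4"])


class TestDistanceMatrix:
    def test_identical_strains_zero_matrix(self):
        g1 = MultilocusGenotype("a", {"C3": (100, 102)})
        g2 = MultilocusGenotype("b", {"C3": (100, 102)})
        dm = distance_matrix([g1, g2], ["C3"])
        assert np.all(dm.data == 0.0)

    def test_invariant_to_strain_order(self):
        rng = np.random.default_rng(4)
        panel = ["C3", "C4", "C5"]
        genos = [random_genotype(rng, f"s{i}", panel) for i in range(6)]
        d1 = distance_matrix(genos, panel)
        d2 = distance_matrix(genos[::-1], panel)
        for a in d1.ids:
            for b in d1.ids:
                assert d1[a, b] == pytest.approx(d2[a, b])


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = skbio.DistanceMatrix(np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]],
                                           dtype=float), ["A", "B", "C"])
        tree = neighbor_joining(dm)
        lengths = {c.name: c.length for c in tree.root.children}
        assert lengths == {"A": 1.0, "B": 1.0, "C": 3.0}

    def test_recovers_random_additive_trees(self):
        rng = np.random.default_rng(20)
        for _ in range(20):
            n = int(rng.integers(5, 9))
            true_tree = random_additive_tree(rng, n)
            names, want = true_tree.leaf_distances()
            dm = skbio.DistanceMatrix(want.values, names)
            got_names, got = neighbor_joining(dm).leaf_distances()
            assert got_names == names
            assert np.allclose(got.values, want.values, atol=1e-9)

    def test_topology_agrees_with_skbio_nj(self):
        rng = np.random.default_rng(21)
        names = [f"t{i}" for i in range(8)]
        base = rng.uniform(0.5, 2.0, size=(8, 8))
        d = (base + base.T) / 2
        np.fill_diagonal(d, 0.0)
        dm = skbio.DistanceMatrix(d, names)
        ours = skbio.TreeNode.read(
            io.StringIO(neighbor_joining(dm).to_newick()))
        theirs = skbio.nj(dm)
        assert ours.compare_rfd(theirs) == 0.0

    def test_tie_breaks_to_lowest_index_pair(self):
        # four equidistant taxa: every Q is tied; (0, 1) must join first
        d = np.ones((4, 4)) - np.eye(4)
        tree = neighbor_joining(skbio.DistanceMatrix(d, list("ABCD")))
        parsed = skbio.TreeNode.read(io.StringIO(tree.to_newick()))
        sibling_sets = [{t.name for t in n.tips()}
                        for n in parsed.non_tips(include_self=False)]
        assert {"A", "B"} in sibling_sets

    def test_rejects_bad_matrices(self):
        with pytest.raises(Exception):
            neighbor_joining(np.array([[0, 1], [2, 0]]), ["a", "b"])
        with pytest.raises(ValueError):
            neighbor_joining(np.zeros((2, 2)), ["a", "b"])


class TestMidpointRoot:
    def test_two_leaf_tree(self):
        tree = PhyloTree(PhyloNode(children=[PhyloNode("A", 1.0),
                                             PhyloNode("B", 3.0)]))
        rooted = midpoint_root(tree)
        names, d = rooted.leaf_distances()
        depths = _leaf_depths(rooted)
        assert depths["A"] == pytest.approx(2.0)
        assert depths["B"] == pytest.approx(2.0)

    def test_max_depth_is_half_diameter_on_random_trees(self):
        rng = np.random.default_rng(30)
        for _ in range(10):
            tree = random_additive_tree(rng, int(rng.integers(4, 10)))
            _, d = tree.leaf_distances()
            diameter = d.values.max()
            rooted = midpoint_root(tree)
            depths = _leaf_depths(rooted)
            assert max(depths.values()) == pytest.approx(diameter / 2, abs=1e-9)

    def test_midpoint_on_existing_node_becomes_root(self):
        # A -1- x -1- B with extra leaf keeps x internal; diameter A..B = 2
        x = PhyloNode(children=[PhyloNode("A", 1.0), PhyloNode("B", 1.0),
                                PhyloNode("C", 0.2)])
        rooted = midpoint_root(PhyloTree(x))
        assert len(rooted.root.children) == 3  # no zero-length edge inserted
        depths = _leaf_depths(rooted)
        assert depths["A"] == pytest.approx(1.0)
        assert depths["B"] == pytest.approx(1.0)

    def test_invariant_to_leaf_input_order(self):
        rng = np.random.default_rng(31)
        tree = random_additive_tree(rng, 7)
        names, want = midpoint_root(tree).leaf_distances()
        # rebuild from the distance matrix with shuffled taxon order
        dm = skbio.DistanceMatrix(want.values, names)
        perm = list(rng.permutation(len(names)))
        dm2 = skbio.DistanceMatrix(want.values[np.ix_(perm, perm)],
                                   [names[i] for i in perm])
        r1 = midpoint_root(neighbor_joining(dm))
        r2 = midpoint_root(neighbor_joining(dm2))
        d1 = r1.leaf_distances()[1]
        d2 = r2.leaf_distances()[1]
        assert np.allclose(d1.values, d2.values, atol=1e-9)

    def test_zero_diameter_flagged_degenerate(self):
        tree = PhyloTree(PhyloNode(children=[PhyloNode("A", 0.0),
                                             PhyloNode("B", 0.0)]))
        rooted = midpoint_root(tree)
        assert rooted.degenerate


def _leaf_depths(tree):
    depths = {}

    def walk(node, acc):
        if node.is_leaf:
            depths[node.name] = acc
        for c in node.children:
            walk(c, acc + c.length)

    walk(tree.root, 0.0)
    return depths


class TestClusterSeparation:
    def test_two_pools_monophyletic(self):
        ms = gen_microsat(GeneratorConfig(seed=5))
        dm = distance_matrix(ms.genotypes, ms.panel)
        tree = midpoint_root(neighbor_joining(dm))
        report = cluster_separation(tree, ms.labels)
        assert report["pool1"]["monophyletic"]
        assert report["pool2"]["monophyletic"]

    def test_all_leaves_same_label(self):
        ms = gen_microsat(GeneratorConfig(seed=5, n_pools=1, n_per_pool=5))
        dm = distance_matrix(ms.genotypes, ms.panel)
        tree = midpoint_root(neighbor_joining(dm))
        report = cluster_separation(tree, {s: "all" for s in ms.labels})
        assert report["all"]["monophyletic"]
        assert report["all"]["clade_size"] == 5

    def test_planted_migrant_breaks_monophyly(self):
        ms = gen_microsat(GeneratorConfig(seed=5))
        labels = dict(ms.labels)
        # mislabel one pool-1 strain as pool 2: pool2 can no longer be a clade
        migrant = next(s for s, l in labels.items() if l == "pool1")
        labels[migrant] = "pool2"
        dm = distance_matrix(ms.genotypes, ms.panel)
        tree = midpoint_root(neighbor_joining(dm))
        report = cluster_separation(tree, labels)
        assert not report["pool2"]["monophyletic"]

    def test_unlabeled_leaf_rejected(self):
        ms = gen_microsat(GeneratorConfig(seed=5, n_per_pool=3))
        dm = distance_matrix(ms.genotypes, ms.panel)
        tree = midpoint_root(neighbor_joining(dm))
        labels = dict(ms.labels)
        labels.popitem()
        with pytest.raises(ValueError, match="unlabeled"):
            cluster_separation(tree, labels)
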