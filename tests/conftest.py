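"""Shared fixtures and independent oracles used across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from fermentype.datamodel_io import PhyloNode, PhyloTree
from fermentype.synthetic_data import GeneratorConfig, gen_its


@pytest.fixture(scope="session")
def its_dataset():
    """The default-shape synthetic ITS collection (29+10+12+1 strains)."""
    return gen_its(GeneratorConfig(seed=101))


@pytest.fixture(scope="session")
def fixtures():
    from fermentype.datamodel_io import load_table_fixtures

    return load_table_fixtures()


def random_additive_tree(rng: np.random.Generator, n_taxa: int) -> PhyloTree:
    """A random binary tree with branch lengths in [0.1, 1.0].

    Its leaf-to-leaf path lengths form an additive distance matrix, the
    exact-recovery oracle for neighbor joining.
    """
    nodes = [PhyloNode(f"t{i}", float(rng.uniform(0.1, 1.0)))
             for i in range(n_taxa)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = PhyloNode(length=float(rng.uniform(0.1, 1.0)))
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = PhyloNode()
    for n in nodes:
        root.add_child(n)
    return PhyloTree(root, rooted=False)


def brute_force_cuts(residues: str, recognition: str, cut_offset: int) -> list[int]:
    """Position-by-position IUPAC sliding-window scan; the digest oracle."""
    from fermentype.datamodel_io import IUPAC_DNA

    sets = [IUPAC_DNA[c] for c in recognition]
    m = len(recognition)
    cuts = set()
    for start in range(len(residues) - m + 1):
        if all(residues[start + k] in sets[k] for k in range(m)):
            cut = start + cut_offset
            if 0 < cut < len(residues):
                cuts.add(cut)
    return sorted(cuts)


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
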