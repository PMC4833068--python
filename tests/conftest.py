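"""Shared fixtures: small hand-built trees plus random-tree generators."""

import numpy as np
import pytest

from phyloforge.seqs import TaxonMap
from phyloforge.trees import Node, PhyloTree, read_newick


@pytest.fixture
def quartet():
    """((A,B),(C,D)) with unit-ish branch lengths."""
    return read_newick("((A:0.1,B:0.2):0.1,(C:0.3,D:0.4):0.2);")


@pytest.fixture
def simple_taxa():
    return TaxonMap(
        ingroup={"A", "B", "C", "D", "E", "F", "G", "H"},
        outgroup={"Aq", "Og"},
        habit={t: ("W" if t in {"A", "B"} else "H")
               for t in ["A", "B", "C", "D", "E", "F", "G", "H"]},
        root_taxon="Aq")


def random_tree(rng: np.random.Generator, labels, min_len=0.01, max_len=0.5
                ) -> PhyloTree:
    """Random binary topology by successive joins, uniform branch lengths."""
    nodes = [Node(label=l, length=float(rng.uniform(min_len, max_len)))
             for l in labels]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = Node(length=float(rng.uniform(min_len, max_len)),
                      support=float(rng.uniform(0, 100)))
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(parent)
    root = Node()
    for n in nodes:
        root.add_child(n)
    return PhyloTree(root, rooted=False)


def random_labels(rng: np.random.Generator, n_taxa: int, max_copies: int = 3):
    """Tip labels taxon@copy with random per-taxon multiplicity >= 1."""
    labels = []
    for i in range(n_taxa):
        for c in range(int(rng.integers(1, max_copies + 1))):
            labels.append(f"T{i}@{c}")
    return labels
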