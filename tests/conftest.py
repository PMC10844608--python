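"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's own code paths: they walk
dendropy trees directly, so metric tests compare two independent
implementations.
"""

from __future__ import annotations

import random

import dendropy
import numpy as np
import pytest

from phyloflora.phylo_core import Phylogeny


@pytest.fixture
def three_tip_tree() -> Phylogeny:
    return Phylogeny.from_newick("((A:1,B:1):1,C:2);")


def random_ultrametric_tree(n_tips: int, seed: int) -> Phylogeny:
    """Seeded birth-death tree used as a generic random-tree source."""
    from dendropy.model import birthdeath

    tree = birthdeath.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_tips,
        rng=random.Random(seed), repeat_until_success=True,
    )
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"t{i}"
    return Phylogeny(tree)


# ------------------------------------------------------- brute-force oracles


def brute_pd(newick: str, tips) -> float:
    """Faith's PD by explicit root-path union on a fresh dendropy parse."""
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    tree.is_rooted = True
    keep = set(tips)
    total = 0.0
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = {lf.taxon.label for lf in node.leaf_iter()}
        if below & keep:
            total += node.edge.length
    return total


def brute_n_edges_covered(newick: str, tips) -> tuple[int, int]:
    """(covered, total) edge counts for the unit-branch comparison tree."""
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    tree.is_rooted = True
    keep = set(tips)
    covered = total = 0
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        total += 1
        if {lf.taxon.label for lf in node.leaf_iter()} & keep:
            covered += 1
    return covered, total


def brute_mpd(newick: str, tips) -> float:
    """MPD from dendropy's own patristic distance matrix."""
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    tree.is_rooted = True
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    tips = list(tips)
    dists = [
        pdm.patristic_distance(taxa[a], taxa[b])
        for i, a in enumerate(tips) for b in tips[i + 1:]
    ]
    return float(np.mean(dists))


def brute_rpd(newick: str, tips) -> float:
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    tree.is_rooted = True
    total_len = sum(e.length for e in tree.edges() if e.length is not None)
    covered, total = brute_n_edges_covered(newick, tips)
    return (brute_pd(newick, tips) / total_len) / (covered / total)
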