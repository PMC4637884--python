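"""Shared fixtures and oracles for the test suite."""

from __future__ import annotations

import random

import pytest

from ervphylo.simulate import default_host_table
from ervphylo.treeio import AnnotatedTree, HostTable, leaf_label


@pytest.fixture
def small_hosts() -> HostTable:
    """A minimal host table: two bats (one family), two rodents, one whale."""
    return HostTable.from_records(
        [
            ("bat1", "Pteropodidae", "Chiroptera", 100, 40),
            ("bat2", "Pteropodidae", "Chiroptera", 120, 50),
            ("rat1", "Muridae", "Rodentia", 200, 300),
            ("rat2", "Muridae", "Rodentia", 180, 280),
            ("whale1", "Delphinidae", "Cetacea", 60, 20),
        ]
    )


@pytest.fixture
def panel_hosts() -> HostTable:
    """The simulator's full synthetic host panel (45 species, 6 groups)."""
    return default_host_table()


def canonical_form(tree: AnnotatedTree):
    """Rotation-invariant canonical form: the tree-isomorphism oracle.

    Two trees are isomorphic with identical supports, labels and branch
    lengths iff their canonical forms are equal.
    """

    def rec(node):
        length = None if node.edge is None or node.edge.length is None else round(
            node.edge.length, 9
        )
        if node.is_leaf():
            return ("leaf", leaf_label(node), length)
        kids = tuple(sorted((rec(c) for c in node.child_nodes()), key=repr))
        return ("node", AnnotatedTree.support(node), length, kids)

    return rec(tree.root)


def random_newick(
    rng: random.Random,
    species_pool: list[str],
    n_tips: int,
    support_choices=(0.5, 0.6, 0.75, 0.9, 0.95, 1.0, None),
) -> str:
    """A random rooted binary Newick string over the given species pool.

    Tips draw species with replacement (so same-host clades arise), internal
    nodes draw supports from ``support_choices`` (None = missing support).
    """
    items = [
        f"{rng.choice(species_pool)}|t{i}:{rng.uniform(0.01, 1.0):.4f}"
        for i in range(n_tips)
    ]
    counter = 0
    while len(items) > 1:
        a = items.pop(rng.randrange(len(items)))
        b = items.pop(rng.randrange(len(items))) if len(items) else None
        support = rng.choice(support_choices)
        sup = "" if support is None else f"{support}"
        items.append(f"({a},{b}){sup}:{rng.uniform(0.01, 1.0):.4f}")
        counter += 1
    return items[0] + ";"
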