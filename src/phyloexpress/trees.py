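"""Lightweight rooted-topology helpers shared by congruence and simulation code.

Rooted binary topologies are represented as nested structures: a leaf is its
label (str), an internal node is a 2-tuple of child subtrees. This is the
working representation for the MAST dynamic program and the Yule null model;
:class:`~phyloexpress.io.SpeciesTree` (dendropy-backed) remains the interface
type and converters are provided both ways.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "simple_from_dendropy",
    "leaves_of",
    "canonical",
    "restrict",
    "random_yule_topology",
]


def simple_from_dendropy(tree) -> tuple | str:
    """Convert a dendropy tree (or SpeciesTree) to the nested-tuple form."""
    t = getattr(tree, "tree", tree)

    def rec(node):
        kids = node.child_nodes()
        if not kids:
            return node.taxon.label
        return tuple(rec(k) for k in kids)

    return rec(t.seed_node)


def leaves_of(node) -> frozenset:
    if isinstance(node, str):
        return frozenset([node])
    out = frozenset()
    for child in node:
        out |= leaves_of(child)
    return out


def canonical(node):
    """Order-insensitive canonical form of a rooted topology (hashable)."""
    if isinstance(node, str):
        return node
    return tuple(sorted((canonical(c) for c in node), key=repr))


def restrict(node, keep: frozenset):
    """Topology induced on ``keep``: prune other leaves, suppress unary nodes.

    Returns None if no kept leaf lies under ``node``.
    """
    if isinstance(node, str):
        return node if node in keep else None
    kids = [r for r in (restrict(c, keep) for c in node) if r is not None]
    if not kids:
        return None
    if len(kids) == 1:
        return kids[0]
    return tuple(kids)


def random_yule_topology(labels, rng: np.random.Generator):
    """Random rooted binary topology under the Yule (pure-birth) process.

    Built by repeatedly splitting a uniformly chosen extant tip (Yule–Harding);
    labels are shuffled onto tips, so the distribution is exchangeable.
    """
    labels = list(labels)
    if len(labels) < 2:
        raise ValueError("need at least 2 labels")
    perm = [labels[i] for i in rng.permutation(len(labels))]
    root = [perm[0], perm[1]]
    # tip registry: (parent node, slot index) of every current leaf
    tips = [(root, 0), (root, 1)]
    for lab in perm[2:]:
        i = int(rng.integers(len(tips)))
        parent, slot = tips[i]
        new = [parent[slot], lab]
        parent[slot] = new
        tips[i] = (new, 0)
        tips.append((new, 1))

    def freeze(node):
        if isinstance(node, str):
            return node
        return tuple(freeze(c) for c in node)

    return freeze(root)
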