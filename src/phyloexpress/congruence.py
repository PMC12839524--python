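"""Expression dendrogram vs species tree congruence via rooted MAST / Icong.

The top differentially expressed orthogroups (ranked by the maximum |Wald|
statistic across species) define a species x orthogroup profile matrix;
hierarchical clustering of the species profiles (Euclidean distance, complete
linkage — the defaults of the R heatmap function) yields a rooted binary
dendrogram. Congruence with the species tree is the size of the rooted maximum
agreement subtree (MAST), normalized by its null expectation for pairs of
independent random Yule topologies on the same leaf set (Icong), with a
randomization p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .trees import leaves_of, random_yule_topology, simple_from_dendropy

__all__ = [
    "Dendrogram",
    "CongruenceResult",
    "top_de_orthogroups",
    "cluster_species",
    "rooted_mast",
    "icong_test",
]


@dataclass
class Dendrogram:
    """Rooted binary tree over species from hierarchical clustering."""

    topology: tuple  # nested tuples, leaves are species labels
    newick_text: str

    @property
    def leaf_labels(self):
        return sorted(leaves_of(self.topology))

    def newick(self) -> str:
        return self.newick_text


@dataclass
class CongruenceResult:
    mast_size: int
    icong: float
    p: float
    n_null: int
    null_mean: float
    null_sd: float

    def as_dict(self) -> dict:
        return {
            "mast_size": self.mast_size,
            "icong": self.icong,
            "p": self.p,
            "n_null": self.n_null,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
        }


def top_de_orthogroups(de_tables: dict, k: int = 30, *, column: str = "wald") -> list:
    """The k orthogroups with the largest |statistic| in any species.

    Ranking statistic is the maximum of |Wald| over species (NaNs ignored);
    ties break deterministically by orthogroup id.
    """
    mat = pd.DataFrame({sp: tab[column] for sp, tab in de_tables.items()})
    score = mat.abs().max(axis=1, skipna=True).dropna()
    if k > len(score):
        raise ValueError(f"k={k} exceeds the {len(score)} rankable orthogroups")
    order = sorted(score.index, key=lambda og: (-score[og], og))
    return order[:k]


def cluster_species(profile: pd.DataFrame) -> Dendrogram:
    """Cluster species profiles (species x orthogroup) into a rooted dendrogram.

    Euclidean distance, complete linkage. Rows are sorted by species label first
    so exact ties resolve deterministically by label order.
    """
    profile = profile.sort_index()
    labels = list(profile.index)
    if len(labels) < 2:
        raise ValueError("need at least 2 species to cluster")
    Z = hierarchy.linkage(pdist(profile.to_numpy(float)), method="complete")
    root, _ = hierarchy.to_tree(Z, rd=True)

    def build(node):
        if node.is_leaf():
            return labels[node.id], 0.0
        (lt, lh), (rt, rh) = build(node.get_left()), build(node.get_right())
        return (lt, rt), node.dist

    topo, _ = build(root)

    def to_newick(node):
        if node.is_leaf():
            return f"{labels[node.id]}:{node.dist:.10g}"  # placeholder, fixed below
        left, right = node.get_left(), node.get_right()

        def part(child):
            length = node.dist - child.dist
            if child.is_leaf():
                return f"{labels[child.id]}:{node.dist:.10g}"
            return f"{to_newick(child)}:{length:.10g}"

        return f"({part(left)},{part(right)})"

    newick = to_newick(root) + ";"
    return Dendrogram(topology=topo, newick_text=newick)


# ---------------------------------------------------------------------------
# rooted maximum agreement subtree
# ---------------------------------------------------------------------------


def _as_topology(tree):
    if isinstance(tree, Dendrogram):
        return tree.topology
    if isinstance(tree, (tuple, str)):
        return tree
    return simple_from_dendropy(tree)  # SpeciesTree / dendropy.Tree


def _postorder(t):
    out, stack = [], [(t, False)]
    while stack:
        node, done = stack.pop()
        if done or isinstance(node, str):
            out.append(node)
            continue
        stack.append((node, True))
        for child in node:
            stack.append((child, False))
    return out


def rooted_mast(t1, t2) -> int:
    """Size of the rooted maximum agreement subtree of two binary trees.

    Dynamic program over node pairs: an internal/internal entry is the best of
    matching the child subtrees in either pairing or dropping one child on
    either side; a leaf matches a subtree iff its label occurs there. Both
    trees must be binary over the same leaf set.
    """
    a, b = _as_topology(t1), _as_topology(t2)
    la, lb = leaves_of(a), leaves_of(b)
    if la != lb:
        raise ValueError("trees must share the same leaf set")
    nodes_a, nodes_b = _postorder(a), _postorder(b)
    for nodes in (nodes_a, nodes_b):
        for n in nodes:
            if not isinstance(n, str) and len(n) != 2:
                raise ValueError("trees must be binary")
    leafset = {}
    for nodes in (nodes_a, nodes_b):
        for n in nodes:
            if id(n) not in leafset:
                leafset[id(n)] = leaves_of(n)
    M = {}
    for u in nodes_a:
        u_leaf = isinstance(u, str)
        for v in nodes_b:
            v_leaf = isinstance(v, str)
            if u_leaf and v_leaf:
                val = 1 if u == v else 0
            elif u_leaf:
                val = 1 if u in leafset[id(v)] else 0
            elif v_leaf:
                val = 1 if v in leafset[id(u)] else 0
            else:
                u1, u2 = u
                v1, v2 = v
                val = max(
                    M[id(u1), id(v1)] + M[id(u2), id(v2)],
                    M[id(u1), id(v2)] + M[id(u2), id(v1)],
                    M[id(u), id(v1)],
                    M[id(u), id(v2)],
                    M[id(u1), id(v)],
                    M[id(u2), id(v)],
                )
            M[id(u), id(v)] = val
    return M[id(nodes_a[-1]), id(nodes_b[-1])]


def icong_test(
    dendrogram, species_tree, *, n_null: int = 1000, seed: int = 0, log=None
) -> CongruenceResult:
    """Congruence index: observed MAST over its random-tree null expectation.

    The null draws ``n_null`` independent pairs of Yule topologies on the same
    leaves; Icong = mast / mean(null MAST) and the p-value is the add-one
    randomization estimate P = (1 + #{null >= observed}) / (n_null + 1), which
    keeps p in (0, 1].
    """
    if n_null < 100 and log is not None:
        log.warning("n_null=%d is small; p-value resolution is coarse", n_null)
    a, b = _as_topology(dendrogram), _as_topology(species_tree)
    labels = sorted(leaves_of(a))
    if len(labels) < 4:
        raise ValueError("need at least 4 shared leaves")
    observed = rooted_mast(a, b)
    rng = np.random.default_rng(seed)
    null = np.empty(n_null)
    for i in range(n_null):
        r1 = random_yule_topology(labels, rng)
        r2 = random_yule_topology(labels, rng)
        null[i] = rooted_mast(r1, r2)
    null_mean = float(null.mean())
    p = float((1 + (null >= observed).sum()) / (n_null + 1))
    return CongruenceResult(
        mast_size=int(observed),
        icong=float(observed / null_mean),
        p=p,
        n_null=int(n_null),
        null_mean=null_mean,
        null_sd=float(null.std(ddof=1)),
    )
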