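"""Distance-based tree construction, outgroup rooting and clade queries.

Trees are :class:`dendropy.Tree` objects throughout. The built-in tree builder is
neighbor joining over corrected distances — exact on additive matrices — and any
tree-consuming stage also accepts an externally computed Newick tree (e.g. a
maximum-likelihood tree) instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .identity import IdentityMatrix


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distance matrix with zero diagonal."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if (self.values < 0).any():
            raise ValueError("negative distances")

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(path)


def to_distances(im: IdentityMatrix, correction: str = "p") -> DistanceMatrix:
    """Convert percent identities to evolutionary distances.

    ``p``: the raw proportion of differing sites, (100 − identity)/100.
    ``jc``: Jukes–Cantor correction −(3/4)·ln(1 − 4p/3), which accounts for
    multiple substitutions at a site; where p ≥ 0.75 the correction is undefined
    and the p-distance is used as-is.
    """
    p = (100.0 - im.values) / 100.0
    if correction == "p":
        d = p
    elif correction == "jc":
        d = p.copy()
        ok = p < 0.75
        d[ok] = -0.75 * np.log(1.0 - (4.0 / 3.0) * p[ok])
    else:
        raise ValueError(f"unknown correction {correction!r}")
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(im.ids), d)


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Neighbor joining (Saitou–Nei, Studier–Keppler form) on a distance matrix.

    Deterministic: when several pairs minimise the Q criterion, the pair whose
    (sorted) cluster labels are lexicographically smallest is joined first; the
    label of a cluster is the smallest leaf id it contains. Negative estimated
    branch lengths are clamped to zero and the deficit moved to the sibling
    branch, so path lengths through the join are preserved.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    tns = dendropy.TaxonNamespace(dm.ids)
    nodes: list[dendropy.Node] = []
    for rid in dm.ids:
        nd = dendropy.Node(taxon=tns.get_taxon(rid))
        nodes.append(nd)
    labels = list(dm.ids)  # tie-break label = min leaf id in cluster
    D = dm.values.astype(float).copy()

    def pick_pair(D: np.ndarray, labels: list[str]) -> tuple[int, int]:
        m = D.shape[0]
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cand = np.argwhere(Q <= qmin + 1e-12)
        best = None
        for i, j in cand:
            if i >= j:
                continue
            key = tuple(sorted((labels[i], labels[j])))
            if best is None or key < best[0]:
                best = (key, (int(i), int(j)))
        return best[1]

    while len(nodes) > 3:
        m = len(nodes)
        i, j = pick_pair(D, labels)
        r = D.sum(axis=1)
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        dnew = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.empty((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = dnew[keep]
        D2[:-1, -1] = dnew[keep]
        D2[-1, -1] = 0.0
        nodes = [nodes[k] for k in keep] + [parent]
        labels = [labels[k] for k in keep] + [min(labels[i], labels[j])]
        D = D2

    # final join: three clusters around the central (unrooted) node
    center = dendropy.Node()
    a, b, c = 0, 1, 2
    lens = [
        0.5 * (D[a, b] + D[a, c] - D[b, c]),
        0.5 * (D[a, b] + D[b, c] - D[a, c]),
        0.5 * (D[a, c] + D[b, c] - D[a, b]),
    ]
    for nd, ln in zip(nodes, lens):
        center.add_child(nd)
        nd.edge.length = max(0.0, ln)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = center
    tree.is_rooted = False
    return tree


def leaf_labels(node: dendropy.Node) -> set[str]:
    return {leaf.taxon.label for leaf in node.leaf_iter()}


def tree_leaf_labels(tree: dendropy.Tree) -> set[str]:
    return {leaf.taxon.label for leaf in tree.leaf_node_iter()}


def root_on_outgroup(tree: dendropy.Tree, outgroup: str) -> dendropy.Tree:
    """Root a copy of the tree at the midpoint of the outgroup's pendant edge."""
    rooted = tree.clone(depth=1)
    leaf = None
    for lf in rooted.leaf_node_iter():
        if lf.taxon.label == outgroup:
            leaf = lf
            break
    if leaf is None:
        raise KeyError(f"outgroup {outgroup!r} is not a leaf of the tree")
    elen = leaf.edge.length if leaf.edge.length is not None else 0.0
    rooted.reroot_at_edge(leaf.edge, length1=elen / 2.0, length2=elen / 2.0,
                          update_bipartitions=False)
    rooted.is_rooted = True
    return rooted


@dataclass
class CladeQuery:
    rooted_tree: dendropy.Tree
    mrca: dendropy.Node
    mrca_leaves: set[str]
    monophyletic: bool


def root_and_query(tree: dendropy.Tree, outgroup: str, leafset: set[str]) -> CladeQuery:
    """Root on the outgroup and test whether ``leafset`` forms a clade.

    Returns the rooted tree, the most recent common ancestor of ``leafset``, the
    full leaf set beneath that ancestor, and whether it equals ``leafset``.
    """
    present = tree_leaf_labels(tree)
    unknown = set(leafset) - present
    if unknown:
        raise KeyError(f"leaf id(s) not in tree: {sorted(unknown)}")
    if outgroup in leafset:
        raise ValueError("outgroup cannot be part of the queried leaf set")
    rooted = root_on_outgroup(tree, outgroup)
    if len(leafset) == 1:
        (only,) = leafset
        mrca = next(lf for lf in rooted.leaf_node_iter() if lf.taxon.label == only)
    else:
        mrca = rooted.mrca(taxon_labels=sorted(leafset))
    under = leaf_labels(mrca)
    return CladeQuery(
        rooted_tree=rooted, mrca=mrca, mrca_leaves=under,
        monophyletic=(under == set(leafset)),
    )


def ingroup_root(rooted: dendropy.Tree, outgroup: str) -> dendropy.Node:
    """The child of the root that does not contain the outgroup."""
    children = rooted.seed_node.child_nodes()
    for ch in children:
        if outgroup not in leaf_labels(ch):
            return ch
    raise ValueError("no outgroup-free child under the root")


def path_distance_matrix(tree: dendropy.Tree) -> DistanceMatrix:
    """Leaf-to-leaf path-length distances (used to check additivity)."""
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(t.label for t in tree.taxon_namespace
                    if any(l.taxon is t for l in tree.leaf_node_iter()))
    n = len(labels)
    taxa = {t.label: t for t in tree.taxon_namespace}
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
            vals[i, j] = vals[j, i] = d
    return DistanceMatrix(labels, vals)
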