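"""Distance-based gene genealogy: p-distances, neighbor joining,
outgroup rooting, monophyly queries and bootstrap support.

Neighbor joining is implemented here (with a deterministic
lexicographic tie-break on the Q matrix) rather than delegated, so
that tree construction is byte-reproducible; trees are handled as
dendropy objects and serialized as newick.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

__all__ = [
    "DistanceMatrix",
    "p_distance",
    "nj_tree",
    "root_with_outgroup",
    "is_monophyletic",
    "bootstrap_support",
]


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    matrix: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self):
        m = self.matrix
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(m, m.T) or not np.allclose(np.diag(m), 0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")


def p_distance(rows: dict[str, str], correction: str = "none") -> DistanceMatrix:
    """Pairwise proportion of differing sites, gap-excluded.

    Only columns where both rows are ungapped are compared; a pair with
    no comparable column is an error.  ``correction='jc'`` applies the
    Jukes-Cantor transform -3/4 ln(1 - 4p/3).
    """
    labels = tuple(rows)
    if len(labels) < 2:
        raise ValueError("need at least 2 rows")
    arr = np.array([list(rows[l]) for l in labels])
    ok = (arr != "-") & (arr != ".")
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ok[i] & ok[j]
            denom = int(both.sum())
            if denom == 0:
                raise ValueError(f"no comparable columns between {labels[i]} and {labels[j]}")
            p = float((arr[i][both] != arr[j][both]).sum()) / denom
            if correction == "jc":
                if p >= 0.75:
                    raise ValueError("p-distance too large for Jukes-Cantor correction")
                p = -0.75 * np.log(1 - 4 * p / 3)
            d[i, j] = d[j, i] = p
    return DistanceMatrix(labels, d)


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Neighbor-joining tree (unrooted, trifurcation at the seed node).

    Ties in the Q matrix are broken by the lexicographically smallest
    pair of representative tip labels, so output is deterministic.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    active = list(range(n))
    reps = {i: dm.labels[i] for i in active}  # smallest tip label in cluster
    nwk = {i: dm.labels[i] for i in active}
    d = {(i, j): float(dm.matrix[i, j]) for i in range(n) for j in range(n)}
    next_id = n

    def dist(i, j):
        return d[(i, j)] if i <= j else d[(j, i)]

    while len(active) > 3:
        m = len(active)
        r = {i: sum(dist(i, k) for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * dist(i, j) - r[i] - r[j]
                key = (q, tuple(sorted((reps[i], reps[j]))))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        dij = dist(i, j)
        li = dij / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        u = next_id
        next_id += 1
        for k in active:
            if k in (i, j):
                continue
            d[(min(u, k), max(u, k))] = (dist(i, k) + dist(j, k) - dij) / 2
        nwk[u] = f"({nwk[i]}:{li:.10g},{nwk[j]}:{lj:.10g})"
        reps[u] = min(reps[i], reps[j])
        active = [k for k in active if k not in (i, j)] + [u]

    a, b, c = active
    la = (dist(a, b) + dist(a, c) - dist(b, c)) / 2
    lb = (dist(a, b) + dist(b, c) - dist(a, c)) / 2
    lc = (dist(a, c) + dist(b, c) - dist(a, b)) / 2
    newick = f"({nwk[a]}:{la:.10g},{nwk[b]}:{lb:.10g},{nwk[c]}:{lc:.10g});"
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    tree.is_rooted = False
    return tree


def leaf_labels(tree: dendropy.Tree) -> set[str]:
    return {leaf.taxon.label for leaf in tree.leaf_node_iter()}


def root_with_outgroup(tree: dendropy.Tree, outgroup_tips: list[str]) -> dendropy.Tree:
    """Root on the branch separating the outgroup from the ingroup.

    The outgroup must form a clade of the unrooted tree; if it does
    not, a ValueError reports the offending tip set rather than
    forcing a root.
    """
    outgroup = set(outgroup_tips)
    all_tips = leaf_labels(tree)
    if not outgroup <= all_tips:
        raise ValueError(f"outgroup tips missing from tree: {sorted(outgroup - all_tips)}")
    if outgroup == all_tips:
        raise ValueError("outgroup cannot be the whole tip set")
    tree = tree.clone(depth=1)
    # anchor the traversal outside the outgroup so MRCA is meaningful
    ingroup_tip = sorted(all_tips - outgroup)[0]
    anchor = tree.find_node_with_taxon_label(ingroup_tip)
    tree.reroot_at_edge(anchor.edge, update_bipartitions=False)
    if len(outgroup) == 1:
        mrca = tree.find_node_with_taxon_label(next(iter(outgroup)))
    else:
        mrca = tree.mrca(taxon_labels=sorted(outgroup))
        under = {leaf.taxon.label for leaf in mrca.leaf_iter()}
        if under != outgroup:
            raise ValueError(
                "outgroup is not a clade in the unrooted tree "
                f"(smallest containing clade has {len(under)} tips)"
            )
    edge = mrca.edge
    half = (edge.length or 0.0) / 2
    tree.reroot_at_edge(edge, length1=half, length2=half, update_bipartitions=False)
    tree.is_rooted = True
    return tree


def is_monophyletic(tree: dendropy.Tree, tips: list[str]) -> bool:
    """True iff ``tips`` is exactly the leaf set of some node of the
    rooted tree."""
    tipset = set(tips)
    if not tipset:
        raise ValueError("empty tip set")
    if not tipset <= leaf_labels(tree):
        raise ValueError("tips not present in tree")
    if len(tipset) == 1:
        return True
    mrca = tree.mrca(taxon_labels=sorted(tipset))
    under = {leaf.taxon.label for leaf in mrca.leaf_iter()}
    return under == tipset


def _bipartitions(tree: dendropy.Tree, all_labels: frozenset[str]) -> set[frozenset[str]]:
    """Canonical non-trivial bipartitions: the side NOT containing the
    lexicographically smallest label."""
    anchor = min(all_labels)
    out: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        side = below if anchor not in below else all_labels - below
        if 1 < len(side) < len(all_labels) - 1:
            out.add(side)
    return out


def bootstrap_support(
    rows: dict[str, str],
    replicates: int = 100,
    seed: int = 0,
    correction: str = "none",
) -> dendropy.Tree:
    """NJ tree with clade support from column-resampled replicates.

    Support (fraction of replicates containing each bipartition of the
    point-estimate tree) is written to internal node labels.
    """
    rng = np.random.default_rng(seed)
    base = nj_tree(p_distance(rows, correction))
    labels = frozenset(rows)
    ncol = len(next(iter(rows.values())))
    counts: dict[frozenset[str], int] = {bp: 0 for bp in _bipartitions(base, labels)}
    for _ in range(replicates):
        cols = rng.integers(0, ncol, size=ncol)
        resampled = {k: "".join(v[c] for c in cols) for k, v in rows.items()}
        try:
            rep = nj_tree(p_distance(resampled, correction))
        except ValueError:  # a pair with no comparable columns in this draw
            continue
        seen = _bipartitions(rep, labels)
        for bp in counts:
            if bp in seen:
                counts[bp] += 1
    anchor = min(labels)
    for node in base.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        side = below if anchor not in below else labels - below
        if side in counts:
            node.label = f"{counts[side] / replicates:.2f}"
    return base
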