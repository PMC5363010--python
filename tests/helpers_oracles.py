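"""Independent brute-force oracles used by unit and acceptance tests.

Each oracle is written from first principles, sharing no code with the
implementation it checks.
"""

from itertools import product

import numpy as np
from Bio.Seq import Seq

NT = "ACGT"
AA20 = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# ORF enumeration oracle: translate every frame wholesale, split on stops
# ---------------------------------------------------------------------------

def orf_oracle(contig: str, min_aa: int):
    """All (strand, nt_start, nt_end, protein, starts_with_met) tuples.

    Segments between stop codons (or frame edges) are reported whole;
    a segment not starting with Met but containing one additionally
    yields the Met-initiated suffix.
    """
    results = set()
    n = len(contig)
    for strand in "+-":
        seq = contig if strand == "+" else str(Seq(contig).reverse_complement())
        for frame in range(3):
            usable = (n - frame) // 3
            if usable == 0:
                continue
            prot = str(Seq(seq[frame : frame + 3 * usable]).translate())
            start = 0
            for seg in prot.split("*"):
                starts = [start] if seg else []
                if seg and not seg.startswith("M") and "M" in seg:
                    starts.append(start + seg.index("M"))
                for s in starts:
                    sub = prot[s : start + len(seg)]
                    if len(sub) >= min_aa:
                        lo = frame + 3 * s
                        hi = frame + 3 * (start + len(seg))
                        if strand == "+":
                            coords = (lo, hi)
                        else:
                            coords = (n - hi, n - lo)
                        results.add((strand, coords[0], coords[1], sub, sub.startswith("M")))
                start += len(seg) + 1
    return results


# ---------------------------------------------------------------------------
# Smith-Waterman affine-gap oracle: explicit three-matrix DP
# ---------------------------------------------------------------------------

def sw_oracle(a: str, b: str, matrix, gap_open: float, gap_extend: float) -> float:
    """Optimal local alignment score; gap of length k costs
    gap_open + (k-1)*gap_extend (both arguments negative)."""
    n, m = len(a), len(b)
    neg = -1e18
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), neg)  # gap in a (deletion in b direction)
    F = np.full((n + 1, m + 1), neg)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] + gap_open, E[i, j - 1] + gap_extend)
            F[i, j] = max(H[i - 1, j] + gap_open, F[i - 1, j] + gap_extend)
            s = matrix[a[i - 1], b[j - 1]]
            H[i, j] = max(0.0, H[i - 1, j - 1] + s, E[i, j], F[i, j])
            best = max(best, H[i, j])
    return best


# ---------------------------------------------------------------------------
# small-parsimony oracle: exhaustive minimization over internal labelings
# ---------------------------------------------------------------------------

def parsimony_oracle(tree_nested, leaf_states: dict[str, str | None]) -> int:
    """Minimum changes for one character on a tree given as nested tuples.

    ``tree_nested`` is a leaf label or a tuple of subtrees.  Missing
    leaves (state None) are free.  Internal nodes are enumerated over
    the observed states (sufficient for unit-cost parsimony).
    """
    observed = sorted({s for s in leaf_states.values() if s is not None})
    if not observed:
        return 0

    internals: list[tuple] = []

    def collect(node):
        if isinstance(node, tuple):
            internals.append(node)
            for child in node:
                collect(child)

    collect(tree_nested)
    if not internals:
        return 0

    def cost(node, assignment) -> tuple[int, str | None]:
        """Return (changes within subtree, state at node)."""
        if not isinstance(node, tuple):
            return 0, leaf_states[node]
        state = assignment[id(node)]
        total = 0
        for child in node:
            sub, child_state = cost(child, assignment)
            total += sub
            if child_state is not None and child_state != state:
                total += 1
        return total, state

    best = None
    for combo in product(observed, repeat=len(internals)):
        assignment = {id(node): s for node, s in zip(internals, combo)}
        total, _ = cost(tree_nested, assignment)
        if best is None or total < best:
            best = total
    return best


def nested_to_newick(node, brlen=1.0) -> str:
    def fmt(n):
        if isinstance(n, tuple):
            return "(" + ",".join(fmt(c) for c in n) + f"):{brlen}"
        return f"{n}:{brlen}"
    return fmt(node) + ";"


# ---------------------------------------------------------------------------
# random additive distance matrices from known trees
# ---------------------------------------------------------------------------

def random_tree_distances(n_tips: int, rng: np.random.Generator):
    """A random binary tree with branch lengths in [0.1, 1.1]; returns
    (labels, distance matrix, set of nontrivial bipartitions)."""
    labels = [f"t{i}" for i in range(n_tips)]
    paths = {l: {l: 0.0} for l in labels}
    # clusters carry (leaf set, distance of each leaf to the cluster root)
    nodes = [(l, frozenset([l]), {l: 0.0}) for l in labels]
    bipartitions = set()
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        rb = nodes.pop(j)
        ra = nodes.pop(i)
        la = 0.1 + rng.random()
        lb = 0.1 + rng.random()
        depths = {l: d + la for l, d in ra[2].items()}
        depths.update({l: d + lb for l, d in rb[2].items()})
        leaves = ra[1] | rb[1]
        nodes.append((None, leaves, depths))
        for side in (ra[1], rb[1]):
            if 1 < len(side) < n_tips - 1:
                bipartitions.add(side)
        for x in ra[2]:
            for y in rb[2]:
                paths.setdefault(x, {})[y] = ra[2][x] + la + rb[2][y] + lb
                paths.setdefault(y, {})[x] = paths[x][y]
    mat = np.array([[paths[x][y] if x != y else 0.0 for y in labels] for x in labels])
    # canonicalize bipartitions: drop sides containing t0
    canon = set()
    full = frozenset(labels)
    for side in bipartitions:
        canon.add(side if "t0" not in side else full - side)
    return labels, mat, canon


def tree_bipartitions(tree, labels) -> set[frozenset]:
    """Canonical nontrivial bipartitions of a dendropy tree (sides not
    containing the lexicographically smallest label)."""
    full = frozenset(labels)
    anchor = min(labels)
    out = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        side = below if anchor not in below else full - below
        if 1 < len(side) < len(full) - 1:
            out.add(side)
    return out
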