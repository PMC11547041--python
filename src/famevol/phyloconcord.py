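"""Distance-based phylogeny and subfamily-concordance statistics.

The family tree is built by Saitou-Nei neighbor joining on protein p-distances
from the family MSA.  The claim exercised downstream is not any particular
branch-length estimate but *subfamily clustering*: on an unrooted tree a
subfamily is concordant when some edge's bipartition separates exactly its
members (a "clan" in unrooted-tree terminology).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DistanceMatrix",
    "ConcordanceReport",
    "pdistance_matrix",
    "neighbor_joining",
    "nj_join_order",
    "subfamily_concordance",
]


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray
    low_overlap_pairs: list[tuple[str, str]]

    def __post_init__(self):
        m = self.matrix
        if m.shape[0] != m.shape[1] or m.shape[0] != len(self.ids):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(m), 0.0):
            raise ValueError("nonzero diagonal")
        if not np.isfinite(m).all():
            raise ValueError("non-finite distances")


def pdistance_matrix(msa: list[str], ids: list[str] | None = None,
                     min_overlap: int = 50) -> DistanceMatrix:
    """Pairwise p-distance with pairwise gap deletion.

    Distance = differing residue pairs / columns where both rows hold a
    residue.  Pairs with fewer than ``min_overlap`` comparable columns are
    flagged (and an all-gap pair is an error).
    """
    n = len(msa)
    if ids is None:
        ids = [f"seq{i}" for i in range(n)]
    arr = np.array([list(row) for row in msa])
    gap = arr == "-"
    D = np.zeros((n, n))
    flagged = []
    for i in range(n):
        for j in range(i + 1, n):
            comparable = ~(gap[i] | gap[j])
            m = int(comparable.sum())
            if m == 0:
                raise ValueError(f"no comparable columns between {ids[i]} and {ids[j]}")
            diff = int((arr[i][comparable] != arr[j][comparable]).sum())
            D[i, j] = D[j, i] = diff / m
            if m < min_overlap:
                flagged.append((ids[i], ids[j]))
    return DistanceMatrix(ids=list(ids), matrix=D, low_overlap_pairs=flagged)


class _Node:
    __slots__ = ("name", "children")  # children: list of (node, branch_length)

    def __init__(self, name=None):
        self.name = name
        self.children = []

    def newick(self) -> str:
        return self._render() + ";"

    def _render(self) -> str:
        if not self.children:
            return self.name
        inner = ",".join(f"{c._render()}:{bl:.6f}" for c, bl in self.children)
        return f"({inner})"


def _nj_core(D: np.ndarray):
    """Run NJ; returns (joins, root_node).

    ``joins`` is [(i, j, new_index)] in join order over cluster indices, where
    leaves are 0..n-1 and new clusters continue the numbering; ties in the
    Q-criterion are broken by the smallest (i, j) index pair.
    """
    n = D.shape[0]
    if n < 2:
        raise ValueError("need >= 2 taxa")
    active = list(range(n))
    dist = {(i, j): float(D[i, j]) for i in range(n) for j in range(i + 1, n)}

    def d(i, j):
        return dist[(i, j) if i < j else (j, i)]

    nodes = {i: _Node(name=str(i)) for i in range(n)}
    joins = []
    nxt = n
    while len(active) > 2:
        r = len(active)
        R = {i: sum(d(i, k) for k in active if k != i) for i in active}
        best = None
        for ai in range(r):
            for aj in range(ai + 1, r):
                i, j = active[ai], active[aj]
                q = (r - 2) * d(i, j) - R[i] - R[j]
                key = (q, i, j)
                if best is None or key < best:
                    best = key
        _, i, j = best
        dij = d(i, j)
        li = dij / 2 + (R[i] - R[j]) / (2 * (r - 2))
        lj = dij - li
        if li < 0 or lj < 0:
            warnings.warn("negative NJ branch length clamped to 0")
            li, lj = max(li, 0.0), max(lj, 0.0)
        new = _Node()
        new.children = [(nodes[i], li), (nodes[j], lj)]
        nodes[nxt] = new
        for k in active:
            if k in (i, j):
                continue
            dist[(k, nxt) if k < nxt else (nxt, k)] = (d(i, k) + d(j, k) - dij) / 2
        active = [k for k in active if k not in (i, j)] + [nxt]
        joins.append((i, j, nxt))
        nxt += 1
    i, j = active
    dij = d(i, j)
    root = _Node()
    root.children = [(nodes[i], dij / 2), (nodes[j], dij / 2)]
    joins.append((i, j, nxt))
    return joins, root


def nj_join_order(D: np.ndarray) -> list[tuple[int, int, int]]:
    """Neighbor-joining cluster-merge order (used as an MSA guide tree)."""
    joins, _ = _nj_core(np.asarray(D, dtype=float))
    return joins


def neighbor_joining(D: DistanceMatrix) -> str:
    """Saitou-Nei NJ tree as a newick string with branch lengths.

    The unrooted tree is emitted rooted at the midpoint of the final join edge
    (leaf-to-leaf path lengths are unchanged by this presentation choice).
    Negative branch-length estimates are clamped to zero with a warning.
    """
    if len(D.ids) < 3:
        raise ValueError("need >= 3 taxa")
    joins, root = _nj_core(D.matrix)
    # replace numeric leaf names with taxon ids
    stack = [root]
    while stack:
        node = stack.pop()
        for child, _ in node.children:
            stack.append(child)
        if not node.children:
            node.name = D.ids[int(node.name)]
    return root.newick()


@dataclass
class ConcordanceReport:
    monophyletic: dict[str, bool]
    fraction_monophyletic: float
    singletons: list[str]


def _leaf_sets(newick: str) -> tuple[set[str], list[set[str]]]:
    """All taxa and the leaf set under every internal edge of a newick tree."""
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    all_taxa = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    sides = []
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        sides.append({leaf.taxon.label for leaf in node.leaf_iter()})
    return all_taxa, sides


def subfamily_concordance(newick: str, labels: dict[str, str]) -> ConcordanceReport:
    """Unrooted clan test per subfamily.

    A subfamily is concordant iff some edge bipartition separates exactly its
    members from everything else.  Subfamilies with a single member are trivial
    clans and are excluded from the denominator (reported separately).
    """
    all_taxa, sides = _leaf_sets(newick)
    missing = set(all_taxa) - set(labels)
    if missing:
        raise ValueError(f"unlabeled leaves: {sorted(missing)[:5]}")
    groups: dict[str, set[str]] = {}
    for taxon, lab in labels.items():
        if taxon in all_taxa:
            groups.setdefault(lab, set()).add(taxon)
    flags: dict[str, bool] = {}
    singletons = []
    for lab, members in sorted(groups.items()):
        if len(members) < 2:
            singletons.append(lab)
            continue
        complement = all_taxa - members
        flags[lab] = any(s == members or s == complement for s in sides)
    denom = len(flags)
    frac = (sum(flags.values()) / denom) if denom else float("nan")
    return ConcordanceReport(monophyletic=flags,
                             fraction_monophyletic=frac,
                             singletons=singletons)
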