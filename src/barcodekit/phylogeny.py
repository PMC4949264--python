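"""Distance-based phylogeny: neighbor joining, bootstrap, outgroup rooting.

Neighbor joining (NJ) on K2P distances gives a deterministic, desk-scale
tree whose deep, well-separated groups are the object of interest here;
it is consistent on additive matrices (it recovers the generating tree
exactly). Clade confidence comes from the nonparametric bootstrap:
alignment columns are resampled with replacement, the distance matrix and
NJ tree recomputed, and each internal edge of the full-data tree is
scored by the percentage of replicate trees containing the same leaf
bipartition. An externally built tree (e.g. a maximum-likelihood tree)
can be imported from Newick and compared on the same bipartition basis.

Conventions: ties in the NJ agglomeration choose the pair whose
(smallest-leaf-label, largest) pair sorts first; negative NJ branch
lengths are clamped to zero with the deficit moved to the sister branch,
preserving the path length between the joined nodes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .k2p import DistanceMatrix, k2p_from_codes
from .msa import AlignmentMatrix

__all__ = [
    "Node",
    "PhyloTree",
    "nj_tree",
    "bootstrap_supports",
    "root_at_outgroup",
    "write_newick",
    "read_newick",
]


@dataclass
class Node:
    """Tree node; ``length`` is the branch to the parent, ``support`` in %."""

    name: str | None = None
    children: list["Node"] = field(default_factory=list)
    length: float = 0.0
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        if self.is_leaf:
            return [self]
        out: list[Node] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def clade_names(self) -> frozenset:
        return frozenset(leaf.name for leaf in self.leaves())


@dataclass
class PhyloTree:
    """A (possibly unrooted, i.e. trifurcating-root) tree over record IDs."""

    root: Node
    rooted: bool = False

    def leaf_names(self) -> frozenset:
        return self.root.clade_names()

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial leaf bipartitions, canonicalized.

        Each internal edge splits the leaves in two; the split is
        represented by the side *not* containing the alphabetically
        smallest leaf, so representations are comparable across trees
        and rootings.
        """
        full = self.leaf_names()
        ref = min(full)
        out: set[frozenset] = set()

        def visit(node: Node, is_root: bool) -> None:
            for child in node.children:
                if not child.is_leaf:
                    visit(child, False)
                clade = child.clade_names()
                canon = clade if ref not in clade else full - clade
                if 2 <= len(canon) <= len(full) - 2:
                    out.add(canon)

        visit(self.root, True)
        return out

    def to_newick(self) -> str:
        return write_newick(self)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    """Clamp negative branch lengths, moving the deficit to the sister."""
    if li < 0.0:
        lj = max(0.0, lj + li)
        li = 0.0
    elif lj < 0.0:
        li = max(0.0, li + lj)
        lj = 0.0
    return li + 0.0, lj + 0.0  # normalize -0.0


def _nj(ids: list[str], D: np.ndarray) -> Node:
    """Canonical NJ; returns a trifurcating (unrooted-style) root for n>=4."""
    n = len(ids)
    nodes = [Node(name=i) for i in ids]
    labels = list(ids)  # smallest leaf label per active cluster
    D = D.astype(float).copy()

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        # rounding makes Q only near-symmetric; search the upper triangle
        Q[np.tril_indices(m)] = np.inf
        qmin = Q.min()
        cands = [(tuple(sorted((labels[i], labels[j]))), i, j)
                 for i, j in zip(*np.where(Q == qmin))]
        _, i, j = min(cands)
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        li, lj = _clamp_pair(li, lj)
        nodes[i].length, nodes[j].length = li, lj
        new = Node(children=[nodes[i], nodes[j]])
        dnew = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.empty((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = dnew[keep]
        D2[-1, -1] = 0.0
        nodes = [nodes[k] for k in keep] + [new]
        labels = [labels[k] for k in keep] + [min(labels[i], labels[j])]
        D = D2

    if len(nodes) == 3:
        d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
        l0 = 0.5 * (d01 + d02 - d12)
        l1 = 0.5 * (d01 + d12 - d02)
        l2 = 0.5 * (d02 + d12 - d01)
        for node, ln in zip(nodes, (l0, l1, l2)):
            node.length = max(0.0, ln)
        order = np.argsort(labels, kind="stable")
        return Node(children=[nodes[k] for k in order])
    # n == 2 handled by caller; n == 3 returns above
    raise AssertionError("unreachable")


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Neighbor-joining tree from a distance matrix (>=3 records)."""
    if len(dm.ids) < 3:
        raise ValueError("need >=3 records for a tree")
    if not np.all(np.isfinite(dm.values)):
        raise ValueError("non-finite distances")
    return PhyloTree(_nj(list(dm.ids), dm.values), rooted=False)


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def bootstrap_supports(aln: AlignmentMatrix,
                       species_of: dict[str, str] | None = None,
                       n_reps: int = 1000,
                       seed: int | np.random.Generator = 0,
                       max_retries: int = 10) -> PhyloTree:
    """NJ tree with bootstrap percentages on its internal edges.

    Columns are resampled with replacement to the original alignment
    length; a replicate whose K2P matrix is undefined (saturation or no
    comparable sites for some pair) is redrawn, up to ``max_retries``
    times, after which the run errors out. Fully reproducible for a
    given seed.
    """
    if len(aln.ids) < 3:
        raise ValueError("need >=3 rows")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    codes = aln.to_codes()
    n_cols = codes.shape[1]

    d, *_ = k2p_from_codes(codes)
    if not np.all(np.isfinite(d)):
        raise ValueError("K2P undefined on the full alignment")
    tree = PhyloTree(_nj(list(aln.ids), d), rooted=False)

    counts: dict[frozenset, int] = {bp: 0 for bp in tree.bipartitions()}
    for _ in range(n_reps):
        for attempt in range(max_retries + 1):
            cols = rng.integers(0, n_cols, size=n_cols)
            db, *_ = k2p_from_codes(codes[:, cols])
            if np.all(np.isfinite(db)):
                break
        else:
            raise RuntimeError(
                f"replicate saturated {max_retries + 1} times in a row")
        rep = PhyloTree(_nj(list(aln.ids), db), rooted=False)
        for bp in rep.bipartitions():
            if bp in counts:
                counts[bp] += 1

    full = tree.leaf_names()
    ref = min(full)

    def annotate(node: Node) -> None:
        for child in node.children:
            if not child.is_leaf:
                clade = child.clade_names()
                canon = clade if ref not in clade else full - clade
                if canon in counts:
                    child.support = 100.0 * counts[canon] / n_reps
                annotate(child)

    annotate(tree.root)
    return tree


# ---------------------------------------------------------------------------
# Rooting
# ---------------------------------------------------------------------------

def _annotate_parents(node: Node, parent: Node | None = None) -> None:
    node._parent = parent  # type: ignore[attr-defined]
    for c in node.children:
        _annotate_parents(c, node)


def _flip(node: Node, came_from: Node, edge_length: float,
          edge_support: float | None) -> Node:
    """Re-orient ``node`` as a child reached through ``came_from``."""
    parent = node._parent  # type: ignore[attr-defined]
    new = Node(name=node.name,
               children=[c for c in node.children if c is not came_from],
               length=edge_length, support=edge_support)
    if parent is not None:
        new.children.append(_flip(parent, node, node.length, node.support))
    if len(new.children) == 1 and new.name is None:
        # suppress the unifurcation left at the old (trifurcating) root
        only = new.children[0]
        only.length += new.length
        if new.support is not None and only.support is None:
            only.support = new.support
        return only
    return new


def root_at_outgroup(tree: PhyloTree, outgroup_ids: list[str] | set[str],
                     ) -> PhyloTree:
    """Root on the edge separating the outgroup from the ingroup.

    If the outgroup is not monophyletic in the unrotted tree a warning is
    issued and the root falls back to the edge above the largest clade
    containing only outgroup leaves (at worst a single pendant edge). The
    root bisects the chosen edge.
    """
    og = frozenset(outgroup_ids)
    full = tree.leaf_names()
    missing = og - full
    if not og:
        raise ValueError("empty outgroup")
    if missing:
        raise ValueError(f"outgroup ids absent from tree: {sorted(missing)}")
    if og == full:
        raise ValueError("outgroup cannot contain every leaf")

    # candidate edges: the og/ingroup split if it exists, else the largest
    # clade consisting solely of outgroup leaves
    exact: Node | None = None
    best: Node | None = None
    best_size = 0

    def visit(node: Node) -> None:
        nonlocal exact, best, best_size
        for child in node.children:
            clade = child.clade_names()
            if exact is None and (clade == og or clade == full - og):
                exact = child
            if clade <= og and len(clade) > best_size:
                best, best_size = child, len(clade)
            if not child.is_leaf:
                visit(child)

    visit(tree.root)
    if exact is not None:
        target = exact
    else:
        warnings.warn("outgroup is not monophyletic; rooting on the largest "
                      "outgroup-only clade", stacklevel=2)
        assert best is not None
        target = best

    _annotate_parents(tree.root)
    parent = target._parent  # type: ignore[attr-defined]
    half = target.length / 2.0
    near_side = Node(name=target.name, children=target.children,
                     length=half, support=target.support)
    far_side = _flip(parent, target, half, target.support)
    children = [near_side, far_side]
    # present the outgroup side first when it is identifiable
    if children[1].clade_names() <= og and not children[0].clade_names() <= og:
        children.reverse()
    return PhyloTree(Node(children=children), rooted=True)


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def _newick(node: Node) -> str:
    if node.is_leaf:
        return f"{node.name}:{node.length:.8f}"
    inner = ",".join(_newick(c) for c in node.children)
    label = "" if node.support is None else f"{node.support:.0f}"
    return f"({inner}){label}:{node.length:.8f}"


def write_newick(tree: PhyloTree, path: str | Path | None = None) -> str:
    inner = ",".join(_newick(c) for c in tree.root.children)
    label = "" if tree.root.support is None else f"{tree.root.support:.0f}"
    text = f"({inner}){label};\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def read_newick(path: str | Path) -> PhyloTree:
    """Import an externally built tree (supports read as internal labels)."""
    import dendropy

    dtree = dendropy.Tree.get(path=str(path), schema="newick")

    def convert(dnode) -> Node:
        node = Node(
            name=dnode.taxon.label.replace(" ", "_") if dnode.taxon else None,
            length=float(dnode.edge.length or 0.0),
        )
        label = getattr(dnode, "label", None)
        if label is not None and not dnode.is_leaf():
            try:
                node.support = float(label)
            except ValueError:
                pass
        node.children = [convert(c) for c in dnode.child_nodes()]
        return node

    root = convert(dtree.seed_node)
    return PhyloTree(root, rooted=len(root.children) == 2)
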