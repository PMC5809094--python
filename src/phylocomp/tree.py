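"""Time-calibrated trees: reading, writing, and the geometry every other
module consumes.

A :class:`TimeTree` is an ultrametric, rooted, strictly binary phylogeny
with branch lengths in time units (My).  Ages are stored as time before
present (tips at age 0, root at age ``T``).  Node numbering is canonical and
deterministic for a given topology: tips ``0..n-1`` sorted by label,
internal nodes ``n..2n-2`` assigned in postorder with children visited in
order of their smallest descendant tip index (the root is always ``2n-2``).
Event tables and serialized results refer to edges by the canonical id of
the edge's child node.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

__all__ = [
    "TimeTree",
    "TreeSet",
    "read_tree",
    "read_tree_set",
    "write_tree",
    "phylo_vcv",
    "branching_times",
    "drop_tips",
]

#: relative tolerance (fraction of root age) for declaring a tree ultrametric
ULTRAMETRIC_RTOL = 1e-6


class TimeTree:
    """Array-backed ultrametric time tree.

    Parameters
    ----------
    labels:
        Tip labels; must be unique.
    parent:
        ``parent[v]`` is the canonical id of the parent of node ``v``
        (root has parent ``-1``).
    length:
        Branch length subtending each node (root entry ignored, stored 0).
    """

    def __init__(self, labels, parent, length):
        labels = list(labels)
        if len(set(labels)) != len(labels):
            raise ValueError("tip labels must be unique")
        n = len(labels)
        self.n_tips = n
        self.labels = labels
        self.parent = np.asarray(parent, dtype=int)
        self.length = np.asarray(length, dtype=float)
        n_nodes = 2 * n - 1
        if self.parent.shape != (n_nodes,) or self.length.shape != (n_nodes,):
            raise ValueError("parent/length arrays must have length 2*n_tips-1")
        nonroot = self.parent >= 0
        if np.any(self.length[nonroot] <= 0):
            bad = np.nonzero(nonroot & (self.length <= 0))[0]
            raise ValueError(f"non-positive branch length at node {bad[0]}")
        self.children: list[tuple[int, ...]] = [() for _ in range(n_nodes)]
        for v in range(n_nodes):
            p = self.parent[v]
            if p >= 0:
                self.children[p] = self.children[p] + (v,)
        self.root = int(np.nonzero(self.parent == -1)[0][0])
        for v in range(n, n_nodes):
            if len(self.children[v]) != 2:
                raise ValueError(f"internal node {v} is not binary")
        # ages from lengths (root age = max root-to-tip path)
        depth = np.zeros(n_nodes)
        for v in self._preorder():
            if self.parent[v] >= 0:
                depth[v] = depth[self.parent[v]] + self.length[v]
        T = float(depth[:n].max())
        self.root_age = T
        self.age = T - depth
        # snap tip ages to exactly zero (checked upstream by read_tree)
        self.age[:n] = 0.0
        self._tip_index = {lab: i for i, lab in enumerate(labels)}

    # -- traversal helpers -------------------------------------------------

    def _preorder(self):
        order, stack = [], [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self.children[v])
        return order

    def postorder(self):
        """Node ids, children always before parents."""
        return self._preorder()[::-1]

    def preorder(self):
        """Node ids, parents always before children."""
        return self._preorder()

    def tip_index(self, label: str) -> int:
        return self._tip_index[label]

    def descendant_tips(self) -> np.ndarray:
        """Boolean matrix ``(2n-1, n)``: tips descended from each node."""
        n = self.n_tips
        M = np.zeros((2 * n - 1, n), dtype=bool)
        M[np.arange(n), np.arange(n)] = True
        for v in self.postorder():
            for c in self.children[v]:
                M[v] |= M[c]
        return M

    def mrca_age_matrix(self) -> np.ndarray:
        """Pairwise MRCA ages between tips (diagonal 0)."""
        n = self.n_tips
        D = self.descendant_tips()
        out = np.zeros((n, n))
        for v in range(n, 2 * n - 1):
            a, b = self.children[v]
            left, right = D[a], D[b]
            out[np.ix_(left, right)] = self.age[v]
            out[np.ix_(right, left)] = self.age[v]
        return out

    # -- serialization -----------------------------------------------------

    def to_newick(self) -> str:
        def fmt(v):
            if v < self.n_tips:
                lab = self.labels[v]
                if any(ch in lab for ch in " ();,:[]'"):
                    lab = "'" + lab.replace("'", "''") + "'"
                body = lab
            else:
                body = "(" + ",".join(fmt(c) for c in self.children[v]) + ")"
            if self.parent[v] >= 0:
                body += f":{self.length[v]:.17g}"
            return body

        return fmt(self.root) + ";"

    def __repr__(self):
        return f"TimeTree(n_tips={self.n_tips}, root_age={self.root_age:.6g})"

    def __eq__(self, other):
        if not isinstance(other, TimeTree):
            return NotImplemented
        return (
            self.labels == other.labels
            and np.array_equal(self.parent, other.parent)
            and np.allclose(self.length, other.length, rtol=0, atol=1e-12)
        )


@dataclass
class TreeSet:
    """Ordered collection of trees sharing a tip-label universe."""

    trees: list[TimeTree]
    source: str = "synthetic"  # MCC | posterior | synthetic

    def __post_init__(self):
        if self.trees:
            universe = set(self.trees[0].labels)
            for t in self.trees[1:]:
                if not set(t.labels) <= universe:
                    universe |= set(t.labels)
        # subsets allowed after pruning; only record the union
        self.label_universe = sorted(
            set().union(*[set(t.labels) for t in self.trees]) if self.trees else set()
        )

    def __len__(self):
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)


# -- dendropy bridge -------------------------------------------------------


def _from_dendropy(dtree: dendropy.Tree) -> TimeTree:
    dtree = dtree.clone(depth=1)
    dtree.suppress_unifurcations()
    leaves = [lf for lf in dtree.leaf_node_iter()]
    labels = []
    for lf in leaves:
        lab = lf.taxon.label if lf.taxon is not None else lf.label
        if lab is None:
            raise ValueError("unlabeled tip in input tree")
        labels.append(str(lab))
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate tip labels in input tree")
    n = len(labels)
    for nd in dtree.preorder_node_iter():
        kids = nd.child_nodes()
        if kids and len(kids) != 2:
            raise ValueError(
                f"unresolved polytomy ({len(kids)} children) at an internal node; "
                "resolve before loading"
            )
    # ultrametricity check on raw depths
    dtree.calc_node_root_distances(return_leaf_distances_only=False)
    tipd = np.array([lf.root_distance for lf in leaves], dtype=float)
    T = float(tipd.max())
    if T <= 0:
        raise ValueError("tree has zero depth")
    worst = int(np.argmax(np.abs(tipd - T)))
    if abs(tipd[worst] - T) > ULTRAMETRIC_RTOL * T:
        raise ValueError(
            f"tree is not ultrametric: tip '{labels[worst]}' at depth "
            f"{tipd[worst]:.9g} vs root age {T:.9g}"
        )
    # canonical numbering
    order = np.argsort(labels)
    tip_id = {}
    for rank, idx in enumerate(order):
        tip_id[id(leaves[idx])] = rank
    min_tip = {}
    for nd in dtree.postorder_node_iter():
        if nd.is_leaf():
            min_tip[id(nd)] = tip_id[id(nd)]
        else:
            min_tip[id(nd)] = min(min_tip[id(c)] for c in nd.child_nodes())
    next_internal = n
    node_id = dict(tip_id)
    stack = [dtree.seed_node]
    post = []
    # postorder with children sorted by min descendant tip
    def walk(nd):
        for c in sorted(nd.child_nodes(), key=lambda c: min_tip[id(c)]):
            walk(c)
        post.append(nd)

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 10000))
    try:
        walk(dtree.seed_node)
    finally:
        sys.setrecursionlimit(old)
    for nd in post:
        if not nd.is_leaf():
            node_id[id(nd)] = next_internal
            next_internal += 1
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=int)
    length = np.zeros(n_nodes)
    for nd in post:
        v = node_id[id(nd)]
        if nd.parent_node is not None:
            parent[v] = node_id[id(nd.parent_node)]
            length[v] = float(nd.edge.length if nd.edge.length is not None else 0.0)
    sorted_labels = [labels[i] for i in order]
    return TimeTree(sorted_labels, parent, length)


def read_tree(path_or_str, format: str = "newick") -> TimeTree:
    """Read a single tree from a file path (or raw string) in Newick/NEXUS.

    NEXUS translate tables are honored; quoted labels kept verbatim.
    Raises if the file holds more than one tree (use :func:`read_tree_set`).
    """
    fmt = format.lower()
    if fmt not in ("newick", "nexus"):
        raise ValueError(f"unknown tree format {format!r}")
    data = _slurp(path_or_str)
    tl = dendropy.TreeList.get(data=data, schema=fmt, preserve_underscores=True)
    if len(tl) != 1:
        raise ValueError(
            f"expected exactly one tree, found {len(tl)}; use read_tree_set"
        )
    return _from_dendropy(tl[0])


def read_tree_set(path_or_str, format: str = "nexus", source: str = "posterior") -> TreeSet:
    """Read every tree in a Newick/NEXUS file into a :class:`TreeSet`."""
    fmt = format.lower()
    data = _slurp(path_or_str)
    tl = dendropy.TreeList.get(data=data, schema=fmt, preserve_underscores=True)
    if not len(tl):
        raise ValueError("no trees found")
    return TreeSet([_from_dendropy(t) for t in tl], source=source)


def _slurp(path_or_str) -> str:
    s = str(path_or_str)
    if "(" in s and ";" in s and "\n" not in s[:200] and not s.lstrip().startswith("#"):
        # looks like a raw newick string
        try:
            import os

            if not os.path.exists(s):
                return s
        except OSError:
            return s
    with open(s) as fh:
        return fh.read()


def write_tree(tree: TimeTree, path, format: str = "newick") -> None:
    fmt = format.lower()
    if fmt == "newick":
        with open(path, "w") as fh:
            fh.write(tree.to_newick() + "\n")
    elif fmt == "nexus":
        dt = dendropy.Tree.get(data=tree.to_newick(), schema="newick",
                               preserve_underscores=True)
        dt.write(path=str(path), schema="nexus", unquoted_underscores=True)
    else:
        raise ValueError(f"unknown tree format {format!r}")


# -- geometry --------------------------------------------------------------


def phylo_vcv(tree: TimeTree) -> np.ndarray:
    """Expected among-tip covariance structure under Brownian motion.

    ``C[i, j]`` is the shared root-to-MRCA path length; on an ultrametric
    tree the diagonal is the root age ``T``.
    """
    C = tree.root_age - tree.mrca_age_matrix()
    np.fill_diagonal(C, tree.root_age)
    return C


def branching_times(tree: TimeTree) -> np.ndarray:
    """Ages of internal nodes, sorted descending (first entry = root age)."""
    return np.sort(tree.age[tree.n_tips :])[::-1]


def drop_tips(tree: TimeTree, labels) -> TimeTree:
    """Induced subtree after removing ``labels``; unary nodes suppressed."""
    labels = set(labels)
    unknown = labels - set(tree.labels)
    if unknown:
        raise ValueError(f"labels not in tree: {sorted(unknown)[:5]}")
    keep = [lab for lab in tree.labels if lab not in labels]
    if len(keep) < 2:
        raise ValueError("drop_tips would leave fewer than 2 tips")
    if not labels:
        return TimeTree(tree.labels, tree.parent.copy(), tree.length.copy())
    keep_tip = np.array([lab not in labels for lab in tree.labels])
    n_nodes = 2 * tree.n_tips - 1
    alive = np.zeros(n_nodes, dtype=bool)
    alive[: tree.n_tips] = keep_tip
    for v in tree.postorder():
        for c in tree.children[v]:
            alive[v] |= alive[c]
    # new structure: map old node -> (representative old node after suppression)
    new_labels = sorted(keep)
    n_new = len(new_labels)
    new_id = {}
    for i, lab in enumerate(new_labels):
        new_id[tree.tip_index(lab)] = i
    parent_new = np.full(2 * n_new - 1, -1, dtype=int)
    length_new = np.zeros(2 * n_new - 1)
    next_int = n_new
    # postorder assembly: each alive subtree reduces to (new node id, age at top)
    red: dict[int, tuple[int, float]] = {}
    order_int = []  # internal new nodes in creation (postorder) order
    for v in tree.postorder():
        if v < tree.n_tips:
            if alive[v]:
                red[v] = (new_id[v], 0.0)
            continue
        kids = [c for c in tree.children[v] if alive[c]]
        if not alive[v]:
            continue
        if len(kids) == 1:
            red[v] = red[kids[0]]
        else:
            u = next_int
            next_int += 1
            for c in kids:
                cid, _ = red[c]
                parent_new[cid] = u
                length_new[cid] = tree.age[v] - _age_of(tree, red, c)
            red[v] = (u, tree.age[v])
            order_int.append((u, tree.age[v]))
    # renumber internals canonically via a newick round trip
    sub = TimeTree(new_labels, parent_new, length_new)
    return _canonicalize(sub)


def _age_of(tree, red, old_node):
    if old_node < tree.n_tips:
        return 0.0
    return red[old_node][1]


def _canonicalize(t: TimeTree) -> TimeTree:
    """Renumber internal nodes to the canonical postorder convention."""
    dt = dendropy.Tree.get(data=t.to_newick(), schema="newick",
                           preserve_underscores=True)
    return _from_dendropy(dt)
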