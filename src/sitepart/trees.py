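"""Phylogenetic tree container.

Wraps an (effectively unrooted) topology as flat arrays convenient for
the pruning likelihood: a parent pointer per node, a post-order node
sequence, and a branch length on every non-root node.  Newick parsing and
writing are delegated to dendropy.  Branches are identified across trees
that share a topology by the set of leaf names below them (their
bipartition key), so branch-wise comparisons never depend on node
numbering.
"""

from __future__ import annotations

import numpy as np
import dendropy

__all__ = ["PhyloTree", "read_tree", "random_tree"]

#: Lower bound applied to branch lengths so P(t) stays well conditioned.
MIN_BRANCH_LENGTH = 1e-8


class PhyloTree:
    """Tree topology with non-negative branch lengths.

    Node indices: leaves first (``0 .. n_leaves-1``, in ``leaf_names``
    order), internal nodes after, the root last.  ``branch_lengths[i]`` is
    the length of the branch above node ``i`` (the root entry is unused
    and held at 0).
    """

    def __init__(self, parent, branch_lengths, leaf_names):
        self.parent = np.asarray(parent, dtype=int)
        self.branch_lengths = np.asarray(branch_lengths, dtype=float)
        self.leaf_names = list(leaf_names)
        n = len(self.parent)
        if self.branch_lengths.shape != (n,):
            raise ValueError("parent/branch length size mismatch")
        roots = np.nonzero(self.parent < 0)[0]
        if len(roots) != 1:
            raise ValueError("tree must have exactly one root node")
        self.root = int(roots[0])
        self.n_nodes = n
        self.n_leaves = len(self.leaf_names)
        self.children = [[] for _ in range(n)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                self.children[p].append(i)
        for i in range(self.n_leaves):
            if self.children[i]:
                raise ValueError("leaf indices must come first")
        if np.any(self.branch_lengths[np.arange(n) != self.root] < 0):
            raise ValueError("negative branch length")
        self.branch_lengths = self.branch_lengths.copy()
        self.branch_lengths[self.root] = 0.0
        # post-order: children before parents, root last
        order, stack = [], [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                order.append(node)
            else:
                stack.append((node, True))
                for c in self.children[node]:
                    stack.append((c, False))
        self.postorder = np.array(order, dtype=int)
        self.preorder = self.postorder[::-1].copy()
        self._clades = None

    # -- construction --------------------------------------------------

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "PhyloTree":
        leaves = [lf for lf in tree.leaf_node_iter()]
        leaf_names = [lf.taxon.label for lf in leaves]
        index = {id(lf): i for i, lf in enumerate(leaves)}
        internals = [
            nd for nd in tree.preorder_node_iter() if not nd.is_leaf()
        ]
        # root (seed node) must be last
        internals = [nd for nd in internals if nd is not tree.seed_node]
        ordering = leaves + internals + [tree.seed_node]
        for j, nd in enumerate(ordering):
            index[id(nd)] = j
        n = len(ordering)
        parent = np.full(n, -1, dtype=int)
        bl = np.zeros(n)
        for nd in ordering:
            i = index[id(nd)]
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                bl[i] = nd.edge.length if nd.edge.length is not None else np.nan
        if np.isnan(bl).any():
            bl = np.where(np.isnan(bl), 0.1, bl)  # topology-only input
        return cls(parent, bl, leaf_names)

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        return cls.from_dendropy(tree)

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.parent, self.branch_lengths, self.leaf_names)

    def with_branch_lengths(self, branch_lengths) -> "PhyloTree":
        bl = np.asarray(branch_lengths, dtype=float).copy()
        bl[self.root] = 0.0
        return PhyloTree(self.parent, bl, self.leaf_names)

    def rescaled(self, s: float) -> "PhyloTree":
        """All branch lengths multiplied by the scale factor ``s``."""
        if s <= 0:
            raise ValueError("scale factor must be positive")
        return self.with_branch_lengths(self.branch_lengths * s)

    # -- serialisation -------------------------------------------------

    def to_dendropy(self) -> dendropy.Tree:
        taxa = dendropy.TaxonNamespace(self.leaf_names)
        tree = dendropy.Tree(taxon_namespace=taxa)
        nodes = {}
        for i in self.preorder:
            nd = tree.seed_node if i == self.root else dendropy.Node()
            if i != self.root:
                nodes[self.parent[i]].add_child(nd)
                nd.edge.length = float(self.branch_lengths[i])
            if i < self.n_leaves:
                nd.taxon = taxa.get_taxon(self.leaf_names[i])
            nodes[i] = nd
        return tree

    def to_newick(self) -> str:
        return (
            self.to_dendropy().as_string(
                schema="newick", suppress_rooting=True, unquoted_underscores=True
            )
        ).strip()

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    # -- branch identity -----------------------------------------------

    def clades(self):
        """Frozenset of leaf names below each node (node-indexed list)."""
        if self._clades is None:
            clades = [None] * self.n_nodes
            for i in self.postorder:
                if i < self.n_leaves:
                    clades[i] = frozenset([self.leaf_names[i]])
                else:
                    s = frozenset()
                    for c in self.children[i]:
                        s |= clades[c]
                    clades[i] = s
            self._clades = clades
        return self._clades

    def branch_map(self) -> dict:
        """bipartition key -> branch length, for every non-root branch."""
        clades = self.clades()
        return {
            clades[i]: float(self.branch_lengths[i])
            for i in range(self.n_nodes)
            if i != self.root
        }

    def same_topology(self, other: "PhyloTree") -> bool:
        return (
            set(self.leaf_names) == set(other.leaf_names)
            and set(self.branch_map()) == set(other.branch_map())
        )

    @property
    def total_length(self) -> float:
        mask = np.arange(self.n_nodes) != self.root
        return float(self.branch_lengths[mask].sum())

    def __repr__(self):
        return (
            f"PhyloTree(n_leaves={self.n_leaves}, n_nodes={self.n_nodes}, "
            f"total_length={self.total_length:.4f})"
        )


def read_tree(path) -> PhyloTree:
    with open(path) as fh:
        return PhyloTree.from_newick(fh.read())


def random_tree(n_taxa, mean_branch_length=0.1, seed=None, names=None) -> PhyloTree:
    """Random binary topology with exponential branch lengths.

    Built by successively joining random pairs of subtrees (a uniform
    coalescent-style shape); useful for simulations and tests.
    """
    if n_taxa < 2:
        raise ValueError("need at least two taxa")
    rng = np.random.default_rng(seed)
    if names is None:
        names = [f"t{i + 1}" for i in range(n_taxa)]
    # unrooted shape: the last join is a trifurcation, so no pair of
    # root-adjacent branches is confounded under a reversible model
    n_nodes = 2 * n_taxa - 1 if n_taxa == 2 else 2 * n_taxa - 2
    parent = np.full(n_nodes, -1, dtype=int)
    bl = np.zeros(n_nodes)
    active = list(range(n_taxa))
    nxt = n_taxa
    while len(active) > 1:
        join = 3 if len(active) == 3 else 2
        picks = rng.choice(len(active), size=join, replace=False)
        chosen = [active[i] for i in picks]
        for a in chosen:
            parent[a] = nxt
            bl[a] = rng.exponential(mean_branch_length) + MIN_BRANCH_LENGTH
        active = [x for x in active if x not in chosen] + [nxt]
        nxt += 1
    return PhyloTree(parent, bl, names)
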