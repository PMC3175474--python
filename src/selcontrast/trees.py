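"""Phylogeny container: array-backed tree with optional compartment tags.

Trees are parsed and written through dendropy but held internally as flat
parent/children arrays so the pruning likelihood can run over them without
object-graph traversal.  Nodes are indexed ``0..n_nodes-1`` with leaves
first (in label registration order); ``postorder`` lists every node with
children before parents, root last.

Each non-root node owns the branch above it.  Branch lengths are expected
substitutions per codon site (under the neutral scaling of the codon
model).  A branch may carry a compartment tag used by clade/branch
partition models: ``background``, ``clade`` or ``stem``.
"""

from __future__ import annotations

import numpy as np
import dendropy

TAG_BACKGROUND = 0
TAG_CLADE = 1
TAG_STEM = 2
TAG_NAMES = {TAG_BACKGROUND: "background", TAG_CLADE: "clade", TAG_STEM: "stem"}


class Phylogeny:
    """Rooted tree over labelled leaves with branch lengths.

    Attributes
    ----------
    labels : list[str]
        Leaf labels; leaf ``i`` is node ``i``.
    parent : ndarray
        Parent node index per node, ``-1`` at the root.
    lengths : ndarray
        Branch length above each node (``nan`` when the input had none);
        the root entry is 0.
    tags : ndarray or None
        Per-branch compartment tag, same indexing as ``lengths``.
    """

    def __init__(self, labels, parent, lengths, children, postorder, tags=None):
        self.labels = list(labels)
        self.parent = np.asarray(parent, dtype=np.int64)
        self.lengths = np.asarray(lengths, dtype=float)
        self.children = [list(c) for c in children]
        self.postorder = np.asarray(postorder, dtype=np.int64)
        self.tags = None if tags is None else np.asarray(tags, dtype=np.int64)
        self.n_leaves = len(self.labels)
        self.n_nodes = len(self.parent)
        roots = np.nonzero(self.parent < 0)[0]
        if len(roots) != 1:
            raise ValueError("tree must have exactly one root")
        self.root = int(roots[0])

    # -- construction ------------------------------------------------------
    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "Phylogeny":
        leaves = [lf for lf in tree.leaf_node_iter()]
        labels = [lf.taxon.label for lf in leaves]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate leaf labels")
        index = {}
        for i, lf in enumerate(leaves):
            index[id(lf)] = i
        nxt = len(leaves)
        for nd in tree.preorder_node_iter():
            if id(nd) not in index:
                index[id(nd)] = nxt
                nxt += 1
        n = nxt
        parent = np.full(n, -1, dtype=np.int64)
        lengths = np.zeros(n)
        children: list[list[int]] = [[] for _ in range(n)]
        for nd in tree.preorder_node_iter():
            i = index[id(nd)]
            if nd.parent_node is not None:
                p = index[id(nd.parent_node)]
                parent[i] = p
                children[p].append(i)
                lengths[i] = np.nan if nd.edge.length is None else float(nd.edge.length)
        post = [index[id(nd)] for nd in tree.postorder_node_iter()]
        return cls(labels, parent, lengths, children, post)

    @classmethod
    def from_newick(cls, source: str) -> "Phylogeny":
        """Parse a Newick string or file path."""
        import os

        if os.path.exists(source):
            tree = dendropy.Tree.get(path=source, schema="newick")
        else:
            tree = dendropy.Tree.get(data=source, schema="newick")
        return cls.from_dendropy(tree)

    def to_dendropy(self) -> dendropy.Tree:
        tn = dendropy.TaxonNamespace(self.labels)
        nodes = [dendropy.Node() for _ in range(self.n_nodes)]
        for i, lab in enumerate(self.labels):
            nodes[i].taxon = tn.get_taxon(lab)
        for i in range(self.n_nodes):
            for c in self.children[i]:
                nodes[i].add_child(nodes[c])
                nodes[c].edge.length = (
                    None if np.isnan(self.lengths[c]) else float(self.lengths[c])
                )
        tree = dendropy.Tree(taxon_namespace=tn)
        tree.seed_node = nodes[self.root]
        return tree

    def to_newick(self) -> str:
        return self.to_dendropy().as_string(schema="newick").strip()

    # -- queries -----------------------------------------------------------
    @property
    def has_lengths(self) -> bool:
        mask = np.ones(self.n_nodes, dtype=bool)
        mask[self.root] = False
        return not np.any(np.isnan(self.lengths[mask]))

    def total_length(self) -> float:
        mask = np.ones(self.n_nodes, dtype=bool)
        mask[self.root] = False
        return float(np.nansum(self.lengths[mask]))

    def leaf_indices(self, labels) -> np.ndarray:
        lookup = {lab: i for i, lab in enumerate(self.labels)}
        try:
            return np.array([lookup[l] for l in labels], dtype=np.int64)
        except KeyError as e:
            raise KeyError(f"label {e.args[0]!r} not in tree") from None

    def node_depths(self) -> np.ndarray:
        """Path length from the root to every node."""
        depth = np.zeros(self.n_nodes)
        for nd in self.postorder[::-1]:
            p = self.parent[nd]
            if p >= 0:
                depth[nd] = depth[p] + self.lengths[nd]
        return depth

    def pairwise_path_lengths(self) -> np.ndarray:
        """Matrix of patristic distances between leaves."""
        # ancestors of each leaf with cumulative depth
        depth = self.node_depths()
        anc = []
        for leaf in range(self.n_leaves):
            chain = []
            nd = leaf
            while nd >= 0:
                chain.append(nd)
                nd = self.parent[nd]
            anc.append(chain)
        sets = [dict.fromkeys(a) for a in anc]
        D = np.zeros((self.n_leaves, self.n_leaves))
        for i in range(self.n_leaves):
            for j in range(i + 1, self.n_leaves):
                mrca = next(nd for nd in anc[i] if nd in sets[j])
                D[i, j] = D[j, i] = depth[i] + depth[j] - 2 * depth[mrca]
        return D

    def mean_pairwise_path(self) -> float:
        D = self.pairwise_path_lengths()
        n = self.n_leaves
        return float(D.sum() / (n * (n - 1)))

    def mrca(self, labels) -> int:
        """Most recent common ancestor node of a set of leaf labels."""
        idx = self.leaf_indices(labels)
        chains = []
        for leaf in idx:
            chain = []
            nd = int(leaf)
            while nd >= 0:
                chain.append(nd)
                nd = self.parent[nd]
            chains.append(chain)
        common = set(chains[0])
        for c in chains[1:]:
            common &= set(c)
        return next(nd for nd in chains[0] if nd in common)

    def subtree_leaves(self, node: int) -> list[int]:
        out = []
        stack = [node]
        while stack:
            nd = stack.pop()
            if nd < self.n_leaves:
                out.append(nd)
            stack.extend(self.children[nd])
        return sorted(out)

    # -- derived trees -----------------------------------------------------
    def with_lengths(self, lengths) -> "Phylogeny":
        return Phylogeny(
            self.labels, self.parent, lengths, self.children, self.postorder, self.tags
        )

    def scaled(self, factor: float) -> "Phylogeny":
        return self.with_lengths(self.lengths * factor)

    def with_tags(self, tags) -> "Phylogeny":
        return Phylogeny(
            self.labels, self.parent, self.lengths, self.children, self.postorder, tags
        )

    def __repr__(self):
        return f"Phylogeny({self.n_leaves} leaves, total length {self.total_length():.4g})"
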