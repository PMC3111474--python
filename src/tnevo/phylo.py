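"""Rooted phylogeny with divergence times.

A thin, validated tree structure used by the regulatory-state CTMC.  Trees are
read from Newick (via dendropy) and kept as a parent-pointer table; branch
lengths are divergence times in the same units as the rate parameters'
inverse, taken as-is from the input with no rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy

__all__ = ["Phylogeny"]


@dataclass(frozen=True)
class Phylogeny:
    """A rooted tree over named leaf species.

    Parameters
    ----------
    parent
        Mapping node id -> parent node id for every non-root node.
    branch_lengths
        Mapping node id -> length of the branch above that node (time from
        its parent).  Required for every non-root node; all >= 0.
    leaf_names
        Mapping node id -> species name for every leaf.
    root
        Id of the unique root node.
    """

    parent: dict[int, int]
    branch_lengths: dict[int, float]
    leaf_names: dict[int, str]
    root: int
    _children: dict[int, list[int]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        nodes = self.nodes
        if self.root in self.parent:
            raise ValueError("root must not have a parent")
        for node in nodes:
            if node == self.root:
                continue
            if node not in self.parent:
                raise ValueError(f"non-root node {node} has no parent")
            if node not in self.branch_lengths:
                raise ValueError(f"node {node} has no branch length")
            if self.branch_lengths[node] < 0:
                raise ValueError(f"negative branch length on node {node}")
        names = list(self.leaf_names.values())
        if len(set(names)) != len(names):
            raise ValueError("leaf names must be unique")
        if any(not n for n in names):
            raise ValueError("leaf names must be nonempty")
        children: dict[int, list[int]] = {n: [] for n in nodes}
        for child, par in self.parent.items():
            if par not in children:
                raise ValueError(f"parent {par} of node {child} is not a node")
            children[par].append(child)
        for leaf in self.leaf_names:
            if children[leaf]:
                raise ValueError(f"leaf {leaf} has children")
        # reachability from the root guarantees a single connected tree
        seen: set[int] = set()
        stack = [self.root]
        while stack:
            node = stack.pop()
            seen.add(node)
            stack.extend(children[node])
        if seen != nodes:
            raise ValueError("tree is not connected from the root")
        object.__setattr__(self, "_children", children)

    @property
    def nodes(self) -> set[int]:
        return {self.root} | set(self.parent)

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_names)

    @property
    def leaves(self) -> list[str]:
        """Species names, sorted lexicographically (the canonical order)."""
        return sorted(self.leaf_names.values())

    def children(self, node: int) -> list[int]:
        return self._children[node]

    def postorder(self) -> list[int]:
        """Node ids, children always before parents."""
        order: list[int] = []
        stack = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                order.append(node)
            else:
                stack.append((node, True))
                for child in self._children[node]:
                    stack.append((child, False))
        return order

    # ------------------------------------------------------------------
    # Newick round trip
    # ------------------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        """Parse a rooted Newick string; branch lengths required on all branches."""
        tree = dendropy.Tree.get(data=newick, schema="newick")
        ids: dict[object, int] = {}
        for i, nd in enumerate(tree.preorder_node_iter()):
            ids[nd] = i
        parent: dict[int, int] = {}
        lengths: dict[int, float] = {}
        leaf_names: dict[int, str] = {}
        root = ids[tree.seed_node]
        for nd in tree.preorder_node_iter():
            i = ids[nd]
            if nd.parent_node is not None:
                parent[i] = ids[nd.parent_node]
                if nd.edge.length is None:
                    raise ValueError("all branches must carry a length")
                lengths[i] = float(nd.edge.length)
            if nd.is_leaf():
                if nd.taxon is None or not nd.taxon.label:
                    raise ValueError("all leaves must be named")
                leaf_names[i] = str(nd.taxon.label)
        return cls(parent=parent, branch_lengths=lengths, leaf_names=leaf_names, root=root)

    @classmethod
    def from_newick_file(cls, path) -> "Phylogeny":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def to_newick(self) -> str:
        """Canonical Newick echo (children ordered by smallest descendant leaf)."""

        def label(node: int) -> str:
            if node in self.leaf_names:
                return self.leaf_names[node]
            return min(label(c) for c in self._children[node])

        def render(node: int) -> str:
            if node in self.leaf_names:
                s = self.leaf_names[node]
            else:
                kids = sorted(self._children[node], key=label)
                s = "(" + ",".join(render(c) for c in kids) + ")"
            if node != self.root:
                s += f":{self.branch_lengths[node]:g}"
            return s

        return render(self.root) + ";"
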