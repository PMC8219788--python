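"""Gene trees with bootstrap supports, read from Newick.

Internal-node labels are interpreted as integer bootstrap supports (the
RAxML/IQ-TREE convention); a missing label means support 0.  Trees are
treated as unrooted: :meth:`Tree.splits` enumerates every bipartition of
the leaf set induced by an internal edge, which is what clan binning
consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterator, List, Optional, Tuple

import dendropy


class NewickParseError(ValueError):
    pass


@dataclass
class Node:
    label: Optional[str] = None
    length: Optional[float] = None
    support: int = 0
    children: List["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


class Tree:
    """A rooted representation of an (interpretation-wise unrooted) tree."""

    def __init__(self, root: Node, label: str | None = None):
        self.root = root
        self.label = label
        labels = self.leaf_labels()
        if len(labels) != len(set(labels)):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise NewickParseError(f"duplicate leaf labels: {dupes}")

    # -- traversal ---------------------------------------------------------
    def _postorder(self) -> Iterator[Node]:
        stack: List[Tuple[Node, bool]] = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded or node.is_leaf:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def leaf_labels(self) -> List[str]:
        return [n.label for n in self._postorder() if n.is_leaf]

    def leaves(self) -> FrozenSet[str]:
        return frozenset(self.leaf_labels())

    # -- unrooted splits ---------------------------------------------------
    def splits(self) -> List[Tuple[FrozenSet[str], FrozenSet[str], int]]:
        """All non-trivial bipartitions as (side, complement, support).

        Each internal edge yields one split; the two edges incident to a
        degree-2 root describe the same unrooted edge and are merged,
        keeping the larger support (a support written on the root itself is
        ignored).  Trivial splits (single leaf vs rest) are excluded.
        """
        all_leaves = self.leaves()
        below: Dict[int, FrozenSet[str]] = {}
        merged: Dict[FrozenSet[str], Tuple[FrozenSet[str], int]] = {}
        for node in self._postorder():
            if node.is_leaf:
                below[id(node)] = frozenset([node.label])
            else:
                below[id(node)] = frozenset().union(
                    *(below[id(c)] for c in node.children)
                )
        for node in self._postorder():
            if node is self.root:
                continue
            side = below[id(node)]
            if len(side) < 2 or not all_leaves - side:
                continue
            key = min(side, all_leaves - side, key=lambda s: sorted(s))
            prev = merged.get(key)
            if prev is None or node.support > prev[1]:
                merged[key] = (side, node.support)
        return [
            (side, all_leaves - side, support) for side, support in merged.values()
        ]

    # -- serialisation -----------------------------------------------------
    def to_newick(self) -> str:
        def render(node: Node) -> str:
            if node.is_leaf:
                body = node.label or ""
            else:
                body = "(" + ",".join(render(c) for c in node.children) + ")"
                if node is not self.root and node.support:
                    body += str(node.support)
            if node.length is not None:
                body += f":{node.length:g}"
            return body

        return render(self.root) + ";"


def _from_dendropy(dnode: "dendropy.Node") -> Node:
    if dnode.is_leaf():
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        return Node(label=label, length=dnode.edge.length)
    label = dnode.label
    support = 0
    if label is not None:
        try:
            support = int(round(float(label)))
        except ValueError:
            support = 0
    node = Node(
        label=label,
        length=dnode.edge.length,
        support=support,
        children=[_from_dendropy(c) for c in dnode.child_nodes()],
    )
    return node


def parse_newick(text: str, label: str | None = None) -> Tree:
    """Parse one Newick string into a :class:`Tree`.

    Internal-node labels become integer supports (missing -> 0); branch
    lengths are retained.  Unbalanced parentheses or duplicate leaf labels
    raise :class:`NewickParseError`.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    root = _from_dendropy(dtree.seed_node)
    return Tree(root, label=label)
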