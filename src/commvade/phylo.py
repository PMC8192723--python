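"""Rooted phylogenetic trees with branch lengths.

The tree is the input to UniFrac: a rooted topology whose leaves are ASV
identifiers and whose edges carry non-negative lengths (units cancel in the
UniFrac ratio). Only the small feature set UniFrac needs is implemented:
Newick round-tripping, postorder traversal, and a flattened array index for
fast repeated traversals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import FormatError, ValidationError

__all__ = ["TreeNode", "PhyloTree", "TreeIndex", "parse_newick", "write_newick"]


@dataclass
class TreeNode:
    name: str | None = None
    length: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


class PhyloTree:
    """A rooted tree over ASV leaves.

    Invariants enforced at construction: unique leaf labels, non-negative
    branch lengths. The root's own length (rare in practice) is tolerated
    but ignored by UniFrac, which only uses proper edges.
    """

    def __init__(self, root: TreeNode):
        self.root = root
        self._validate()

    def _validate(self) -> None:
        seen: set[str] = set()
        for node in self.postorder():
            if node.is_leaf:
                if not node.name:
                    raise ValidationError("unnamed leaf in tree")
                if node.name in seen:
                    raise ValidationError(f"duplicate leaf label {node.name!r}")
                seen.add(node.name)
            if node.length is not None and node.length < 0:
                raise ValidationError(
                    f"negative branch length {node.length} at {node.name or 'internal node'}"
                )

    def postorder(self):
        """Yield nodes children-before-parents (iterative, no recursion limit)."""
        stack: list[tuple[TreeNode, bool]] = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_leaf]

    @property
    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def total_branch_length(self) -> float:
        return sum(n.length or 0.0 for n in self.postorder() if n is not self.root)

    def to_newick(self) -> str:
        return write_newick(self)

    def index(self) -> "TreeIndex":
        return TreeIndex(self)


class TreeIndex:
    """Flattened arrays for one-pass postorder computations.

    Attributes
    ----------
    n_nodes : total node count; the root is the last postorder entry.
    lengths : branch length of each node's parent edge (0 for the root).
    children : list of child-index lists, postorder-aligned.
    leaf_pos : leaf name -> node index.
    """

    def __init__(self, tree: PhyloTree):
        order = list(tree.postorder())
        pos = {id(n): i for i, n in enumerate(order)}
        self.n_nodes = len(order)
        self.lengths = np.array(
            [0.0 if n is tree.root else float(n.length or 0.0) for n in order]
        )
        self.children = [[pos[id(c)] for c in n.children] for n in order]
        self.leaf_pos = {n.name: pos[id(n)] for n in order if n.is_leaf}
        self.is_root = np.zeros(self.n_nodes, dtype=bool)
        self.is_root[-1] = True

    def leaf_mass_matrix(self) -> "np.ndarray":
        """Sparse-free helper unused for large trees; kept simple on purpose."""
        raise NotImplementedError


def parse_newick(text: str) -> PhyloTree:
    """Parse a single rooted Newick string.

    Supports quoted labels, internal node names, and per-edge lengths. A
    missing semicolon, unbalanced parentheses, or trailing garbage raise
    :class:`FormatError`; negative lengths raise :class:`ValidationError`.
    """
    s = text.strip()
    if not s.endswith(";"):
        raise FormatError("Newick string must end with ';'")
    s = s[:-1]
    pos = 0

    def error(msg: str) -> FormatError:
        return FormatError(f"Newick parse error at position {pos}: {msg}")

    def parse_label() -> tuple[str | None, float | None]:
        nonlocal pos
        name: str | None = None
        if pos < len(s) and s[pos] == "'":
            end = s.find("'", pos + 1)
            if end < 0:
                raise error("unterminated quoted label")
            name = s[pos + 1 : end]
            pos = end + 1
        else:
            start = pos
            while pos < len(s) and s[pos] not in "(),:;":
                pos += 1
            if pos > start:
                name = s[start:pos].strip() or None
        length: float | None = None
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in "(),;":
                pos += 1
            try:
                length = float(s[start:pos])
            except ValueError:
                raise error(f"bad branch length {s[start:pos]!r}") from None
        return name, length

    def parse_clade() -> TreeNode:
        nonlocal pos
        node = TreeNode()
        if pos < len(s) and s[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse_clade())
                if pos >= len(s):
                    raise error("unbalanced parentheses")
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
                raise error(f"unexpected character {s[pos]!r}")
        node.name, node.length = parse_label()
        return node

    root = parse_clade()
    if pos != len(s):
        raise error("trailing characters after tree")
    return PhyloTree(root)


def _format_node(node: TreeNode) -> str:
    label = node.name or ""
    if label and any(c in label for c in "(),:; '\t\n"):
        label = "'" + label.replace("'", "''") + "'"
    out = ""
    if node.children:
        out = "(" + ",".join(_format_node(c) for c in node.children) + ")"
    out += label
    if node.length is not None:
        out += f":{node.length:.12g}"
    return out


def write_newick(tree: PhyloTree) -> str:
    return _format_node(tree.root) + ";"
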