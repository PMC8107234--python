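"""Rooted/unrooted phylogenetic trees with Newick round-tripping.

The tree is a plain linked structure (:class:`Node`) rather than a wrapper
around an external toolkit: the simulator, the neighbor-joining builder and
the Wagner-parsimony dynamic program all need cheap parent links, stable
node labels and exact control over how branch lengths are printed so that
write→read round-trips are byte-stable.
"""

from __future__ import annotations

from typing import Iterator, Optional


class Node:
    __slots__ = ("name", "length", "children", "parent")

    def __init__(self, name: str = "", length: Optional[float] = None):
        self.name = name
        self.length = length  # branch length to parent; None at the root
        self.children: list[Node] = []
        self.parent: Optional[Node] = None

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"internal({len(self.children)})"
        return f"<Node {self.name or '?'} {kind}>"


class PhyloTree:
    """A node-labelled tree; leaves carry genome IDs, internals N1..Nk."""

    def __init__(self, root: Node, rooted: bool = True):
        self.root = root
        self.rooted = rooted

    # ---------------------------------------------------------------- walks
    def postorder(self) -> Iterator[Node]:
        stack, out = [self.root], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def find(self, name: str) -> Optional[Node]:
        for node in self.postorder():
            if node.name == name:
                return node
        return None

    def lca(self, a: str, b: str) -> Node:
        na, nb = self.find(a), self.find(b)
        if na is None or nb is None:
            raise KeyError(f"leaf not in tree: {a if na is None else b}")
        seen = set()
        while na is not None:
            seen.add(id(na))
            na = na.parent
        while nb is not None:
            if id(nb) in seen:
                return nb
            nb = nb.parent
        raise RuntimeError("disconnected tree")  # pragma: no cover

    def label_internals(self, prefix: str = "N") -> None:
        """Assign deterministic preorder labels N1..Nk to internal nodes."""
        k = 0
        for node in self.preorder():
            if not node.is_leaf:
                k += 1
                node.name = f"{prefix}{k}"

    def branches(self) -> Iterator[tuple[Node, Node]]:
        """(parent, child) pairs; the root's virtual branch is excluded."""
        for node in self.preorder():
            for child in node.children:
                yield node, child

    def total_length(self) -> float:
        return sum(c.length or 0.0 for _, c in self.branches())

    def depths(self) -> dict[str, float]:
        """Root-to-node path lengths keyed by node name."""
        out = {self.root.name: 0.0}
        for parent, child in self.branches():
            out[child.name] = out[parent.name] + (child.length or 0.0)
        return out

    def copy(self) -> "PhyloTree":
        def clone(node: Node) -> Node:
            new = Node(node.name, node.length)
            for child in node.children:
                new.add(clone(child))
            return new

        return PhyloTree(clone(self.root), self.rooted)

    # --------------------------------------------------------------- newick
    def to_newick(self) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                body = node.name
            else:
                body = "(" + ",".join(fmt(c) for c in node.children) + ")" + node.name
            if node.length is not None:
                body += f":{format(node.length, '.10g')}"
            return body

        return fmt(self.root) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        tree = parse_newick(text)
        names = tree.leaf_names()
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate leaf labels: {sorted(dupes)}")
        return tree

    def __repr__(self) -> str:  # pragma: no cover
        return f"<PhyloTree {len(self.leaf_names())} leaves rooted={self.rooted}>"


def parse_newick(text: str) -> PhyloTree:
    """Recursive-descent Newick parser (labels, branch lengths; no quoting)."""
    s = text.strip()
    if not s.endswith(";"):
        raise ValueError("Newick string must end with ';'")
    s = s[:-1]
    pos = 0

    def error(msg: str) -> ValueError:
        return ValueError(f"Newick parse error at position {pos}: {msg}")

    def parse_node() -> Node:
        nonlocal pos
        node = Node()
        if pos < len(s) and s[pos] == "(":
            pos += 1
            while True:
                node.add(parse_node())
                if pos >= len(s):
                    raise error("unbalanced parentheses")
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
                raise error(f"unexpected character {s[pos]!r}")
        start = pos
        while pos < len(s) and s[pos] not in ",():;":
            pos += 1
        node.name = s[start:pos].strip()
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in ",()":
                pos += 1
            try:
                node.length = float(s[start:pos])
            except ValueError:
                raise error(f"bad branch length {s[start:pos]!r}")
        return node

    root = parse_node()
    if pos != len(s):
        raise ValueError(f"Newick parse error: trailing characters at {pos}")
    rooted = len(root.children) == 2
    return PhyloTree(root, rooted=rooted)
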