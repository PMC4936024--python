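"""Rooted-tree container shared by the whole pipeline.

Trees here are rooted, possibly dated: every node may carry an absolute age
in Ma before present (larger = older).  Branch durations are derived,
``parent.age - child.age``, in Myr.  Topology-only trees simply leave
``age`` as ``None``.  Tips carry taxon labels; internal nodes usually do
not.  The container is deliberately small — parsing and serialisation of
Newick/NEXUS live in :mod:`paleorates.io`.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Optional


class Node:
    """A single tree node: children, optional parent, label and age (Ma)."""

    __slots__ = ("children", "parent", "label", "age", "index")

    def __init__(self, label: Optional[str] = None, age: Optional[float] = None):
        self.children: list["Node"] = []
        self.parent: Optional["Node"] = None
        self.label = label
        self.age = age
        self.index: int = -1

    def add_child(self, node: "Node") -> "Node":
        node.parent = self
        self.children.append(node)
        return node

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"internal({len(self.children)})"
        return f"<Node {self.label or self.index} {kind} age={self.age}>"


class Tree:
    """A rooted tree with postorder node indexing.

    ``tree.nodes`` is the postorder node list; ``node.index`` is the
    position in that list (so children always precede parents).  Call
    :meth:`reindex` after any topology surgery.
    """

    def __init__(self, root: Node):
        self.root = root
        self.nodes: list[Node] = []
        self.reindex()

    # ------------------------------------------------------------------
    # structure & traversal
    # ------------------------------------------------------------------
    def reindex(self) -> None:
        self.nodes = list(self._postorder(self.root))
        for i, n in enumerate(self.nodes):
            n.index = i

    @staticmethod
    def _postorder(root: Node) -> Iterator[Node]:
        stack: list[tuple[Node, bool]] = [(root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                yield node
            else:
                stack.append((node, True))
                for c in reversed(node.children):
                    stack.append((c, False))

    def postorder(self) -> Iterator[Node]:
        return iter(self.nodes)

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    @property
    def leaves(self) -> list[Node]:
        return [n for n in self.nodes if n.is_leaf]

    @property
    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves]

    @property
    def internal_nodes(self) -> list[Node]:
        return [n for n in self.nodes if not n.is_leaf]

    def branches(self) -> list[Node]:
        """Every non-root node; a branch is identified by its child node."""
        return [n for n in self.nodes if n.parent is not None]

    @property
    def is_binary(self) -> bool:
        return all(len(n.children) == 2 for n in self.internal_nodes)

    def __len__(self) -> int:
        return len(self.nodes)

    # ------------------------------------------------------------------
    # ages / durations
    # ------------------------------------------------------------------
    def duration(self, node: Node) -> float:
        if node.parent is None:
            raise ValueError("the root has no subtending branch")
        return node.parent.age - node.age

    def branch_durations(self) -> list[float]:
        return [self.duration(b) for b in self.branches()]

    def total_duration(self) -> float:
        return sum(self.branch_durations())

    def validate_ages(self, tol: float = 1e-9) -> None:
        """Assert age monotonicity: every parent at least as old as each child."""
        for n in self.nodes:
            if n.age is None:
                raise ValueError(f"node {n.label or n.index} has no age")
            for c in n.children:
                if n.age < c.age - tol:
                    raise ValueError(
                        f"age monotonicity violated at node {n.label or n.index}: "
                        f"parent {n.age} Ma younger than child {c.age} Ma"
                    )

    # ------------------------------------------------------------------
    # copying / queries / surgery
    # ------------------------------------------------------------------
    def copy(self) -> "Tree":
        # iterative clone to be safe on deep (pectinate) trees
        root_new = Node(self.root.label, self.root.age)
        stack = [(self.root, root_new)]
        while stack:
            old, new = stack.pop()
            for c in old.children:
                cc = Node(c.label, c.age)
                new.add_child(cc)
                stack.append((c, cc))
        return Tree(root_new)

    def leaf_map(self) -> dict[str, Node]:
        out: dict[str, Node] = {}
        for leaf in self.leaves:
            if leaf.label in out:
                raise ValueError(f"duplicate tip label {leaf.label!r}")
            out[leaf.label] = leaf
        return out

    def mrca(self, labels: Iterable[str]) -> Node:
        """Most recent common ancestor of the named tips."""
        lmap = self.leaf_map()
        labels = list(labels)
        if not labels:
            raise ValueError("empty taxon set")
        missing = [x for x in labels if x not in lmap]
        if missing:
            raise KeyError(f"unknown taxa: {missing}")
        paths = []
        for lab in labels:
            path = []
            n: Optional[Node] = lmap[lab]
            while n is not None:
                path.append(n)
                n = n.parent
            paths.append(set(path))
        common = set.intersection(*paths)
        node = lmap[labels[0]]
        while node not in common:
            node = node.parent
        return node

    def subtree_nodes(self, node: Node) -> list[Node]:
        out = []
        stack = [node]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(n.children)
        return out

    def prune_to(self, keep: Iterable[str]) -> "Tree":
        """Return a copy restricted to the named tips.

        Internal nodes left with a single child are suppressed (their ages
        are discarded; the surviving child keeps its own age), so the result
        spans exactly the requested tips, rooted at their MRCA.
        """
        keep = set(keep)
        lmap = self.leaf_map()
        missing = keep - set(lmap)
        if missing:
            raise KeyError(f"unknown taxa: {sorted(missing)}")
        if len(keep) < 2:
            raise ValueError("need at least two tips to prune to")

        def build(node: Node) -> Optional[Node]:
            if node.is_leaf:
                if node.label in keep:
                    return Node(node.label, node.age)
                return None
            kids = [build(c) for c in node.children]
            kids = [k for k in kids if k is not None]
            if not kids:
                return None
            if len(kids) == 1:
                return kids[0]
            new = Node(node.label, node.age)
            for k in kids:
                new.add_child(k)
            return new

        import sys

        old = sys.getrecursionlimit()
        sys.setrecursionlimit(max(old, len(self.nodes) + 100))
        try:
            root = build(self.root)
        finally:
            sys.setrecursionlimit(old)
        assert root is not None
        return Tree(root)

    # ------------------------------------------------------------------
    # serialisation helper (Newick text; file IO lives in io.py)
    # ------------------------------------------------------------------
    def newick(self, lengths: bool = True, internal_labels: bool = False) -> str:
        parts: dict[int, str] = {}
        for n in self.nodes:  # postorder: children before parents
            if n.is_leaf:
                s = _quote(n.label or "")
            else:
                s = "(" + ",".join(parts[c.index] for c in n.children) + ")"
                if internal_labels and n.label:
                    s += _quote(n.label)
            if lengths and n.parent is not None and n.age is not None and n.parent.age is not None:
                s += f":{n.parent.age - n.age:.6f}"
            parts[n.index] = s
        return parts[self.root.index] + ";"


def _quote(label: str) -> str:
    if any(ch in label for ch in " ()[]{}/\\,;:=*'\"`<>"):
        return "'" + label.replace("'", "''") + "'"
    return label


def cherry(a: str, b: str, age_a: float = 0.0, age_b: float = 0.0,
           root_age: Optional[float] = None) -> Tree:
    """Convenience two-tip tree, used widely in tests and examples."""
    root = Node(age=root_age)
    root.add_child(Node(a, age_a))
    root.add_child(Node(b, age_b))
    return Tree(root)
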