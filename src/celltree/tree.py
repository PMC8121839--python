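"""Rooted classification trees with named nodes.

A :class:`ClassificationTree` encodes the hierarchy of cell populations that
all classifiers, matching steps and scores traverse.  Every node carries a
population name that is unique within the tree; the single root is a synthetic
node conventionally named ``"root"`` that never carries a classifier.  A flat
classifier is simply a tree of depth one (root with only leaf children).

Trees are read and written as Newick text with named internal nodes and no
branch lengths (lengths are ignored on read, never written).  Child order is
insertion order and is preserved by serialisation, so serialisation is
deterministic.
"""

from __future__ import annotations

from typing import Iterable, Iterator

ROOT_NAME = "root"

#: Reserved prediction label for cells that no node claims.
REJECTED = "rejected"

# Characters with structural meaning in Newick; names containing them are
# single-quoted on write.
_SPECIAL = set("(),;:")


class TreeNode:
    """A single named node of a classification tree."""

    __slots__ = ("name", "children", "parent")

    def __init__(self, name: str, children: Iterable["TreeNode"] = ()):
        if not name:
            raise ValueError("node name must be a non-empty string")
        self.name = name
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None
        for child in children:
            self.add_child(child)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "TreeNode") -> None:
        child.parent = self
        self.children.append(child)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TreeNode({self.name!r}, {len(self.children)} children)"


class ClassificationTree:
    """Rooted tree of named cell populations.

    Parameters
    ----------
    root : TreeNode
        Root of the tree.  Node names must be unique.

    Attributes
    ----------
    root : TreeNode
    synonyms : dict[str, set[str]]
        Alternative names per node (e.g. the label a matched dataset used for
        a population that perfectly matched an existing node).
    """

    def __init__(self, root: TreeNode):
        self.root = root
        self.synonyms: dict[str, set[str]] = {}
        self._reindex()

    # ------------------------------------------------------------------ #
    # construction / serialisation
    # ------------------------------------------------------------------ #

    @classmethod
    def from_newick(cls, text: str) -> "ClassificationTree":
        """Parse Newick text with named internal nodes into a tree."""
        return cls(parse_newick(text))

    def to_newick(self) -> str:
        """Serialise to Newick text (deterministic given child order)."""

        def fmt(node: TreeNode) -> str:
            name = _quote(node.name)
            if node.is_leaf:
                return name
            inner = ",".join(fmt(c) for c in node.children)
            return f"({inner}){name}"

        return fmt(self.root) + ";"

    @classmethod
    def flat(cls, labels: Iterable[str]) -> "ClassificationTree":
        """Depth-one tree: root with one leaf per (unique, ordered) label."""
        seen: dict[str, None] = {}
        for lab in labels:
            seen.setdefault(str(lab), None)
        root = TreeNode(ROOT_NAME, [TreeNode(lab) for lab in seen])
        return cls(root)

    def copy(self) -> "ClassificationTree":
        def clone(node: TreeNode) -> TreeNode:
            return TreeNode(node.name, [clone(c) for c in node.children])

        new = ClassificationTree(clone(self.root))
        new.synonyms = {k: set(v) for k, v in self.synonyms.items()}
        return new

    # ------------------------------------------------------------------ #
    # lookups and traversal
    # ------------------------------------------------------------------ #

    def node(self, name: str) -> TreeNode:
        try:
            return self._index[name]
        except KeyError:
            raise KeyError(f"unknown node {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def __iter__(self) -> Iterator[TreeNode]:
        """Preorder traversal (root first, children in insertion order)."""
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def names(self) -> list[str]:
        return [n.name for n in self]

    def nonroot_names(self) -> list[str]:
        return [n.name for n in self if n is not self.root]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self if n.is_leaf]

    def internal_names(self) -> list[str]:
        """Non-root nodes that have children."""
        return [n.name for n in self if n.children and n is not self.root]

    def __len__(self) -> int:
        return len(self._index)

    def ancestors(self, name: str) -> list[str]:
        """Names from the immediate parent up to, but excluding, the root.

        The root is excluded by contract (ancestor overlap with the root would
        be awarded to every prediction and is uninformative); asking for the
        root's ancestors is therefore an error.
        """
        node = self.node(name)
        if node is self.root:
            raise ValueError("the root has no ancestors by contract")
        out = []
        node = node.parent
        while node is not None and node is not self.root:
            out.append(node.name)
            node = node.parent
        return out

    def subtree_labels(self, name: str) -> set[str]:
        """The node's name plus all descendant names (positive-sample pool)."""
        start = self.node(name)
        out = set()
        stack = [start]
        while stack:
            node = stack.pop()
            out.add(node.name)
            stack.extend(node.children)
        return out

    def is_ancestor(self, ancestor: str, descendant: str) -> bool:
        node = self.node(descendant).parent
        while node is not None:
            if node.name == ancestor:
                return True
            node = node.parent
        return False

    # ------------------------------------------------------------------ #
    # edits (used by tree updating); each edit revalidates invariants
    # ------------------------------------------------------------------ #

    def add_child(self, parent_name: str, name: str) -> TreeNode:
        """Attach a new leaf ``name`` under ``parent_name``."""
        if name in self._index:
            raise ValueError(f"duplicate node name {name!r}")
        parent = self.node(parent_name)
        child = TreeNode(name)
        parent.add_child(child)
        self._reindex()
        return child

    def insert_parent(self, name: str, child_names: Iterable[str]) -> TreeNode:
        """Insert a new node ``name`` between a set of siblings and their parent."""
        if name in self._index:
            raise ValueError(f"duplicate node name {name!r}")
        children = [self.node(c) for c in child_names]
        if not children:
            raise ValueError("insert_parent needs at least one child")
        parents = {id(c.parent) for c in children}
        if len(parents) != 1 or children[0].parent is None:
            raise ValueError(
                f"nodes {sorted(c.name for c in children)} are not siblings"
            )
        parent = children[0].parent
        new = TreeNode(name)
        slot = parent.children.index(children[0])
        for c in children:
            parent.children.remove(c)
            new.add_child(c)
        parent.children.insert(slot, new)
        new.parent = parent
        self._reindex()
        return new

    def add_synonym(self, name: str, alias: str) -> None:
        """Record ``alias`` as an alternative name for node ``name``."""
        self.node(name)
        if alias in self._index and alias != name:
            raise ValueError(f"alias {alias!r} is already a node name")
        self.synonyms.setdefault(name, set()).add(alias)

    def name_set(self, name: str) -> set[str]:
        """Primary name plus recorded synonyms of a node."""
        return {name} | self.synonyms.get(name, set())

    # ------------------------------------------------------------------ #
    # invariants
    # ------------------------------------------------------------------ #

    def _reindex(self) -> None:
        index: dict[str, TreeNode] = {}
        stack: list[TreeNode] = [self.root]
        while stack:
            node = stack.pop()
            if node.name in index:
                raise ValueError(f"duplicate node name {node.name!r}")
            index[node.name] = node
            for child in node.children:
                if child.parent is not node:
                    raise ValueError(
                        f"broken parent link at node {child.name!r}"
                    )
                stack.append(child)
        if self.root.parent is not None:
            raise ValueError("root must not have a parent")
        self._index = index

    def validate(self) -> None:
        """Re-check unique names, single root and parent links."""
        self._reindex()

    # ------------------------------------------------------------------ #

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ClassificationTree):
            return NotImplemented

        def eq(a: TreeNode, b: TreeNode) -> bool:
            return (
                a.name == b.name
                and len(a.children) == len(b.children)
                and all(eq(x, y) for x, y in zip(a.children, b.children))
            )

        return eq(self.root, other.root)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"ClassificationTree({self.to_newick()!r})"


def trees_equivalent(
    learned: ClassificationTree, expected: ClassificationTree
) -> bool:
    """Topology equality up to synonyms and child order.

    A learned node is identified with an expected node when any of its
    recorded names (primary or synonym) matches; children are compared as
    unordered sets.  Useful for checking a progressively learned tree
    against a ground-truth hierarchy whose populations may have entered
    under a different dataset's label.
    """
    expected_names = set(expected.names())

    def canon_learned(node: TreeNode):
        names = learned.name_set(node.name) & expected_names
        rep = sorted(names)[0] if names else node.name
        return (rep, tuple(sorted(canon_learned(c) for c in node.children)))

    def canon_expected(node: TreeNode):
        return (node.name, tuple(sorted(canon_expected(c) for c in node.children)))

    return canon_learned(learned.root) == canon_expected(expected.root)


# ---------------------------------------------------------------------- #
# Newick parsing
# ---------------------------------------------------------------------- #


def _quote(name: str) -> str:
    if any(c in _SPECIAL for c in name) or name != name.strip() or "'" in name:
        return "'" + name.replace("'", "''") + "'"
    return name


def parse_newick(text: str) -> TreeNode:
    """Parse a Newick string in which *every* node is named.

    Branch lengths (``:0.1``) are accepted and ignored.  Unnamed nodes raise an
    error reporting the character position; duplicate names raise an error
    naming the duplicate (via :class:`ClassificationTree` indexing).
    """
    s = text.strip()
    if not s.endswith(";"):
        raise ValueError("Newick text must end with ';'")
    s = s[:-1]
    pos = 0

    def error(msg: str) -> ValueError:
        return ValueError(f"{msg} at position {pos}")

    def skip_ws() -> None:
        nonlocal pos
        while pos < len(s) and s[pos].isspace():
            pos += 1

    def parse_name() -> str:
        nonlocal pos
        skip_ws()
        if pos < len(s) and s[pos] == "'":
            pos += 1
            out = []
            while pos < len(s):
                if s[pos] == "'":
                    if pos + 1 < len(s) and s[pos + 1] == "'":
                        out.append("'")
                        pos += 2
                        continue
                    pos += 1
                    break
                out.append(s[pos])
                pos += 1
            else:
                raise error("unterminated quoted name")
            name = "".join(out)
        else:
            start = pos
            while pos < len(s) and s[pos] not in _SPECIAL:
                pos += 1
            name = s[start:pos].strip()
        # ignore a branch length if present
        skip_ws()
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in "(),;":
                pos += 1
        return name

    def parse_subtree() -> TreeNode:
        nonlocal pos
        skip_ws()
        if pos < len(s) and s[pos] == "(":
            pos += 1
            children = [parse_subtree()]
            skip_ws()
            while pos < len(s) and s[pos] == ",":
                pos += 1
                children.append(parse_subtree())
            skip_ws()
            if pos >= len(s) or s[pos] != ")":
                raise error("expected ')'")
            pos += 1
            name = parse_name()
            if not name:
                raise error("unnamed internal node")
            node = TreeNode(name)
            for c in children:
                node.add_child(c)
            return node
        name = parse_name()
        if not name:
            raise error("unnamed leaf node")
        return TreeNode(name)

    root = parse_subtree()
    skip_ws()
    if pos != len(s):
        raise error(f"unexpected trailing text {s[pos:]!r}")
    return root


# Functional aliases matching the operation-level vocabulary.


def parse_tree(text: str) -> ClassificationTree:
    """Parse Newick text into a :class:`ClassificationTree`."""
    return ClassificationTree.from_newick(text)


def serialize_tree(tree: ClassificationTree) -> str:
    """Serialise a tree to Newick text."""
    return tree.to_newick()


def ancestors(tree: ClassificationTree, name: str) -> list[str]:
    """Ancestor names of ``name`` from parent upward, root excluded."""
    return tree.ancestors(name)


def subtree_labels(tree: ClassificationTree, name: str) -> set[str]:
    """``name`` plus all of its descendants' names."""
    return tree.subtree_labels(name)
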