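"""Rooted trees, Newick I/O, supertree grafting, and clade queries.

Trees are rooted, may contain polytomies, and carry optional branch
lengths (Myr) and node ages (Ma).  Tip labels are taxon identifiers and
must be unique within a tree.  Newick parsing is delegated to dendropy;
the in-memory representation is a small purpose-built node/tree pair so
that grafting surgery, age bookkeeping and stable node ids stay simple.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import dendropy


class TreeError(ValueError):
    """Structural or validation problem with a tree."""


class NewickParseError(TreeError):
    """Malformed Newick input."""


class GraftConflictError(TreeError):
    """A source tree re-introduces a taxon already placed in the backbone."""


class Node:
    """One node of a rooted tree.

    Attributes
    ----------
    label : str or None
        Taxon identifier for tips; optional name for internal nodes.
    length : float or None
        Length of the branch subtending this node, in Myr.
    age : float or None
        Node age in Ma (before present); set by timescaling.
    id : int
        Stable postorder index, assigned by :meth:`Tree.assign_ids`.
    """

    __slots__ = ("label", "parent", "children", "length", "age", "id")

    def __init__(self, label: Optional[str] = None, length: Optional[float] = None):
        self.label = label
        self.parent: Optional[Node] = None
        self.children: list[Node] = []
        self.length = length
        self.age: Optional[float] = None
        self.id: int = -1

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["Node"]:
        for child in self.children:
            yield from child.postorder()
        yield self

    def preorder(self) -> Iterator["Node"]:
        yield self
        for child in self.children:
            yield from child.preorder()

    def leaves(self) -> Iterator["Node"]:
        return (n for n in self.postorder() if n.is_leaf)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"{len(self.children)}-furcation"
        return f"<Node {self.label or '(unnamed)'} {kind}>"


class Tree:
    """A rooted tree with unique tip labels; polytomies permitted."""

    def __init__(self, root: Node):
        self.root = root
        self.mbl: Optional[float] = None          # set by timescaling
        self.branch_mode: Optional[str] = None    # "timescaled" | "unit"
        self.assign_ids()
        self.validate()

    # -- structure -----------------------------------------------------
    def assign_ids(self) -> None:
        for i, node in enumerate(self.root.postorder()):
            node.id = i

    def validate(self) -> None:
        labels = [n.label for n in self.leaves()]
        seen: set[str] = set()
        for lab in labels:
            if lab is None:
                raise TreeError("every tip must carry a taxon label")
            if lab in seen:
                raise TreeError(f"duplicate tip label: {lab!r}")
            seen.add(lab)
        for node in self.root.postorder():
            if node.length is not None and node.length < 0:
                raise TreeError(
                    f"negative branch length {node.length} at node {node.label or node.id}"
                )

    def postorder(self) -> Iterator[Node]:
        return self.root.postorder()

    def preorder(self) -> Iterator[Node]:
        return self.root.preorder()

    def leaves(self) -> Iterator[Node]:
        return self.root.leaves()

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.leaves())

    @property
    def n_nodes(self) -> int:
        return sum(1 for _ in self.postorder())

    def find_leaf(self, label: str) -> Node:
        for node in self.leaves():
            if node.label == label:
                return node
        raise TreeError(f"taxon {label!r} is not a tip of this tree")

    def depth(self) -> float:
        """Maximum root-to-tip path length (branch lengths must be set)."""
        best = 0.0

        def walk(node: Node, acc: float) -> None:
            nonlocal best
            acc += node.length or 0.0
            if node.is_leaf:
                best = max(best, acc)
            for c in node.children:
                walk(c, acc)

        for c in self.root.children:
            walk(c, 0.0)
        return best

    def copy(self) -> "Tree":
        def clone(node: Node) -> Node:
            new = Node(node.label, node.length)
            new.age = node.age
            for c in node.children:
                new.add_child(clone(c))
            return new

        t = Tree(clone(self.root))
        t.mbl = self.mbl
        t.branch_mode = self.branch_mode
        return t

    # -- queries -------------------------------------------------------
    def mrca(self, taxa: Iterable[str]) -> Node:
        """Most recent common ancestor of a set of tips.

        A singleton set returns the tip itself.
        """
        taxa = list(taxa)
        if not taxa:
            raise TreeError("mrca requires at least one taxon")
        nodes = [self.find_leaf(t) for t in taxa]

        def ancestors(n: Node) -> list[Node]:
            path = [n]
            while path[-1].parent is not None:
                path.append(path[-1].parent)
            return path

        common = set(ancestors(nodes[0]))
        for n in nodes[1:]:
            common &= set(ancestors(n))
        # deepest common ancestor = the one whose parent is not common
        for anc in ancestors(nodes[0]):
            if anc in common:
                return anc
        raise TreeError("disconnected tree")  # pragma: no cover

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Tree with {self.n_tips} tips>"


@dataclass(frozen=True)
class CladeDefinition:
    """A named clade, defined as the MRCA of a set of ≥2 tips."""

    name: str
    defining_taxa: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        object.__setattr__(self, "defining_taxa", frozenset(self.defining_taxa))
        if len(self.defining_taxa) < 2:
            raise ValueError(f"clade {self.name!r} needs >=2 defining taxa")


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def parse_newick(text: str) -> Tree:
    """Parse a single rooted Newick statement into a :class:`Tree`.

    Internal node labels are read and stored but ignored by analyses;
    unlabeled internal nodes and polytomies are fine.  Duplicate tip
    labels raise a validation error naming the label.
    """
    text = text.strip()
    if not text:
        raise NewickParseError("empty Newick string")
    if not text.endswith(";"):
        raise NewickParseError(
            f"Newick statement must end with ';' (offset {len(text)})"
        )
    # cheap structural pre-check so errors carry a character offset
    depth = 0
    in_quote = False
    for i, ch in enumerate(text):
        if ch == "'":
            in_quote = not in_quote
        elif not in_quote:
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
                if depth < 0:
                    raise NewickParseError(f"unbalanced ')' at offset {i}")
    if in_quote:
        raise NewickParseError(f"unterminated quote (offset {len(text)})")
    if depth != 0:
        raise NewickParseError(f"unbalanced '(' (offset {len(text)})")

    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises assorted DataError subclasses
        raise NewickParseError(f"malformed Newick: {exc}") from exc

    def convert(dnode) -> Node:
        if dnode.taxon is not None:
            label = dnode.taxon.label
        else:
            label = dnode.label
        node = Node(label=label, length=dnode.edge.length)
        for dchild in dnode.child_nodes():
            node.add_child(convert(dchild))
        return node

    root = convert(dtree.seed_node)
    root.length = None  # no stem edge on the root
    return Tree(root)


def _format_label(label: str) -> str:
    if any(ch in label for ch in "(),:;[] \t'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: Tree, include_lengths: bool = True) -> str:
    """Serialize a tree to Newick; inverse of :func:`parse_newick`."""
    if tree is None or tree.root is None:
        raise TreeError("cannot serialize an empty tree")

    def fmt(node: Node) -> str:
        if node.is_leaf:
            s = _format_label(node.label)
        else:
            s = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.label:
                s += _format_label(node.label)
        if include_lengths and node.length is not None and node.parent is not None:
            s += f":{node.length!r}"  # shortest exact float: lossless round trip
        return s

    return fmt(tree.root) + ";"


def read_newick_file(path) -> Tree:
    with open(path, "r", encoding="utf-8") as fh:
        return parse_newick(fh.read())


def write_newick_file(tree: Tree, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(write_newick(tree) + "\n")


# ---------------------------------------------------------------------------
# Isomorphism (used by tests and the grafting contract)
# ---------------------------------------------------------------------------

def canonical_form(tree: Tree, with_lengths: bool = False):
    """Order-independent canonical representation of a rooted tree."""

    def canon(node: Node):
        if node.is_leaf:
            base = ("leaf", node.label)
        else:
            base = ("clade", tuple(sorted(canon(c) for c in node.children)))
        if with_lengths:
            return (base, None if node.length is None else round(node.length, 9))
        return base

    return canon(tree.root)


def trees_isomorphic(a: Tree, b: Tree, with_lengths: bool = False) -> bool:
    return canonical_form(a, with_lengths) == canonical_form(b, with_lengths)


def induced_subtree(tree: Tree, taxa: Iterable[str]) -> Tree:
    """Restriction of a tree to a subset of its tips, unifurcations suppressed."""
    keep = set(taxa)
    missing = keep - set(tree.leaf_labels())
    if missing:
        raise TreeError(f"taxa not in tree: {sorted(missing)}")

    def restrict(node: Node) -> Optional[Node]:
        if node.is_leaf:
            return Node(node.label, node.length) if node.label in keep else None
        kids = [k for k in (restrict(c) for c in node.children) if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]
        new = Node(node.label, node.length)
        for k in kids:
            new.add_child(k)
        return new

    root = restrict(tree.root)
    if root is None:
        raise TreeError("restriction is empty")
    root.length = None
    return Tree(root)


# ---------------------------------------------------------------------------
# Supertree grafting
# ---------------------------------------------------------------------------

def graft(backbone: Tree, source: Tree, landmark: str, on_shared: str = "prune") -> Tree:
    """Graft a source tree onto a backbone at a shared landmark taxon.

    The landmark tip of the backbone is replaced, in situ, by the
    smallest source clade containing the landmark plus every source
    taxon absent from the backbone.  Taxa shared between source and
    backbone other than the landmark stay at their backbone positions:
    with ``on_shared="prune"`` (default) they are dropped from the
    grafted subtree with a topology-conflict warning; with
    ``on_shared="error"`` a :class:`GraftConflictError` names the taxon.

    The induced subtree of the result restricted to the backbone's taxa
    is always isomorphic to the backbone.
    """
    if on_shared not in ("prune", "error"):
        raise ValueError("on_shared must be 'prune' or 'error'")
    backbone_taxa = set(backbone.leaf_labels())
    source_taxa = set(source.leaf_labels())
    if landmark not in backbone_taxa:
        raise TreeError(f"landmark {landmark!r} is not a tip of the backbone")
    if landmark not in source_taxa:
        raise TreeError(f"landmark {landmark!r} is not a tip of the source")

    new_taxa = source_taxa - backbone_taxa
    result = backbone.copy()
    if not new_taxa:
        return result  # nothing to add: idempotent

    attach_root = source.mrca({landmark} | new_taxa)

    def clone(node: Node) -> Node:
        new = Node(node.label, node.length)
        new.age = node.age
        for c in node.children:
            new.add_child(clone(c))
        return new

    sub = clone(attach_root)

    # drop shared-but-not-landmark taxa from the grafted piece
    shared_extra = (source_taxa & backbone_taxa) - {landmark}

    def prune_leaf(root: Node, label: str) -> Node:
        target = next(n for n in root.postorder() if n.is_leaf and n.label == label)
        parent = target.parent
        if parent is None:
            raise GraftConflictError(f"cannot prune the subtree root {label!r}")
        parent.children.remove(target)
        if len(parent.children) == 1 and parent.parent is not None:
            only = parent.children[0]
            only.parent = parent.parent
            idx = parent.parent.children.index(parent)
            parent.parent.children[idx] = only
        elif len(parent.children) == 1 and parent.parent is None:
            only = parent.children[0]
            only.parent = None
            return only
        return root

    for taxon in sorted(shared_extra):
        if any(n.label == taxon for n in sub.postorder() if n.is_leaf):
            if on_shared == "error":
                raise GraftConflictError(
                    f"taxon {taxon!r} of the source is already present in the backbone"
                )
            warnings.warn(
                f"topology conflict: shared taxon {taxon!r} kept at its backbone "
                f"position and pruned from the grafted source subtree",
                stacklevel=2,
            )
            sub = prune_leaf(sub, taxon)

    # splice: the grafted clade inherits the landmark tip's branch length
    old_tip = result.find_leaf(landmark)
    sub.length = old_tip.length
    parent = old_tip.parent
    if parent is None:  # single-tip backbone
        sub.length = None
        out = Tree(sub)
    else:
        idx = parent.children.index(old_tip)
        parent.children[idx] = sub
        sub.parent = parent
        out = Tree(result.root)
    return out
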