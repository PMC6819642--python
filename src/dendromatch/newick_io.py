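"""Reading, writing and height annotation of rooted dendrograms.

A dendrogram is a rooted tree produced by hierarchical clustering: every
internal node records the distance (measured from the leaves) at which its
descendant clusters were merged.  Trees travel as Newick text with branch
lengths and leaf names; parsing is delegated to Biopython's Newick reader,
which keeps unquoted underscores verbatim and takes quoted labels as-is, so
replicate suffixes in leaf names survive exactly.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from io import StringIO
from typing import Iterator

from Bio import Phylo

from .errors import NewickParseError, ValidationError

# Program-wide id stream: node ids are unique across every tree built in a
# session, so (tree-role, node-id) pairs are never ambiguous.
_NODE_IDS = itertools.count()


@dataclass(eq=False)
class DendroNode:
    """One node of a dendrogram.

    ``height`` is the distance from this node down to the leaves: 0 for
    every leaf, and for an internal node the maximum over descendant leaves
    of the summed branch lengths on the way down (in an ultrametric tree all
    those sums agree and height is the merge distance).
    """

    name: str | None = None
    branch_length: float = 0.0
    children: list["DendroNode"] = field(default_factory=list)
    height: float = 0.0
    id: int = field(default_factory=lambda: next(_NODE_IDS))
    parent: "DendroNode | None" = field(default=None, repr=False)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk_postorder(self) -> Iterator["DendroNode"]:
        for child in self.children:
            yield from child.walk_postorder()
        yield self

    def walk_preorder(self) -> Iterator["DendroNode"]:
        yield self
        for child in self.children:
            yield from child.walk_preorder()

    def leaves(self) -> list["DendroNode"]:
        return [n for n in self.walk_postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]  # type: ignore[misc]


@dataclass(eq=False)
class Dendrogram:
    """A rooted dendrogram plus display metadata."""

    root: DendroNode
    title: str = "dendrogram"
    #: display orientation: "root-left" draws the root on the left and the
    #: leaves (with their labels) on the right; flipping toggles it.
    orientation: str = "root-left"

    @property
    def leaf_count(self) -> int:
        return len(self.root.leaves())

    @property
    def root_height(self) -> float:
        return self.root.height

    def nodes(self) -> list[DendroNode]:
        return list(self.root.walk_postorder())

    def internal_nodes(self) -> list[DendroNode]:
        return [n for n in self.root.walk_postorder() if not n.is_leaf]

    def copy(self) -> "Dendrogram":
        """Deep structural copy with fresh node ids."""

        def rec(node: DendroNode) -> DendroNode:
            clone = DendroNode(name=node.name, branch_length=node.branch_length)
            clone.children = [rec(c) for c in node.children]
            for c in clone.children:
                c.parent = clone
            return clone

        out = Dendrogram(root=rec(self.root), title=self.title,
                         orientation=self.orientation)
        return compute_heights(out)


def _scan_newick(text: str) -> None:
    """Pre-validate parenthesis/quote balance, reporting character offsets.

    Biopython reports malformed input without positions; this scan covers
    the structural errors worth pinpointing.
    """
    if not text.strip():
        raise NewickParseError("empty Newick input")
    depth = 0
    in_quote = False
    quote_start = -1
    terminated_at = -1
    for i, ch in enumerate(text):
        if in_quote:
            if ch == "'":
                in_quote = False
            continue
        if ch == "'":
            in_quote = True
            quote_start = i
        elif ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise NewickParseError("unbalanced ')'", offset=i)
        elif ch == ";":
            if depth != 0:
                raise NewickParseError(
                    f"';' inside {depth} unclosed parenthesis group(s)", offset=i)
            terminated_at = i
            break
    if in_quote:
        raise NewickParseError("unterminated quoted label", offset=quote_start)
    if depth > 0:
        raise NewickParseError(f"{depth} unclosed '(' at end of input",
                               offset=len(text) - 1)
    if terminated_at < 0:
        raise NewickParseError("missing ';' terminator", offset=len(text) - 1)


def parse_newick(text: str, title: str = "dendrogram") -> Dendrogram:
    """Parse one ';'-terminated Newick statement into a :class:`Dendrogram`.

    Missing branch lengths default to 0; the root's branch length is always
    treated as 0.  Internal node names and numeric support annotations are
    preserved on the nodes but ignored by every algorithm in this package.
    Duplicate full leaf names only warn: matching operates on sample types,
    so repeated full names are tolerable.
    """
    _scan_newick(text)
    try:
        clade_tree = Phylo.read(StringIO(text), "newick")
    except Exception as exc:  # pragma: no cover - pre-scan catches most
        raise NewickParseError(str(exc)) from exc

    def rec(clade) -> DendroNode:
        name = clade.name
        if name is None and clade.confidence is not None and not clade.clades:
            name = str(clade.confidence)
        node = DendroNode(
            name=name,
            branch_length=float(clade.branch_length or 0.0),
            children=[rec(c) for c in clade.clades],
        )
        for c in node.children:
            c.parent = node
        return node

    root = rec(clade_tree.root)
    root.branch_length = 0.0
    for leaf in root.leaves():
        if not leaf.name:
            raise NewickParseError("leaf without a name")
    names = root.leaf_names()
    if len(names) != len(set(names)):
        dupes = sorted({n for n in names if names.count(n) > 1})
        warnings.warn(f"duplicate leaf names tolerated: {', '.join(dupes)}",
                      stacklevel=2)
    return compute_heights(Dendrogram(root=root, title=title))


def parse_newick_file(path, title: str | None = None) -> Dendrogram:
    """Read one Newick tree from ``path``; the title defaults to the file stem."""
    from pathlib import Path

    p = Path(path)
    return parse_newick(p.read_text(), title=title or p.stem)


def _fmt_length(x: float) -> str:
    s = f"{x:.12g}"
    return s


def write_newick(d: Dendrogram) -> str:
    """Serialize a dendrogram as one Newick statement.

    Every non-root node carries its branch length; leaves carry their names;
    child order is emitted exactly as stored, so output is deterministic.
    """

    def needs_quotes(name: str) -> bool:
        return any(c in name for c in "()[]{}:;,'\" \t\n")

    def fmt_name(name: str) -> str:
        if needs_quotes(name):
            return "'" + name.replace("'", "''") + "'"
        return name

    def rec(node: DendroNode, is_root: bool) -> str:
        if node.is_leaf:
            body = fmt_name(node.name or "")
        else:
            body = "(" + ",".join(rec(c, False) for c in node.children) + ")"
            if node.name:
                body += fmt_name(node.name)
        if not is_root:
            body += ":" + _fmt_length(node.branch_length)
        return body

    root = d.root
    if root.is_leaf:
        # degenerate single-leaf tree: keep the conventional wrapping parens
        return f"({fmt_name(root.name or '')}:{_fmt_length(root.height)});"
    return rec(root, True) + ";"


def compute_heights(d: Dendrogram) -> Dendrogram:
    """Annotate every node with its height (distance down to the leaves).

    height(leaf) = 0; height(node) = max over children of
    child.height + child.branch_length.  For ultrametric trees — the normal
    output of agglomerative clustering — this is the merge distance; for
    non-ultrametric input the max-over-descendants rule keeps heights
    monotone from leaves to root so threshold semantics degrade gracefully.
    """
    for node in d.root.walk_postorder():
        if node.branch_length < 0:
            raise ValidationError(
                f"negative branch length {node.branch_length} on node "
                f"{node.name or node.id}")
        if node.is_leaf:
            node.height = 0.0
        else:
            node.height = max(c.height + c.branch_length for c in node.children)
    return d
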