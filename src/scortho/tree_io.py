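"""Tree structures, Newick I/O and the structural edits applied upstream of
reconciliation: support collapsing, taxon pruning and rooting enumeration.

Newick conventions
------------------
Internal node labels are interpreted as bootstrap support values by default
(the convention of most maximum-likelihood tree builders); pass
``internal_labels="name"`` to :func:`parse_newick` to keep them as plain
names.  Unquoted underscores are preserved verbatim; labels containing
whitespace or Newick punctuation are single-quoted on output.  A tree whose
root has exactly two children is treated as rooted; a root of degree three or
more marks the tree as unrooted (override with the ``rooted`` argument).

Branches that carry *no* support value are treated as resolved: collapsing
removes only branches whose support is present and falls below the threshold.
"""

from __future__ import annotations

import io
from typing import Callable, Iterable, Iterator, Mapping

import dendropy

__all__ = [
    "TreeNode",
    "Tree",
    "TaxonMap",
    "NewickError",
    "TreeValidationError",
    "EmptyTreeError",
    "parse_newick",
    "write_newick",
    "collapse_low_support",
    "prune_to_taxa",
    "unroot",
    "enumerate_rootings",
    "edge_bipartition_id",
    "rooted_shape",
    "unrooted_shape",
    "trees_isomorphic",
]

#: Default separator between the taxon prefix and the gene part of a leaf
#: label, e.g. ``"T03|fam0001_g2"`` belongs to taxon ``"T03"``.
DEFAULT_GENE_DELIMITER = "|"

_NEEDS_QUOTING = set(" \t\n()[]':;,")


class NewickError(ValueError):
    """Raised for syntactically invalid Newick input.

    The message includes the line/column position reported by the parser.
    """


class TreeValidationError(ValueError):
    """Raised when a tree violates a structural invariant."""


class EmptyTreeError(TreeValidationError):
    """Raised when an operation would leave a tree without any leaves."""


class TreeNode:
    """A node of a (possibly multifurcating) tree.

    Attributes
    ----------
    label:
        Taxon id for species-tree leaves, gene id for gene-tree leaves,
        free text (usually empty) for internal nodes.
    length:
        Branch length of the edge above this node, or ``None``.
    support:
        Bootstrap support (0..100) of the edge above this node, or ``None``.
        Only meaningful on internal branches.
    children:
        Ordered list of child nodes; empty for leaves.
    inferred:
        True for nodes introduced by soft-polytomy refinement (not observed
        in the input tree).
    """

    __slots__ = ("label", "length", "support", "children", "inferred")

    def __init__(self, label="", length=None, support=None, children=None,
                 inferred=False):
        self.label = label
        self.length = length
        self.support = support
        self.children = list(children) if children is not None else []
        self.inferred = inferred

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, node: "TreeNode") -> "TreeNode":
        self.children.append(node)
        return node

    def postorder(self) -> Iterator["TreeNode"]:
        for child in self.children:
            yield from child.postorder()
        yield self

    def preorder(self) -> Iterator["TreeNode"]:
        yield self
        for child in self.children:
            yield from child.preorder()

    def leaves(self) -> Iterator["TreeNode"]:
        if self.is_leaf:
            yield self
        else:
            for child in self.children:
                yield from child.leaves()

    def copy(self) -> "TreeNode":
        return TreeNode(self.label, self.length, self.support,
                        [c.copy() for c in self.children], self.inferred)

    def __repr__(self):  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"internal/{len(self.children)}"
        return f"<TreeNode {kind} {self.label!r}>"


class Tree:
    """A tree plus its rootedness flag.

    An unrooted tree is stored rooted at an arbitrary internal node (usually
    of degree >= 3) with ``rooted`` set to False.
    """

    def __init__(self, root: TreeNode, rooted: bool = True):
        self.root = root
        self.rooted = rooted

    # -- queries ---------------------------------------------------------
    def leaves(self) -> Iterator[TreeNode]:
        return self.root.leaves()

    def leaf_labels(self) -> list[str]:
        return [leaf.label for leaf in self.leaves()]

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in self.leaves())

    @property
    def is_degenerate(self) -> bool:
        """True when fewer than two leaves remain (e.g. after pruning)."""
        return self.n_leaves < 2

    @property
    def is_binary(self) -> bool:
        return all(len(n.children) == 2
                   for n in self.root.postorder() if not n.is_leaf)

    def postorder(self) -> Iterator[TreeNode]:
        return self.root.postorder()

    def preorder(self) -> Iterator[TreeNode]:
        return self.root.preorder()

    def copy(self) -> "Tree":
        return Tree(self.root.copy(), self.rooted)

    def validate(self) -> None:
        """Check leaf-label uniqueness and attribute ranges."""
        seen = set()
        for node in self.root.postorder():
            if node.is_leaf:
                if node.label in seen:
                    raise TreeValidationError(
                        f"duplicate leaf label {node.label!r}")
                seen.add(node.label)
            if node.length is not None and node.length < 0:
                raise TreeValidationError(
                    f"negative branch length {node.length} above "
                    f"{node.label!r}")
            if node.support is not None and not 0 <= node.support <= 100:
                raise TreeValidationError(
                    f"support {node.support} outside [0, 100]")

    def __repr__(self):  # pragma: no cover - debugging aid
        state = "rooted" if self.rooted else "unrooted"
        return f"<Tree {state}, {self.n_leaves} leaves>"


class TaxonMap:
    """Maps gene ids to taxon ids.

    Three flavours, in order of precedence:

    * an explicit gene -> taxon mapping (e.g. loaded from a two-column TSV);
    * a delimiter convention, where the taxon is the prefix of the gene id
      before the first occurrence of the delimiter (``"T03|g12" -> "T03"``);
    * identity (gene id *is* the taxon id) as the fallback, which is what a
      species tree or a one-gene-per-taxon toy tree needs.
    """

    def __init__(self, mapping: Mapping[str, str] | None = None,
                 delimiter: str | None = None):
        self.mapping = dict(mapping) if mapping is not None else None
        self.delimiter = delimiter

    @classmethod
    def identity(cls) -> "TaxonMap":
        return cls()

    @classmethod
    def from_delimiter(cls, delimiter: str = DEFAULT_GENE_DELIMITER) -> "TaxonMap":
        return cls(delimiter=delimiter)

    @classmethod
    def from_tsv(cls, path) -> "TaxonMap":
        mapping = {}
        with open(path, encoding="utf-8") as handle:
            for lineno, line in enumerate(handle, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise TreeValidationError(
                        f"{path}:{lineno}: expected 'gene<TAB>taxon'")
                mapping[fields[0]] = fields[1]
        return cls(mapping=mapping)

    def taxon_for(self, gene_id: str) -> str:
        if self.mapping is not None:
            try:
                return self.mapping[gene_id]
            except KeyError:
                raise TreeValidationError(
                    f"gene {gene_id!r} missing from taxon map") from None
        if self.delimiter and self.delimiter in gene_id:
            return gene_id.split(self.delimiter, 1)[0]
        return gene_id

    def taxa_of(self, tree: Tree) -> set[str]:
        return {self.taxon_for(label) for label in tree.leaf_labels()}


# ---------------------------------------------------------------------------
# Newick I/O (parsing delegated to dendropy)
# ---------------------------------------------------------------------------

def parse_newick(text: str, *, internal_labels: str = "support",
                 rooted: bool | None = None) -> Tree:
    """Parse a single Newick tree.

    Parameters
    ----------
    text:
        The Newick string (one tree, terminated by ``;``).
    internal_labels:
        ``"support"`` (default) reads numeric internal-node labels as
        bootstrap supports of the branch above; ``"name"`` keeps them as
        node names.
    rooted:
        Force the rootedness flag; by default a root of degree two is
        considered rooted, anything else unrooted.
    """
    if internal_labels not in ("support", "name"):
        raise ValueError("internal_labels must be 'support' or 'name'")
    if not text or not text.strip():
        raise NewickError("empty Newick input")
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True)
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise TreeValidationError(f"duplicate leaf labels: {exc}") from exc
    except Exception as exc:  # dendropy raises several DataParseError types
        raise NewickError(f"malformed Newick: {exc}") from exc

    def convert(dnode) -> TreeNode:
        if not dnode.child_nodes():
            label = dnode.taxon.label if dnode.taxon is not None else (dnode.label or "")
            return TreeNode(label=label, length=dnode.edge.length)
        raw = dnode.label or ""
        support = None
        label = raw
        if internal_labels == "support" and raw:
            try:
                support = float(raw)
                label = ""
            except ValueError:
                pass
        node = TreeNode(label=label, length=dnode.edge.length, support=support)
        for child in dnode.child_nodes():
            node.add_child(convert(child))
        return node

    root = convert(dtree.seed_node)
    if rooted is None:
        rooted = len(root.children) == 2 or root.is_leaf
    tree = Tree(root, rooted=rooted)
    tree.validate()
    return tree


def _format_number(value: float, fmt: str = "%.6g") -> str:
    if value == int(value):
        return str(int(value))
    return fmt % value


def _escape_label(label: str) -> str:
    if label and any(ch in _NEEDS_QUOTING for ch in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: Tree, *, lengths: bool = True,
                 supports: bool = True) -> str:
    """Serialise a tree to Newick; supports are emitted as internal labels."""
    out = io.StringIO()

    def write(node: TreeNode) -> None:
        if node.is_leaf:
            out.write(_escape_label(node.label))
        else:
            out.write("(")
            for i, child in enumerate(node.children):
                if i:
                    out.write(",")
                write(child)
            out.write(")")
            if supports and node.support is not None:
                out.write(_format_number(node.support))
            elif node.label:
                out.write(_escape_label(node.label))
        if lengths and node.length is not None:
            out.write(":" + _format_number(node.length))

    write(tree.root)
    out.write(";")
    return out.getvalue()


# ---------------------------------------------------------------------------
# Structural edits
# ---------------------------------------------------------------------------

def collapse_low_support(tree: Tree, threshold: float) -> Tree:
    """Contract every internal branch whose support is below ``threshold``.

    Branches at exactly the threshold are kept, as are branches without a
    support value.  Contracted nodes have their children promoted to the
    grandparent (producing soft polytomies); the contracted branch length is
    added to the promoted children so root-to-leaf distances are preserved.
    """
    if not 0 <= threshold <= 100:
        raise TreeValidationError(
            f"support threshold {threshold} outside [0, 100]")
    result = tree.copy()

    def walk(node: TreeNode) -> None:
        new_children: list[TreeNode] = []
        for child in node.children:
            walk(child)
            if (not child.is_leaf and child.support is not None
                    and child.support < threshold):
                for grandchild in child.children:
                    if child.length is not None:
                        if grandchild.length is None:
                            grandchild.length = child.length
                        else:
                            grandchild.length += child.length
                    new_children.append(grandchild)
            else:
                new_children.append(child)
        node.children = new_children

    walk(result.root)
    return result


def prune_to_taxa(tree: Tree, keep: Iterable[str],
                  taxon_map: TaxonMap | None = None) -> Tree:
    """Restrict a tree to the leaves whose taxon is in ``keep``.

    Unary internal nodes left behind are suppressed with their branch
    lengths summed.  Returns a degenerate tree (flagged via
    :attr:`Tree.is_degenerate`) when fewer than two leaves remain; raises
    :class:`EmptyTreeError` when no leaf survives.
    """
    keep = set(keep)
    if not keep:
        raise TreeValidationError("taxon set to keep is empty")
    tmap = taxon_map if taxon_map is not None else TaxonMap.identity()

    def rec(node: TreeNode) -> TreeNode | None:
        if node.is_leaf:
            if tmap.taxon_for(node.label) in keep:
                return node.copy()
            return None
        kids = [k for k in (rec(c) for c in node.children) if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            child = kids[0]
            if node.length is not None:
                child.length = (child.length or 0.0) + node.length
            return child
        return TreeNode(node.label, node.length, node.support, kids,
                        node.inferred)

    root = rec(tree.root)
    if root is None:
        raise EmptyTreeError("no leaves left after pruning")
    return Tree(root, rooted=tree.rooted)


def unroot(tree: Tree) -> Tree:
    """Return an unrooted copy: a degree-two root is spliced away."""
    result = tree.copy()
    root = result.root
    if len(root.children) != 2:
        return Tree(root, rooted=False)
    first, second = root.children
    inner = first if first.children else second
    if not inner.children:  # two-leaf tree; cannot splice further
        return Tree(root, rooted=False)
    other = second if inner is first else first
    if first.length is not None or second.length is not None:
        other.length = (first.length or 0.0) + (second.length or 0.0)
    else:
        other.length = None
    if other.children:
        other.support = (other.support if other.support is not None
                         else inner.support)
    else:
        other.support = None
    new_root = TreeNode(label=inner.label,
                        children=list(inner.children) + [other])
    return Tree(new_root, rooted=False)


def edge_bipartition_id(clade_labels: Iterable[str],
                        all_labels: Iterable[str]) -> str:
    """Stable identifier for an unrooted-tree edge: the leaf bipartition.

    Each side is sorted and comma-joined; the two sides are then ordered
    lexicographically and joined with ``" | "``.
    """
    clade = set(clade_labels)
    rest = set(all_labels) - clade
    side_a = ",".join(sorted(clade))
    side_b = ",".join(sorted(rest))
    return " | ".join(sorted([side_a, side_b]))


def _adjacency(tree: Tree):
    """Undirected view of a tree: neighbour lists and per-edge attributes."""
    adj: dict[TreeNode, list[TreeNode]] = {}
    attrs: dict[frozenset, tuple] = {}

    def visit(node: TreeNode) -> None:
        adj.setdefault(node, [])
        for child in node.children:
            adj[node].append(child)
            adj.setdefault(child, []).append(node)
            attrs[frozenset((id(node), id(child)))] = (child.length,
                                                       child.support)
            visit(child)

    visit(tree.root)
    return adj, attrs


def _root_on_edge(adj, attrs, parent: TreeNode, child: TreeNode) -> Tree:
    """Build a rooted tree with the root placed on the parent-child edge.

    With branch lengths present the root sits at the edge midpoint; the
    edge's support value is carried onto both root children.
    """
    def build(node: TreeNode, come_from: TreeNode,
              length, support) -> TreeNode:
        kids = []
        for neighbour in adj[node]:
            if neighbour is come_from:
                continue
            elen, esup = attrs[frozenset((id(node), id(neighbour)))]
            kids.append(build(neighbour, node, elen, esup))
        if not kids:
            return TreeNode(node.label, length=length)
        return TreeNode(node.label, length=length,
                        support=support, children=kids)

    elen, esup = attrs[frozenset((id(parent), id(child)))]
    half = elen / 2.0 if elen is not None else None
    root = TreeNode(children=[build(child, parent, half, esup),
                              build(parent, child, half, esup)])
    return Tree(root, rooted=True)


def enumerate_rootings(tree: Tree, *, on_rooted: str = "unroot"
                       ) -> list[tuple[str, Tree]]:
    """All rootings of an unrooted tree, one per edge.

    Returns ``(edge id, rooted tree)`` pairs sorted by edge id.  A fully
    binary unrooted tree on n leaves yields 2n-3 rootings.  Rooted input is
    unrooted first when ``on_rooted="unroot"`` (the default) and rejected
    when ``on_rooted="error"``.
    """
    if tree.n_leaves < 3:
        raise TreeValidationError("rooting enumeration needs >= 3 leaves")
    work = tree
    if tree.rooted or len(tree.root.children) == 2:
        if on_rooted == "error" and tree.rooted:
            raise TreeValidationError("input tree is already rooted")
        work = unroot(tree)
    adj, attrs = _adjacency(work)
    all_labels = work.leaf_labels()
    rootings = []
    for node in work.root.postorder():
        for child in node.children:
            clade = [leaf.label for leaf in child.leaves()]
            eid = edge_bipartition_id(clade, all_labels)
            rootings.append((eid, _root_on_edge(adj, attrs, node, child)))
    rootings.sort(key=lambda pair: pair[0])
    return rootings


# ---------------------------------------------------------------------------
# Order-insensitive comparisons
# ---------------------------------------------------------------------------

def rooted_shape(node: TreeNode):
    """Canonical, child-order-insensitive form of a rooted (sub)tree."""
    if node.is_leaf:
        return ("L", node.label)
    return ("I", tuple(sorted(rooted_shape(c) for c in node.children)))


def unrooted_shape(tree: Tree):
    """Canonical form of a tree regardless of root placement."""
    if tree.n_leaves < 3:
        return ("U", tuple(sorted(tree.leaf_labels())))
    work = tree if not (tree.rooted or len(tree.root.children) == 2) \
        else unroot(tree)
    return ("U", min(rooted_shape(rooted.root)
                     for _, rooted in enumerate_rootings(work)))


def trees_isomorphic(a: Tree, b: Tree, *, rooted: bool = True) -> bool:
    if rooted:
        return rooted_shape(a.root) == rooted_shape(b.root)
    return unrooted_shape(a) == unrooted_shape(b)
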