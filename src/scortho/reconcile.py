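"""Duplication-loss parsimony reconciliation of gene trees with species trees.

The engine maps every gene-tree node to the lowest common ancestor (in the
species tree) of the taxa below it.  An internal gene-tree node is a
duplication when it maps to the same species node as one of its children;
every other internal node is a speciation.  Losses are charged per edge from
the depth difference of the two mappings: ``d - 1`` below a speciation and
``d`` below a duplication, the classical gene-tree-parsimony count.

Unresolved gene-tree nodes are treated as soft polytomies: before counting
events each multifurcation is replaced by a binary refinement of minimal
duplication+loss cost against the species tree, found by a dynamic program
over the species tree (verified optimal against exhaustive resolution in the
test suite).  When the children of a polytomy map to disjoint species
lineages the refinement is free.

Unrooted gene trees are handled by reconciling every possible rooting and
keeping the cheapest; ties are reported in full, with the lexicographically
smallest root-edge bipartition as the canonical representative.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .tree_io import (
    TaxonMap,
    Tree,
    TreeNode,
    edge_bipartition_id,
    enumerate_rootings,
    write_newick,
)

__all__ = [
    "ReconcileError",
    "LcaIndex",
    "Reconciliation",
    "build_lca_index",
    "map_gene_tree",
    "classify_duplications",
    "count_losses",
    "resolve_soft_polytomies",
    "reconcile_rooted",
    "best_rooting",
    "sweep_rootings",
    "all_optimal_rootings",
]


class ReconcileError(ValueError):
    """Raised for inputs the reconciliation engine cannot accept."""


class LcaIndex:
    """Ancestry index over a rooted species tree.

    Answers ``lca(u, v)`` and the downward edge count ``dist(u, v)`` (for
    ``v`` a descendant-or-equal of ``u``) by parent-pointer walks; tree
    sizes here never justify anything fancier.
    """

    def __init__(self, species_tree: Tree):
        if not species_tree.rooted:
            raise ReconcileError("species tree must be rooted")
        species_tree.validate()
        self.tree = species_tree
        self.parent: dict[TreeNode, TreeNode | None] = {species_tree.root: None}
        self.depth: dict[TreeNode, int] = {species_tree.root: 0}
        self.leaf_by_label: dict[str, TreeNode] = {}
        for node in species_tree.preorder():
            for child in node.children:
                self.parent[child] = node
                self.depth[child] = self.depth[node] + 1
            if node.is_leaf:
                self.leaf_by_label[node.label] = node

    @property
    def is_binary(self) -> bool:
        return self.tree.is_binary

    def node_for_taxon(self, taxon: str) -> TreeNode:
        try:
            return self.leaf_by_label[taxon]
        except KeyError:
            raise ReconcileError(
                f"taxon {taxon!r} not found in species tree") from None

    def lca(self, u: TreeNode, v: TreeNode) -> TreeNode:
        du, dv = self.depth[u], self.depth[v]
        while du > dv:
            u = self.parent[u]
            du -= 1
        while dv > du:
            v = self.parent[v]
            dv -= 1
        while u is not v:
            u = self.parent[u]
            v = self.parent[v]
        return u

    def is_ancestor(self, u: TreeNode, v: TreeNode) -> bool:
        """True when ``u`` is an ancestor of (or equal to) ``v``."""
        while self.depth[v] > self.depth[u]:
            v = self.parent[v]
        return u is v

    def dist(self, u: TreeNode, v: TreeNode) -> int:
        """Edges on the path from ``u`` down to its descendant ``v``."""
        if not self.is_ancestor(u, v):
            raise ReconcileError("dist() requires v to descend from u")
        return self.depth[v] - self.depth[u]

    def mrca(self, taxa) -> TreeNode:
        nodes = [self.node_for_taxon(t) for t in taxa]
        if not nodes:
            raise ReconcileError("mrca() of an empty taxon set")
        out = nodes[0]
        for node in nodes[1:]:
            out = self.lca(out, node)
        return out


def build_lca_index(species_tree: Tree) -> LcaIndex:
    return LcaIndex(species_tree)


def map_gene_tree(gene_tree: Tree, taxon_map: TaxonMap,
                  index: LcaIndex) -> dict[TreeNode, TreeNode]:
    """LCA mapping: gene-tree node -> species-tree node."""
    mapping: dict[TreeNode, TreeNode] = {}
    for node in gene_tree.postorder():
        if node.is_leaf:
            taxon = taxon_map.taxon_for(node.label)
            try:
                mapping[node] = index.leaf_by_label[taxon]
            except KeyError:
                raise ReconcileError(
                    f"gene {node.label!r} maps to taxon {taxon!r}, "
                    f"which is not in the species tree") from None
        else:
            value = mapping[node.children[0]]
            for child in node.children[1:]:
                value = index.lca(value, mapping[child])
            mapping[node] = value
    return mapping


def classify_duplications(gene_tree: Tree,
                          mapping: dict[TreeNode, TreeNode]) -> set[TreeNode]:
    """Internal nodes mapping to the same species node as one of their
    children are duplications; all others are speciations."""
    return {node for node in gene_tree.postorder()
            if not node.is_leaf
            and any(mapping[c] is mapping[node] for c in node.children)}


def count_losses(gene_tree: Tree, mapping: dict[TreeNode, TreeNode],
                 duplications: set[TreeNode],
                 index: LcaIndex) -> dict[TreeNode, int]:
    """Per-edge loss counts, keyed by the child node of each edge."""
    losses: dict[TreeNode, int] = {}
    for node in gene_tree.postorder():
        for child in node.children:
            d = index.depth[mapping[child]] - index.depth[mapping[node]]
            losses[child] = d if node in duplications else max(d - 1, 0)
    return losses


# ---------------------------------------------------------------------------
# Soft-polytomy refinement
# ---------------------------------------------------------------------------

def _subtree_mapping(node: TreeNode, taxon_map: TaxonMap,
                     index: LcaIndex) -> TreeNode:
    value = None
    for leaf in node.leaves():
        spec = index.node_for_taxon(taxon_map.taxon_for(leaf.label))
        value = spec if value is None else index.lca(value, spec)
    return value


def _dup_chain(cost: float, forest: list[TreeNode]):
    """All ways of merging a forest down to k subtrees with duplications.

    Yields ``{k: (cost, forest)}``: keeping all ``len(forest)`` subtrees is
    free; every further left-to-right duplication join costs 1.
    """
    options = {}
    if not forest:
        options[0] = (cost, [])
        return options
    current = list(forest)
    extra = 0
    options[len(current)] = (cost, list(current))
    while len(current) > 1:
        joined = TreeNode(children=[current[0], current[1]], inferred=True)
        current = [joined] + current[2:]
        extra += 1
        options[len(current)] = (cost + extra, list(current))
    return options


def _resolve_polytomy(children: list[TreeNode], child_maps: list[TreeNode],
                      index: LcaIndex) -> tuple[TreeNode, int]:
    """Minimum duplication+loss binary refinement of one polytomy.

    Dynamic program over the species tree.  State: ``F[s][k]`` is the
    cheapest way to organise every polytomy child mapping inside the clade
    of species node ``s`` into exactly ``k`` gene lineages present at ``s``.
    Lineages from the two species children are paired into free speciation
    joins; each unpaired lineage carried up costs one loss; surplus lineages
    at a node are merged by duplications at one event each.  Returns the
    root of the refined subtree (a fresh node with two children) and the
    added duplication+loss cost.
    """
    top_species = child_maps[0]
    for value in child_maps[1:]:
        top_species = index.lca(top_species, value)
    mapped_here: dict[TreeNode, list[TreeNode]] = {}
    for child, value in zip(children, child_maps):
        mapped_here.setdefault(value, []).append(child)

    F: dict[TreeNode, dict[int, tuple[int, list[TreeNode]]]] = {}
    for snode in top_species.postorder():
        here = mapped_here.get(snode, [])
        if snode.is_leaf:
            F[snode] = _dup_chain(0, list(here))
            continue
        best: dict[int, tuple[int, list[TreeNode]]] = {}
        left = F.get(snode.children[0], {0: (0, [])})
        right = F.get(snode.children[1], {0: (0, [])})
        for k_left, (cost_left, forest_left) in left.items():
            for k_right, (cost_right, forest_right) in right.items():
                for paired in range(min(k_left, k_right) + 1):
                    # paired lineages meet in a free speciation at snode;
                    # every unpaired lineage carried up costs one loss.
                    base = (cost_left + cost_right
                            + (k_left - paired) + (k_right - paired))
                    forest = [TreeNode(children=[forest_left[i],
                                                 forest_right[i]],
                                       inferred=True)
                              for i in range(paired)]
                    forest += forest_left[paired:]
                    forest += forest_right[paired:]
                    forest += here
                    for k, (cost, trees) in _dup_chain(base, forest).items():
                        if k not in best or cost < best[k][0]:
                            best[k] = (cost, trees)
        if not best:
            best = {0: (0, [])}
        F[snode] = best

    cost, forest = F[top_species][1]
    return forest[0], cost


def resolve_soft_polytomies(gene_tree: Tree, index: LcaIndex,
                            taxon_map: TaxonMap | None = None
                            ) -> tuple[Tree, list[TreeNode]]:
    """Binary-refine every multifurcation at minimal duplication+loss cost.

    Returns a refined copy of the tree plus the list of inferred (not
    observed) internal nodes introduced by the refinement.
    """
    tmap = taxon_map if taxon_map is not None else TaxonMap.from_delimiter()
    result = gene_tree.copy()
    for node in result.root.postorder():
        if len(node.children) <= 2:
            continue
        maps = [_subtree_mapping(child, tmap, index)
                for child in node.children]
        top, _cost = _resolve_polytomy(list(node.children), maps, index)
        # the polytomy node itself takes over the refinement's root
        node.children = list(top.children)
    inferred = [n for n in result.root.postorder() if n.inferred]
    return Tree(result.root, rooted=True), inferred


# ---------------------------------------------------------------------------
# Reconciliation of a rooted gene tree
# ---------------------------------------------------------------------------

@dataclass
class Reconciliation:
    """Result of reconciling one rooted gene tree against a species tree.

    ``gene_tree`` is the (polytomy-refined, rooted) tree the counts refer
    to; ``losses_per_edge`` is keyed by the child node of each edge.
    """

    gene_tree: Tree
    species_tree: Tree
    taxon_map: TaxonMap
    index: LcaIndex
    mapping: dict[TreeNode, TreeNode]
    duplication_nodes: set[TreeNode]
    losses_per_edge: dict[TreeNode, int]
    n_duplications: int
    n_losses: int
    total_cost: int
    root_edge: str = "as_given"
    co_optimal_roots: list[str] = field(default_factory=list)
    inferred_nodes: list[TreeNode] = field(default_factory=list)

    def _clade_id(self, node: TreeNode) -> str:
        return ",".join(sorted(leaf.label for leaf in node.leaves()))

    def to_json_dict(self) -> dict:
        return {
            "root_edge": self.root_edge,
            "n_duplications": self.n_duplications,
            "n_losses": self.n_losses,
            "total_cost": self.total_cost,
            "co_optimal_roots": list(self.co_optimal_roots),
            "duplication_clades": sorted(
                self._clade_id(n) for n in self.duplication_nodes),
            "losses_per_edge": {
                self._clade_id(child): count
                for child, count in sorted(self.losses_per_edge.items(),
                                           key=lambda kv: self._clade_id(kv[0]))
                if count},
            "n_inferred_nodes": len(self.inferred_nodes),
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        return json.dumps(self.to_json_dict(), **kwargs)

    def annotated_newick(self) -> str:
        """Newick of the reconciled tree with duplication nodes labelled D."""
        annotated = self.gene_tree.copy()
        originals = list(self.gene_tree.root.postorder())
        copies = list(annotated.root.postorder())
        for original, copy in zip(originals, copies):
            if original in self.duplication_nodes:
                copy.support = None
                copy.label = "D"
        return write_newick(annotated)


def reconcile_rooted(gene_tree: Tree, species_tree: Tree,
                     taxon_map: TaxonMap | None = None, *,
                     index: LcaIndex | None = None,
                     root_edge: str = "as_given") -> Reconciliation:
    """Duplication-loss parsimony reconciliation of a rooted gene tree.

    Polytomies in the gene tree are refined first (soft-polytomy rule);
    the species tree must be rooted and fully binary.
    """
    if not gene_tree.rooted:
        raise ReconcileError(
            "gene tree is unrooted; use best_rooting() instead")
    if index is None:
        index = build_lca_index(species_tree)
    if not index.is_binary:
        raise ReconcileError("species tree must be fully binary")
    tmap = taxon_map if taxon_map is not None else TaxonMap.from_delimiter()
    resolved, inferred = resolve_soft_polytomies(gene_tree, index, tmap)
    mapping = map_gene_tree(resolved, tmap, index)
    duplications = classify_duplications(resolved, mapping)
    losses = count_losses(resolved, mapping, duplications, index)
    n_losses = sum(losses.values())
    return Reconciliation(
        gene_tree=resolved,
        species_tree=species_tree,
        taxon_map=tmap,
        index=index,
        mapping=mapping,
        duplication_nodes=duplications,
        losses_per_edge=losses,
        n_duplications=len(duplications),
        n_losses=n_losses,
        total_cost=len(duplications) + n_losses,
        root_edge=root_edge,
        inferred_nodes=inferred,
    )


def sweep_rootings(gene_tree: Tree, species_tree: Tree,
                   taxon_map: TaxonMap | None = None, *,
                   index: LcaIndex | None = None
                   ) -> list[Reconciliation]:
    """Reconcile every rooting of an unrooted gene tree (sorted by edge id)."""
    if index is None:
        index = build_lca_index(species_tree)
    return [reconcile_rooted(rooted, species_tree, taxon_map,
                             index=index, root_edge=eid)
            for eid, rooted in enumerate_rootings(gene_tree)]


def best_rooting(gene_tree: Tree, species_tree: Tree,
                 taxon_map: TaxonMap | None = None, *,
                 index: LcaIndex | None = None) -> Reconciliation:
    """Most parsimonious rooting of an unrooted gene tree.

    All rootings are assessed; the returned reconciliation is the one whose
    root edge has the lexicographically smallest bipartition id among the
    cost minima, with every co-optimal root edge listed in
    ``co_optimal_roots``.
    """
    results = sweep_rootings(gene_tree, species_tree, taxon_map, index=index)
    minimum = min(r.total_cost for r in results)
    optimal = [r for r in results if r.total_cost == minimum]
    best = optimal[0]  # sweep is sorted by edge id
    best.co_optimal_roots = [r.root_edge for r in optimal]
    return best


def all_optimal_rootings(gene_tree: Tree, species_tree: Tree,
                         taxon_map: TaxonMap | None = None, *,
                         index: LcaIndex | None = None
                         ) -> list[Reconciliation]:
    """Every minimum-cost rooting, each with ``co_optimal_roots`` filled."""
    results = sweep_rootings(gene_tree, species_tree, taxon_map, index=index)
    minimum = min(r.total_cost for r in results)
    optimal = [r for r in results if r.total_cost == minimum]
    ids = [r.root_edge for r in optimal]
    for r in optimal:
        r.co_optimal_roots = list(ids)
    return optimal
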