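"""Independent brute-force oracles used to validate the package.

Nothing here shares code with the implementation paths it checks:
ancestry is recomputed from scratch, reconciliation cost is minimised over
*all* ancestrally-consistent node mappings, topologies are enumerated by
leaf insertion, and rerooting is delegated to dendropy.
"""

from __future__ import annotations

import itertools

import dendropy
import numpy as np

from scortho.tree_io import Tree, TreeNode, parse_newick, write_newick


# ---------------------------------------------------------------------------
# ancestry from scratch
# ---------------------------------------------------------------------------

def ancestor_chains(tree: Tree) -> dict[TreeNode, list[TreeNode]]:
    """node -> [node, parent, ..., root] built by plain recursion."""
    chains: dict[TreeNode, list[TreeNode]] = {}

    def visit(node: TreeNode, path: list[TreeNode]) -> None:
        chains[node] = [node] + path
        for child in node.children:
            visit(child, chains[node])

    visit(tree.root, [])
    return chains


def naive_lca(chains, u: TreeNode, v: TreeNode) -> TreeNode:
    seen = set(map(id, chains[u]))
    for node in chains[v]:
        if id(node) in seen:
            return node
    raise AssertionError("nodes share no ancestor")


# ---------------------------------------------------------------------------
# reconciliation cost by exhaustive mapping enumeration
# ---------------------------------------------------------------------------

def brute_force_reconcile(gene_tree: Tree, species_tree: Tree,
                          taxon_for) -> tuple[int, int]:
    """(min dup+loss cost, min #duplications among cost-minimal mappings).

    Enumerates every mapping of gene-tree internal nodes to species nodes
    that is ancestrally consistent (each node at or above the LCA of its
    children's images).  A node is a speciation only when it sits exactly
    at that LCA with both children strictly below it; losses follow the
    depth-difference rule.
    """
    chains = ancestor_chains(species_tree)
    depth = {node: len(chain) - 1 for node, chain in chains.items()}
    sp_leaf = {leaf.label: leaf for leaf in species_tree.leaves()}

    gene_internal = [n for n in gene_tree.postorder() if not n.is_leaf]
    for node in gene_internal:
        assert len(node.children) == 2, "oracle requires binary gene trees"
    fixed = {leaf: sp_leaf[taxon_for(leaf.label)]
             for leaf in gene_tree.leaves()}

    best = [None, None]  # (cost, dups)

    def evaluate(assign) -> None:
        dups = 0
        losses = 0
        for node in gene_internal:
            left, right = node.children
            m_node = assign[node]
            m_left, m_right = assign[left], assign[right]
            low = naive_lca(chains, m_left, m_right)
            speciation = (m_node is low and m_left is not m_node
                          and m_right is not m_node)
            if not speciation:
                dups += 1
            for m_child in (m_left, m_right):
                d = depth[m_child] - depth[m_node]
                losses += d if not speciation else d - 1
        cost = dups + losses
        if best[0] is None or (cost, dups) < (best[0], best[1]):
            best[0], best[1] = cost, dups

    def extend(i: int, assign) -> None:
        if i == len(gene_internal):
            evaluate(assign)
            return
        node = gene_internal[i]
        low = naive_lca(chains, assign[node.children[0]],
                        assign[node.children[1]])
        for candidate in chains[low]:  # low .. root
            assign[node] = candidate
            extend(i + 1, assign)
        del assign[node]

    extend(0, dict(fixed))
    return best[0], best[1]


# ---------------------------------------------------------------------------
# topology enumeration by leaf insertion
# ---------------------------------------------------------------------------

def all_rooted_shapes(items: list):
    """Every rooted binary topology over ``items`` as nested 2-tuples.

    Yields (2k-3)!! distinct shapes for k items, by inserting each item on
    every edge (including the root edge) of every smaller shape.
    """
    if len(items) == 1:
        yield items[0]
        return

    def insertions(shape, item):
        yield (shape, item)
        if isinstance(shape, tuple):
            left, right = shape
            for variant in insertions(left, item):
                yield (variant, right)
            for variant in insertions(right, item):
                yield (left, variant)

    for smaller in all_rooted_shapes(items[:-1]):
        yield from insertions(smaller, items[-1])


def shape_to_tree(shape, leaf_factory=None) -> Tree:
    """Materialise a nested-tuple shape; leaves are labels (str) or, with a
    ``leaf_factory``, arbitrary prebuilt subtrees keyed by the shape item."""
    def build(node):
        if isinstance(node, tuple):
            return TreeNode(children=[build(node[0]), build(node[1])])
        if leaf_factory is not None:
            return leaf_factory(node)
        return TreeNode(label=node)

    return Tree(build(shape), rooted=True)


# ---------------------------------------------------------------------------
# independent rooting sweep via dendropy
# ---------------------------------------------------------------------------

def dendropy_rootings(unrooted: Tree) -> list[Tree]:
    """All rootings of an unrooted tree, produced by dendropy rerooting."""
    newick = write_newick(unrooted)
    base = dendropy.Tree.get(data=newick, schema="newick",
                             suppress_internal_node_taxa=True,
                             preserve_underscores=True)
    n_edges = sum(1 for e in base.preorder_edge_iter()
                  if e.head_node is not base.seed_node)
    out = []
    for i in range(n_edges):
        clone = dendropy.Tree.get(data=newick, schema="newick",
                                  suppress_internal_node_taxa=True,
                                  preserve_underscores=True)
        edges = [e for e in clone.preorder_edge_iter()
                 if e.head_node is not clone.seed_node]
        edge = edges[i]
        if edge.length is None:
            edge.length = 1.0  # reroot_at_edge needs a length to split
        clone.reroot_at_edge(edge, update_bipartitions=False)
        rerooted = clone.as_string(schema="newick",
                                   suppress_rooting=True,
                                   unquoted_underscores=True)
        out.append(parse_newick(rerooted, rooted=True))
    return out


# ---------------------------------------------------------------------------
# random inputs
# ---------------------------------------------------------------------------

def random_gene_tree(rng: np.random.Generator, taxa: list[str],
                     n_leaves: int, *, allow_duplicates: bool = True) -> Tree:
    """Random rooted binary gene tree by uniform pairwise joins."""
    if allow_duplicates:
        chosen = [taxa[int(rng.integers(len(taxa)))] for _ in range(n_leaves)]
    else:
        chosen = list(rng.choice(taxa, size=n_leaves, replace=False))
    counters = {}
    nodes = []
    for taxon in chosen:
        counters[taxon] = counters.get(taxon, 0) + 1
        nodes.append(TreeNode(label=f"{taxon}|g{counters[taxon]}"))
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        joined = TreeNode(children=[nodes[i], nodes[j]])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(joined)
    return Tree(nodes[0], rooted=True)


def decorate_supports(tree: Tree, rng: np.random.Generator) -> Tree:
    """Random supports on internal non-root branches, lengths everywhere."""
    result = tree.copy()
    for node in result.postorder():
        if node is result.root:
            continue
        node.length = round(float(rng.uniform(0.01, 1.0)), 4)
        if not node.is_leaf:
            node.support = float(rng.integers(0, 101))
    return result
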