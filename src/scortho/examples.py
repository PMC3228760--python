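"""A small hand-checkable reconciliation example used in docs and tests.

Three taxa A, B, C with guide tree ((A,B),C) and an unrooted four-leaf gene
tree containing two copies from taxon A.  Two rootings are of interest:

* rooting X, on the internal edge separating {A_1,B_1} from {A_2,C_1},
  costs one duplication and two losses;
* rooting Y, on the pendant edge above C_1, costs one duplication and one
  loss and is the unique most parsimonious rooting.

Under rooting Y the cherry (A_1,B_1) is a sub-tree in single copy since the
ancestor of {A, B}.
"""

from __future__ import annotations

from .tree_io import TaxonMap, Tree, edge_bipartition_id, parse_newick

__all__ = [
    "SPECIES_NEWICK",
    "GENE_NEWICK",
    "load_example",
    "edge_x_id",
    "edge_y_id",
]

SPECIES_NEWICK = "((A,B),C);"
GENE_NEWICK = "((A_1,B_1),(A_2,C_1));"

_LEAVES = ("A_1", "A_2", "B_1", "C_1")


def load_example() -> tuple[Tree, Tree, TaxonMap]:
    """Parsed (species tree, unrooted gene tree, taxon map) triple."""
    species = parse_newick(SPECIES_NEWICK)
    gene = parse_newick(GENE_NEWICK, rooted=False)
    return species, gene, TaxonMap.from_delimiter("_")


def edge_x_id() -> str:
    return edge_bipartition_id({"A_1", "B_1"}, _LEAVES)


def edge_y_id() -> str:
    return edge_bipartition_id({"C_1"}, _LEAVES)
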