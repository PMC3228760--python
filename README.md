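# scortho

Single-copy ortholog discovery by duplication–loss gene-tree reconciliation.

`scortho` identifies genes that have remained in single copy since a focal
ancestor. It combines two routes:

1. **Taxon count** — a group is single copy when every genome of the
   declared universe contributes exactly one member, with a configurable
   tolerance (default: one deviating genome per family, either a missing
   copy or an extra one) to absorb annotation artifacts.
2. **Subtree rescue** — multigene families are reconciled against one or
   more guide species trees by duplication–loss parsimony (LCA mapping).
   Low-support branches (< 80% BP by default) are collapsed first and
   treated as soft polytomies, refined at minimal cost; every possible
   rooting of the gene tree is assessed and the cheapest kept. The
   reconciled tree is then scanned for maximal sub-trees whose root maps
   exactly to the focal ancestor and that contain no events other than
   species-specific duplications or losses, within a per-subtree budget
   (default: one deviating genome). Calls from different guide trees are
   pooled and deduplicated on their exact gene set.

The package also ships a birth–death family **simulator** (species trees,
gene trees, membership tables, ground-truth event logs, annotation
dropout) so everything is testable without external data, and a
**coverage** module that reports the completeness of a query gene set
against a single-copy reference.

## CLI

```sh
# reconcile one gene tree with a species tree (best rooting by default)
scortho reconcile gene.nwk species.nwk --delimiter "|" \
    --out-json rec.json --out-newick annotated.nwk

# full single-copy pipeline
scortho find-single-copy groups.tsv manifest.tsv \
    --guide-tree coelomata=guideA.nwk --guide-tree ecdysozoa=guideB.nwk \
    --focal T01,T02,T03,T04 --support-threshold 80 --tolerance 1 \
    --budget 1 --out run/

# synthetic benchmark
scortho simulate --n-taxa 12 --n-families 100 --dup-rate 0.3 \
    --loss-rate 0.2 --seed 1 --out bench/

# completeness of per-species assignments against a reference id list
scortho coverage assignments.tsv --reference reference_ids.txt

# copy-number classification of groups
scortho classify groups.tsv
```

File formats (all plain text): Newick trees; group membership TSV
(`group_id<TAB>gene_id<TAB>taxon_id`); gene-tree manifest TSV
(`group_id<TAB>newick_path`); assignment TSV (`species<TAB>group_id`).
Gene leaf labels encode their taxon as a prefix (`TAXON|gene`, delimiter
configurable); an explicit two-column gene→taxon TSV overrides the
convention.

## Layout

| module | role |
| --- | --- |
| `scortho.tree_io` | tree structures, Newick I/O, collapsing, pruning, rooting enumeration |
| `scortho.reconcile` | LCA mapping, duplication/loss counting, soft-polytomy refinement, all-rootings search |
| `scortho.singlecopy` | taxon-count rule, subtree rescue, pooling, end-to-end pipeline |
| `scortho.simulate` | birth–death family simulator and benchmark generator |
| `scortho.coverage` | completeness reports against a single-copy reference |
| `scortho.cli` | `scortho` command-line entry point |

The test suite under `tests/` validates the engine against independent
brute-force oracles: exhaustive enumeration of ancestrally consistent
embeddings, exhaustive binary resolutions of polytomies, and rerooting via
dendropy.
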