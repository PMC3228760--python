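"""Single-copy ortholog identification.

Two routes are implemented and pooled:

* the taxon-count rule: a group is single copy when every taxon of the
  declared universe has exactly one member, with a configurable tolerance
  (default one deviating genome per family, either a missing or a
  duplicated copy);
* subtree rescue: reconciled multigene-family trees are scanned for maximal
  sub-trees that have been in single copy since the focal ancestor, allowing
  only species-specific duplications or losses up to a per-subtree budget.

Calls found under different guide trees are pooled, deduplicated on their
exact gene set.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from .reconcile import (
    LcaIndex,
    ReconcileError,
    Reconciliation,
    all_optimal_rootings,
    build_lca_index,
    reconcile_rooted,
)
from .tree_io import TaxonMap, Tree, TreeNode, collapse_low_support

__all__ = [
    "OrthologGroup",
    "CopyNumberVector",
    "SingleCopyCall",
    "PipelineConfig",
    "PipelineReport",
    "copy_numbers",
    "classify_relationship",
    "taxon_count_call",
    "find_single_copy_subtrees",
    "pool_calls",
    "run_pipeline",
    "read_groups_tsv",
    "read_manifest_tsv",
    "write_calls_tsv",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OrthologGroup:
    """An orthologous group: a set of (gene id, taxon id) members."""

    group_id: str
    members: tuple[tuple[str, str], ...]

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"group {self.group_id!r} has no members")
        genes = [gene for gene, _ in self.members]
        if len(genes) != len(set(genes)):
            raise ValueError(f"group {self.group_id!r} has duplicate gene ids")

    @property
    def taxa(self) -> set[str]:
        return {taxon for _, taxon in self.members}

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(gene for gene, _ in self.members)


@dataclass(frozen=True)
class CopyNumberVector:
    """Per-taxon copy counts of one group over a declared taxon universe."""

    counts: tuple[tuple[str, int], ...]  # sorted by taxon

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    @property
    def total(self) -> int:
        return sum(count for _, count in self.counts)


@dataclass(frozen=True)
class SingleCopyCall:
    """A group (or sub-tree of a group) certified single copy.

    ``allowed_events`` lists the tolerated species-specific deviations as
    ``(kind, taxon)`` pairs with kind in {"duplication", "loss"}.
    """

    group_id: str
    genes: tuple[str, ...]
    mode: str            # "taxon_count" | "subtree"
    category: str        # "exact" | "one_duplication" | "one_loss" | "mixed" | "subtree"
    allowed_events: tuple[tuple[str, str], ...] = ()
    guide_tree_ids: tuple[str, ...] = ()
    focal_taxa: tuple[str, ...] = ()

    @property
    def key(self) -> tuple[str, frozenset]:
        return (self.group_id, frozenset(self.genes))


@dataclass
class PipelineConfig:
    support_threshold: float = 80.0
    tolerance: int = 1
    budget: int = 1


@dataclass
class PipelineReport:
    n_taxon_count_exact: int = 0
    n_taxon_count_one_dup: int = 0
    n_taxon_count_one_loss: int = 0
    n_taxon_count_other: int = 0
    n_subtree_rescued: int = 0
    n_total_unique: int = 0
    percent_increase: float | None = None

    @property
    def n_taxon_count_total(self) -> int:
        return (self.n_taxon_count_exact + self.n_taxon_count_one_dup
                + self.n_taxon_count_one_loss + self.n_taxon_count_other)

    def to_json_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["n_taxon_count_total"] = self.n_taxon_count_total
        if self.percent_increase is not None:
            out["percent_increase"] = round(self.percent_increase, 1)
        return out

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        return json.dumps(self.to_json_dict(), **kwargs)


# ---------------------------------------------------------------------------
# Taxon-count route
# ---------------------------------------------------------------------------

def copy_numbers(group: OrthologGroup,
                 universe: Iterable[str]) -> CopyNumberVector:
    """Per-taxon copy counts; taxa absent from the group count zero."""
    counts = {taxon: 0 for taxon in universe}
    for _, taxon in group.members:
        if taxon in counts:
            counts[taxon] += 1
    return CopyNumberVector(tuple(sorted(counts.items())))


def classify_relationship(vector: CopyNumberVector) -> str:
    """one_to_one / one_to_many / many_to_many from copy counts.

    Absent taxa (count zero) do not disqualify the one_to_one label;
    spanning the full universe is the taxon-count rule's job, not this
    classifier's.
    """
    n_multi = sum(1 for _, count in vector.counts if count > 1)
    if n_multi == 0:
        return "one_to_one"
    if n_multi == 1:
        return "one_to_many"
    return "many_to_many"


def taxon_count_call(group: OrthologGroup, universe: Iterable[str],
                     tolerance: int = 1) -> SingleCopyCall | None:
    """Single-copy call by copy counts, or None.

    A call is made when at most ``tolerance`` taxa deviate from one copy:
    a deviating taxon has either zero copies (a loss) or two-plus copies
    (a duplication).  Deviating taxa are recorded as allowed events.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    universe = frozenset(universe)
    vector = copy_numbers(group, universe)
    events = []
    for taxon, count in vector.counts:
        if count == 0:
            events.append(("loss", taxon))
        elif count > 1:
            events.append(("duplication", taxon))
    if len(events) > tolerance:
        return None
    kinds = {kind for kind, _ in events}
    if not kinds:
        category = "exact"
    elif kinds == {"duplication"}:
        category = "one_duplication"
    elif kinds == {"loss"}:
        category = "one_loss"
    else:
        category = "mixed"
    genes = tuple(sorted(gene for gene, taxon in group.members
                         if taxon in universe))
    return SingleCopyCall(
        group_id=group.group_id,
        genes=genes,
        mode="taxon_count",
        category=category,
        allowed_events=tuple(sorted(events)),
        focal_taxa=tuple(sorted(universe)),
    )


# ---------------------------------------------------------------------------
# Subtree rescue route
# ---------------------------------------------------------------------------

def _resolve_focal(index: LcaIndex, focal) -> TreeNode:
    if isinstance(focal, TreeNode):
        if focal not in index.depth:
            raise ReconcileError("focal node is not part of the guide tree")
        return focal
    if isinstance(focal, str):
        for node in index.tree.preorder():
            if node.label == focal:
                return node
        raise ReconcileError(f"no guide-tree node labelled {focal!r}")
    return index.mrca(focal)


def _lost_species_subtrees(top: TreeNode, bottom: TreeNode, is_dup: bool,
                           index: LcaIndex) -> list[TreeNode]:
    """Species subtrees lost along a gene-tree edge mapped top -> bottom.

    Walking up from ``bottom``, the off-path child at each intermediate
    species node is lost; below a duplication the off-path child at ``top``
    itself is lost as well.
    """
    lost = []
    prev = bottom
    while prev is not top:
        cur = index.parent[prev]
        if cur is not top or is_dup:
            for child in cur.children:
                if child is not prev:
                    lost.append(child)
        prev = cur
    return lost


def find_single_copy_subtrees(reconciliation: Reconciliation,
                              index: LcaIndex, focal, *,
                              budget: int = 1,
                              group_id: str = "",
                              guide_tree_id: str = ""
                              ) -> list[SingleCopyCall]:
    """Maximal sub-trees in single copy since the focal species node.

    A sub-tree qualifies when its root maps exactly to ``focal``, every
    internal node is a speciation except duplications mapping to a species
    leaf (species-specific duplications), every loss charged inside it is
    of a single terminal taxon (species-specific losses), and the number of
    deviating taxa (duplication taxa plus loss taxa) does not exceed
    ``budget``.  Returned sub-trees are maximal: none is contained in
    another.
    """
    focal_node = _resolve_focal(index, focal)
    mapping = reconciliation.mapping
    duplications = reconciliation.duplication_nodes
    focal_taxa = tuple(sorted(leaf.label for leaf in focal_node.leaves()))

    # bottom-up summaries: (clean?, species-specific dup taxa, loss taxa)
    info: dict[TreeNode, tuple[bool, frozenset, frozenset]] = {}
    for node in reconciliation.gene_tree.postorder():
        if node.is_leaf:
            info[node] = (True, frozenset(), frozenset())
            continue
        ok = True
        dup_taxa: set[str] = set()
        loss_taxa: set[str] = set()
        for child in node.children:
            child_ok, child_dups, child_losses = info[child]
            ok = ok and child_ok
            dup_taxa |= child_dups
            loss_taxa |= child_losses
        is_dup = node in duplications
        if is_dup:
            if mapping[node].is_leaf:
                dup_taxa.add(mapping[node].label)
            else:
                ok = False
        for child in node.children:
            for lost in _lost_species_subtrees(mapping[node], mapping[child],
                                               is_dup, index):
                if lost.is_leaf:
                    loss_taxa.add(lost.label)
                else:
                    ok = False
        info[node] = (ok, frozenset(dup_taxa), frozenset(loss_taxa))

    calls: list[SingleCopyCall] = []

    def coverage_ok(node: TreeNode, dup_taxa, loss_taxa) -> bool:
        counts = {taxon: 0 for taxon in focal_taxa}
        for leaf in node.leaves():
            taxon = reconciliation.taxon_map.taxon_for(leaf.label)
            if taxon not in counts:
                return False
            counts[taxon] += 1
        for taxon, count in counts.items():
            expected_multi = taxon in dup_taxa
            expected_zero = taxon in loss_taxa and not expected_multi
            if expected_multi and count < 2:
                return False
            if expected_zero and count != 0:
                return False
            if not expected_multi and not expected_zero and count != 1:
                return False
        return True

    def scan(node: TreeNode) -> None:
        ok, dup_taxa, loss_taxa = info[node]
        if (mapping[node] is focal_node and ok
                and len(dup_taxa) + len(loss_taxa) <= budget
                and coverage_ok(node, dup_taxa, loss_taxa)):
            events = tuple(sorted(
                [("duplication", t) for t in dup_taxa]
                + [("loss", t) for t in loss_taxa]))
            calls.append(SingleCopyCall(
                group_id=group_id,
                genes=tuple(sorted(leaf.label for leaf in node.leaves())),
                mode="subtree",
                category="subtree",
                allowed_events=events,
                guide_tree_ids=(guide_tree_id,) if guide_tree_id else (),
                focal_taxa=focal_taxa,
            ))
            return  # maximality: do not descend into an emitted sub-tree
        for child in node.children:
            scan(child)

    scan(reconciliation.gene_tree.root)
    return calls


def pool_calls(calls: Iterable[SingleCopyCall]) -> list[SingleCopyCall]:
    """Merge calls identical in (group id, gene set); union their guides.

    Idempotent and order-insensitive; distinct gene sets from the same
    group are all kept.
    """
    merged: dict[tuple, SingleCopyCall] = {}
    for call in calls:
        key = (call.group_id, call.genes)
        if key in merged:
            existing = merged[key]
            guides = tuple(sorted(set(existing.guide_tree_ids)
                                  | set(call.guide_tree_ids)))
            merged[key] = dataclasses.replace(existing, guide_tree_ids=guides)
        else:
            merged[key] = dataclasses.replace(
                call, guide_tree_ids=tuple(sorted(set(call.guide_tree_ids))))
    return [merged[key] for key in sorted(merged)]


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

def run_pipeline(groups: Mapping[str, OrthologGroup],
                 gene_trees: Mapping[str, Tree],
                 guide_trees: Mapping[str, Tree],
                 focal_taxa: Iterable[str],
                 config: PipelineConfig | None = None,
                 taxon_map: TaxonMap | None = None
                 ) -> tuple[PipelineReport, list[SingleCopyCall]]:
    """Taxon-count pass, then reconciliation rescue of the remainder.

    Groups already called by the taxon-count rule skip reconciliation.  For
    every other group with a gene tree, low-support branches are collapsed,
    every most-parsimonious rooting under each guide tree is scanned for
    single-copy sub-trees, and the resulting calls are pooled.  Groups
    without a gene tree are skipped with a logged warning.
    """
    cfg = config or PipelineConfig()
    tmap = taxon_map if taxon_map is not None else TaxonMap.from_delimiter()
    universe = frozenset(focal_taxa)

    taxon_calls: list[SingleCopyCall] = []
    remaining: list[str] = []
    for group_id in sorted(groups):
        call = taxon_count_call(groups[group_id], universe, cfg.tolerance)
        if call is not None:
            taxon_calls.append(call)
        else:
            remaining.append(group_id)

    indices = {gid: build_lca_index(tree)
               for gid, tree in guide_trees.items()}
    focal_nodes = {gid: index.mrca(universe)
                   for gid, index in indices.items()}

    subtree_calls: list[SingleCopyCall] = []
    for group_id in remaining:
        tree = gene_trees.get(group_id)
        if tree is None:
            logger.warning("group %s: no gene tree available; skipped",
                           group_id)
            continue
        for guide_id in sorted(guide_trees):
            index = indices[guide_id]
            focal_node = focal_nodes[guide_id]
            try:
                collapsed = collapse_low_support(tree, cfg.support_threshold)
                if collapsed.n_leaves < 3:
                    rooted = Tree(collapsed.root.copy(), rooted=True)
                    optima = [reconcile_rooted(rooted, guide_trees[guide_id],
                                               tmap, index=index)]
                else:
                    optima = all_optimal_rootings(
                        collapsed, guide_trees[guide_id], tmap, index=index)
            except ReconcileError as exc:
                logger.warning("group %s vs guide %s: %s",
                               group_id, guide_id, exc)
                continue
            for reconciliation in optima:
                subtree_calls.extend(find_single_copy_subtrees(
                    reconciliation, index, focal_node, budget=cfg.budget,
                    group_id=group_id, guide_tree_id=guide_id))

    pooled = pool_calls(subtree_calls)

    report = PipelineReport()
    for call in taxon_calls:
        if call.category == "exact":
            report.n_taxon_count_exact += 1
        elif call.category == "one_duplication":
            report.n_taxon_count_one_dup += 1
        elif call.category == "one_loss":
            report.n_taxon_count_one_loss += 1
        else:
            report.n_taxon_count_other += 1
    report.n_subtree_rescued = len(pooled)
    report.n_total_unique = len(taxon_calls) + len(pooled)
    if report.n_taxon_count_total:
        report.percent_increase = (100.0 * report.n_subtree_rescued
                                   / report.n_taxon_count_total)
    elif report.n_subtree_rescued == 0:
        report.percent_increase = 0.0
    else:
        report.percent_increase = None  # undefined: nothing to increase

    return report, taxon_calls + pooled


# ---------------------------------------------------------------------------
# Table I/O
# ---------------------------------------------------------------------------

def read_groups_tsv(path) -> dict[str, OrthologGroup]:
    """Read ``group_id <TAB> gene_id <TAB> taxon_id`` membership rows."""
    members: dict[str, list[tuple[str, str]]] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected "
                    f"'group_id<TAB>gene_id<TAB>taxon_id'")
            members.setdefault(fields[0], []).append((fields[1], fields[2]))
    return {gid: OrthologGroup(gid, tuple(rows))
            for gid, rows in members.items()}


def read_manifest_tsv(path) -> dict[str, Path]:
    """Read ``group_id <TAB> newick_path`` rows (paths relative to the
    manifest file)."""
    base = Path(path).parent
    out: dict[str, Path] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 'group_id<TAB>path'")
            tree_path = Path(fields[1])
            out[fields[0]] = tree_path if tree_path.is_absolute() \
                else base / tree_path
    return out


def write_calls_tsv(calls: Iterable[SingleCopyCall], path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("group_id\tmode\tcategory\tguide_tree_ids\t"
                     "allowed_events\tgenes\n")
        for call in calls:
            events = ";".join(f"{kind}:{taxon}"
                              for kind, taxon in call.allowed_events)
            handle.write("\t".join([
                call.group_id,
                call.mode,
                call.category,
                ";".join(call.guide_tree_ids),
                events,
                ",".join(call.genes),
            ]) + "\n")
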