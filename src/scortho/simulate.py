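"""Synthetic species trees, gene families and benchmarks.

Gene families evolve under a birth-death duplication-loss model along a
random (Yule-shape) species tree: a single lineage enters the root and
splits at every species node; along a branch of length ``t`` each copy
duplicates as a Poisson process with rate ``dup_rate`` and survives the
branch with probability ``exp(-loss_rate * t)``.  Losses are applied as
per-branch survival thinning rather than full event-time competition with
duplication -- a deliberate model simplification (a copy that dies on a
branch leaves no duplicates on that branch), adequate for generating test
fixtures with a complete event log.

Every operation is deterministic given a seed.  Annotation dropout
(``perturb_annotation``) removes genes independently to emulate incomplete
genome annotation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import NamedTuple

import numpy as np

from .singlecopy import OrthologGroup
from .tree_io import Tree, TreeNode, prune_to_taxa, write_newick

__all__ = [
    "SimConfig",
    "Event",
    "FamilySim",
    "SimulatedDataset",
    "simulate_species_tree",
    "simulate_family",
    "plant_paralog_family",
    "simulate_dataset",
    "perturb_annotation",
    "generate_benchmark",
]

DEFAULT_BRANCH_LENGTH = 0.1


class Event(NamedTuple):
    kind: str        # "duplication" | "loss"
    species: str     # label of the species node below the branch
    time: float      # position along that branch
    lineage: int     # id of the affected (or newly created) copy


@dataclass
class FamilySim:
    """One simulated gene family plus its ground truth."""

    family_id: str
    tree: Tree | None                 # rooted gene tree; None if extinct
    group: OrthologGroup | None       # None if extinct
    events: tuple[Event, ...]
    is_single_copy: bool
    single_copy_subclades: tuple[tuple[str, ...], ...]

    @property
    def n_duplications(self) -> int:
        return sum(1 for e in self.events if e.kind == "duplication")

    @property
    def n_losses(self) -> int:
        return sum(1 for e in self.events if e.kind == "loss")


@dataclass
class SimConfig:
    n_taxa: int = 12
    n_families: int = 100
    dup_rate: float = 0.0
    loss_rate: float = 0.0
    dropout_prob: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_taxa < 2:
            raise ValueError("n_taxa must be >= 2")
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        for name in ("dup_rate", "loss_rate"):
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise ValueError(f"{name} must be finite and >= 0")
        if not 0 <= self.dropout_prob <= 1:
            raise ValueError("dropout_prob must be in [0, 1]")


@dataclass
class SimulatedDataset:
    species_tree: Tree
    families: dict[str, FamilySim]
    config: SimConfig
    removals: tuple[tuple[str, str], ...] = ()  # (family_id, gene_id)


def _taxon_labels(n_taxa: int) -> list[str]:
    width = max(2, len(str(n_taxa)))
    return [f"T{i + 1:0{width}d}" for i in range(n_taxa)]


def simulate_species_tree(n_taxa: int, seed: int = 0,
                          rng: np.random.Generator | None = None) -> Tree:
    """Random rooted binary species tree with positive branch lengths."""
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    rng = rng if rng is not None else np.random.default_rng(seed)
    labels = _taxon_labels(n_taxa)
    leaves = [TreeNode(label=labels[0]), TreeNode(label=labels[1])]
    root = TreeNode(children=list(leaves))
    for i in range(2, n_taxa):
        # split a uniformly chosen extant leaf (Yule shape)
        target = leaves[int(rng.integers(len(leaves)))]
        old = TreeNode(label=target.label)
        new = TreeNode(label=labels[i])
        target.label = ""
        target.children = [old, new]
        leaves[leaves.index(target)] = old
        leaves.append(new)
    tree = Tree(root, rooted=True)
    for node in tree.postorder():
        if node is not root:
            node.length = round(float(rng.uniform(0.05, 0.3)), 6)
    return tree


def _species_id(node: TreeNode) -> str:
    if node.label:
        return node.label
    return "+".join(sorted(leaf.label for leaf in node.leaves()))


def simulate_family(species_tree: Tree, config: SimConfig,
                    rng: np.random.Generator,
                    family_id: str = "fam0001") -> FamilySim:
    """Evolve one gene family; returns the true gene tree and event log."""
    events: list[Event] = []
    gene_counter = 0
    lineage_counter = 0

    def next_lineage() -> int:
        nonlocal lineage_counter
        lineage_counter += 1
        return lineage_counter

    def at_species_node(snode: TreeNode, lineage: int) -> TreeNode | None:
        nonlocal gene_counter
        if snode.is_leaf:
            gene_counter += 1
            return TreeNode(label=f"{snode.label}|{family_id}_g{gene_counter}")
        kids = []
        for child in snode.children:
            length = child.length if child.length is not None \
                else DEFAULT_BRANCH_LENGTH
            sub = along_branch(child, length, 0.0, lineage)
            if sub is not None:
                kids.append(sub)
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]
        return TreeNode(children=kids)

    def along_branch(snode: TreeNode, t: float, entry: float,
                     lineage: int) -> TreeNode | None:
        # per-branch survival thinning: a copy that dies duplicates no more
        if config.loss_rate > 0:
            if rng.random() > math.exp(-config.loss_rate * (t - entry)):
                when = entry + float(rng.uniform(0, max(t - entry, 1e-12)))
                events.append(Event("loss", _species_id(snode),
                                    when, lineage))
                return None
        dup_times: list[float] = []
        if config.dup_rate > 0:
            clock = entry
            while True:
                clock += float(rng.exponential(1.0 / config.dup_rate))
                if clock >= t:
                    break
                dup_times.append(clock)
        subtree = at_species_node(snode, lineage)
        for when in reversed(dup_times):
            born = next_lineage()
            events.append(Event("duplication", _species_id(snode),
                                when, born))
            sibling = along_branch(snode, t, when, born)
            if sibling is None:
                continue
            if subtree is None:
                subtree = sibling
            else:
                subtree = TreeNode(children=[subtree, sibling])
        return subtree

    root_gene = at_species_node(species_tree.root, next_lineage())
    if root_gene is None:
        return FamilySim(family_id, None, None, tuple(events), False, ())
    tree = Tree(root_gene, rooted=True)
    members = tuple((leaf.label, leaf.label.split("|", 1)[0])
                    for leaf in tree.leaves())
    group = OrthologGroup(family_id, members)
    clean = not events
    subclades = (tuple(sorted(g for g, _ in members)),) if clean else ()
    return FamilySim(family_id, tree, group, tuple(events),
                     is_single_copy=clean, single_copy_subclades=subclades)


def plant_paralog_family(species_tree: Tree, n_clades: int = 2,
                         family_id: str = "fam0001") -> FamilySim:
    """A family with ``n_clades`` clean paralog clades over all taxa.

    Ancient duplications (before the first speciation) create
    ``n_clades`` congruent one-copy clades; the truth table lists each
    clade as a single-copy subclade.
    """
    if n_clades < 1:
        raise ValueError("n_clades must be >= 1")

    def congruent(snode: TreeNode, tag: str) -> TreeNode:
        if snode.is_leaf:
            return TreeNode(label=f"{snode.label}|{family_id}_{tag}")
        return TreeNode(children=[congruent(c, tag) for c in snode.children])

    clades = [congruent(species_tree.root, f"c{i + 1}")
              for i in range(n_clades)]
    root = clades[0]
    events = []
    for i, clade in enumerate(clades[1:], start=2):
        root = TreeNode(children=[root, clade])
        events.append(Event("duplication",
                            _species_id(species_tree.root), 0.0, i))
    tree = Tree(root, rooted=True)
    members = tuple((leaf.label, leaf.label.split("|", 1)[0])
                    for leaf in tree.leaves())
    subclades = tuple(tuple(sorted(leaf.label for leaf in clade.leaves()))
                      for clade in clades)
    return FamilySim(family_id, tree, OrthologGroup(family_id, members),
                     tuple(events), is_single_copy=(n_clades == 1),
                     single_copy_subclades=subclades)


def simulate_dataset(config: SimConfig,
                     species_tree: Tree | None = None) -> SimulatedDataset:
    """Simulate a whole dataset (species tree + families), then apply
    dropout if configured."""
    rng = np.random.default_rng(config.seed)
    if species_tree is None:
        species_tree = simulate_species_tree(config.n_taxa, rng=rng)
    width = max(4, len(str(config.n_families)))
    families = {}
    for i in range(config.n_families):
        fam_id = f"fam{i + 1:0{width}d}"
        families[fam_id] = simulate_family(species_tree, config, rng, fam_id)
    dataset = SimulatedDataset(species_tree, families, config)
    if config.dropout_prob > 0:
        dataset, _ = perturb_annotation(dataset, config.dropout_prob, rng=rng)
    return dataset


def perturb_annotation(dataset: SimulatedDataset, dropout_prob: float,
                       seed: int = 0,
                       rng: np.random.Generator | None = None
                       ) -> tuple[SimulatedDataset, list[tuple[str, str]]]:
    """Remove each gene independently with probability ``dropout_prob``.

    Gene trees are pruned accordingly; the returned log lists removed
    (family id, gene id) pairs.  Truth labels (event log, flags) keep
    describing the *unperturbed* history.
    """
    if not 0 <= dropout_prob <= 1:
        raise ValueError("dropout_prob must be in [0, 1]")
    rng = rng if rng is not None else np.random.default_rng(seed)
    removed: list[tuple[str, str]] = []
    families: dict[str, FamilySim] = {}
    for fam_id in sorted(dataset.families):
        fam = dataset.families[fam_id]
        if fam.group is None:
            families[fam_id] = fam
            continue
        keep = []
        for gene, taxon in fam.group.members:
            if rng.random() < dropout_prob:
                removed.append((fam_id, gene))
            else:
                keep.append((gene, taxon))
        if not keep:
            families[fam_id] = replace(fam, tree=None, group=None)
            continue
        kept_labels = {gene for gene, _ in keep}
        tree = fam.tree
        if tree is not None:
            tree = prune_to_taxa(tree, kept_labels)  # leaf labels as taxa
        families[fam_id] = replace(
            fam, tree=tree, group=OrthologGroup(fam_id, tuple(keep)))
    out = SimulatedDataset(dataset.species_tree, families, dataset.config,
                           removals=dataset.removals + tuple(removed))
    return out, removed


def generate_benchmark(config: SimConfig, out_dir) -> dict[str, Path]:
    """Write a complete benchmark to disk in the formats the CLI consumes.

    Produces ``species.nwk``, one Newick per family under ``trees/``, the
    group membership TSV, the gene-tree manifest TSV, the truth TSV and
    (when dropout was applied) the removal log.  Extinct or fully
    dropped-out families appear in the truth table but not in the group
    table.  Deterministic per seed, byte for byte.
    """
    out_dir = Path(out_dir)
    (out_dir / "trees").mkdir(parents=True, exist_ok=True)
    dataset = simulate_dataset(config)

    paths = {
        "species": out_dir / "species.nwk",
        "groups": out_dir / "groups.tsv",
        "manifest": out_dir / "manifest.tsv",
        "truth": out_dir / "truth.tsv",
    }
    paths["species"].write_text(write_newick(dataset.species_tree) + "\n",
                                encoding="utf-8")
    with open(paths["groups"], "w", encoding="utf-8") as groups_out, \
            open(paths["manifest"], "w", encoding="utf-8") as manifest_out, \
            open(paths["truth"], "w", encoding="utf-8") as truth_out:
        truth_out.write("family_id\tis_single_copy\tn_duplications\t"
                        "n_losses\tsingle_copy_subclades\n")
        for fam_id in sorted(dataset.families):
            fam = dataset.families[fam_id]
            subclades = "|".join(",".join(clade)
                                 for clade in fam.single_copy_subclades)
            truth_out.write(f"{fam_id}\t{int(fam.is_single_copy)}\t"
                            f"{fam.n_duplications}\t{fam.n_losses}\t"
                            f"{subclades}\n")
            if fam.group is None:
                continue
            for gene, taxon in fam.group.members:
                groups_out.write(f"{fam_id}\t{gene}\t{taxon}\n")
            tree_path = out_dir / "trees" / f"{fam_id}.nwk"
            tree_path.write_text(write_newick(fam.tree) + "\n",
                                 encoding="utf-8")
            manifest_out.write(f"{fam_id}\ttrees/{fam_id}.nwk\n")
    if dataset.removals:
        paths["removals"] = out_dir / "removals.tsv"
        with open(paths["removals"], "w", encoding="utf-8") as handle:
            for fam_id, gene in dataset.removals:
                handle.write(f"{fam_id}\t{gene}\n")
    return paths
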