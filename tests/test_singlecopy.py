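import itertools

import numpy as np
import pytest

from oracles import random_gene_tree
from scortho.examples import load_example
from scortho.reconcile import best_rooting, build_lca_index, reconcile_rooted
from scortho.simulate import (
    SimConfig,
    plant_paralog_family,
    simulate_dataset,
    simulate_species_tree,
)
from scortho.singlecopy import (
    CopyNumberVector,
    OrthologGroup,
    PipelineConfig,
    SingleCopyCall,
    classify_relationship,
    copy_numbers,
    find_single_copy_subtrees,
    pool_calls,
    read_groups_tsv,
    read_manifest_tsv,
    run_pipeline,
    taxon_count_call,
    write_calls_tsv,
)
from scortho.tree_io import TaxonMap, Tree, parse_newick

PIPE = TaxonMap.from_delimiter("|")


def group_of(genes_taxa, gid="g1"):
    return OrthologGroup(gid, tuple(genes_taxa))


def one_per_taxon(taxa, gid="g1"):
    return group_of([(f"{t}|{gid}", t) for t in taxa], gid)


class TestCopyNumbers:
    def test_all_ones(self):
        taxa = [f"T{i:02d}" for i in range(1, 19)]
        vector = copy_numbers(one_per_taxon(taxa), taxa)
        assert all(count == 1 for _, count in vector.counts)
        assert vector.total == 18

    def test_two_and_zero(self):
        group = group_of([("A|g1", "A"), ("A|g2", "A")])
        vector = copy_numbers(group, ["A", "B"])
        assert vector.as_dict() == {"A": 2, "B": 0}

    def test_total_matches_members_in_universe(self, rng):
        taxa = [f"T{i}" for i in range(6)]
        for _ in range(20):
            members = [(f"x{j}", taxa[int(rng.integers(8)) % 6])
                       for j in range(int(rng.integers(1, 12)))]
            universe = set(taxa[:4])
            vector = copy_numbers(group_of(members), universe)
            assert vector.total == sum(1 for _, t in members
                                       if t in universe)


class TestClassifyRelationship:
    def test_one_to_one_allows_zeros(self):
        vector = CopyNumberVector((("A", 1), ("B", 0), ("C", 1)))
        assert classify_relationship(vector) == "one_to_one"

    def test_one_to_many(self):
        vector = CopyNumberVector((("A", 3), ("B", 1), ("C", 1)))
        assert classify_relationship(vector) == "one_to_many"

    def test_many_to_many(self):
        vector = CopyNumberVector((("A", 2), ("B", 2), ("C", 1)))
        assert classify_relationship(vector) == "many_to_many"


class TestTaxonCountCall:
    TAXA = [f"T{i:02d}" for i in range(1, 19)]

    def test_exact(self):
        call = taxon_count_call(one_per_taxon(self.TAXA), self.TAXA)
        assert call is not None
        assert call.category == "exact"
        assert call.allowed_events == ()
        assert len(call.genes) == 18

    def test_one_duplication(self):
        members = [(f"{t}|g", t) for t in self.TAXA] + [("T01|g2", "T01")]
        call = taxon_count_call(group_of(members), self.TAXA)
        assert call.category == "one_duplication"
        assert call.allowed_events == (("duplication", "T01"),)

    def test_one_loss(self):
        members = [(f"{t}|g", t) for t in self.TAXA[:-1]]
        call = taxon_count_call(group_of(members), self.TAXA)
        assert call.category == "one_loss"
        assert call.allowed_events == (("loss", "T18"),)

    def test_two_deviations_rejected(self):
        members = [(f"{t}|g", t) for t in self.TAXA[:-2]]
        assert taxon_count_call(group_of(members), self.TAXA) is None

    def test_tolerance_zero(self):
        members = [(f"{t}|g", t) for t in self.TAXA[:-1]]
        assert taxon_count_call(group_of(members), self.TAXA, 0) is None

    def test_tolerance_two_mixed(self):
        members = [(f"{t}|g", t) for t in self.TAXA[:-1]] \
            + [("T01|g2", "T01")]
        call = taxon_count_call(group_of(members), self.TAXA, 2)
        assert call is not None
        assert call.category == "mixed"

    def test_negative_tolerance_rejected(self):
        with pytest.raises(ValueError):
            taxon_count_call(one_per_taxon(self.TAXA), self.TAXA, -1)


class TestFindSingleCopySubtrees:
    def test_worked_example_subtree_at_ab(self):
        species, gene, tmap = load_example()
        index = build_lca_index(species)
        best = best_rooting(gene, species, tmap)
        focal = index.mrca(["A", "B"])
        calls = find_single_copy_subtrees(best, index, focal,
                                          group_id="fam", budget=1)
        assert any(call.genes == ("A_1", "B_1") for call in calls)

    def test_congruent_family_one_call_whole_tree(self, species_abcd):
        index = build_lca_index(species_abcd)
        gene = parse_newick("(((A|g,B|g),C|g),D|g);", rooted=True)
        rec = reconcile_rooted(gene, species_abcd, PIPE)
        calls = find_single_copy_subtrees(rec, index, species_abcd.root,
                                          group_id="fam")
        assert len(calls) == 1
        assert calls[0].genes == ("A|g", "B|g", "C|g", "D|g")
        assert calls[0].allowed_events == ()

    def test_planted_paralog_clades_two_calls(self, species_factory):
        species = species_factory(6, seed=3)
        fam = plant_paralog_family(species, 2, "fam1")
        index = build_lca_index(species)
        rec = reconcile_rooted(fam.tree, species, PIPE)
        calls = find_single_copy_subtrees(rec, index, species.root,
                                          group_id="fam1")
        assert len(calls) == 2
        assert {call.genes for call in calls} == \
            set(fam.single_copy_subclades)

    def test_species_specific_duplication_tolerated(self, species_abcd):
        index = build_lca_index(species_abcd)
        gene = parse_newick("((((A|g1,A|g2),B|g),C|g),D|g);", rooted=True)
        rec = reconcile_rooted(gene, species_abcd, PIPE)
        calls = find_single_copy_subtrees(rec, index, species_abcd.root)
        assert len(calls) == 1
        assert calls[0].allowed_events == (("duplication", "A"),)
        with_zero_budget = find_single_copy_subtrees(
            rec, index, species_abcd.root, budget=0)
        assert with_zero_budget == []

    def test_family_missing_whole_clade_not_called(self, species_abcd):
        index = build_lca_index(species_abcd)
        gene = parse_newick("(((A|g,B|g),C|g));", rooted=True)
        # drop the unary wrapper produced by the outer parentheses
        gene = Tree(gene.root.children[0] if len(gene.root.children) == 1
                    else gene.root, rooted=True)
        rec = reconcile_rooted(gene, species_abcd, PIPE)
        calls = find_single_copy_subtrees(rec, index, species_abcd.root)
        # root maps to ABC, not the focal ABCD root: no call at the root
        assert calls == []

    def test_missing_leaf_inside_clade_counts_as_loss(self, species_abcd):
        index = build_lca_index(species_abcd)
        gene = parse_newick("((A|g,C|g),D|g);", rooted=True)
        rec = reconcile_rooted(gene, species_abcd, PIPE)
        calls = find_single_copy_subtrees(rec, index, species_abcd.root)
        assert len(calls) == 1
        assert calls[0].allowed_events == (("loss", "B"),)

    def test_nonmonophyletic_clade_excluded(self):
        # chordate-style violation: deep taxa interleaved
        species = parse_newick("((A,B),(C,D));")
        index = build_lca_index(species)
        gene = parse_newick("((A|g,C|g),(B|g,D|g));", rooted=True)
        rec = reconcile_rooted(gene, species, PIPE)
        calls = find_single_copy_subtrees(rec, index, species.root)
        assert calls == []

    def test_budget_monotonicity(self, rng):
        for seed in range(10):
            species = simulate_species_tree(5, seed=seed)
            index = build_lca_index(species)
            gene = random_gene_tree(rng, species.leaf_labels(), 7)
            rec = reconcile_rooted(gene, species, PIPE)
            previous = -1
            for budget in (0, 1, 2, 3):
                calls = find_single_copy_subtrees(rec, index, species.root,
                                                  budget=budget)
                assert len(calls) >= previous
                previous = len(calls)

    def test_child_order_invariance(self, rng):
        for seed in range(10):
            species = simulate_species_tree(5, seed=seed)
            index = build_lca_index(species)
            gene = random_gene_tree(rng, species.leaf_labels(), 7)
            flipped = gene.copy()
            for node in flipped.postorder():
                node.children.reverse()
            a = find_single_copy_subtrees(
                reconcile_rooted(gene, species, PIPE), index, species.root)
            b = find_single_copy_subtrees(
                reconcile_rooted(flipped, species, PIPE), index, species.root)
            assert sorted(c.genes for c in a) == sorted(c.genes for c in b)

    def test_call_copy_invariant(self, rng):
        # every call: one gene per focal taxon except allowed events
        for seed in range(15):
            species = simulate_species_tree(6, seed=seed)
            index = build_lca_index(species)
            gene = random_gene_tree(rng, species.leaf_labels(), 8)
            rec = reconcile_rooted(gene, species, PIPE)
            for call in find_single_copy_subtrees(rec, index, species.root,
                                                  budget=2):
                counts = {t: 0 for t in call.focal_taxa}
                for g in call.genes:
                    counts[g.split("|", 1)[0]] += 1
                deviating = {t for _, t in call.allowed_events}
                for taxon, count in counts.items():
                    if taxon not in deviating:
                        assert count == 1

    def test_budget_zero_matches_exhaustive_congruence_scan(self, rng):
        # independent oracle: a clean sub-tree rooted at focal is exactly a
        # cost-0 reconciliation covering each focal taxon once
        for seed in range(15):
            species = simulate_species_tree(4, seed=seed)
            index = build_lca_index(species)
            gene = random_gene_tree(rng, species.leaf_labels(), 6)
            rec = reconcile_rooted(gene, species, PIPE)
            got = {call.genes
                   for call in find_single_copy_subtrees(
                       rec, index, species.root, budget=0)}
            taxa = set(species.leaf_labels())
            clean_nodes = []
            for node in gene.postorder():
                sub = Tree(node.copy(), rooted=True)
                leaf_taxa = [l.label.split("|", 1)[0] for l in sub.leaves()]
                if sorted(leaf_taxa) != sorted(taxa):
                    continue
                if reconcile_rooted(sub, species, PIPE).total_cost == 0:
                    clean_nodes.append(node)
            maximal = [n for n in clean_nodes
                       if not any(other is not n and n in
                                  list(other.postorder())
                                  for other in clean_nodes)]
            expected = {tuple(sorted(l.label for l in n.leaves()))
                        for n in maximal}
            assert got == expected


class TestPoolCalls:
    def make(self, gid, genes, guides=("g",)):
        return SingleCopyCall(group_id=gid, genes=tuple(sorted(genes)),
                              mode="subtree", category="subtree",
                              guide_tree_ids=tuple(guides))

    def test_same_call_two_guides_merged(self):
        calls = [self.make("f", ["a", "b"], ["coelomata"]),
                 self.make("f", ["a", "b"], ["ecdysozoa"])]
        pooled = pool_calls(calls)
        assert len(pooled) == 1
        assert pooled[0].guide_tree_ids == ("coelomata", "ecdysozoa")

    def test_distinct_gene_sets_kept(self):
        calls = [self.make("f", ["a", "b"]), self.make("f", ["c", "d"])]
        assert len(pool_calls(calls)) == 2

    def test_idempotent_and_order_insensitive(self):
        calls = [self.make("f", ["a", "b"], ["x"]),
                 self.make("f", ["c", "d"], ["y"]),
                 self.make("f", ["a", "b"], ["y"])]
        once = pool_calls(calls)
        twice = pool_calls(once)
        reversed_input = pool_calls(list(reversed(calls)))
        assert once == twice == reversed_input


class TestRunPipeline:
    def build_clean_dataset(self, n_taxa=6, n_families=8, seed=11):
        config = SimConfig(n_taxa=n_taxa, n_families=n_families, seed=seed)
        dataset = simulate_dataset(config)
        groups = {fid: fam.group for fid, fam in dataset.families.items()
                  if fam.group is not None}
        trees = {fid: fam.tree for fid, fam in dataset.families.items()
                 if fam.tree is not None}
        return dataset, groups, trees

    def test_clean_dataset_zero_increase(self):
        dataset, groups, trees = self.build_clean_dataset()
        report, calls = run_pipeline(
            groups, trees, {"guide": dataset.species_tree},
            dataset.species_tree.leaf_labels())
        assert report.n_taxon_count_exact == len(groups)
        assert report.n_subtree_rescued == 0
        assert report.percent_increase == 0.0
        assert all(c.category == "exact" for c in calls)

    def test_planted_families_rescued(self, species_factory):
        species = species_factory(6, seed=5)
        taxa = species.leaf_labels()
        groups, trees = {}, {}
        expected_subclades = {}
        for i in range(4):
            fam = plant_paralog_family(species, 2, f"plant{i}")
            groups[fam.family_id] = fam.group
            trees[fam.family_id] = fam.tree
            expected_subclades[fam.family_id] = set(fam.single_copy_subclades)
        report, calls = run_pipeline(groups, trees, {"guide": species}, taxa)
        assert report.n_taxon_count_total == 0
        assert report.n_subtree_rescued == 8  # two clades per family
        got = {}
        for call in calls:
            got.setdefault(call.group_id, set()).add(call.genes)
        assert got == expected_subclades

    def test_percent_increase_known_by_construction(self, species_factory):
        species = species_factory(6, seed=7)
        taxa = species.leaf_labels()
        dataset, groups, trees = self.build_clean_dataset(
            n_taxa=6, n_families=10, seed=13)
        # same species tree must be used for the planted families
        groups = dict(groups)
        trees = dict(trees)
        species = dataset.species_tree
        taxa = species.leaf_labels()
        for i in range(2):
            fam = plant_paralog_family(species, 2, f"plant{i}")
            groups[fam.family_id] = fam.group
            trees[fam.family_id] = fam.tree
        report, _ = run_pipeline(groups, trees, {"guide": species}, taxa)
        assert report.n_taxon_count_total == 10
        assert report.n_subtree_rescued == 4
        assert report.percent_increase == pytest.approx(40.0)

    def test_union_property(self):
        dataset, groups, trees = self.build_clean_dataset(seed=17)
        report, calls = run_pipeline(
            groups, trees, {"guide": dataset.species_tree},
            dataset.species_tree.leaf_labels())
        assert report.n_total_unique >= report.n_taxon_count_total
        assert len(calls) == report.n_total_unique

    def test_missing_gene_tree_skipped(self, species_factory, caplog):
        species = species_factory(4, seed=1)
        fam = plant_paralog_family(species, 2, "plant")
        report, calls = run_pipeline({"plant": fam.group}, {},
                                     {"guide": species},
                                     species.leaf_labels())
        assert calls == []
        assert report.n_subtree_rescued == 0

    def test_two_identical_guides_same_as_one(self, species_factory):
        species = species_factory(5, seed=9)
        fam = plant_paralog_family(species, 2, "plant")
        one, calls_one = run_pipeline(
            {"plant": fam.group}, {"plant": fam.tree},
            {"g1": species}, species.leaf_labels())
        two, calls_two = run_pipeline(
            {"plant": fam.group}, {"plant": fam.tree},
            {"g1": species, "g2": species.copy()}, species.leaf_labels())
        assert one.n_subtree_rescued == two.n_subtree_rescued
        assert [c.genes for c in calls_one] == [c.genes for c in calls_two]


class TestTableIO:
    def test_groups_round_trip(self, tmp_path):
        path = tmp_path / "groups.tsv"
        path.write_text("f1\tA|g1\tA\nf1\tB|g1\tB\nf2\tA|g2\tA\n")
        groups = read_groups_tsv(path)
        assert set(groups) == {"f1", "f2"}
        assert groups["f1"].taxa == {"A", "B"}

    def test_manifest_relative_paths(self, tmp_path):
        manifest = tmp_path / "manifest.tsv"
        manifest.write_text("f1\ttrees/f1.nwk\n")
        paths = read_manifest_tsv(manifest)
        assert paths["f1"] == tmp_path / "trees" / "f1.nwk"

    def test_calls_tsv(self, tmp_path):
        call = SingleCopyCall(group_id="f1", genes=("A|g", "B|g"),
                              mode="subtree", category="subtree",
                              allowed_events=(("loss", "C"),),
                              guide_tree_ids=("g1",))
        out = tmp_path / "calls.tsv"
        write_calls_tsv([call], out)
        lines = out.read_text().splitlines()
        assert lines[0].startswith("group_id\t")
        assert lines[1] == "f1\tsubtree\tsubtree\tg1\tloss:C\tA|g,B|g"
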