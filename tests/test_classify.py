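import pytest

from tandemdiv.classify import (
    assign_gene_types,
    classify_tandem_genes,
    find_focal_clusters,
    nearest_outgroup_orthologs,
    outgroup_tandem_evidence,
    summarize_labels,
)
from tandemdiv.io import parse_gene_tree
from tandemdiv.tandem import TandemRepeat, detect_tandem_repeats

from conftest import make_gene


def _tree(newick, focal_prefix="A"):
    names = set()
    depth = 0
    token = ""
    for ch in newick:
        if ch in "(),;:":
            if token:
                names.add(token.split(":")[0])
            token = ""
        else:
            token += ch
    species = {
        n: ("focal" if n.startswith(focal_prefix) else "outgroup") for n in names
    }
    return parse_gene_tree(newick, species)


class TestFindFocalClusters:
    def test_sister_focal_pair_is_cluster(self):
        tree = _tree("((A1,A2),(O1,O2));")
        (cluster,) = find_focal_clusters(tree)
        assert cluster.members == frozenset({"A1", "A2"})

    def test_interleaved_species_no_cluster(self):
        tree = _tree("((A1,O1),(A2,O2));")
        assert find_focal_clusters(tree) == []

    def test_mixed_polytomy_not_a_cluster(self):
        tree = _tree("((A1,A2,O1),O2);")
        assert find_focal_clusters(tree) == []

    def test_nested_focal_clades_merge_to_maximal(self):
        tree = _tree("(((A1,A2),A3),(O1,O2));")
        (cluster,) = find_focal_clusters(tree)
        assert cluster.members == frozenset({"A1", "A2", "A3"})

    def test_no_focal_tips_error(self):
        tree = _tree("(O1,O2);")
        with pytest.raises(ValueError, match="no focal"):
            find_focal_clusters(tree)

    def test_invariant_to_ladderization(self, sim_family):
        tree = parse_gene_tree(sim_family.newick, sim_family.species_map)
        ref = {c.members for c in find_focal_clusters(tree)}
        for order in (True, False):
            tree2 = parse_gene_tree(sim_family.newick, sim_family.species_map)
            tree2.tree.ladderize(reverse=order)
            assert {c.members for c in find_focal_clusters(tree2)} == ref

    def test_simulated_clusters_recovered(self, sim_family):
        tree = parse_gene_tree(sim_family.newick, sim_family.species_map)
        got = sorted(sorted(c.members) for c in find_focal_clusters(tree))
        assert got == sim_family.truth.clusters


class TestAssignGeneTypes:
    def test_cluster_members_are_type_one(self):
        tree = _tree("((A1,A2),(O1,O2));")
        types = assign_gene_types(tree, find_focal_clusters(tree))
        assert types == {"A1": "I", "A2": "I"}

    def test_unclustered_genes_are_type_two(self):
        tree = _tree("((A1,O1),(A2,O2));")
        types = assign_gene_types(tree, find_focal_clusters(tree))
        assert types == {"A1": "II", "A2": "II"}

    def test_published_partition_sizes(self):
        # 10 clusters totalling 24 type I genes; 67 singletons are type II
        sizes = [3, 3, 3, 3, 2, 2, 2, 2, 2, 2]
        parts = []
        k = 0
        for s in sizes:
            tips = ",".join(f"A{k + i}" for i in range(s))
            parts.append(f"(({tips}),O{len(parts)})")
            k += s
        for j in range(67):
            parts.append(f"(A_s{j},O_s{j})")
        newick = parts[0]
        for p in parts[1:]:
            newick = f"({newick},{p})"
        tree = _tree(newick + ";")
        clusters = find_focal_clusters(tree)
        types = assign_gene_types(tree, clusters)
        assert len(clusters) == 10
        assert sum(1 for t in types.values() if t == "I") == 24
        assert sum(1 for t in types.values() if t == "II") == 67


class TestOutgroupTandemEvidence:
    def test_adjacent_orthologs_true(self):
        out_genes = [
            make_gene("O1", 1000, 1999, chromosome="oc1", family=True),
            make_gene("O2", 5000, 5999, chromosome="oc1", family=True),
        ]
        ortho = {"A1": {"O1"}, "A2": {"O2"}}
        assert outgroup_tandem_evidence(("A1", "A2"), ortho, out_genes)

    def test_different_chromosomes_false(self):
        out_genes = [
            make_gene("O1", 1000, chromosome="oc1", family=True),
            make_gene("O2", 1000, chromosome="oc2", family=True),
        ]
        ortho = {"A1": {"O1"}, "A2": {"O2"}}
        assert not outgroup_tandem_evidence(("A1", "A2"), ortho, out_genes)

    def test_empty_ortholog_set_false_not_error(self):
        assert not outgroup_tandem_evidence(("A1", "A2"), {"A1": set()}, [])

    def test_simulated_ancestral_pairs_supported(self, sim_family):
        tree = parse_gene_tree(sim_family.newick, sim_family.species_map)
        ortho = nearest_outgroup_orthologs(tree)
        anc_pairs = [
            tuple(k.split("|"))
            for k, v in sim_family.truth.pair_class.items()
            if v == "ancestral"
        ]
        assert anc_pairs
        assert all(
            outgroup_tandem_evidence(p, ortho, sim_family.outgroup_genes)
            for p in anc_pairs
        )


class TestClassifyTandemGenes:
    def test_cluster_pair_is_lineage_specific(self):
        tree = _tree("((((A1,A2),O3),A3),(O1,O2));")
        clusters = find_focal_clusters(tree)
        types = assign_gene_types(tree, clusters)
        reps = [TandemRepeat("c1", ("A1", "A2"), (1, 2))]
        labels = {l.gene_id: l for l in classify_tandem_genes(reps, clusters, types)}
        assert labels["A1"].tandem_class == "lineage_specific"
        assert labels["A2"].tandem_class == "lineage_specific"
        assert labels["A3"].tandem_class == "none"

    def test_type_two_repeat_is_ancestral(self):
        tree = _tree("((A1,O1),(A2,O2));")
        clusters = find_focal_clusters(tree)
        types = assign_gene_types(tree, clusters)
        reps = [TandemRepeat("c1", ("A1", "A2"), (1, 2))]
        labels = {l.gene_id: l for l in classify_tandem_genes(reps, clusters, types)}
        assert labels["A1"].tandem_class == "ancestral"
        assert labels["A2"].tandem_class == "ancestral"

    def test_six_gene_repeat_mixed_classes(self):
        # five clustered genes plus one type II gene in the same repeat:
        # the clustered ones are in both classes, the type II one ancestral
        newick = "((((A1,A2),(A3,(A4,A5))),(A6,O6)),(O1,O2));"
        tree = _tree(newick)
        clusters = find_focal_clusters(tree)
        types = assign_gene_types(tree, clusters)
        reps = [TandemRepeat("c2", tuple(f"A{i}" for i in range(1, 7)), (1, 2))]
        labels = {l.gene_id: l for l in classify_tandem_genes(reps, clusters, types)}
        assert {labels[f"A{i}"].tandem_class for i in range(1, 6)} == {"both"}
        assert labels["A6"].tandem_class == "ancestral"
        counts = summarize_labels(list(labels.values()))
        assert counts["inclusion_exclusion_ok"]
        assert counts["n_tandem"] == 6
        assert counts["n_both"] == 5

    def test_repeat_gene_missing_from_tree_error(self):
        tree = _tree("((A1,A2),(O1,O2));")
        clusters = find_focal_clusters(tree)
        types = assign_gene_types(tree, clusters)
        reps = [TandemRepeat("c1", ("A1", "ghost"), (1, 2))]
        with pytest.raises(ValueError, match="ghost"):
            classify_tandem_genes(reps, clusters, types)

    def test_simulated_labels_recovered_exactly(self, sim_family):
        tree = parse_gene_tree(sim_family.newick, sim_family.species_map)
        clusters = find_focal_clusters(tree)
        types = assign_gene_types(tree, clusters)
        reps = detect_tandem_repeats(sim_family.focal_genes)
        labels = classify_tandem_genes(reps, clusters, types)
        got = {l.gene_id: l.tandem_class for l in labels}
        assert got == sim_family.truth.tandem_class
        assert {l.gene_id: l.gene_type for l in labels} == sim_family.truth.gene_type

    def test_inclusion_exclusion_identity(self, sim_family):
        tree = parse_gene_tree(sim_family.newick, sim_family.species_map)
        clusters = find_focal_clusters(tree)
        types = assign_gene_types(tree, clusters)
        reps = detect_tandem_repeats(sim_family.focal_genes)
        counts = summarize_labels(classify_tandem_genes(reps, clusters, types))
        assert counts["inclusion_exclusion_ok"]
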