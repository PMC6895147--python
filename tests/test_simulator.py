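"""Multispecies-coalescent simulator: analytics, calibration, perturbations."""

import math
from collections import Counter

import pytest

from topocensus import (
    SpeciesTreeModel,
    apply_perturbations,
    classify_topology,
    default_model,
    enumerate_rooted_topologies,
    expected_triplet_frequencies,
    frequency_agreement_test,
    parse_newick,
    run_census,
    simulate_gene_trees,
    simulator_taxon_map,
)


def triplet_model(T, tip=6.0, seed=0, **kw):
    """((A,B),C) with internal branch T coalescent units, no scaffold."""
    h = tip + T
    nwk = f"((A:{tip},B:{tip}):{T},C:{h});"
    return SpeciesTreeModel(species_tree=parse_newick(nwk), scaffold_species=(),
                            p_dropout=0, p_duplicate=0, p_paralog=0,
                            seed=seed, **kw)


def triplet_counts(model, n_loci):
    cat = enumerate_rooted_topologies("ABC")
    cid = classify_topology(parse_newick("((A,B),C);"), cat)
    obs = Counter(f.true_focal_topology
                  for f in simulate_gene_trees(model, n_loci))
    others = [i for i in cat.ids() if i != cid]
    return [obs.get(cid, 0)] + [obs.get(i, 0) for i in others]


class TestExpectedTripletFrequencies:
    def test_star_tree_is_uniform(self):
        assert expected_triplet_frequencies(0.0) == pytest.approx(
            (1 / 3, 1 / 3, 1 / 3))

    def test_ln3_closed_form(self):
        assert expected_triplet_frequencies(math.log(3)) == pytest.approx(
            (7 / 9, 1 / 9, 1 / 9))

    def test_deep_split_is_concordant(self):
        c, d1, d2 = expected_triplet_frequencies(50.0)
        assert c == pytest.approx(1.0, abs=1e-12) and d1 < 1e-12

    def test_components_sum_to_one(self):
        for T in (0.0, 0.3, 1.7, 9.0):
            assert sum(expected_triplet_frequencies(T)) == pytest.approx(1.0)

    def test_negative_branch_rejected(self):
        with pytest.raises(ValueError):
            expected_triplet_frequencies(-0.1)


class TestSimulateGeneTrees:
    def test_trees_binary_with_positive_lengths(self):
        model = default_model(seed=1)
        for fam in simulate_gene_trees(model, 20):
            assert fam.tree.is_binary()
            for node in fam.tree.preorder():
                if node.parent is not None:
                    assert node.length is not None and node.length > 0

    def test_leafset_is_focal_copies_plus_scaffold(self):
        model = default_model(seed=1)
        fam = simulate_gene_trees(model, 1)[0]
        assert fam.tree.leaf_labels() == {"A_1", "B_1", "C_1", "D_1",
                                          "OG1", "OG2", "OG3", "OG4"}

    def test_identical_seed_gives_byte_identical_newick(self):
        a = [f.tree.canonical_newick()
             for f in simulate_gene_trees(default_model(seed=5), 10)]
        b = [f.tree.canonical_newick()
             for f in simulate_gene_trees(default_model(seed=5), 10)]
        assert a == b

    def test_per_locus_substreams_stable_under_n_loci(self):
        short = [f.tree.canonical_newick()
                 for f in simulate_gene_trees(default_model(seed=5), 5)]
        long = [f.tree.canonical_newick()
                for f in simulate_gene_trees(default_model(seed=5), 10)]
        assert long[:5] == short

    def test_deep_split_suppresses_discordance(self):
        counts = triplet_counts(triplet_model(20.0, seed=2), 2000)
        assert counts[0] >= 1998

    def test_star_tree_frequencies_uniform(self):
        counts = triplet_counts(triplet_model(0.0, seed=3), 3000)
        _, p = frequency_agreement_test(counts, [1 / 3, 1 / 3, 1 / 3])
        assert p > 0.001

    def test_nonultrametric_species_tree_rejected(self):
        with pytest.raises(ValueError, match="ultrametric"):
            SpeciesTreeModel(species_tree=parse_newick("((A:1,B:2):1,C:2);"),
                             scaffold_species=())

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            default_model().__class__(
                species_tree=parse_newick("(A:1,B:1);"), p_dropout=1.5)

    def test_zero_loci_rejected(self):
        with pytest.raises(ValueError):
            simulate_gene_trees(default_model(), 0)

    def test_embedded_triplet_marginals_match_closed_form(self):
        """Dropping one taxon from 4-taxon gene trees must reproduce the
        triplet closed form for the induced species tree (marginalization
        consistency of the coalescent).  Default tree (((A,B),C),D): the
        induced internal branches are 2 (ABC triplet) and 4 (ABD)."""
        model = default_model(seed=8)
        model.p_dropout = model.p_duplicate = model.p_paralog = 0.0
        fams = simulate_gene_trees(model, 4000)
        cat3 = enumerate_rooted_topologies("XYZ")
        for keep, T in ((("A", "B", "C"), 2.0), (("A", "B", "D"), 4.0)):
            relabel = dict(zip(keep, "XYZ"))
            obs = Counter()
            for f in fams:
                t = f.tree.copy()
                for leaf in list(t.leaves()):
                    sp = leaf.label.rsplit("_", 1)[0]
                    if sp in relabel:
                        leaf.label = relabel[sp]
                for leaf in list(t.leaves()):
                    if leaf.label not in "XYZ":
                        t = _drop(t, leaf.label)
                obs[classify_topology(t, cat3)] += 1
            conc = classify_topology(parse_newick("((X,Y),Z);"), cat3)
            exp = expected_triplet_frequencies(T)
            counts = [obs.get(conc, 0)] + \
                [obs.get(i, 0) for i in cat3.ids() if i != conc]
            _, p = frequency_agreement_test(counts, list(exp))
            assert p > 0.001, (keep, counts, exp)

    def test_topology_diversity_tracks_internal_branch_length(self):
        """Shorter internal branches yield more distinct topologies: the
        incomplete-lineage-sorting signature the census quantifies."""
        def n_distinct(internal, seed):
            tip = 1.0
            nwk = (f"(((A:{tip},B:{tip}):{internal},C:{tip + internal})"
                   f":{internal},D:{tip + 2 * internal});")
            m = SpeciesTreeModel(species_tree=parse_newick(nwk),
                                 scaffold_species=(), p_dropout=0,
                                 p_duplicate=0, p_paralog=0, seed=seed)
            return len({f.true_focal_topology
                        for f in simulate_gene_trees(m, 1500)})

        assert n_distinct(0.01, 13) >= 10   # toward all 15
        assert n_distinct(8.0, 13) <= 4     # collapses toward 1


def _drop(tree, label):
    from topocensus.topocensus import _detach_leaf
    return _detach_leaf(tree, tree.find_leaf(label))


class TestApplyPerturbations:
    def test_zero_probabilities_are_identity(self):
        model = default_model(seed=4)
        model.p_dropout = model.p_duplicate = model.p_paralog = 0.0
        fams = simulate_gene_trees(model, 10)
        out = apply_perturbations(fams, model)
        assert [f.tree.canonical_newick() for f in out] == \
            [f.tree.canonical_newick() for f in fams]
        assert all(f.expected_category == "complete" for f in out)

    def test_certain_duplication_doubles_every_species(self):
        model = default_model(seed=4)
        model.p_dropout = model.p_paralog = 0.0
        model.p_duplicate = 1.0
        out = apply_perturbations(simulate_gene_trees(model, 15), model)
        for fam in out:
            labels = fam.tree.leaf_labels()
            for sp in "ABCD":
                assert {f"{sp}_1", f"{sp}_2"} <= labels
            assert fam.expected_category == "duplicated_collapsed"
        records, res = run_census([(f.family_id, f.tree) for f in out],
                                  simulator_taxon_map(model), "focal")
        assert all(r.category == "duplicated_collapsed" for r in records)

    def test_certain_paralog_forces_cross_species_rejection(self):
        model = default_model(seed=4)
        model.p_dropout = model.p_duplicate = 0.0
        model.p_paralog = 1.0
        out = apply_perturbations(simulate_gene_trees(model, 15), model)
        records, res = run_census([(f.family_id, f.tree) for f in out],
                                  simulator_taxon_map(model), "focal")
        assert all(r.reject_reason == "cross_species_duplication"
                   for r in records)
        assert res.n_rejected == 15

    def test_certain_dropout_rejects_too_few(self):
        model = default_model(seed=4)
        model.p_dropout = 1.0
        model.p_duplicate = model.p_paralog = 0.0
        out = apply_perturbations(simulate_gene_trees(model, 5), model)
        assert all(f.expected_reject_reason == "too_few_species" for f in out)

    def test_perturbation_tags_recorded(self):
        model = default_model(seed=6)
        model.p_dropout, model.p_duplicate, model.p_paralog = 0.5, 0.5, 0.5
        out = apply_perturbations(simulate_gene_trees(model, 30), model)
        tags = {t.split(":")[0] for f in out for t in f.perturbations_applied}
        assert tags == {"dropout", "duplicate", "paralog"}


class TestFrequencyAgreement:
    def test_exact_proportions_give_zero_statistic(self):
        stat, p = frequency_agreement_test([300, 300, 400],
                                           [0.3, 0.3, 0.4])
        assert stat == 0.0 and p == 1.0

    def test_known_statistic(self):
        stat, _ = frequency_agreement_test([400, 300, 300],
                                           [1 / 3, 1 / 3, 1 / 3])
        assert stat == pytest.approx(20.0, abs=1e-6)

    def test_small_expected_categories_pooled(self):
        # expected counts 0.5/0.5/99 -> the two small cells merge
        stat, p = frequency_agreement_test([1, 0, 99],
                                           [0.005, 0.005, 0.99])
        assert math.isfinite(stat) and 0 <= p <= 1

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            frequency_agreement_test([10], [1.0])
        with pytest.raises(ValueError):
            frequency_agreement_test([1, 2], [0.6, 0.6])
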