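"""Census aggregation: counting, proportions, consensus, bookkeeping."""

import dendropy
import numpy as np
import pytest

from topocensus import (
    CensusOptions,
    TreeError,
    apply_perturbations,
    census_summary_text,
    clade_set,
    default_model,
    majority_consensus,
    parse_newick,
    run_census,
    simulate_gene_trees,
    simulator_taxon_map,
)


def _families_to_input(fams):
    return [(f.family_id, f.tree) for f in fams]


class TestMajorityConsensus:
    def test_unanimous_trees_give_full_support(self):
        trees = [parse_newick("(((a,b),c),d);") for _ in range(5)]
        cons, support = majority_consensus(trees)
        assert cons.canonical_newick(lengths=False) == "(((a,b)100,c)100,d);"
        assert all(v == 1.0 for v in support.values())

    def test_two_thirds_clade_kept_minority_dropped(self):
        trees = [parse_newick(s) for s in
                 ["((a,b),c);", "((a,b),c);", "((a,c),b);"]]
        cons, support = majority_consensus(trees)
        assert support == {frozenset("ab"): pytest.approx(2 / 3)}
        assert cons.canonical_newick(lengths=False) == "((a,b)67,c);"

    def test_three_way_tie_gives_star(self):
        trees = [parse_newick(s) for s in
                 ["((a,b),c);", "((a,c),b);", "((b,c),a);"]]
        cons, support = majority_consensus(trees)
        assert support == {}
        assert cons.canonical_newick(lengths=False) == "(a,b,c);"

    def test_exactly_half_excluded(self):
        trees = [parse_newick(s) for s in
                 ["((a,b),(c,d));", "((a,b),(c,d));",
                  "(((a,c),b),d);", "(((a,c),b),d);"]]
        _, support = majority_consensus(trees)
        assert frozenset("ab") not in support
        assert frozenset("ac") not in support

    def test_leaf_set_mismatch_rejected(self):
        with pytest.raises(TreeError):
            majority_consensus([parse_newick("((a,b),c);"),
                                parse_newick("((a,b),d);")])

    def test_agrees_with_dendropy_on_simulated_trees(self):
        """Independent cross-check against dendropy's majority consensus."""
        model = default_model(seed=11)
        fams = simulate_gene_trees(
            model.__class__(species_tree=model.species_tree,
                            scaffold_species=(), p_dropout=0, p_duplicate=0,
                            p_paralog=0, seed=11), 25)
        trees = []
        for f in fams:
            t = f.tree.copy()
            for leaf in t.leaves():
                leaf.label = leaf.label.rsplit("_", 1)[0]
            trees.append(t)
        cons, support = majority_consensus(trees)
        tns = dendropy.TaxonNamespace()
        tl = dendropy.TreeList([
            dendropy.Tree.get(data=t.canonical_newick(lengths=False),
                              schema="newick", taxon_namespace=tns,
                              rooting="force-rooted") for t in trees])
        dcons = tl.consensus(min_freq=0.5)
        d_clades = set()
        for node in dcons.preorder_node_iter():
            labs = frozenset(l.taxon.label for l in node.leaf_iter())
            if 1 < len(labs) < 4:
                d_clades.add(labs)
        assert set(support) == d_clades


class TestRunCensus:
    def test_simple_proportion_counting(self, fixture_taxon_map):
        a = "(((((x1:1,y1:1):1,z1:1):1,w1:1):1,og1:9):1,og2:9);"
        b = "(((((x1:1,z1:1):1,y1:1):1,w1:1):1,og1:9):1,og2:9);"
        trees = [(str(i), parse_newick(a)) for i in range(7)]
        trees += [(str(7 + i), parse_newick(b)) for i in range(3)]
        _, res = run_census(trees, fixture_taxon_map, "focal")
        assert res.n_rejected == 0
        props = sorted(res.proportions["complete"].values(), reverse=True)
        assert props == [pytest.approx(0.7), pytest.approx(0.3)]

    def test_rejected_families_excluded_from_proportions(
            self, fixture_taxon_map):
        good = "(((((x1:1,y1:1):1,z1:1):1,w1:1):1,og1:9):1,og2:9);"
        para = "((((x1,og1),(y1,z1)):1,w1):1,og2);"
        _, res = run_census([("1", parse_newick(good)),
                             ("2", parse_newick(para))],
                            fixture_taxon_map, "focal")
        assert res.n_rejected == 1
        assert res.rejection_reasons["paraphyletic_focal_group"] == 1
        assert sum(res.proportions["complete"].values()) == pytest.approx(1.0)

    def test_empty_input_rejected(self, fixture_taxon_map):
        with pytest.raises(ValueError):
            run_census([], fixture_taxon_map, "focal")

    def test_consensus_scope_flag(self):
        model = default_model(seed=3)
        fams = apply_perturbations(simulate_gene_trees(model, 120), model)
        tmap = simulator_taxon_map(model)
        trees = _families_to_input(fams)
        _, both = run_census(trees, tmap, "focal",
                             CensusOptions(consensus_scope="complete_plus_collapsed"))
        _, only = run_census(trees, tmap, "focal",
                             CensusOptions(consensus_scope="complete_only"))
        # scope changes only the consensus pool, never the counts
        assert both.counts == only.counts
        assert sum(both.counts["duplicated_collapsed"].values()) > 0
        assert both.consensus is not None and only.consensus is not None
        # support values must differ in denominator when collapsed families exist
        n_both = sum(both.counts["complete"].values()) + \
            sum(both.counts["duplicated_collapsed"].values())
        n_only = sum(only.counts["complete"].values())
        assert n_both > n_only

    def test_accounting_invariants_over_random_fixtures(self):
        """n_input = n_rejected + sum of category counts, and per-category
        proportions sum to 1, over >= 200 randomized simulated families."""
        rng = np.random.default_rng(2024)
        total = 0
        for rep in range(10):
            model = default_model(seed=int(rng.integers(2**31)))
            model.p_dropout = float(rng.uniform(0, 0.4))
            model.p_duplicate = float(rng.uniform(0, 0.5))
            model.p_paralog = float(rng.uniform(0, 0.3))
            fams = apply_perturbations(simulate_gene_trees(model, 25), model)
            records, res = run_census(_families_to_input(fams),
                                      simulator_taxon_map(model), "focal")
            assert len(records) == res.n_input == 25
            classified = sum(sum(c.values()) for c in res.counts.values())
            assert res.n_input == res.n_rejected + classified
            for cat, props in res.proportions.items():
                if props:
                    assert sum(props.values()) == pytest.approx(1.0, abs=1e-9)
            if res.pooled_full_proportions:
                assert sum(res.pooled_full_proportions.values()) == \
                    pytest.approx(1.0, abs=1e-9)
            total += len(records)
        assert total >= 200

    def test_consensus_support_equals_topology_proportion_sum(self):
        """Each consensus clade's support equals the summed proportion of
        topologies containing that clade (the quantity read off the census
        figures)."""
        model = default_model(seed=99)
        fams = apply_perturbations(simulate_gene_trees(model, 200), model)
        _, res = run_census(_families_to_input(fams),
                            simulator_taxon_map(model), "focal")
        assert res.consensus_support
        for cl, sup in res.consensus_support.items():
            total = sum(p for tid, p in res.pooled_full_proportions.items()
                        if cl in clade_set(res.catalog.tree(tid)))
            assert sup == pytest.approx(total, abs=1e-12)

    def test_summary_text_reports_counts(self, fixture_taxon_map):
        good = "(((((x1:1,y1:1):1,z1:1):1,w1:1):1,og1:9):1,og2:9);"
        _, res = run_census([("1", parse_newick(good))],
                            fixture_taxon_map, "focal")
        text = census_summary_text(res)
        assert "gene families analysed: 1" in text
        assert "100%" in text
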