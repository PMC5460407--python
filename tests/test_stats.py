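"""Monophyly, support-threshold collapsing, and conflict/support diagnostics."""

import pytest

from plct import (
    Status,
    build_leg,
    build_plct,
    collapse_low_support,
    collapse_sweep,
    conflict_support_comparison,
    batch_table,
    decide,
    monophyly,
    parse_leafmap_from_names,
    read_gene_tree,
)

from conftest import random_instance


class TestMonophyly:
    def test_coalesced_samples_are_monophyletic(self):
        tree = read_gene_tree("((C|2|i,C|2|ii),C|1|i);")
        rep = monophyly(tree, parse_leafmap_from_names(tree))
        from plct import SpeciesLocus

        assert rep.per_locus[SpeciesLocus("C", "2")] is True
        assert rep.tree_monophyletic  # the singleton C:1 is trivially a clade

    def test_crossed_quartet_nothing_monophyletic(self, crossed_instance):
        rep = monophyly(*crossed_instance)
        assert not any(rep.per_locus.values())
        assert not rep.tree_monophyletic
        assert rep.fraction_loci == 0.0

    def test_singletons_trivially_monophyletic(self):
        tree = read_gene_tree("((A|1,B|1),C|1);")
        rep = monophyly(tree, parse_leafmap_from_names(tree))
        assert all(rep.per_locus.values())

    def test_unrooted_mode_accepts_complement_side(self):
        # A:1 = {left cherry}; rooted at one of its genes it is not a clade,
        # but one side of a bipartition still isolates it
        tree = read_gene_tree("(A|1|i,(A|1|ii,(B|1|i,B|2|i)));")
        lmap = parse_leafmap_from_names(tree)
        from plct import SpeciesLocus

        rooted = monophyly(tree, lmap, mode="rooted")
        unrooted = monophyly(tree, lmap, mode="unrooted")
        a1 = SpeciesLocus("A", "1")
        assert rooted.per_locus[a1] is False
        assert unrooted.per_locus[a1] is True

    def test_tree_monophyletic_implies_all_loci(self):
        for seed in range(20):
            tree, lmap = random_instance(8, seed)
            rep = monophyly(tree, lmap)
            assert rep.tree_monophyletic == all(rep.per_locus.values())
            assert 0.0 <= rep.fraction_loci <= 1.0

    def test_all_monophyletic_implies_feasible(self):
        """Edge-disjoint label subtrees cannot co-label any branch."""
        tree = read_gene_tree(
            "(((A|1|i,A|1|ii),(A|2|i,A|2|ii)),((B|1|i,B|1|ii),(B|2|i,B|2|ii)));"
        )
        lmap = parse_leafmap_from_names(tree)
        assert monophyly(tree, lmap).tree_monophyletic
        assert decide(tree, lmap).status is Status.FEASIBLE


class TestCollapse:
    def test_quartet_below_threshold_becomes_star(self):
        tree = read_gene_tree("((a,b)30,(c,d)30);")
        star = collapse_low_support(tree, 50)
        assert len(star.root.children) == 4
        assert not star.is_binary

    def test_threshold_zero_is_identity(self):
        tree = read_gene_tree("((a:1,b:1)95,(c:1,d:1)30);")
        out = collapse_low_support(tree, 0)
        assert set(out.branch_bipartitions().values()) == set(
            tree.branch_bipartitions().values()
        )

    def test_only_low_support_branch_contracted(self):
        tree = read_gene_tree("(((a,b)95,c)30,(d,e));")
        out = collapse_low_support(tree, 50)
        bips = {frozenset(b) for b in out.branch_bipartitions().values()}
        assert len(out.unrooted_branches()) == len(tree.unrooted_branches()) - 1
        # the 95 clade survives
        survived = any(b == frozenset({"a", "b"}) or b == frozenset({"c", "d", "e"}) for b in bips)
        assert survived

    def test_unknown_support_never_collapses(self):
        tree = read_gene_tree("((a,b),(c,d));")
        out = collapse_low_support(tree, 100)
        assert len(out.unrooted_branches()) == len(tree.unrooted_branches())

    def test_strict_inequality_at_threshold(self):
        tree = read_gene_tree("((a,b)50,(c,d)50);")
        out = collapse_low_support(tree, 50)
        assert len(out.unrooted_branches()) == len(tree.unrooted_branches())


class TestCollapseSweep:
    def test_crossed_quartet_sweep(self, crossed_instance):
        tree, lmap = crossed_instance
        supported = read_gene_tree("((A|1|i,A|2|i)30,(A|1|ii,A|2|ii)30);")
        report = collapse_sweep([(supported, lmap)], [0, 100])
        assert report.verdicts[0] == [Status.INFEASIBLE]
        assert report.verdicts[100] == [Status.UNKNOWN]

    def test_feasible_batch_stays_feasible_at_zero(self):
        from plct import SimParams, assign_supports, simulate_batch

        fams = simulate_batch(SimParams(seed=5), 10)
        instances = [
            (assign_supports(f.gene_tree, "random", seed=i), f.leaf_map)
            for i, f in enumerate(fams)
        ]
        report = collapse_sweep(instances, [0])
        assert report.counts[0] == {Status.FEASIBLE: 10}

    def test_counts_sum_to_batch_size(self):
        from plct import SimParams, assign_supports, perturb_nni, simulate_batch

        fams = simulate_batch(SimParams(seed=11, dup_rate=0.3), 12)
        instances = []
        for i, f in enumerate(fams):
            t = perturb_nni(f.gene_tree, i % 4, seed=i)
            instances.append((assign_supports(t, "random", seed=i), f.leaf_map))
        thresholds = [25, 50, 75, 100]
        report = collapse_sweep(instances, thresholds)
        for t in thresholds:
            assert sum(report.counts[t].values()) == 12
        frame = report.to_frame()
        assert list(frame["threshold"]) == thresholds
        # infeasible count non-increasing, unknown non-decreasing
        assert list(frame["n_infeasible"]) == sorted(frame["n_infeasible"], reverse=True)
        assert list(frame["n_unknown"]) == sorted(frame["n_unknown"])

    def test_collapsed_leg_edges_subset_of_original(self):
        """Contraction only removes co-label witnesses; edges never appear."""
        from plct import SimParams, assign_supports, perturb_nni, simulate_batch

        fams = simulate_batch(SimParams(seed=21, dup_rate=0.3), 8)
        for i, f in enumerate(fams):
            t = assign_supports(
                perturb_nni(f.gene_tree, 2, seed=i), "random", seed=100 + i
            )
            orig = build_leg(build_plct(t, f.leaf_map)).edges()
            for thr in (25, 50, 75, 100):
                coll = collapse_low_support(t, thr)
                edges = build_leg(build_plct(coll, f.leaf_map)).edges()
                assert edges <= orig


class TestConflictSupportComparison:
    def test_no_conflict_gives_undefined_statistic(self):
        tree = read_gene_tree("((A|1|i,A|1|ii)90,(B|1|i,B|1|ii)80);")
        df, results = conflict_support_comparison(tree, parse_leafmap_from_names(tree))
        assert set(df["conflict"]) <= {"none"}
        assert results["weak"] is None and results["strong"] is None

    def test_crossed_internal_branch_is_strong_conflict(self):
        tree = read_gene_tree("((A|1|i,A|2|i)30,(A|1|ii,A|2|ii));")
        df, _ = conflict_support_comparison(tree, parse_leafmap_from_names(tree))
        assert list(df["conflict"]) == ["strong"]
        assert list(df["support"]) == [30.0]

    def test_constructed_separation_detected(self):
        """Conflicting branches assigned low support rank strictly lower."""
        from plct import SimParams, assign_supports, perturb_nni, simulate_batch

        fams = simulate_batch(SimParams(seed=31, dup_rate=0.4, samples_per_species=2), 30)
        stats_seen = 0
        for i, f in enumerate(fams):
            t = perturb_nni(f.gene_tree, 3, seed=i)
            t = assign_supports(t, "conflict-aware", seed=i, leaf_map=f.leaf_map)
            df, results = conflict_support_comparison(t, f.leaf_map)
            if results["weak"] is None:
                continue
            stat, p = results["weak"]
            assert stat < 0  # conflicting group lower
            stats_seen += 1
        assert stats_seen >= 3


def test_batch_table_fields():
    from plct import SimParams, simulate_batch

    fams = simulate_batch(SimParams(seed=41), 6)
    table = batch_table([(f.gene_tree, f.leaf_map) for f in fams])
    assert table["trees"] == 6
    assert table["infeasible"] == 0
    assert 0 <= table["monophyletic_loci_pct"] <= 100
    assert table["loci"] >= 12
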