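"""DLC simulator with multiple individuals, and controlled perturbations."""

import pytest

from plct import (
    SimParams,
    Status,
    assign_supports,
    decide,
    make_crossed_cherries,
    monophyly,
    perturb_nni,
    scale_species_tree,
    simulate_batch,
    simulate_family,
)


class TestSimulateFamily:
    def test_no_duplication_gives_single_locus_coalescent(self):
        fam = simulate_family(SimParams(dup_rate=0.0, loss_rate=0.0, seed=1))
        assert not fam.empty
        lmap = fam.leaf_map
        assert all(sl.locus == "1" for sl in lmap.assignments.values())
        assert len(lmap.assignments) == 24  # 12 species x 2 samples
        assert fam.gene_tree.is_binary
        assert decide(fam.gene_tree, lmap).status is Status.FEASIBLE

    def test_k_samples_per_surviving_locus(self):
        fam = simulate_family(SimParams(dup_rate=0.3, loss_rate=0.1, seed=4, samples_per_species=3))
        assert not fam.empty
        for genes in fam.leaf_map.genes_by_locus().values():
            assert len(genes) == 3

    def test_true_trees_always_feasible(self):
        """The generative model admits a reconciliation for every history."""
        n_checked = 0
        for seed in range(60):
            for k in (2, 5):
                fam = simulate_family(
                    SimParams(dup_rate=0.2, loss_rate=0.2, seed=seed, samples_per_species=k)
                )
                if fam.empty:
                    continue
                assert decide(fam.gene_tree, fam.leaf_map).status is Status.FEASIBLE
                n_checked += 1
        assert n_checked >= 100

    def test_fixed_seed_reproducible(self):
        a = simulate_family(SimParams(seed=99, dup_rate=0.2))
        b = simulate_family(SimParams(seed=99, dup_rate=0.2))
        assert a.gene_tree.to_newick() == b.gene_tree.to_newick()
        assert a.leaf_map.assignments == b.leaf_map.assignments
        assert a.locus_events == b.locus_events

    def test_heavy_loss_flags_empty_family(self):
        found_empty = False
        for seed in range(80):
            fam = simulate_family(SimParams(dup_rate=0.0, loss_rate=3.0, seed=seed))
            if fam.empty:
                assert fam.gene_tree is None
                found_empty = True
                break
        assert found_empty

    def test_loss_induced_copy_number_variation_still_validates(self):
        """Species may lack loci entirely; maps still pair with their trees."""
        seen_variable = False
        for seed in range(60):
            fam = simulate_family(SimParams(dup_rate=0.4, loss_rate=0.4, seed=seed))
            if fam.empty:
                continue
            fam.leaf_map.validate_against(fam.gene_tree)
            per_species = fam.leaf_map.loci_by_species()
            if len({len(v) for v in per_species.values()}) > 1:
                seen_variable = True
        assert seen_variable

    def test_batch_seeds_derived_from_master(self):
        b1 = simulate_batch(SimParams(seed=5), 4)
        b2 = simulate_batch(SimParams(seed=5), 4)
        assert [f.gene_tree.to_newick() for f in b1] == [f.gene_tree.to_newick() for f in b2]
        trees = {f.gene_tree.to_newick() for f in b1}
        assert len(trees) == 4  # sub-streams differ


class TestIlsTrend:
    def test_monophyly_decreases_with_more_samples(self):
        """More samples per species mean more chances for deep coalescence."""
        fractions = {}
        for k in (2, 10):
            fams = simulate_batch(
                SimParams(seed=13, dup_rate=0.1, loss_rate=0.1, samples_per_species=k), 60
            )
            vals = [monophyly(f.gene_tree, f.leaf_map).fraction_loci for f in fams]
            fractions[k] = sum(vals) / len(vals)
        assert fractions[10] < fractions[2]

    def test_monophyly_decreases_with_shorter_branches(self):
        """Scaling down coalescent-unit lengths (larger populations) raises ILS."""
        fractions = {}
        for scale in (1.0, 0.25):
            tree = scale_species_tree(
                SimParams().species_tree, scale
            )
            fams = simulate_batch(
                SimParams(species_tree=tree, seed=17, samples_per_species=2), 60
            )
            vals = [monophyly(f.gene_tree, f.leaf_map).fraction_loci for f in fams]
            fractions[scale] = sum(vals) / len(vals)
        assert fractions[0.25] < fractions[1.0]


class TestPerturbNni:
    def test_zero_moves_is_identity(self):
        fam = simulate_family(SimParams(seed=2))
        t = perturb_nni(fam.gene_tree, 0, seed=0)
        assert set(t.branch_bipartitions().values()) == set(
            fam.gene_tree.branch_bipartitions().values()
        )

    def test_single_move_on_quartet_crosses_the_cherries(self, uncrossed_instance):
        tree, lmap = uncrossed_instance
        for seed in range(8):
            t = perturb_nni(tree, 1, seed=seed)
            assert decide(t, lmap).status is Status.INFEASIBLE

    def test_leaf_set_preserved(self):
        fam = simulate_family(SimParams(seed=3, dup_rate=0.2))
        t = perturb_nni(fam.gene_tree, 10, seed=1)
        assert t.leaf_names == fam.gene_tree.leaf_names
        assert t.is_binary

    def test_infeasibility_rises_with_moves(self):
        """Monte-Carlo trend: more NNI noise, more infeasible trees."""
        levels = [0, 2, 8]
        fractions = []
        fams = simulate_batch(SimParams(seed=23, dup_rate=0.3, loss_rate=0.1), 40)
        for moves in levels:
            bad = 0
            for i, f in enumerate(fams):
                t = perturb_nni(f.gene_tree, moves, seed=1000 + i)
                if decide(t, f.leaf_map).status is Status.INFEASIBLE:
                    bad += 1
            fractions.append(bad / len(fams))
        assert fractions[0] == 0.0
        assert fractions[2] >= fractions[1] >= fractions[0]
        assert fractions[2] > 0.0


class TestCrossedCherries:
    def test_plain_quartet_matches_worked_example(self):
        tree, lmap = make_crossed_cherries(species="A")
        assert decide(tree, lmap).status is Status.INFEASIBLE
        assert tree.leaf_names == {"A|1|i", "A|2|i", "A|1|ii", "A|2|ii"}

    def test_embedded_in_feasible_background_stays_infeasible(self):
        for seed in range(10):
            fam = simulate_family(SimParams(seed=seed))
            if fam.empty:
                continue
            assert decide(fam.gene_tree, fam.leaf_map).status is Status.FEASIBLE
            tree, lmap = make_crossed_cherries(
                species="X", background=(fam.gene_tree, fam.leaf_map)
            )
            assert decide(tree, lmap).status is Status.INFEASIBLE

    def test_leaf_name_collision_with_background_rejected(self):
        q, qm = make_crossed_cherries(species="A")
        with pytest.raises(ValueError, match="shares leaf names"):
            make_crossed_cherries(species="A", background=(q, qm))


class TestAssignSupports:
    def test_constant_rule(self, uncrossed_instance):
        tree, _ = uncrossed_instance
        out = assign_supports(tree, "constant", value=100.0)
        internal = [b for b in out.unrooted_branches() if not out.is_leaf_branch(b)]
        assert all(out.branch_support(b) == 100.0 for b in internal)

    def test_random_rule_reproducible(self):
        fam = simulate_family(SimParams(seed=8))
        a = assign_supports(fam.gene_tree, "random", seed=5)
        b = assign_supports(fam.gene_tree, "random", seed=5)
        assert a.to_newick() == b.to_newick()

    def test_conflict_aware_separates_ranges(self, crossed_instance):
        tree, lmap = crossed_instance
        out = assign_supports(tree, "conflict-aware", seed=0, leaf_map=lmap)
        sup = out.branch_support(out.merged_root_branch_id)
        assert sup is not None and sup < 50  # the conflicting internal branch

    def test_unknown_rule_rejected(self, crossed_instance):
        with pytest.raises(ValueError, match="rule"):
            assign_supports(crossed_instance[0], "bogus")
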