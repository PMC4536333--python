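import numpy as np
import pandas as pd
import pytest

from oracles import enumerate_gene_trees, oracle_reconcile, tree_to_newick

from balaena.expansion import (
    assign_expansions,
    expression_flag,
    identity_band_filter,
    lca_reconcile,
    percent_protein_difference,
    root_minimizing_duplications,
)
from balaena.simulate import (
    DuplicationEvent,
    FamilySimSpec,
    simulate_family_evolution,
)
from balaena.trees import PhyloTree

SPECIES_TREE = PhyloTree.from_newick("((A:1,B:1):1,C:1);")
SPECIES_PARENT = {"A": "A+B", "B": "A+B", "A+B": "A+B+C", "C": "A+B+C",
                  "A+B+C": None}


class TestLcaReconcile:
    def test_congruent_gene_tree_has_no_duplications(self):
        gene = PhyloTree.from_newick("((A|g1,B|g2),C|g3);")
        rec = lca_reconcile(gene, SPECIES_TREE)
        assert rec.n_duplications == 0
        assert all(e == "speciation" for e in rec.events.values())

    def test_single_duplication_at_ab_ancestor(self):
        gene = PhyloTree.from_newick("((A|g1,(A|g2,B|g3)),C|g4);")
        rec = lca_reconcile(gene, SPECIES_TREE)
        assert rec.n_duplications == 1
        assert rec.duplications_by_branch == {"A+B": 1}

    def test_three_copies_in_one_species_give_two_terminal_duplications(self):
        gene = PhyloTree.from_newick("((A|g1,A|g2),A|g3);")
        rec = lca_reconcile(gene, SPECIES_TREE)
        assert rec.n_duplications == 2
        assert rec.duplications_by_branch == {"A": 2}

    def test_unmapped_species_rejected(self):
        gene = PhyloTree.from_newick("(A|g1,Z|g2);")
        with pytest.raises(ValueError, match="unknown species"):
            lca_reconcile(gene, SPECIES_TREE)

    def test_matches_exhaustive_oracle_up_to_five_leaves(self):
        for n in range(2, 6):
            for shape in enumerate_gene_trees(n, ("A", "B", "C")):
                gene = PhyloTree.from_newick(tree_to_newick(shape))
                rec = lca_reconcile(gene, SPECIES_TREE)
                n_dups, by_branch = oracle_reconcile(shape, SPECIES_PARENT)
                assert rec.n_duplications == n_dups, shape
                assert rec.duplications_by_branch == by_branch, shape


class TestAssignExpansions:
    def test_counts_sum_over_families(self):
        g1 = PhyloTree.from_newick("((A|g1,A|g2),C|g3);")
        g2 = PhyloTree.from_newick("((A|g4,(A|g5,B|g6)),C|g7);")
        recs = [lca_reconcile(g, SPECIES_TREE, gene_tree_id=f"f{i}")
                for i, g in enumerate([g1, g2])]
        table = assign_expansions(recs, SPECIES_TREE)
        counts = dict(zip(table["branch"], table["duplications"]))
        assert counts["A"] == 1 and counts["A+B"] == 1
        assert table["duplications"].sum() == sum(r.n_duplications for r in recs)

    def test_no_duplications_gives_all_zero_vector(self):
        gene = PhyloTree.from_newick("((A|g1,B|g2),C|g3);")
        table = assign_expansions([lca_reconcile(gene, SPECIES_TREE)], SPECIES_TREE)
        assert (table["duplications"] == 0).all()


class TestRootingByMinimalDuplications:
    def test_multifurcating_root_resolved_to_zero_duplications(self):
        # the unrooted version of the congruent tree must reconcile cleanly
        gene = PhyloTree.from_newick("(A|g1,B|g2,C|g3);")
        rooted = root_minimizing_duplications(gene, SPECIES_TREE)
        rec = lca_reconcile(rooted, SPECIES_TREE)
        assert rec.n_duplications == 0


class TestIdentityBand:
    def protein_pair(self, n_mismatches, length=100):
        a = "ACDEFGHIKLMNPQRSTVWY" * (length // 20)
        b = list(a)
        for i in range(n_mismatches):
            pos = 5 * i  # spread the mismatches out
            b[pos] = "W" if a[pos] != "W" else "Y"
        return a, "".join(b)

    @pytest.mark.parametrize(
        "mismatches,expected_d,keep",
        [(5, 5.0, True), (0, 0.0, False), (15, 15.0, False), (1, 1.0, True),
         (10, 10.0, True)],
    )
    def test_band_boundaries_inclusive(self, mismatches, expected_d, keep):
        a, b = self.protein_pair(mismatches)
        got_keep, d = identity_band_filter(a, b)
        assert d == pytest.approx(expected_d)
        assert got_keep is keep

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            identity_band_filter("", "ACDE")

    def test_percent_difference_counts_aligned_positions_only(self):
        # an internal deletion creates gap columns that must not count
        d = percent_protein_difference("ACDEFGHIKL" * 4, "ACDEF" + "ACDEFGHIKL" * 3)
        assert 0.0 <= d <= 100.0


class TestExpressionFlag:
    def counts(self):
        return pd.DataFrame(
            [("g1", "muscle", 50), ("g1", "kidney", 3), ("g2", "muscle", 9)],
            columns=["gene_id", "tissue", "count"],
        )

    def test_total_across_tissues_reaches_threshold(self):
        table = expression_flag(["g1"], self.counts())
        assert bool(table.loc[0, "expressed"]) is True
        assert table.loc[0, "total_reads"] == 53

    def test_below_threshold_not_expressed(self):
        table = expression_flag(["g2"], self.counts())
        assert bool(table.loc[0, "expressed"]) is False

    def test_missing_gene_flagged(self):
        table = expression_flag(["absent"], self.counts())
        row = table.iloc[0]
        assert bool(row["missing"]) and not bool(row["expressed"])

    def test_negative_counts_rejected(self):
        bad = self.counts()
        bad.loc[0, "count"] = -1
        with pytest.raises(ValueError):
            expression_flag(["g1"], bad)


class TestClosedLoopWithSimulator:
    def test_planted_events_recovered_exactly(self):
        from balaena.simulate import DEFAULT_STUDY_TREE

        species_tree = PhyloTree.from_newick(DEFAULT_STUDY_TREE)
        spec = FamilySimSpec(
            species_tree=species_tree, family_id="fam", n_codons=120, seed=11,
            events=[
                DuplicationEvent(branch="mm_bmysticetus"),
                DuplicationEvent(branch=frozenset(
                    {"mm_balaenoptera", "mm_bmysticetus"})),
            ],
        )
        family = simulate_family_evolution(spec)
        rec = lca_reconcile(family.gene_tree, species_tree)
        assert rec.n_duplications == 2
        assert rec.duplications_by_branch == {
            "mm_bmysticetus": 1,
            "mm_balaenoptera+mm_bmysticetus": 1,
        }

    def test_no_planted_events_reconcile_to_zero(self):
        from balaena.simulate import DEFAULT_STUDY_TREE

        species_tree = PhyloTree.from_newick(DEFAULT_STUDY_TREE)
        spec = FamilySimSpec(
            species_tree=species_tree, family_id="fam", n_codons=60, seed=3,
        )
        family = simulate_family_evolution(spec)
        rec = lca_reconcile(family.gene_tree, species_tree)
        assert rec.n_duplications == 0

    def test_planted_duplicate_pair_lands_in_identity_band(self):
        from balaena.simulate import DEFAULT_STUDY_TREE

        species_tree = PhyloTree.from_newick(DEFAULT_STUDY_TREE)
        spec = FamilySimSpec(
            species_tree=species_tree, family_id="fam", n_codons=150, seed=23,
            events=[DuplicationEvent(branch="mm_bmysticetus")],
        )
        family = simulate_family_evolution(spec)
        copies = sorted(
            g for g, s in family.species_of.items() if s == "mm_bmysticetus"
        )
        assert len(copies) == 2
        keep, d = identity_band_filter(
            family.proteins[copies[0]], family.proteins[copies[1]]
        )
        assert keep, f"divergence {d}% outside band"
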