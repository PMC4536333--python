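import numpy as np
import pytest

from oracles import brute_force_lnl_3taxon

from balaena.codonmodel import (
    CodonAlignment,
    EigenQ,
    FlatTree,
    LikelihoodEngine,
    SiteClass,
    class_time_scalings,
    codon_space,
    compress_patterns,
    f3x4_frequencies,
    log_likelihood,
    mixture_log_likelihood,
    rate_matrix,
    transition_probabilities,
    uniform_frequencies,
)
from balaena.trees import PhyloTree

SPACE = codon_space()
PI = uniform_frequencies(SPACE)


class TestRateMatrix:
    def test_rows_sum_to_zero_and_unit_mean_rate(self):
        q = rate_matrix(2.0, 0.5, PI, SPACE)
        assert np.abs(q.sum(axis=1)).max() < 1e-12
        assert -float(PI @ np.diag(q)) == pytest.approx(1.0)

    def test_multi_nucleotide_changes_have_zero_rate(self):
        q = rate_matrix(2.0, 0.5, PI, SPACE)
        multi = ~(SPACE.syn_ts | SPACE.syn_tv | SPACE.non_ts | SPACE.non_tv)
        np.fill_diagonal(multi, False)
        assert np.all(q[multi] == 0.0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            rate_matrix(-1.0, 0.5, PI, SPACE)


class TestTransitionProbabilities:
    def test_zero_time_is_identity(self):
        p = transition_probabilities(2.0, 0.5, PI, 0.0, SPACE)
        assert np.allclose(p, np.eye(SPACE.n), atol=1e-12)

    def test_long_time_reaches_stationarity(self):
        p = transition_probabilities(2.0, 0.5, PI, 500.0, SPACE)
        assert np.abs(p - PI[None, :]).max() < 1e-9

    def test_rows_sum_to_one_and_nonnegative(self):
        p = transition_probabilities(1.5, 2.0, PI, 0.3, SPACE)
        assert np.abs(p.sum(axis=1) - 1.0).max() < 1e-9
        assert p.min() >= 0.0

    def test_detailed_balance(self):
        pi = f3x4_frequencies(
            np.array([[SPACE.index["ATG"], SPACE.index["AAA"],
                       SPACE.index["TGC"], SPACE.index["GGG"]]]),
            SPACE,
        )
        p = transition_probabilities(2.0, 0.3, pi, 0.2, SPACE)
        flow = pi[:, None] * p
        assert np.abs(flow - flow.T).max() < 1e-8

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            transition_probabilities(2.0, 0.5, PI, -0.1, SPACE)


class TestCodonAlignment:
    def test_gap_codons_and_ambiguity_become_missing(self):
        aln = CodonAlignment.from_sequences([("a", "ATG---NNN"), ("b", "ATGAAACCC")])
        assert aln.matrix[0, 1] == -1 and aln.matrix[0, 2] == -1
        clean, kept = aln.drop_incomplete_columns()
        assert clean.n_sites == 1 and list(kept) == [0]

    def test_partial_codon_gap_rejected(self):
        with pytest.raises(ValueError, match="codon-sized"):
            CodonAlignment.from_sequences([("a", "AT-AAA"), ("b", "ATGAAA")])

    def test_round_trip_to_sequences(self):
        seqs = [("a", "ATGAAA"), ("b", "ATG---")]
        aln = CodonAlignment.from_sequences(seqs)
        assert aln.to_sequences() == seqs

    def test_pattern_compression_preserves_column_multiset(self):
        aln = CodonAlignment.from_sequences(
            [("a", "ATGATGAAA"), ("b", "ATGATGCCC")]
        )
        patterns, weights, s2p = compress_patterns(aln.matrix)
        assert weights.sum() == aln.n_sites
        assert np.all(patterns[:, s2p] == aln.matrix)


class TestLikelihood:
    def test_zero_tree_single_site_is_single_draw_from_pi(self):
        aln = CodonAlignment.from_sequences([("a", "ATG"), ("b", "ATG")])
        tree = PhyloTree.from_newick("(a:0,b:0);")
        lnl = log_likelihood(aln, tree, [SiteClass(1.0, 0.5, 0.5)], 2.0, PI)
        assert lnl == pytest.approx(np.log(1 / 61), abs=1e-9)

    def test_pruning_matches_brute_force_on_three_taxa(self):
        aln = CodonAlignment.from_sequences([
            ("X", "ATGAAATGCGGG"), ("Y", "ATGAAGTGTGGC"), ("Z", "ATGCAATGCGGA")
        ])
        lengths = (0.2, 0.3, 0.1, 0.4)
        tree = PhyloTree.from_newick("((X:0.2,Y:0.3):0.1,Z:0.4);")
        kappa, omega = 2.5, 0.4
        lnl = log_likelihood(aln, tree, [SiteClass(1.0, omega, omega)], kappa, PI)
        brute = brute_force_lnl_3taxon(
            aln.matrix, lengths, kappa, omega, PI, SPACE
        )
        assert lnl == pytest.approx(brute, abs=1e-8)

    def test_reroot_invariance(self):
        # same unrooted tree rooted on two different branches
        aln = CodonAlignment.from_sequences([
            ("X", "ATGAAATGCGGG"), ("Y", "ATGAAGTGTGGC"), ("Z", "ATGCAATGCGGA")
        ])
        classes = [SiteClass(1.0, 0.4, 0.4)]
        t1 = PhyloTree.from_newick("((X:0.2,Y:0.3):0.1,Z:0.4);")
        t2 = PhyloTree.from_newick("(X:0.2,(Y:0.3,Z:0.5):0.0);")
        lnl1 = log_likelihood(aln, t1, classes, 2.0, PI)
        lnl2 = log_likelihood(aln, t2, classes, 2.0, PI)
        assert lnl1 == pytest.approx(lnl2, abs=1e-8)

    def test_engine_matches_standalone_mixture_for_branch_site_classes(self):
        tree = PhyloTree.from_newick("((a:0.2,b:0.2):0.1,(c:0.3,d:0.4):0.1);")
        tree.set_foreground("d")
        aln = CodonAlignment.from_sequences([
            ("a", "ATGAAATGC"), ("b", "ATGAAGTGT"),
            ("c", "ATGCAATGC"), ("d", "TTGCAATGC"),
        ])
        classes = [
            SiteClass(0.5, 0.2, 0.2), SiteClass(0.3, 1.0, 1.0),
            SiteClass(0.2, 0.2, 5.0),
        ]
        clean, _ = aln.drop_incomplete_columns()
        patterns, weights, _ = compress_patterns(clean.matrix)
        flat = FlatTree(tree, clean.taxa)
        engine = LikelihoodEngine(patterns, weights, flat, PI, SPACE)
        direct = mixture_log_likelihood(
            patterns, weights, flat, classes, 2.0, PI, SPACE
        )
        assert engine.mixture_lnl(classes, 2.0) == pytest.approx(direct, abs=1e-10)
        # cached second call returns the identical value
        assert engine.mixture_lnl(classes, 2.0) == pytest.approx(direct, abs=1e-12)

    def test_mismatched_taxa_rejected(self):
        aln = CodonAlignment.from_sequences([("a", "ATG"), ("b", "ATG")])
        tree = PhyloTree.from_newick("(a:0.1,c:0.1);")
        with pytest.raises(ValueError, match="differ"):
            log_likelihood(aln, tree, [SiteClass(1.0, 1.0, 1.0)], 2.0, PI)


class TestFrequencies:
    def test_f3x4_sums_to_one_and_positive(self):
        aln = CodonAlignment.from_sequences([("a", "ATGAAATGCCCG")])
        pi = f3x4_frequencies(aln.matrix, SPACE)
        assert pi.sum() == pytest.approx(1.0)
        assert pi.min() > 0

    def test_mixture_scaling_is_background_flux_weighted(self):
        classes = [SiteClass(0.5, 0.1, 0.1), SiteClass(0.5, 1.0, 1.0)]
        bg, fg = class_time_scalings(classes, 2.0, PI, SPACE)
        assert bg == fg  # no branch-site structure
        # proportion-weighted background rates average to one
        assert 0.5 * bg[0] + 0.5 * bg[1] == pytest.approx(1.0)
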