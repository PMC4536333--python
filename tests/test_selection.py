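import numpy as np
import pytest
from scipy.stats import spearmanr

from oracles import brute_force_lnl_3taxon

from balaena.codonmodel import CodonAlignment, codon_space, uniform_frequencies
from balaena.ng86 import ng86_pairwise
from balaena.selection import (
    CodonModelParams,
    LRTResult,
    SelectionFit,
    acceleration_ratio,
    branch_site_test,
    build_site_classes,
    call_positive_selection,
    fit_model,
    lrt,
    neb_site_posteriors,
    pairwise_ml_dnds,
    rank_acceleration,
)
from balaena.simulate import SimulationSpec, simulate_codon_alignment
from balaena.trees import PhyloTree

SPACE = codon_space()
PI = uniform_frequencies(SPACE)


@pytest.fixture(scope="module")
def purifying_data(request):
    """6-taxon alignment simulated under a single purifying ratio."""
    tree = PhyloTree.from_newick(
        "((A:0.2,B:0.2):0.1,(C:0.15,(D:0.1,(E:0.05,F:0.05):0.05):0.05):0.1);"
    )
    spec = SimulationSpec(
        tree=tree, model="M0", theta={"omega": 0.2}, n_codons=500, seed=42
    )
    aln, _ = simulate_codon_alignment(spec)
    return aln, tree


class TestFitModel:
    def test_m0_recovers_simulated_omega(self, purifying_data):
        aln, tree = purifying_data
        fit = fit_model(aln, tree, "M0")
        assert fit.converged
        assert 0.15 <= fit.params.omegas[0] <= 0.25

    def test_unknown_model_rejected(self, purifying_data):
        aln, tree = purifying_data
        with pytest.raises(ValueError, match="unknown model"):
            fit_model(aln, tree, "M9")

    def test_branch_site_model_requires_foreground(self, purifying_data):
        aln, tree = purifying_data
        with pytest.raises(ValueError, match="foreground"):
            fit_model(aln, tree, "A")

    def test_nesting_monotonicity_with_site_and_branch_site_models(
        self, purifying_data
    ):
        aln, tree = purifying_data
        fg = tree.copy()
        fg.set_foreground("F")
        suite = branch_site_test(aln, fg)
        eps = 1e-6
        assert suite.m0.lnl <= suite.site.lnl + eps
        assert suite.site.lnl <= suite.a.lnl + eps
        assert suite.a_null.lnl <= suite.a.lnl + eps

    def test_classic_two_class_dialect_fits(self, purifying_data):
        aln, tree = purifying_data
        fit = fit_model(aln, tree, "M1")
        omegas = fit.params.omegas
        assert omegas == [0.0, 1.0]
        assert fit.n_free_params == 2


class TestLrt:
    def fake_fit(self, model, lnl):
        params = CodonModelParams(
            kappa=2.0,
            site_classes=build_site_classes(
                model,
                {"omega": 0.5, "p0": 0.5, "p1": 0.3, "omega0": 0.5,
                 "omega2": 2.0, "q": 0.8, "r": 0.5},
            ),
            pi=PI,
        )
        from balaena.selection import MODEL_FREE_PARAMS

        return SelectionFit(
            model=model, params=params, lnl=lnl,
            n_free_params=MODEL_FREE_PARAMS[model], converged=True,
        )

    def test_equal_likelihoods_give_p_one(self):
        r = lrt(self.fake_fit("M1a", -100.0), self.fake_fit("A", -100.0))
        assert r.statistic == 0.0 and r.p_value == pytest.approx(1.0)

    def test_chi_square_critical_values(self):
        r2 = lrt(self.fake_fit("M1a", -100.0), self.fake_fit("A", -100.0 + 5.991 / 2))
        assert r2.df == 2
        assert r2.p_value == pytest.approx(0.05, abs=1e-3)
        r1 = lrt(self.fake_fit("A_null", -100.0), self.fake_fit("A", -100.0 + 3.841 / 2))
        assert r1.df == 1
        assert r1.p_value == pytest.approx(0.05, abs=1e-3)

    def test_statistic_clamped_at_zero(self):
        r = lrt(self.fake_fit("M1a", -99.0), self.fake_fit("A", -100.0))
        assert r.statistic == 0.0

    def test_non_nested_pair_rejected(self):
        with pytest.raises(ValueError, match="nested"):
            lrt(self.fake_fit("M2", -100.0), self.fake_fit("A", -99.0))


class TestNebPosteriors:
    def test_posteriors_sum_to_one_and_match_bayes_formula(self):
        """Posteriors equal the hand-computed Bayes ratio built from
        brute-force per-class site likelihoods on a tiny fixture."""
        tree = PhyloTree.from_newick("((X:0.2,Y:0.3):0.1,Z:0.4);")
        tree.set_foreground("Z")
        aln = CodonAlignment.from_sequences(
            [("X", "ATGAAA"), ("Y", "ATGAAG"), ("Z", "TTGCAA")]
        )
        theta = {"q": 0.8, "r": 0.5, "omega0": 0.2, "omega2": 3.0}
        classes = build_site_classes("A", theta)
        params = CodonModelParams(kappa=2.0, site_classes=classes, pi=PI)
        fit = SelectionFit(
            model="A", params=params, lnl=-1.0, n_free_params=5,
            converged=True, fitted_tree=tree,
        )
        post = neb_site_posteriors(fit, aln, tree, pp_threshold=0.5)
        assert np.allclose(post.posteriors.sum(axis=1), 1.0, atol=1e-9)

        # oracle: per-class likelihood by brute-force marginalization with
        # mixture-scaled branch lengths, then Bayes' rule
        from balaena.codonmodel import class_time_scalings

        sbg, sfg = class_time_scalings(classes, 2.0, PI, SPACE)
        expected = []
        for site in range(aln.n_sites):
            joint = []
            for ci, c in enumerate(classes):
                from balaena.codonmodel import EigenQ, rate_matrix

                px = EigenQ.decompose(
                    rate_matrix(2.0, c.omega_background, PI, SPACE), PI
                ).transition_matrix(0.2 * sbg[ci])
                py = EigenQ.decompose(
                    rate_matrix(2.0, c.omega_background, PI, SPACE), PI
                ).transition_matrix(0.3 * sbg[ci])
                pin = EigenQ.decompose(
                    rate_matrix(2.0, c.omega_background, PI, SPACE), PI
                ).transition_matrix(0.1 * sbg[ci])
                pz = EigenQ.decompose(
                    rate_matrix(2.0, c.omega_foreground, PI, SPACE), PI
                ).transition_matrix(0.4 * sfg[ci])
                x, y, z = aln.matrix[:, site]
                like = 0.0
                for root in range(SPACE.n):
                    for inner in range(SPACE.n):
                        like += (PI[root] * pin[root, inner] * px[inner, x]
                                 * py[inner, y] * pz[root, z])
                joint.append(c.proportion * like)
            expected.append(np.array(joint) / sum(joint))
        assert np.allclose(post.posteriors, np.array(expected), atol=1e-8)

    def test_zero_positive_mass_flags_nothing(self):
        tree = PhyloTree.from_newick("(X:0.1,Y:0.1);")
        tree.set_foreground("Y")
        aln = CodonAlignment.from_sequences([("X", "ATGAAA"), ("Y", "TTGCAA")])
        theta = {"q": 1.0 - 1e-9, "r": 0.5, "omega0": 0.2, "omega2": 9.0}
        classes = build_site_classes("A", theta)
        # squeeze the positive classes to zero mass exactly
        from balaena.codonmodel import SiteClass

        classes = [
            SiteClass(0.5, 0.2, 0.2), SiteClass(0.5, 1.0, 1.0),
            SiteClass(0.0, 0.2, 9.0), SiteClass(0.0, 1.0, 9.0),
        ]
        params = CodonModelParams(kappa=2.0, site_classes=classes, pi=PI)
        fit = SelectionFit(model="A", params=params, lnl=-1.0,
                           n_free_params=5, converged=True, fitted_tree=tree)
        post = neb_site_posteriors(fit, aln, tree)
        assert post.flagged == []

    def test_unconverged_fit_rejected(self):
        params = CodonModelParams(
            kappa=2.0, site_classes=build_site_classes("M0", {"omega": 1.0}),
            pi=PI,
        )
        fit = SelectionFit(model="M0", params=params, lnl=-1.0,
                           n_free_params=2, converged=False)
        with pytest.raises(ValueError, match="unconverged"):
            neb_site_posteriors(fit, None)


class TestPairwiseMl:
    def test_identical_sequences_flagged_undefined(self):
        r = pairwise_ml_dnds("ATGAAATGC", "ATGAAATGC")
        assert r.dn == 0.0 and r.ds == 0.0 and r.omega is None

    def test_recovers_simulated_omega(self):
        tree = PhyloTree.from_newick("(a:0.1,b:0.1);")
        spec = SimulationSpec(tree=tree, model="M0", theta={"omega": 0.2},
                              n_codons=500, seed=17)
        aln, _ = simulate_codon_alignment(spec)
        seqs = dict(aln.to_sequences())
        r = pairwise_ml_dnds(seqs["a"], seqs["b"])
        assert 0.1 <= r.omega <= 0.35
        assert r.omega == pytest.approx(r.dn / r.ds, rel=1e-6)

    def test_rank_agreement_with_truth_and_counting_estimator(self):
        tree = PhyloTree.from_newick("(a:0.1,b:0.1);")
        true_omegas = np.linspace(0.05, 1.5, 10)
        ml, ng = [], []
        for i, w in enumerate(true_omegas):
            spec = SimulationSpec(tree=tree, model="M0",
                                  theta={"omega": float(w)},
                                  n_codons=300, seed=100 + i)
            aln, _ = simulate_codon_alignment(spec)
            seqs = dict(aln.to_sequences())
            ml.append(pairwise_ml_dnds(seqs["a"], seqs["b"]).omega)
            ng.append(ng86_pairwise(seqs["a"], seqs["b"]).omega)
        assert spearmanr(true_omegas, ml).statistic >= 0.8
        assert spearmanr(ml, ng).statistic >= 0.8


class TestAccelerationRatio:
    @pytest.mark.parametrize(
        "focal,r1,r2,expected",
        [(0.5, 0.5, 0.25, 1.0), (1.2, 0.6, 0.4, 2.0), (0.3, 0.0, 0.0, None)],
    )
    def test_examples(self, focal, r1, r2, expected):
        assert acceleration_ratio(focal, r1, r2) == expected

    def test_undefined_inputs_propagate(self):
        assert acceleration_ratio(None, 0.5, 0.5) is None

    def test_ranking_flags_top_fraction(self):
        ratios = {f"g{i:02d}": float(i) for i in range(40)}
        ratios["g_undef"] = None
        ranked = rank_acceleration(ratios, top_fraction=0.05)
        top = [r for r in ranked if r["top"]]
        assert len(top) == 2  # ceil(0.05 * 40)
        assert {r["gene_id"] for r in top} == {"g39", "g38"}
        undef = [r for r in ranked if r["ratio"] is None]
        assert undef and not undef[0]["top"]


class TestPositiveSelectionCall:
    def fit_with_omega2(self, omega2, p2=0.1):
        q = 1.0 - p2
        theta = {"q": q, "r": 0.5, "omega0": 0.2, "omega2": omega2}
        params = CodonModelParams(
            kappa=2.0, site_classes=build_site_classes("A", theta), pi=PI
        )
        return SelectionFit(model="A", params=params, lnl=-1.0,
                            n_free_params=5, converged=True)

    def lrt_result(self, p):
        return LRTResult("A_null", "A", 4.0, 1, p)

    def test_all_criteria_met_is_positive(self):
        call = call_positive_selection(
            self.lrt_result(0.01), self.lrt_result(0.02),
            self.fit_with_omega2(3.2), qc_passed=True,
        )
        assert call.positive and call.failed_criteria == []

    def test_omega_at_most_one_fails_parameter_criterion(self):
        call = call_positive_selection(
            self.lrt_result(0.01), self.lrt_result(0.02),
            self.fit_with_omega2(1.0), qc_passed=True,
        )
        assert not call.positive
        assert "parameters_not_positive" in call.failed_criteria

    def test_qc_failure_blocks_call(self):
        call = call_positive_selection(
            self.lrt_result(0.01), self.lrt_result(0.02),
            self.fit_with_omega2(3.2), qc_passed=False,
        )
        assert not call.positive
        assert call.failed_criteria == ["alignment_qc_failed"]

    def test_insignificant_lrt_blocks_call(self):
        call = call_positive_selection(
            self.lrt_result(0.2), self.lrt_result(0.01),
            self.fit_with_omega2(3.2), qc_passed=True,
        )
        assert call.failed_criteria == ["lrt_not_significant"]
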