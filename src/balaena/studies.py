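"""Simulation calibration studies for the branch-site machinery.

These studies define the package's reference simulation conditions: a
six-taxon tree with mammal-scale background divergence (~0.3 expected
substitutions per codon per terminal branch) and a deep foreground branch
(1.0), moderate purifying background selection (omega0 = 0.2, half of the
remaining sites neutral), transition/transversion ratio kappa = 2, and a
10% positively selected site fraction with omega2 = 4 when a signal is
planted.

* Type-I error: simulate under the branch-site null (omega2 fixed at 1),
  fit null and alternative, and measure the rejection rate of the LRT at a
  given alpha.  Because the true omega2 sits on the boundary of the
  alternative's parameter space, the chi-square(1) reference distribution
  is conservative and the empirical rate should fall below nominal.
* Power / parameter recovery: simulate under the alternative with
  omega2 = 4, and measure the fitted omega2 distribution, the LRT power,
  and how many truly positive sites the naive empirical Bayes scan flags
  at high posterior probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .selection import fit_model, lrt, neb_site_posteriors, _theta_of
from .simulate import SimulationSpec, simulate_codon_alignment
from .trees import PhyloTree

#: reference six-taxon study tree; F is the foreground lineage
STUDY_TREE_NEWICK = (
    "((A:0.3,B:0.3):0.1,(C:0.3,(D:0.3,(E:0.3,F:1.0):0.1):0.1):0.1);"
)
STUDY_FOREGROUND = "F"
STUDY_KAPPA = 2.0
STUDY_THETA_NULL = {"q": 0.9, "r": 0.5, "omega0": 0.2}
STUDY_THETA_ALT = {"q": 0.9, "r": 0.5, "omega0": 0.2, "omega2": 4.0}


def study_tree() -> PhyloTree:
    tree = PhyloTree.from_newick(STUDY_TREE_NEWICK)
    tree.set_foreground(STUDY_FOREGROUND)
    return tree


def _replicate_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def _fit_branch_site_pair(aln, tree):
    """M0 for branch lengths and kappa, then the branch-site null and
    alternative with kappa held at the M0 estimate (shared by both models,
    so the LRT comparison is unaffected)."""
    m0 = fit_model(aln, tree, "M0")
    kappa = m0.params.kappa
    a_null = fit_model(aln, tree, "A_null", m0_fit=m0, fix_kappa=kappa)
    a = fit_model(
        aln, tree, "A", m0_fit=m0, fix_kappa=kappa,
        extra_starts=[{**_theta_of(a_null), "omega2": 1.0}],
    )
    return m0, a_null, a


@dataclass
class TypeIErrorResult:
    n_replicates: int
    n_rejections: int
    alpha: float
    p_values: list[float] = field(repr=False, default_factory=list)

    @property
    def rejection_rate(self) -> float:
        return self.n_rejections / self.n_replicates


def type_i_error_study(
    n_replicates: int = 200,
    n_codons: int = 200,
    seed: int = 0,
    alpha: float = 0.05,
) -> TypeIErrorResult:
    """False-positive rate of the branch-site LRT under its null."""
    tree = study_tree()
    p_values = []
    for rep_seed in _replicate_seeds(seed, n_replicates):
        spec = SimulationSpec(
            tree=tree, model="A_null", theta=dict(STUDY_THETA_NULL),
            kappa=STUDY_KAPPA, n_codons=n_codons, seed=rep_seed,
        )
        aln, _ = simulate_codon_alignment(spec)
        _, a_null, a = _fit_branch_site_pair(aln, tree)
        p_values.append(lrt(a_null, a).p_value)
    rejections = sum(p < alpha for p in p_values)
    return TypeIErrorResult(
        n_replicates=n_replicates, n_rejections=rejections, alpha=alpha,
        p_values=p_values,
    )


@dataclass
class PowerRecoveryResult:
    n_replicates: int
    omega2_estimates: list[float]
    site_recoveries: list[float]
    p_values: list[float]
    pp_threshold: float
    n_true_positive_sites: int
    n_recovered_sites: int

    @property
    def median_omega2(self) -> float:
        return float(np.median(self.omega2_estimates))

    @property
    def median_site_recovery(self) -> float:
        return float(np.median(self.site_recoveries))

    @property
    def pooled_site_recovery(self) -> float:
        return self.n_recovered_sites / max(self.n_true_positive_sites, 1)

    def power(self, alpha: float = 0.05) -> float:
        return float(np.mean(np.asarray(self.p_values) < alpha))


def power_recovery_study(
    n_replicates: int = 25,
    n_codons: int = 500,
    seed: int = 0,
    pp_threshold: float = 0.95,
) -> PowerRecoveryResult:
    """Recovery of omega2 and of positively selected sites under model A."""
    tree = study_tree()
    omega2s, recoveries, p_values = [], [], []
    n_true = n_found = 0
    for rep_seed in _replicate_seeds(seed, n_replicates):
        spec = SimulationSpec(
            tree=tree, model="A", theta=dict(STUDY_THETA_ALT),
            kappa=STUDY_KAPPA, n_codons=n_codons, seed=rep_seed,
        )
        aln, labels = simulate_codon_alignment(spec)
        _, a_null, a = _fit_branch_site_pair(aln, tree)
        omega2s.append(a.params.site_classes[2].omega_foreground)
        p_values.append(lrt(a_null, a).p_value)
        posterior = neb_site_posteriors(a, aln, pp_threshold=pp_threshold)
        true_sites = set(np.nonzero((labels == 2) | (labels == 3))[0] + 1)
        flagged = {e["alignment_column"] for e in posterior.flagged}
        n_true += len(true_sites)
        n_found += len(flagged & true_sites)
        recoveries.append(
            len(flagged & true_sites) / len(true_sites) if true_sites else 0.0
        )
    return PowerRecoveryResult(
        n_replicates=n_replicates,
        omega2_estimates=omega2s,
        site_recoveries=recoveries,
        p_values=p_values,
        pp_threshold=pp_threshold,
        n_true_positive_sites=n_true,
        n_recovered_sites=n_found,
    )
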