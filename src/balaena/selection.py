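"""Model fitting, likelihood-ratio tests, and empirical-Bayes site scans.

Implemented models (site classes give the background/foreground dN/dS used
on unmarked/marked branches):

========  =============================================  free parameters
M0        one ratio for all sites and branches           kappa, omega
M1        sites with omega 0 or 1                        kappa, p0
M1a       sites with omega0 in [0,1] or 1                kappa, p0, omega0
M2        sites with omega 0, 1, or omega2 (free)        kappa, p0, p1, omega2
A         branch-site: background classes omega0/1,      kappa, p0, p1,
          foreground adds a class with omega2 >= 1         omega0, omega2
A_null    model A with omega2 fixed at 1                 kappa, p0, p1, omega0
========  =============================================  free parameters

Branch lengths are estimated once under M0 and held fixed for the richer
models (re-estimation available); this stabilizes fits on short alignments.
Every model with a free omega is started from several omega values and the
best of the converged fits is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

from .codonmodel import (
    CodonAlignment,
    CodonSpace,
    FlatTree,
    LikelihoodEngine,
    SiteClass,
    codon_space,
    compress_patterns,
    f3x4_frequencies,
    f61_frequencies,
    mixture_log_likelihood,
    class_site_log_likelihoods,
    rate_matrix,
    uniform_frequencies,
)
from .ng86 import PairwiseDnDs
from .trees import PhyloTree

KAPPA_BOUNDS = (0.1, 20.0)
OMEGA_BOUNDS = (1e-4, 50.0)
BRANCH_BOUNDS = (1e-7, 60.0)
PROP_BOUNDS = (0.0, 1.0)  # zero-mass classes are legal and contribute nothing

MODELS = ("M0", "M1", "M1a", "M2", "A", "A_null")

#: free parameters per model, branch lengths excluded (shared across models)
MODEL_FREE_PARAMS = {
    "M0": 2,
    "M1": 2,
    "M1a": 3,
    "M2": 4,
    "A": 5,
    "A_null": 4,
}

#: nested (null, alternative) pairs accepted by :func:`lrt`
NESTED_PAIRS = {
    ("M1", "M2"),
    ("M1", "A"),
    ("M1a", "A"),
    ("A_null", "A"),
    ("M0", "M2"),
    ("M0", "A"),
}

BRANCH_SITE_MODELS = ("A", "A_null")


@dataclass
class CodonModelParams:
    """Fitted parameters of a codon model."""

    kappa: float
    site_classes: list[SiteClass]
    pi: np.ndarray
    branch_lengths: np.ndarray | None = None  # postorder edge order

    def __post_init__(self) -> None:
        props = self.class_props
        if abs(sum(props) - 1.0) > 1e-9:
            raise ValueError(f"class proportions sum to {sum(props)}")
        if abs(float(np.sum(self.pi)) - 1.0) > 1e-9:
            raise ValueError("pi does not sum to 1")

    @property
    def class_props(self) -> list[float]:
        return [c.proportion for c in self.site_classes]

    @property
    def omegas(self) -> list[float]:
        """Background omega of each site class."""
        return [c.omega_background for c in self.site_classes]

    @property
    def foreground_omegas(self) -> list[float]:
        return [c.omega_foreground for c in self.site_classes]


@dataclass
class SelectionFit:
    model: str
    params: CodonModelParams
    lnl: float
    n_free_params: int
    converged: bool
    start_points: list[float] = field(default_factory=list)
    fitted_tree: PhyloTree | None = None

    @property
    def positive_site_classes(self) -> list[int]:
        """Indices of classes with foreground omega > 1 and mass > 0."""
        return [
            i
            for i, c in enumerate(self.params.site_classes)
            if c.omega_foreground > 1.0 and c.proportion > 0.0
        ]


@dataclass
class LRTResult:
    null_model: str
    alt_model: str
    statistic: float
    df: int
    p_value: float


@dataclass
class SitePosterior:
    """Per-site class posteriors from a naive empirical Bayes scan."""

    model: str
    posteriors: np.ndarray  # (n_clean_sites, n_classes)
    alignment_columns: np.ndarray  # 1-based original codon columns
    positive_pp: np.ndarray  # PP(any positive class) per clean site
    flagged: list[dict]  # sites with positive_pp >= threshold
    pp_threshold: float


# ---------------------------------------------------------------------------
# model structure


def build_site_classes(model: str, theta: dict[str, float]) -> list[SiteClass]:
    """Site classes for a model from its named free parameters."""
    if model == "M0":
        w = theta["omega"]
        return [SiteClass(1.0, w, w)]
    if model == "M1":
        p0 = theta["p0"]
        return [SiteClass(p0, 0.0, 0.0), SiteClass(1 - p0, 1.0, 1.0)]
    if model == "M1a":
        p0, w0 = theta["p0"], theta["omega0"]
        return [SiteClass(p0, w0, w0), SiteClass(1 - p0, 1.0, 1.0)]
    if model == "M2":
        p0, p1, w2 = theta["p0"], theta["p1"], theta["omega2"]
        p2 = max(1.0 - p0 - p1, 0.0)
        return [
            SiteClass(p0, 0.0, 0.0),
            SiteClass(p1, 1.0, 1.0),
            SiteClass(p2, w2, w2),
        ]
    if model in BRANCH_SITE_MODELS:
        q, r, w0 = theta["q"], theta["r"], theta["omega0"]
        w2 = 1.0 if model == "A_null" else theta["omega2"]
        p0, p1 = q * r, q * (1 - r)
        p2a, p2b = (1 - q) * r, (1 - q) * (1 - r)
        return [
            SiteClass(p0, w0, w0),
            SiteClass(p1, 1.0, 1.0),
            SiteClass(p2a, w0, w2),
            SiteClass(p2b, 1.0, w2),
        ]
    raise ValueError(f"unknown model {model!r}")


_MODEL_THETA: dict[str, list[tuple[str, tuple[float, float]]]] = {
    "M0": [("omega", OMEGA_BOUNDS)],
    "M1": [("p0", PROP_BOUNDS)],
    "M1a": [("p0", PROP_BOUNDS), ("omega0", (1e-4, 1.0))],
    "M2": [("p0", (0.0, 1.0)), ("p1", (0.0, 1.0)), ("omega2", OMEGA_BOUNDS)],
    "A": [
        ("q", PROP_BOUNDS),
        ("r", PROP_BOUNDS),
        ("omega0", (1e-4, 1.0)),
        ("omega2", (1.0, OMEGA_BOUNDS[1])),
    ],
    "A_null": [("q", PROP_BOUNDS), ("r", PROP_BOUNDS), ("omega0", (1e-4, 1.0))],
}


def _theta_starts(model: str, start_omegas: Sequence[float]) -> list[dict[str, float]]:
    starts: list[dict[str, float]] = []
    for s in start_omegas:
        theta: dict[str, float] = {}
        for name, (lo, hi) in _MODEL_THETA[model]:
            if name == "omega":
                theta[name] = float(np.clip(s, lo, hi))
            elif name == "omega0":
                theta[name] = float(np.clip(s, lo, min(hi, 0.9)))
            elif name == "omega2":
                theta[name] = float(np.clip(max(s, 1.5), lo, hi))
            elif name in ("p0", "q"):
                theta[name] = 0.85 if model in BRANCH_SITE_MODELS else 0.6
            elif name == "r":
                theta[name] = 0.7
            elif name == "p1":
                theta[name] = 0.3
        if theta not in starts:
            starts.append(theta)
    return starts


# ---------------------------------------------------------------------------
# fitting


def _prepare(aln: CodonAlignment, tree: PhyloTree, pi_mode, clean=True):
    if clean:
        clean_aln, kept = aln.drop_incomplete_columns()
    else:
        clean_aln, kept = aln, np.arange(aln.n_sites)
    if clean_aln.n_sites == 0:
        raise ValueError("no complete codon columns left after cleaning")
    patterns, weights, site_to_pattern = compress_patterns(clean_aln.matrix)
    flat = FlatTree(tree, clean_aln.taxa)
    space = clean_aln.space
    if isinstance(pi_mode, np.ndarray):
        pi = pi_mode
    elif pi_mode == "f3x4":
        pi = f3x4_frequencies(clean_aln.matrix, space)
    elif pi_mode == "f61":
        pi = f61_frequencies(clean_aln.matrix, space)
    elif pi_mode == "uniform":
        pi = uniform_frequencies(space)
    else:
        raise ValueError(f"unknown pi mode {pi_mode!r}")
    return clean_aln, kept, patterns, weights, site_to_pattern, flat, space, pi


def fit_model(
    aln: CodonAlignment,
    tree: PhyloTree,
    model: str,
    *,
    start_omegas: Sequence[float] = (0.5, 1.0, 2.0),
    pi_mode="f3x4",
    m0_fit: SelectionFit | None = None,
    estimate_branch_lengths: bool | None = None,
    kappa_start: float = 2.0,
    fix_kappa: float | None = None,
    extra_starts: Sequence[dict[str, float]] | None = None,
) -> SelectionFit:
    """Maximum-likelihood fit of one codon model.

    Branch lengths: M0 estimates them jointly (initialized from the tree when
    present).  Other models reuse the M0-fitted branch lengths by default;
    pass ``estimate_branch_lengths=True`` to re-estimate, or supply a tree
    whose lengths should be trusted together with ``m0_fit``-free usage via
    ``estimate_branch_lengths=False``.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
    if model in BRANCH_SITE_MODELS and not any(
        n.foreground for n in tree.postorder()
    ):
        raise ValueError(f"model {model} requires a foreground branch label")

    if estimate_branch_lengths is None:
        estimate_branch_lengths = model == "M0"

    work_tree = tree
    if model != "M0" and not estimate_branch_lengths:
        if m0_fit is None:
            m0_fit = fit_model(
                aln, tree, "M0", start_omegas=start_omegas, pi_mode=pi_mode,
                kappa_start=kappa_start,
            )
        work_tree = m0_fit.fitted_tree.copy()
        # preserve the foreground labelling of the requested tree
        for node, src in zip(work_tree.postorder(), tree.postorder()):
            node.foreground = src.foreground

    (clean_aln, _, patterns, weights, _, flat, space, pi) = _prepare(
        aln, work_tree, pi_mode
    )
    prev_engine = getattr(m0_fit, "_engine", None) if m0_fit is not None else None
    engine = LikelihoodEngine(
        patterns, weights, flat, pi, space, share_matrices_from=prev_engine
    )

    theta_spec = _MODEL_THETA[model]
    n_theta = len(theta_spec)
    edge_init = np.array(
        [flat.lengths[e] if flat.lengths[e] > 0 else 0.1 for e in flat.edge_nodes]
    )
    n_edges = len(flat.edge_nodes)
    # Branch-site models re-estimate the foreground branch length(s): the M0
    # estimate absorbs any foreground acceleration, which would otherwise
    # bias omega2 toward 1.  Background branches stay at the M0 values.
    free_fg_idx: list[int] = []
    if model in BRANCH_SITE_MODELS and not estimate_branch_lengths:
        free_fg_idx = [
            i for i, e in enumerate(flat.edge_nodes) if flat.foreground[e]
        ]

    n_kappa = 0 if fix_kappa is not None else 1

    def unpack(x: np.ndarray):
        kappa = fix_kappa if fix_kappa is not None else float(x[0])
        theta = {
            name: float(v)
            for (name, _), v in zip(theta_spec, x[n_kappa : n_kappa + n_theta])
        }
        if model == "M2":  # renormalize the two free proportions onto the simplex
            tot = theta["p0"] + theta["p1"]
            if tot > 1.0:
                theta["p0"] /= tot
                theta["p1"] /= tot
        if estimate_branch_lengths:
            lengths = tuple(float(t) for t in np.exp(x[n_kappa + n_theta :]))
        elif free_fg_idx:
            full = edge_init.copy()
            full[free_fg_idx] = np.exp(x[n_kappa + n_theta :])
            lengths = tuple(float(t) for t in full)
        else:
            lengths = tuple(float(t) for t in edge_init)
        return kappa, theta, lengths

    def negative_lnl(x: np.ndarray) -> float:
        kappa, theta, lengths = unpack(x)
        classes = build_site_classes(model, theta)
        try:
            lnl = engine.mixture_lnl(classes, kappa, lengths)
        except (ValueError, np.linalg.LinAlgError):
            return 1e10
        return -lnl if np.isfinite(lnl) else 1e10

    log_bb = (np.log(BRANCH_BOUNDS[0]), np.log(BRANCH_BOUNDS[1]))
    bounds = ([KAPPA_BOUNDS] if n_kappa else []) + [b for _, b in theta_spec]
    if estimate_branch_lengths:
        bounds += [log_bb] * n_edges
    else:
        bounds += [log_bb] * len(free_fg_idx)

    best = None
    starts = _theta_starts(model, start_omegas)
    for extra in extra_starts or ():
        theta = {
            name: float(np.clip(extra[name], lo, hi))
            for name, (lo, hi) in theta_spec
            if name in extra
        }
        if len(theta) == n_theta and theta not in starts:
            starts.append(theta)
    any_converged = False
    for theta0 in starts:
        x0 = ([kappa_start] if n_kappa else []) + [
            theta0[name] for name, _ in theta_spec
        ]
        if estimate_branch_lengths:
            x0 += list(np.log(np.maximum(edge_init, BRANCH_BOUNDS[0])))
        else:
            x0 += list(
                np.log(np.maximum(edge_init[free_fg_idx], BRANCH_BOUNDS[0]))
            )
        res = minimize(
            negative_lnl,
            np.array(x0),
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": 1e-11, "gtol": 1e-7, "maxiter": 500},
        )
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res

    kappa, theta, lengths = unpack(best.x)
    classes = build_site_classes(model, theta)
    fitted_tree = work_tree.copy()
    fitted_nodes = [
        n for n in fitted_tree.postorder() if n.parent is not None
    ]
    for node, t in zip(fitted_nodes, lengths):
        node.length = float(t)
    params = CodonModelParams(
        kappa=kappa,
        site_classes=classes,
        pi=pi,
        branch_lengths=np.asarray(lengths, dtype=float),
    )
    fit = SelectionFit(
        model=model,
        params=params,
        lnl=float(-best.fun),
        n_free_params=MODEL_FREE_PARAMS[model],
        converged=any_converged,
        start_points=list(start_omegas),
        fitted_tree=fitted_tree,
    )
    fit._engine = engine  # reused by later fits on the same alignment
    return fit


def _theta_of(fit: SelectionFit) -> dict[str, float]:
    """Named free parameters recovered from a fit's site classes."""
    c = fit.params.site_classes
    if fit.model == "M0":
        return {"omega": c[0].omega_background}
    if fit.model in ("M1", "M1a"):
        return {"p0": c[0].proportion, "omega0": c[0].omega_background}
    if fit.model == "M2":
        return {"p0": c[0].proportion, "p1": c[1].proportion,
                "omega2": c[2].omega_background}
    q = c[0].proportion + c[1].proportion
    r = c[0].proportion / q if q > 0 else 0.5
    theta = {"q": q, "r": r, "omega0": c[0].omega_background}
    if fit.model == "A":
        theta["omega2"] = c[2].omega_foreground
    return theta


@dataclass
class BranchSiteSuite:
    """All fits and tests for one alignment/foreground combination."""

    m0: SelectionFit
    site: SelectionFit
    a_null: SelectionFit
    a: SelectionFit
    lrt_vs_site: LRTResult
    lrt_vs_null: LRTResult


def branch_site_test(
    aln: CodonAlignment,
    tree: PhyloTree,
    *,
    site_model: str = "M1a",
    start_omegas: Sequence[float] = (0.5, 1.0, 2.0),
    pi_mode="f3x4",
) -> BranchSiteSuite:
    """Fit M0, the site model, A_null, and A; run both branch-site LRTs.

    The A fit is additionally started from the fitted A_null and site-model
    parameters (with omega2 at its nested value), so its optimum can never
    fall below the nulls it is tested against.
    """
    m0 = fit_model(aln, tree, "M0", start_omegas=start_omegas, pi_mode=pi_mode)
    kappa = m0.params.kappa
    site = fit_model(aln, tree, site_model, m0_fit=m0, fix_kappa=kappa,
                     start_omegas=start_omegas, pi_mode=pi_mode)
    a_null = fit_model(aln, tree, "A_null", m0_fit=m0, fix_kappa=kappa,
                       start_omegas=start_omegas, pi_mode=pi_mode)
    nested_from_site = _theta_of(site)
    nested_from_site = {
        "q": 1.0, "r": nested_from_site["p0"],
        "omega0": nested_from_site["omega0"], "omega2": 1.0,
    }
    a = fit_model(
        aln, tree, "A", m0_fit=m0, fix_kappa=kappa,
        start_omegas=start_omegas, pi_mode=pi_mode,
        extra_starts=[{**_theta_of(a_null), "omega2": 1.0}, nested_from_site],
    )
    return BranchSiteSuite(
        m0=m0, site=site, a_null=a_null, a=a,
        lrt_vs_site=lrt(site, a), lrt_vs_null=lrt(a_null, a),
    )


# ---------------------------------------------------------------------------
# likelihood-ratio test


def lrt(null_fit: SelectionFit, alt_fit: SelectionFit) -> LRTResult:
    """Chi-square LRT of two nested fits.

    The statistic 2(lnL_alt - lnL_null) is clamped at zero; degrees of
    freedom are the difference in free parameter counts.
    """
    pair = (null_fit.model, alt_fit.model)
    if pair not in NESTED_PAIRS:
        raise ValueError(f"models {pair} are not a supported nested pair")
    df = alt_fit.n_free_params - null_fit.n_free_params
    if df <= 0:
        raise ValueError("alternative model must have more free parameters")
    statistic = max(0.0, 2.0 * (alt_fit.lnl - null_fit.lnl))
    p_value = float(chi2.sf(statistic, df))
    return LRTResult(
        null_model=null_fit.model,
        alt_model=alt_fit.model,
        statistic=statistic,
        df=df,
        p_value=p_value,
    )


# ---------------------------------------------------------------------------
# naive empirical Bayes site scan


def neb_site_posteriors(
    fit: SelectionFit,
    aln: CodonAlignment,
    tree: PhyloTree | None = None,
    pp_threshold: float = 0.95,
    focal_taxon: str | None = None,
) -> SitePosterior:
    """Posterior probability of each site class at each codon site.

    PP(class c | site) = p_c L_c(site) / sum_k p_k L_k(site).  Sites whose
    total posterior mass on positively selected classes (foreground omega
    > 1) reaches the threshold are flagged, with 1-based coordinates both in
    alignment columns and in the ungapped focal sequence when given.
    """
    if not fit.converged:
        raise ValueError("cannot compute posteriors from an unconverged fit")
    tree = tree if tree is not None else fit.fitted_tree
    (clean_aln, kept, patterns, weights, site_to_pattern, flat, space, _) = _prepare(
        aln, tree, fit.params.pi
    )
    class_lnl = class_site_log_likelihoods(
        patterns, flat, fit.params.site_classes, fit.params.kappa, fit.params.pi, space
    )
    props = np.array(fit.params.class_props)
    log_joint = np.log(np.maximum(props, 1e-300))[:, None] + class_lnl
    log_joint -= log_joint.max(axis=0, keepdims=True)
    joint = np.exp(log_joint)
    post_patterns = (joint / joint.sum(axis=0, keepdims=True)).T
    posteriors = post_patterns[site_to_pattern]

    pos_classes = fit.positive_site_classes
    positive_pp = (
        posteriors[:, pos_classes].sum(axis=1)
        if pos_classes
        else np.zeros(len(posteriors))
    )

    focal_positions = None
    if focal_taxon is not None:
        row = aln.taxa.index(focal_taxon)
        ungapped = np.cumsum(aln.matrix[row] != -1)  # 1-based when indexed at col
        focal_positions = ungapped

    flagged = []
    for i, col in enumerate(kept):
        if positive_pp[i] >= pp_threshold:
            entry = {
                "alignment_column": int(col) + 1,
                "pp": float(positive_pp[i]),
            }
            if focal_positions is not None and aln.matrix[aln.taxa.index(focal_taxon), col] != -1:
                entry["focal_position"] = int(focal_positions[col])
            flagged.append(entry)
    return SitePosterior(
        model=fit.model,
        posteriors=posteriors,
        alignment_columns=kept + 1,
        positive_pp=positive_pp,
        flagged=flagged,
        pp_threshold=pp_threshold,
    )


# ---------------------------------------------------------------------------
# pairwise ML dN/dS


def _site_proportions(kappa: float, omega: float, pi: np.ndarray, space: CodonSpace):
    """Synonymous/nonsynonymous flux proportions and site fractions."""
    base = (space.syn_ts * kappa + space.syn_tv) * pi[None, :]
    non = (space.non_ts * kappa + space.non_tv) * pi[None, :]
    f_syn = float(pi @ base.sum(axis=1))
    f_non_unit = float(pi @ non.sum(axis=1))  # nonsynonymous flux at omega=1
    flux_syn = f_syn
    flux_non = omega * f_non_unit
    total = flux_syn + flux_non
    rho_s = f_syn / (f_syn + f_non_unit)  # synonymous site fraction
    return flux_syn / total, flux_non / total, rho_s, 1.0 - rho_s


def pairwise_ml_dnds(
    cds_a: str,
    cds_b: str,
    *,
    gene_id: str = "",
    species_a: str = "a",
    species_b: str = "b",
    pi_mode="f3x4",
    start_omegas: Sequence[float] = (0.5, 1.0, 2.0),
) -> PairwiseDnDs:
    """Maximum-likelihood pairwise dN/dS (one-ratio model on a 2-leaf tree).

    dN and dS are decomposed from the fitted (kappa, omega, t) with the
    standard mutational-opportunity site definition, so dN/dS equals the
    fitted omega exactly.
    """
    aln = CodonAlignment.from_sequences([(species_a, cds_a), (species_b, cds_b)])
    clean, _ = aln.drop_incomplete_columns()
    if clean.n_sites == 0:
        raise ValueError("no comparable codon columns")
    if np.array_equal(clean.matrix[0], clean.matrix[1]):
        return PairwiseDnDs(
            gene_id=gene_id, species_a=species_a, species_b=species_b,
            dn=0.0, ds=0.0, omega=None, method="ML", flags=["identical_sequences"],
        )
    tree = PhyloTree.from_newick(f"({species_a}:0.05,{species_b}:0.05);")
    fit = fit_model(
        clean, tree, "M0", start_omegas=start_omegas, pi_mode=pi_mode,
        estimate_branch_lengths=True,
    )
    kappa = fit.params.kappa
    omega = fit.params.omegas[0]
    t = float(np.sum(fit.params.branch_lengths))
    p_s, p_n, rho_s, rho_n = _site_proportions(
        kappa, omega, fit.params.pi, clean.space
    )
    ds = t * p_s / (3.0 * rho_s)
    dn = t * p_n / (3.0 * rho_n)
    flags = [] if fit.converged else ["not_converged"]
    if ds <= 0:
        return PairwiseDnDs(
            gene_id=gene_id, species_a=species_a, species_b=species_b,
            dn=dn, ds=ds, omega=None, method="ML", flags=flags + ["dS_zero"],
        )
    return PairwiseDnDs(
        gene_id=gene_id, species_a=species_a, species_b=species_b,
        dn=dn, ds=ds, omega=omega, method="ML", flags=flags,
    )


# ---------------------------------------------------------------------------
# acceleration ratio and the positive-selection call


def acceleration_ratio(
    omega_focal_pair: float | None,
    omega_ref1: float | None,
    omega_ref2: float | None,
) -> float | None:
    """Focal-pair omega over the larger of two reference-pair omegas.

    Returns None (undefined) when any input is undefined or both references
    are zero.
    """
    if omega_focal_pair is None or omega_ref1 is None or omega_ref2 is None:
        return None
    denom = max(omega_ref1, omega_ref2)
    if denom <= 0:
        return None
    return omega_focal_pair / denom


def rank_acceleration(
    ratios: dict[str, float | None], top_fraction: float = 0.05
) -> list[dict]:
    """Rank genes by acceleration ratio (descending) and flag the top slice."""
    defined = [(g, r) for g, r in ratios.items() if r is not None]
    defined.sort(key=lambda x: (-x[1], x[0]))
    n_top = int(np.ceil(top_fraction * len(defined))) if defined else 0
    out = [
        {"gene_id": g, "ratio": r, "rank": i + 1, "top": i < n_top}
        for i, (g, r) in enumerate(defined)
    ]
    out += [
        {"gene_id": g, "ratio": None, "rank": None, "top": False}
        for g, r in sorted(ratios.items())
        if r is None
    ]
    return out


@dataclass
class SelectionCall:
    gene_id: str
    positive: bool
    failed_criteria: list[str]
    p_vs_site_null: float | None = None
    p_vs_a_null: float | None = None
    omega2: float | None = None


def call_positive_selection(
    lrt_vs_site_model: LRTResult,
    lrt_vs_a_null: LRTResult,
    fit: SelectionFit,
    qc_passed: bool,
    alpha: float = 0.05,
    gene_id: str = "",
) -> SelectionCall:
    """Positive selection is called only when all three criteria hold:

    1. both LRTs (branch-site vs site model, branch-site vs its null) are
       significant at ``alpha``;
    2. the fitted parameters indicate positive selection (a foreground class
       with omega > 1 and nonzero proportion);
    3. the alignment passed quality control.
    """
    failed = []
    if not (lrt_vs_site_model.p_value < alpha and lrt_vs_a_null.p_value < alpha):
        failed.append("lrt_not_significant")
    pos_classes = fit.positive_site_classes
    pos_mass = sum(fit.params.class_props[i] for i in pos_classes)
    omega2 = (
        fit.params.site_classes[pos_classes[0]].omega_foreground
        if pos_classes
        else max(c.omega_foreground for c in fit.params.site_classes)
    )
    if not (pos_classes and omega2 > 1.0 and pos_mass > 0.0):
        failed.append("parameters_not_positive")
    if not qc_passed:
        failed.append("alignment_qc_failed")
    return SelectionCall(
        gene_id=gene_id,
        positive=not failed,
        failed_criteria=failed,
        p_vs_site_null=lrt_vs_site_model.p_value,
        p_vs_a_null=lrt_vs_a_null.p_value,
        omega2=omega2,
    )
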