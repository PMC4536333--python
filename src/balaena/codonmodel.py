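"""Codon substitution model engine.

Implements the Goldman-Yang style Markov model on the 61 sense codons:
instantaneous change is allowed only between codons differing at a single
nucleotide, with rate multipliers kappa (transition/transversion) and omega
(nonsynonymous/synonymous, i.e. dN/dS), target-codon equilibrium frequency
pi, and zero rate to/from stop codons.  Each rate matrix is scaled so one
unit of branch length equals one expected substitution per codon under that
matrix.  Likelihoods are computed by Felsenstein pruning over site patterns,
with per-site-class and per-branch (foreground/background) matrices so the
same engine serves the one-ratio, site, and branch-site models.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np

from .genetics import GeneticCode, STANDARD_CODE
from .trees import PhyloTree

_NUC_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_PURINES = {"A", "G"}

GAP_CODE = -1


class CodonSpace:
    """Precomputed structure of the sense-codon state space for one code."""

    def __init__(self, code: GeneticCode = STANDARD_CODE):
        self.code = code
        self.codons = list(code.sense_codons)
        self.n = len(self.codons)
        self.index = {c: i for i, c in enumerate(self.codons)}
        self.amino_acids = np.array([code.codon_to_aa[c] for c in self.codons])
        # nucleotide index of each codon position, shape (n, 3)
        self.position_nucs = np.array(
            [[_NUC_INDEX[b] for b in codon] for codon in self.codons]
        )
        self._build_masks()

    def _build_masks(self) -> None:
        n = self.n
        syn_ts = np.zeros((n, n), dtype=bool)
        syn_tv = np.zeros((n, n), dtype=bool)
        non_ts = np.zeros((n, n), dtype=bool)
        non_tv = np.zeros((n, n), dtype=bool)
        for i, ci in enumerate(self.codons):
            for j, cj in enumerate(self.codons):
                if i == j:
                    continue
                diffs = [k for k in range(3) if ci[k] != cj[k]]
                if len(diffs) != 1:
                    continue
                k = diffs[0]
                transition = (ci[k] in _PURINES) == (cj[k] in _PURINES)
                synonymous = self.amino_acids[i] == self.amino_acids[j]
                if synonymous and transition:
                    syn_ts[i, j] = True
                elif synonymous:
                    syn_tv[i, j] = True
                elif transition:
                    non_ts[i, j] = True
                else:
                    non_tv[i, j] = True
        self.syn_ts, self.syn_tv = syn_ts, syn_tv
        self.non_ts, self.non_tv = non_ts, non_tv
        self.synonymous_mask = syn_ts | syn_tv


@lru_cache(maxsize=4)
def codon_space(table_id: int = 1) -> CodonSpace:
    return CodonSpace(GeneticCode.from_table(table_id))


# ---------------------------------------------------------------------------
# equilibrium frequencies


def uniform_frequencies(space: CodonSpace) -> np.ndarray:
    return np.full(space.n, 1.0 / space.n)


def f61_frequencies(codon_matrix: np.ndarray, space: CodonSpace) -> np.ndarray:
    """Empirical codon frequencies with a one-count pseudo-observation."""
    counts = np.ones(space.n)
    obs = codon_matrix[codon_matrix >= 0]
    counts += np.bincount(obs, minlength=space.n)
    return counts / counts.sum()


def f3x4_frequencies(codon_matrix: np.ndarray, space: CodonSpace) -> np.ndarray:
    """F3x4 frequencies: product of per-codon-position nucleotide frequencies.

    Stop codons are excluded and the vector renormalized; a small floor keeps
    every sense codon reachable even when a nucleotide is unobserved at some
    position in a short alignment.
    """
    obs = codon_matrix[codon_matrix >= 0]
    pos_counts = np.zeros((3, 4))
    for pos in range(3):
        nucs = space.position_nucs[obs, pos]
        pos_counts[pos] = np.bincount(nucs, minlength=4)
    pos_freqs = (pos_counts + 0.5) / (pos_counts + 0.5).sum(axis=1, keepdims=True)
    pi = (
        pos_freqs[0, space.position_nucs[:, 0]]
        * pos_freqs[1, space.position_nucs[:, 1]]
        * pos_freqs[2, space.position_nucs[:, 2]]
    )
    pi = np.maximum(pi, 1e-9)
    return pi / pi.sum()


# ---------------------------------------------------------------------------
# rate matrix and transition probabilities


def rate_matrix(
    kappa: float, omega: float, pi: np.ndarray, space: CodonSpace
) -> np.ndarray:
    """Normalized instantaneous rate matrix Q (61x61).

    Scaled so that -sum_i pi_i Q_ii = 1: branch lengths are expected
    substitutions per codon.
    """
    if kappa <= 0 or omega < 0:
        raise ValueError("kappa must be > 0 and omega >= 0")
    q = (
        space.syn_ts * kappa
        + space.syn_tv * 1.0
        + space.non_ts * (kappa * omega)
        + space.non_tv * omega
    ) * pi[None, :]
    np.fill_diagonal(q, 0.0)
    rowsum = q.sum(axis=1)
    np.fill_diagonal(q, -rowsum)
    mu = float(np.dot(pi, rowsum))
    if mu <= 0:
        raise ValueError("degenerate rate matrix (zero total rate)")
    return q / mu


def substitution_flux(
    kappa: float, omega: float, pi: np.ndarray, space: CodonSpace
) -> float:
    """Expected substitutions per codon per unit time of the *unnormalized*
    rate matrix with these parameters (the mixture-scaling weight)."""
    q = (
        space.syn_ts * kappa
        + space.syn_tv * 1.0
        + space.non_ts * (kappa * omega)
        + space.non_tv * omega
    ) * pi[None, :]
    np.fill_diagonal(q, 0.0)
    return float(np.dot(pi, q.sum(axis=1)))


def class_time_scalings(
    classes: Sequence["SiteClass"],
    kappa: float,
    pi: np.ndarray,
    space: CodonSpace,
) -> tuple[list[float], list[float]]:
    """Per-class branch-length multipliers under mixture normalization.

    One unit of branch length is one expected substitution per codon under
    the *background* site-class mixture.  Since each per-omega matrix here
    is normalized to unit rate, a class with rate multiplier omega evolves
    for an effective time t * mu(omega) / mu_mix where mu_mix is the
    proportion-weighted background flux.  The same factor scales foreground
    branches, so a positively selected foreground class is genuinely
    accelerated rather than absorbed into branch-length rescaling (which
    would leave omega2 nearly unidentifiable).
    """
    mu: dict[float, float] = {}

    def flux(w: float) -> float:
        if w not in mu:
            mu[w] = substitution_flux(kappa, w, pi, space)
        return mu[w]

    mix_bg = sum(c.proportion * flux(c.omega_background) for c in classes)
    bg = [flux(c.omega_background) / mix_bg for c in classes]
    fg = [flux(c.omega_foreground) / mix_bg for c in classes]
    return bg, fg


@dataclass
class EigenQ:
    """Spectral decomposition of a reversible Q for fast exp(Qt)."""

    rates: np.ndarray  # eigenvalues
    left: np.ndarray  # D^{-1} U
    right: np.ndarray  # (D U)^T

    @classmethod
    def decompose(cls, q: np.ndarray, pi: np.ndarray) -> "EigenQ":
        d = np.sqrt(pi)
        b = q * (d[:, None] / d[None, :])
        b = 0.5 * (b + b.T)  # symmetrize against roundoff
        lam, u = np.linalg.eigh(b)
        return cls(rates=lam, left=u / d[:, None], right=(u * d[:, None]).T)

    def transition_matrix(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError("branch length must be nonnegative")
        p = (self.left * np.exp(self.rates * t)[None, :]) @ self.right
        np.clip(p, 0.0, None, out=p)
        p /= p.sum(axis=1, keepdims=True)
        return p


def transition_probabilities(
    kappa: float, omega: float, pi: np.ndarray, t: float, space: CodonSpace
) -> np.ndarray:
    """P(t) = exp(Qt) for a single (kappa, omega) matrix."""
    q = rate_matrix(kappa, omega, pi, space)
    return EigenQ.decompose(q, pi).transition_matrix(t)


# ---------------------------------------------------------------------------
# codon alignments


class CodonAlignment:
    """An in-frame codon alignment encoded as sense-codon state indices.

    ``matrix[t, s]`` is the codon-state index of taxon ``t`` at codon site
    ``s``; gap or ambiguous codons are ``GAP_CODE``.
    """

    def __init__(self, taxa: Sequence[str], matrix: np.ndarray, space: CodonSpace):
        if len(taxa) != matrix.shape[0]:
            raise ValueError("taxa/matrix shape mismatch")
        if len(set(taxa)) != len(taxa):
            raise ValueError("duplicate taxa in alignment")
        self.taxa = list(taxa)
        self.matrix = matrix
        self.space = space

    @classmethod
    def from_sequences(
        cls,
        named_seqs: Sequence[tuple[str, str]],
        space: CodonSpace | None = None,
    ) -> "CodonAlignment":
        """Build from gapped, equal-length, in-frame nucleotide strings."""
        space = space or codon_space()
        if not named_seqs:
            raise ValueError("empty alignment")
        lengths = {len(s) for _, s in named_seqs}
        if len(lengths) != 1:
            raise ValueError("alignment rows differ in length")
        (length,) = lengths
        if length % 3:
            raise ValueError(f"alignment length {length} not divisible by 3")
        n_sites = length // 3
        matrix = np.full((len(named_seqs), n_sites), GAP_CODE, dtype=np.int64)
        for ti, (_, seq) in enumerate(named_seqs):
            seq = seq.upper()
            for si in range(n_sites):
                codon = seq[3 * si : 3 * si + 3]
                state = space.index.get(codon)
                if state is not None:
                    matrix[ti, si] = state
                elif not set(codon) <= set("ACGTN-"):
                    raise ValueError(f"illegal codon {codon!r}")
                elif codon.count("-") not in (0, 3) :
                    raise ValueError(
                        f"gap not in codon-sized run at site {si + 1}: {codon!r}"
                    )
        return cls([n for n, _ in named_seqs], matrix, space)

    @property
    def n_taxa(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def drop_incomplete_columns(self) -> tuple["CodonAlignment", np.ndarray]:
        """Remove columns containing any gap or ambiguous codon.

        Returns the cleaned alignment and the original column indices kept,
        so site reports can be mapped back to input coordinates.
        """
        keep = np.all(self.matrix != GAP_CODE, axis=0)
        kept_idx = np.nonzero(keep)[0]
        return CodonAlignment(self.taxa, self.matrix[:, keep], self.space), kept_idx

    def subset(self, taxa: Sequence[str]) -> "CodonAlignment":
        rows = [self.taxa.index(t) for t in taxa]
        return CodonAlignment(list(taxa), self.matrix[rows], self.space)

    def to_sequences(self) -> list[tuple[str, str]]:
        out = []
        for ti, taxon in enumerate(self.taxa):
            seq = "".join(
                self.space.codons[s] if s >= 0 else "---" for s in self.matrix[ti]
            )
            out.append((taxon, seq))
        return out


def compress_patterns(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Collapse identical alignment columns.

    Returns (patterns, weights, site_to_pattern): patterns has shape
    (n_taxa, n_patterns); weights are column multiplicities.
    """
    cols, site_to_pattern, weights = np.unique(
        matrix.T, axis=0, return_inverse=True, return_counts=True
    )
    return cols.T, weights.astype(float), site_to_pattern


# ---------------------------------------------------------------------------
# pruning likelihood


@dataclass(frozen=True)
class SiteClass:
    """One site class of a mixture codon model."""

    proportion: float
    omega_background: float
    omega_foreground: float


class FlatTree:
    """Tree flattened to postorder arrays for fast repeated pruning."""

    def __init__(self, tree: PhyloTree, taxa: Sequence[str]):
        nodes = list(tree.postorder())
        self.n_nodes = len(nodes)
        index = {id(n): i for i, n in enumerate(nodes)}
        self.parent = np.full(self.n_nodes, -1, dtype=np.int64)
        self.lengths = np.zeros(self.n_nodes)
        self.foreground = np.zeros(self.n_nodes, dtype=bool)
        self.is_leaf = np.zeros(self.n_nodes, dtype=bool)
        self.leaf_row = np.full(self.n_nodes, -1, dtype=np.int64)
        self.children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        taxon_row = {t: i for i, t in enumerate(taxa)}
        tree_leaves = set(tree.leaf_names())
        if tree_leaves != set(taxa):
            raise ValueError(
                "tree leaves and alignment taxa differ: "
                f"only-in-tree={sorted(tree_leaves - set(taxa))}, "
                f"only-in-alignment={sorted(set(taxa) - tree_leaves)}"
            )
        for i, node in enumerate(nodes):
            if node.parent is not None:
                self.parent[i] = index[id(node.parent)]
                self.children[index[id(node.parent)]].append(i)
                self.lengths[i] = node.length if node.length is not None else 0.0
            self.foreground[i] = node.foreground
            if node.is_leaf:
                self.is_leaf[i] = True
                self.leaf_row[i] = taxon_row[node.name]
        self.root = self.n_nodes - 1
        self.edge_nodes = [i for i in range(self.n_nodes) if self.parent[i] >= 0]

    def with_lengths(self, lengths: np.ndarray) -> "FlatTree":
        import copy

        new = copy.copy(self)
        full = np.zeros(self.n_nodes)
        full[self.edge_nodes] = lengths
        new.lengths = full
        return new


def class_site_log_likelihoods(
    patterns: np.ndarray,
    flat: FlatTree,
    classes: Sequence[SiteClass],
    kappa: float,
    pi: np.ndarray,
    space: CodonSpace,
) -> np.ndarray:
    """Per-class per-pattern log-likelihoods, shape (n_classes, n_patterns).

    Patterns must be gap-free (run :meth:`CodonAlignment.drop_incomplete_columns`
    first).  Branches flagged foreground use each class's foreground omega.
    """
    n_classes = len(classes)
    n_patterns = patterns.shape[1]
    omegas = sorted(
        {c.omega_background for c in classes} | {c.omega_foreground for c in classes}
    )
    eigens = {
        w: EigenQ.decompose(rate_matrix(kappa, w, pi, space), pi) for w in omegas
    }
    scale_bg, scale_fg = class_time_scalings(classes, kappa, pi, space)

    out = np.empty((n_classes, n_patterns))
    for ci, cls_ in enumerate(classes):
        partial = {}  # node -> (n_patterns, n_states)
        logscale = np.zeros(n_patterns)
        for node in range(flat.n_nodes):
            if flat.is_leaf[node]:
                continue
            prod = None
            for child in flat.children[node]:
                if flat.foreground[child]:
                    w, s = cls_.omega_foreground, scale_fg[ci]
                else:
                    w, s = cls_.omega_background, scale_bg[ci]
                p = eigens[w].transition_matrix(flat.lengths[child] * s)
                if flat.is_leaf[child]:
                    obs = patterns[flat.leaf_row[child]]
                    msg = p[:, obs].T  # (n_patterns, n_states)
                else:
                    msg = partial.pop(child) @ p.T
                prod = msg if prod is None else prod * msg
            scale = prod.max(axis=1)
            scale[scale == 0] = 1.0
            prod /= scale[:, None]
            logscale += np.log(scale)
            partial[node] = prod
        site_l = partial[flat.root] @ pi
        out[ci] = np.log(np.maximum(site_l, 1e-300)) + logscale
    return out


def mixture_log_likelihood(
    patterns: np.ndarray,
    weights: np.ndarray,
    flat: FlatTree,
    classes: Sequence[SiteClass],
    kappa: float,
    pi: np.ndarray,
    space: CodonSpace,
) -> float:
    """Total log-likelihood of the site-class mixture."""
    class_lnl = class_site_log_likelihoods(patterns, flat, classes, kappa, pi, space)
    props = np.array([c.proportion for c in classes])
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError(f"class proportions sum to {props.sum()}, not 1")
    m = class_lnl.max(axis=0)
    site_lnl = m + np.log(np.dot(props, np.exp(class_lnl - m[None, :])))
    return float(np.dot(weights, site_lnl))


class LikelihoodEngine:
    """Pruning likelihood with memoization for iterative optimization.

    Numerical optimizers re-evaluate the likelihood at points differing in a
    single coordinate (finite-difference gradients), so eigensystems,
    per-branch transition matrices, and whole per-class site likelihood
    vectors are cached keyed on the exact parameter values that produced
    them.  Results are identical to :func:`mixture_log_likelihood`.
    """

    def __init__(
        self,
        patterns: np.ndarray,
        weights: np.ndarray,
        flat: FlatTree,
        pi: np.ndarray,
        space: CodonSpace,
        share_matrices_from: "LikelihoodEngine | None" = None,
    ):
        self.patterns = patterns
        self.weights = weights
        self.flat = flat
        self.pi = pi
        self.space = space
        if share_matrices_from is not None and np.array_equal(
            share_matrices_from.pi, pi
        ):
            # eigensystems and P(t) depend only on (kappa, omega, pi, t),
            # so they can be shared between fits on the same alignment
            self._eig = share_matrices_from._eig
            self._pmat = share_matrices_from._pmat
        else:
            self._eig = {}
            self._pmat = {}
        self._class_lnl: dict = {}

    def _eigen(self, kappa: float, omega: float) -> EigenQ:
        key = (kappa, omega)
        eig = self._eig.get(key)
        if eig is None:
            if len(self._eig) > 256:
                self._eig.clear()
            eig = EigenQ.decompose(
                rate_matrix(kappa, omega, self.pi, self.space), self.pi
            )
            self._eig[key] = eig
        return eig

    def _transition(self, kappa: float, omega: float, t: float) -> np.ndarray:
        key = (kappa, omega, t)
        p = self._pmat.get(key)
        if p is None:
            if len(self._pmat) > 4096:
                self._pmat.clear()
            p = self._eigen(kappa, omega).transition_matrix(t)
            self._pmat[key] = p
        return p

    def class_site_lnl(
        self,
        kappa: float,
        omega_background: float,
        omega_foreground: float,
        lengths: tuple[float, ...],
        scale_background: float = 1.0,
        scale_foreground: float = 1.0,
    ) -> np.ndarray:
        key = (
            kappa, omega_background, omega_foreground, lengths,
            scale_background, scale_foreground,
        )
        cached = self._class_lnl.get(key)
        if cached is not None:
            return cached
        if len(self._class_lnl) > 1024:
            self._class_lnl.clear()
        flat = self.flat
        edge_t = dict(zip(flat.edge_nodes, lengths))
        patterns = self.patterns
        n_patterns = patterns.shape[1]
        partial: dict[int, np.ndarray] = {}
        logscale = np.zeros(n_patterns)
        for node in range(flat.n_nodes):
            if flat.is_leaf[node]:
                continue
            prod = None
            for child in flat.children[node]:
                if flat.foreground[child]:
                    w, s = omega_foreground, scale_foreground
                else:
                    w, s = omega_background, scale_background
                p = self._transition(kappa, w, edge_t[child] * s)
                if flat.is_leaf[child]:
                    msg = p[:, patterns[flat.leaf_row[child]]].T
                else:
                    msg = partial.pop(child) @ p.T
                prod = msg if prod is None else prod * msg
            scale = prod.max(axis=1)
            scale[scale == 0] = 1.0
            prod /= scale[:, None]
            logscale += np.log(scale)
            partial[node] = prod
        site_l = partial[flat.root] @ self.pi
        out = np.log(np.maximum(site_l, 1e-300)) + logscale
        self._class_lnl[key] = out
        return out

    def mixture_lnl(
        self,
        classes: Sequence[SiteClass],
        kappa: float,
        lengths: tuple[float, ...] | None = None,
    ) -> float:
        if lengths is None:
            lengths = tuple(self.flat.lengths[e] for e in self.flat.edge_nodes)
        props = np.array([c.proportion for c in classes])
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError(f"class proportions sum to {props.sum()}, not 1")
        scale_bg, scale_fg = class_time_scalings(classes, kappa, self.pi, self.space)
        class_lnl = np.stack(
            [
                self.class_site_lnl(
                    kappa, c.omega_background, c.omega_foreground, lengths,
                    scale_bg[ci], scale_fg[ci],
                )
                for ci, c in enumerate(classes)
            ]
        )
        m = class_lnl.max(axis=0)
        site_lnl = m + np.log(np.dot(props, np.exp(class_lnl - m[None, :])))
        return float(np.dot(self.weights, site_lnl))


def log_likelihood(
    aln: CodonAlignment,
    tree: PhyloTree,
    classes: Sequence[SiteClass],
    kappa: float,
    pi: np.ndarray,
) -> float:
    """Convenience wrapper: clean alignment, compress, prune, mix."""
    clean, _ = aln.drop_incomplete_columns()
    if clean.n_sites == 0:
        raise ValueError("no complete codon columns in alignment")
    patterns, weights, _ = compress_patterns(clean.matrix)
    flat = FlatTree(tree, clean.taxa)
    return mixture_log_likelihood(
        patterns, weights, flat, classes, kappa, pi, clean.space
    )
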