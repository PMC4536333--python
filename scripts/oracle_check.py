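"""Brute-force oracle comparisons used by the acceptance script.

Self-contained naive implementations: exhaustive marginalization over
internal states for the pruning likelihood, and path-intersection LCA
mapping over exhaustively enumerated gene-tree shapes for reconciliation.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np

from balaena.codonmodel import (
    CodonAlignment,
    EigenQ,
    SiteClass,
    codon_space,
    log_likelihood,
    rate_matrix,
    uniform_frequencies,
)
from balaena.expansion import lca_reconcile
from balaena.trees import PhyloTree


def max_pruning_brute_force_gap(seed: int) -> tuple[float, int]:
    """Largest |pruning lnL - brute-force lnL| over rooted 3-leaf trees."""
    space = codon_space()
    pi = uniform_frequencies(space)
    rng = np.random.default_rng(seed)
    topologies = [
        ("((X:{a},Y:{b}):{c},Z:{d});", ("X", "Y", "Z")),
        ("((X:{a},Z:{b}):{c},Y:{d});", ("X", "Z", "Y")),
        ("((Y:{a},Z:{b}):{c},X:{d});", ("Y", "Z", "X")),
    ]
    length_sets = [(0.2, 0.3, 0.1, 0.4), (0.05, 0.5, 0.01, 1.2)]
    param_sets = [(2.0, 0.2), (1.2, 1.8)]
    worst = 0.0
    n_checked = 0
    for (template, order), lengths, (kappa, omega) in itertools.product(
        topologies, length_sets, param_sets
    ):
        eig = EigenQ.decompose(rate_matrix(kappa, omega, pi, space), pi)
        pa, pb, pin, pc = (eig.transition_matrix(t) for t in lengths)
        for n_sites in range(1, 6):
            states = rng.integers(0, space.n, size=(3, n_sites))
            seqs = [
                (name, "".join(space.codons[s] for s in states[i]))
                for i, name in enumerate(order)
            ]
            aln = CodonAlignment.from_sequences(seqs)
            tree = PhyloTree.from_newick(template.format(
                a=lengths[0], b=lengths[1], c=lengths[2], d=lengths[3]
            ))
            pruned = log_likelihood(
                aln, tree, [SiteClass(1.0, omega, omega)], kappa, pi
            )
            brute = 0.0
            for site in range(n_sites):
                x, y, z = states[:, site]
                like = 0.0
                for root in range(space.n):
                    for inner in range(space.n):
                        like += (pi[root] * pin[root, inner] * pa[inner, x]
                                 * pb[inner, y] * pc[root, z])
                brute += np.log(like)
            worst = max(worst, abs(pruned - brute))
            n_checked += 1
    return worst, n_checked


@lru_cache(maxsize=None)
def _gene_tree_shapes(n_leaves: int, species: tuple[str, ...]):
    if n_leaves == 1:
        return tuple(species)
    shapes = set()
    for k in range(1, n_leaves // 2 + 1):
        for left in _gene_tree_shapes(k, species):
            for right in _gene_tree_shapes(n_leaves - k, species):
                shapes.add(tuple(sorted((left, right), key=repr)))
    return tuple(sorted(shapes, key=repr))


def _shape_to_newick(shape) -> str:
    counter = itertools.count(1)

    def render(node) -> str:
        if isinstance(node, str):
            return f"{node}|g{next(counter)}"
        return "(" + ",".join(render(c) for c in node) + ")"

    return render(shape) + ";"


def _oracle_reconcile(shape, parent_of):
    def path(name):
        out = [name]
        while parent_of[out[-1]] is not None:
            out.append(parent_of[out[-1]])
        return out

    def lca(a, b):
        pa = path(a)
        for node in pa:
            if node in path(b):
                return node

    counts: dict[str, int] = {}

    def walk(node):
        if isinstance(node, str):
            return node
        maps = [walk(c) for c in node]
        m = maps[0]
        for other in maps[1:]:
            m = lca(m, other)
        if any(cm == m for cm in maps):
            counts[m] = counts.get(m, 0) + 1
        return m

    walk(shape)
    return sum(counts.values()), counts


def reconciliation_agreement(max_leaves: int = 6) -> tuple[float, int]:
    """Fraction of exhaustively enumerated gene trees on which LCA
    reconciliation matches the naive oracle (1.0 = perfect)."""
    species_tree = PhyloTree.from_newick("((A:1,B:1):1,C:1);")
    parent_of = {"A": "A+B", "B": "A+B", "A+B": "A+B+C", "C": "A+B+C",
                 "A+B+C": None}
    n_trees = n_agree = 0
    for n in range(2, max_leaves + 1):
        for shape in _gene_tree_shapes(n, ("A", "B", "C")):
            gene = PhyloTree.from_newick(_shape_to_newick(shape))
            rec = lca_reconcile(gene, species_tree)
            n_dups, by_branch = _oracle_reconcile(shape, parent_of)
            n_trees += 1
            n_agree += (
                rec.n_duplications == n_dups
                and rec.duplications_by_branch == by_branch
            )
    return n_agree / n_trees, n_trees
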