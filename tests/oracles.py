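"""Independent oracle implementations used by the test suite.

Deliberately naive re-implementations (exhaustive enumeration, per-column
scans, path-intersection LCA) kept separate from the package code paths
they validate.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np

from balaena.codonmodel import EigenQ, rate_matrix


# ---------------------------------------------------------------------------
# brute-force pruning oracle: marginalize over all internal states


def brute_force_lnl_3taxon(matrix, lengths, kappa, omega, pi, space):
    """Sum over both internal states of a 3-leaf rooted tree ((X,Y),Z).

    ``matrix`` rows are leaf codon states in order X, Y, Z; ``lengths`` are
    (tX, tY, t_internal, tZ).
    """
    tx, ty, tin, tz = lengths
    q = rate_matrix(kappa, omega, pi, space)
    eig = EigenQ.decompose(q, pi)
    px, py, pin, pz = (eig.transition_matrix(t) for t in (tx, ty, tin, tz))
    total = 0.0
    n = space.n
    for site in range(matrix.shape[1]):
        x, y, z = matrix[:, site]
        like = 0.0
        for root in range(n):
            for inner in range(n):
                like += (
                    pi[root] * pin[root, inner] * px[inner, x] * py[inner, y]
                    * pz[root, z]
                )
        total += np.log(like)
    return total


# ---------------------------------------------------------------------------
# exhaustive gene-tree enumeration over a species alphabet


@lru_cache(maxsize=None)
def enumerate_gene_trees(n_leaves: int, species: tuple[str, ...]):
    """All distinct rooted binary tree shapes with leaves labelled from
    ``species``, as canonical nested tuples (leaves are strings)."""
    if n_leaves == 1:
        return tuple(species)
    shapes = set()
    for k in range(1, n_leaves // 2 + 1):
        for left in enumerate_gene_trees(k, species):
            for right in enumerate_gene_trees(n_leaves - k, species):
                shapes.add(tuple(sorted((left, right), key=repr)))
    return tuple(sorted(shapes, key=repr))


def tree_to_newick(shape, counter=None) -> str:
    """Nested-tuple shape to a Newick string with unique leaf labels
    ``species|g<N>``."""
    if counter is None:
        counter = itertools.count(1)

    def render(node) -> str:
        if isinstance(node, str):
            return f"{node}|g{next(counter)}"
        return "(" + ",".join(render(c) for c in node) + ")"

    return render(shape) + ";"


# ---------------------------------------------------------------------------
# path-intersection LCA reconciliation oracle


def oracle_reconcile(shape, species_parent: dict[str, str]):
    """Duplication count per species-tree node by explicit LCA mapping.

    ``species_parent`` maps each species-tree node name to its parent name
    (root maps to None).  Returns (n_duplications, {node_name: count}).
    """

    def path_to_root(name: str) -> list[str]:
        path = [name]
        while species_parent[path[-1]] is not None:
            path.append(species_parent[path[-1]])
        return path

    def lca(a: str, b: str) -> str:
        pa, pb = path_to_root(a), path_to_root(b)
        for node in pa:
            if node in pb:
                return node
        raise AssertionError("no common ancestor")

    counts: dict[str, int] = {}

    def walk(node) -> str:
        if isinstance(node, str):
            return node
        child_maps = [walk(c) for c in node]
        m = child_maps[0]
        for other in child_maps[1:]:
            m = lca(m, other)
        if any(cm == m for cm in child_maps):
            counts[m] = counts.get(m, 0) + 1
        return m

    walk(shape)
    return sum(counts.values()), counts
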