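"""Gene-family expansion detection by gene-tree/species-tree reconciliation.

Each gene-tree node is mapped to the last common ancestor (LCA) of its
leaves' species in the species tree; a node mapping to the same species-tree
node as one of its children marks a gene duplication, attributed to the
species-tree branch above the mapped node.  Candidate expansions then pass
an identity-band filter on duplicate protein pairs (removing both assembly
artifacts, which are nearly identical, and long-diverged copies) and an
expression check from read counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .trees import PhyloTree, TreeNode

DEFAULT_MIN_DIFF_PCT = 1.0
DEFAULT_MAX_DIFF_PCT = 10.0
DEFAULT_MIN_READS = 10


def default_species_of(gene_label: str) -> str:
    """Gene leaves are labelled ``species|gene``; bare labels map to themselves."""
    return gene_label.split("|", 1)[0]


@dataclass
class ReconciliationResult:
    gene_tree_id: str
    events: dict[int, str]  # internal-node preorder index -> speciation|duplication
    duplications_by_branch: dict[str, int]  # species-tree branch name -> count
    duplication_depths: list[int] = field(default_factory=list)  # gene-tree depths

    @property
    def n_duplications(self) -> int:
        return sum(1 for e in self.events.values() if e == "duplication")


def branch_name(node: TreeNode) -> str:
    """Stable name for a species-tree branch: the node's name, or the sorted
    leaf set it subtends for unnamed internal nodes."""
    if node.name:
        return node.name
    return "+".join(sorted(leaf.name for leaf in node.leaves()))


def lca_reconcile(
    gene_tree: PhyloTree,
    species_tree: PhyloTree,
    species_of: Callable[[str], str] = default_species_of,
    gene_tree_id: str = "",
) -> ReconciliationResult:
    """Standard LCA reconciliation of a rooted gene tree.

    Raises if any gene leaf maps to a species absent from the species tree.
    """
    species_nodes = {leaf.name: leaf for leaf in species_tree.root.leaves()}
    depth: dict[int, int] = {}
    for node in species_tree.preorder():
        depth[id(node)] = 0 if node.parent is None else depth[id(node.parent)] + 1

    def lca(a: TreeNode, b: TreeNode) -> TreeNode:
        while a is not b:
            if depth[id(a)] < depth[id(b)]:
                b = b.parent
            elif depth[id(a)] > depth[id(b)]:
                a = a.parent
            else:
                a, b = a.parent, b.parent
        return a

    mapping: dict[int, TreeNode] = {}
    events: dict[int, str] = {}
    dup_counts: dict[str, int] = {}
    dup_depths: list[int] = []
    internal_index = {
        id(n): i
        for i, n in enumerate(gene_tree.preorder())
        if not n.is_leaf
    }
    gene_depth: dict[int, int] = {}
    for node in gene_tree.preorder():
        gene_depth[id(node)] = (
            0 if node.parent is None else gene_depth[id(node.parent)] + 1
        )
    for node in gene_tree.postorder():
        if node.is_leaf:
            species = species_of(node.name)
            if species not in species_nodes:
                raise ValueError(
                    f"gene leaf {node.name!r} maps to unknown species {species!r}"
                )
            mapping[id(node)] = species_nodes[species]
            continue
        m = mapping[id(node.children[0])]
        for child in node.children[1:]:
            m = lca(m, mapping[id(child)])
        mapping[id(node)] = m
        is_dup = any(mapping[id(c)] is m for c in node.children)
        events[internal_index[id(node)]] = "duplication" if is_dup else "speciation"
        if is_dup:
            name = branch_name(m)
            dup_counts[name] = dup_counts.get(name, 0) + 1
            dup_depths.append(gene_depth[id(node)])
    return ReconciliationResult(
        gene_tree_id=gene_tree_id,
        events=events,
        duplications_by_branch=dup_counts,
        duplication_depths=sorted(dup_depths),
    )


def root_minimizing_duplications(
    gene_tree: PhyloTree,
    species_tree: PhyloTree,
    species_of: Callable[[str], str] = default_species_of,
) -> PhyloTree:
    """Root an unrooted (multifurcating-root) gene tree to minimize the
    duplication count; ties break toward fewer deep duplications."""
    if len(gene_tree.root.children) <= 2:
        return gene_tree
    candidates = []
    nodes = [n for n in gene_tree.postorder() if n.parent is not None]
    for i in range(len(nodes)):
        rerooted = _reroot_on_edge(gene_tree, i)
        rec = lca_reconcile(rerooted, species_tree, species_of)
        # tie-break: prefer rootings whose duplications sit closer to the root
        depth_penalty = sum(rec.duplication_depths)
        candidates.append((rec.n_duplications, depth_penalty, i, rerooted))
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    return candidates[0][3]


def _reroot_on_edge(tree: PhyloTree, edge_index: int) -> PhyloTree:
    work = tree.copy()
    nodes = [n for n in work.postorder() if n.parent is not None]
    target = nodes[edge_index]
    new_root = TreeNode()
    old_parent = target.parent
    old_parent.children.remove(target)
    half = (target.length or 0.0) / 2.0
    target.length = half
    new_root.add_child(target)
    # walk up from old_parent, reversing parent links
    prev = new_root
    carry = half
    node = old_parent
    while node is not None:
        parent = node.parent
        length = node.length
        node.parent = None
        node.length = carry
        if parent is not None:
            parent.children.remove(node)
        prev.add_child(node)
        prev = node
        carry = length
        node = parent
    _suppress_unary(new_root)
    return PhyloTree(new_root)


def _suppress_unary(node: TreeNode) -> None:
    for child in list(node.children):
        _suppress_unary(child)
    for child in list(node.children):
        if len(child.children) == 1:
            grand = child.children[0]
            grand.length = (grand.length or 0.0) + (child.length or 0.0)
            idx = node.children.index(child)
            node.children[idx] = grand
            grand.parent = node


def assign_expansions(
    reconciliations: Iterable[ReconciliationResult],
    species_tree: PhyloTree,
) -> pd.DataFrame:
    """Total duplication events per species-tree branch across families."""
    totals: dict[str, int] = {
        branch_name(n): 0 for n in species_tree.postorder()
    }
    for rec in reconciliations:
        for name, count in rec.duplications_by_branch.items():
            totals[name] = totals.get(name, 0) + count
    rows = [
        (branch_name(n), totals[branch_name(n)])
        for n in species_tree.postorder()
    ]
    return pd.DataFrame(rows, columns=["branch", "duplications"])


# ---------------------------------------------------------------------------
# identity-band filter


def _global_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def percent_protein_difference(protein_a: str, protein_b: str) -> float:
    """Percent mismatches over aligned non-gap positions of a global alignment."""
    if not protein_a or not protein_b:
        raise ValueError("empty protein sequence")
    alignment = _global_aligner().align(protein_a, protein_b)[0]
    a_row, b_row = alignment[0], alignment[1]
    aligned = mismatches = 0
    for x, y in zip(a_row, b_row):
        if x == "-" or y == "-":
            continue
        aligned += 1
        if x != y:
            mismatches += 1
    if aligned == 0:
        raise ValueError("no aligned positions between proteins")
    return 100.0 * mismatches / aligned


def identity_band_filter(
    protein_a: str,
    protein_b: str,
    min_diff: float = DEFAULT_MIN_DIFF_PCT,
    max_diff: float = DEFAULT_MAX_DIFF_PCT,
) -> tuple[bool, float]:
    """Keep a duplicate pair iff its percent protein difference d satisfies
    min_diff <= d <= max_diff (both boundaries inclusive).

    The lower bound removes assembly artifacts and dead-recent copies; the
    upper bound removes anciently diverged copies.
    """
    d = percent_protein_difference(protein_a, protein_b)
    return min_diff <= d <= max_diff, d


# ---------------------------------------------------------------------------
# expression check


def expression_flag(
    gene_ids: Sequence[str],
    read_counts: pd.DataFrame,
    min_reads: int = DEFAULT_MIN_READS,
) -> pd.DataFrame:
    """Expressed iff total reads across tissues >= ``min_reads``.

    ``read_counts`` columns: gene_id, tissue, count.  Genes absent from the
    table are flagged missing and not expressed.
    """
    if (read_counts["count"] < 0).any():
        raise ValueError("negative read counts")
    totals = read_counts.groupby("gene_id")["count"].sum()
    rows = []
    for gene in gene_ids:
        if gene in totals.index:
            total = int(totals[gene])
            rows.append((gene, total, total >= min_reads, False))
        else:
            rows.append((gene, 0, False, True))
    return pd.DataFrame(
        rows, columns=["gene_id", "total_reads", "expressed", "missing"]
    )


@dataclass
class ExpansionReport:
    family_id: str
    lineage: str
    duplicate_pairs: list[dict] = field(default_factory=list)

    @property
    def passes_identity_band(self) -> bool:
        return any(p["band_keep"] for p in self.duplicate_pairs)


def screen_family_expansion(
    family_id: str,
    gene_tree: PhyloTree,
    species_tree: PhyloTree,
    proteins: Mapping[str, str],
    read_counts: pd.DataFrame | None,
    focal_species: str,
    species_of: Callable[[str], str] = default_species_of,
    min_diff: float = DEFAULT_MIN_DIFF_PCT,
    max_diff: float = DEFAULT_MAX_DIFF_PCT,
    min_reads: int = DEFAULT_MIN_READS,
) -> tuple[ReconciliationResult, ExpansionReport | None]:
    """Reconcile one family and, if the focal terminal branch carries a
    duplication, apply the identity-band and expression filters to the
    focal duplicate pairs."""
    rec = lca_reconcile(gene_tree, species_tree, species_of, gene_tree_id=family_id)
    if rec.duplications_by_branch.get(focal_species, 0) == 0:
        return rec, None
    focal_genes = sorted(
        leaf.name
        for leaf in gene_tree.root.leaves()
        if species_of(leaf.name) == focal_species
    )
    report = ExpansionReport(family_id=family_id, lineage=focal_species)
    expr = (
        expression_flag(focal_genes, read_counts, min_reads)
        if read_counts is not None
        else None
    )
    for i, a in enumerate(focal_genes):
        for b in focal_genes[i + 1 :]:
            keep, d = identity_band_filter(proteins[a], proteins[b], min_diff, max_diff)
            pair = {"gene_a": a, "gene_b": b, "percent_diff": d, "band_keep": keep}
            if expr is not None:
                flags = expr.set_index("gene_id")["expressed"]
                pair["expressed_a"] = bool(flags[a])
                pair["expressed_b"] = bool(flags[b])
            report.duplicate_pairs.append(pair)
    return rec, report
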