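"""Reciprocal-best-hit orthology clustering and single-gene ortholog extraction.

Gene families are the connected components of the cross-species reciprocal
best hit (RBH) graph.  A family qualifies as a single-gene ortholog (SGO)
family when it has at most one member per species (one-to-one, with
one-to-zero allowed for missing species), spans more than the minimum
number of species, and no member CDS contains an internal stop codon.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping

import networkx as nx
import pandas as pd

from .genetics import CdsRecord, GeneticCode, STANDARD_CODE, translate_cds

DEFAULT_CLUSTER_EVALUE = 1e-7  # family building
DEFAULT_ANNOTATION_EVALUE = 1e-5  # best-hit annotation against a reference


@dataclass
class GeneFamily:
    family_id: str
    members: set[tuple[str, str]]  # (species, gene_id)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("gene family with no members")

    @property
    def copy_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for species, _ in self.members:
            counts[species] = counts.get(species, 0) + 1
        return counts

    @property
    def species_count(self) -> int:
        return len(self.copy_counts)

    @property
    def is_single_copy(self) -> bool:
        return all(c == 1 for c in self.copy_counts.values())


@dataclass
class SGO:
    family_id: str
    gene_by_species: dict[str, str]

    @property
    def species_count(self) -> int:
        return len(self.gene_by_species)


@dataclass
class Rejection:
    family_id: str
    reason: str
    detail: str = ""


def best_hits(
    hits: pd.DataFrame, evalue_cutoff: float = DEFAULT_CLUSTER_EVALUE
) -> dict[str, str]:
    """Best subject per query among hits passing the e-value cutoff.

    Ties on bit score break to the lower e-value, then the lexicographically
    smaller subject id, so the result does not depend on input row order.
    """
    if evalue_cutoff <= 0:
        raise ValueError("e-value cutoff must be positive")
    if hits.empty:
        raise ValueError("empty hit table")
    passing = hits[hits["e_value"] <= evalue_cutoff]
    ranked = passing.sort_values(
        ["query_id", "bit_score", "e_value", "subject_id"],
        ascending=[True, False, True, True],
        kind="mergesort",
    )
    best = ranked.drop_duplicates("query_id", keep="first")
    return dict(zip(best["query_id"], best["subject_id"]))


def reciprocal_best_hits(
    bh_ab: Mapping[str, str], bh_ba: Mapping[str, str]
) -> list[tuple[str, str]]:
    """Pairs (a, b) with a's best hit b and b's best hit a."""
    return sorted(
        (a, b) for a, b in bh_ab.items() if bh_ba.get(b) == a
    )


def cluster_families(
    rbh_pairs: Iterable[tuple[str, str]],
    all_genes: Iterable[str],
    species_of: Callable[[str], str],
) -> list[GeneFamily]:
    """Families = connected components of the RBH graph (single linkage).

    Every gene in ``all_genes`` lands in exactly one family; genes without
    any RBH partner become singleton families.  Family ids are assigned in
    order of each component's lexicographically smallest member, making the
    output independent of input ordering.
    """
    graph = nx.Graph()
    graph.add_nodes_from(all_genes)
    graph.add_edges_from(rbh_pairs)
    components = sorted(nx.connected_components(graph), key=lambda c: min(c))
    return [
        GeneFamily(
            family_id=f"fam{idx:05d}",
            members={(species_of(g), g) for g in comp},
        )
        for idx, comp in enumerate(components, start=1)
    ]


def extract_sgos(
    families: Iterable[GeneFamily],
    cds_by_gene: Mapping[str, CdsRecord],
    code: GeneticCode = STANDARD_CODE,
    min_species_exclusive: int = 7,
) -> tuple[list[SGO], list[Rejection]]:
    """Keep single-copy families spanning strictly more than ``min_species_exclusive``
    species whose members all translate without internal stop codons.

    Every rejected family is logged with a reason code: ``multi_copy``,
    ``too_few_species``, ``missing_cds``, or ``internal_stop``.
    """
    sgos: list[SGO] = []
    rejections: list[Rejection] = []
    for family in sorted(families, key=lambda f: f.family_id):
        if not family.is_single_copy:
            multi = [s for s, c in family.copy_counts.items() if c > 1]
            rejections.append(
                Rejection(family.family_id, "multi_copy", ",".join(sorted(multi)))
            )
            continue
        if family.species_count <= min_species_exclusive:
            rejections.append(
                Rejection(
                    family.family_id,
                    "too_few_species",
                    f"{family.species_count} species",
                )
            )
            continue
        missing = sorted(g for _, g in family.members if g not in cds_by_gene)
        if missing:
            rejections.append(
                Rejection(family.family_id, "missing_cds", ",".join(missing))
            )
            continue
        stops = sorted(
            g
            for _, g in family.members
            if translate_cds(cds_by_gene[g], code).has_internal_stop
        )
        if stops:
            rejections.append(
                Rejection(family.family_id, "internal_stop", ",".join(stops))
            )
            continue
        sgos.append(
            SGO(
                family_id=family.family_id,
                gene_by_species={s: g for s, g in family.members},
            )
        )
    return sgos, rejections


def families_report(families: Iterable[GeneFamily]) -> pd.DataFrame:
    rows = [
        (f.family_id, species, gene)
        for f in families
        for species, gene in sorted(f.members)
    ]
    return pd.DataFrame(rows, columns=["family_id", "species", "gene_id"])


def rejections_report(rejections: Iterable[Rejection]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.family_id, r.reason, r.detail) for r in rejections],
        columns=["family_id", "reason", "detail"],
    )
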