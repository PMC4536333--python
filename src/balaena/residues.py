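"""Lineage-unique residue identification and density ranking.

Given a protein alignment of a focal species against other mammals, a
column carries a focal-unique residue when no taxon is gapped there, at
most one non-focal residue is unknown (X), and the focal residue does not
occur among the known non-focal residues.  Proteins are ranked by the count
of unique residues normalized by focal protein length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

GAP = "-"
UNKNOWN = "X"


@dataclass
class UniquePosition:
    focal_position: int  # 1-based in the ungapped focal sequence
    alignment_column: int  # 1-based
    focal_residue: str
    other_residues: str
    reference_position: int | None = None  # in a named reference taxon


@dataclass
class ResidueReport:
    protein_id: str
    unique_positions: list[UniquePosition]
    focal_length: int
    rank: int | None = None
    top5: bool = False

    @property
    def u(self) -> int:
        return len(self.unique_positions)

    @property
    def density(self) -> float:
        if self.focal_length <= 0:
            raise ValueError(f"{self.protein_id}: focal length must be positive")
        return self.u / self.focal_length


def unique_residue_columns(
    msa: Sequence[tuple[str, str]],
    focal: str,
    max_unknown_others: int = 1,
    require_others_identical: bool = False,
    skip_gapped_taxa: bool = False,
    reference_taxon: str | None = None,
    protein_id: str = "",
) -> ResidueReport:
    """Scan an aligned protein family for focal-unique columns.

    ``require_others_identical`` switches to a strict mode in which all
    known non-focal residues must additionally agree with each other.
    ``skip_gapped_taxa`` relaxes the gap rule to ignore gapped taxa instead
    of discarding the column.
    """
    seqs = dict(msa)
    if focal not in seqs:
        raise ValueError(f"focal taxon {focal!r} absent from alignment")
    others = [(n, s) for n, s in msa if n != focal]
    if len(others) < 2:
        raise ValueError("need at least two non-focal taxa")
    lengths = {len(s) for _, s in msa}
    if len(lengths) != 1:
        raise ValueError("alignment rows differ in length")
    focal_seq = seqs[focal]
    ref_seq = None
    if reference_taxon is not None:
        if reference_taxon not in seqs:
            raise ValueError(f"reference taxon {reference_taxon!r} absent")
        ref_seq = seqs[reference_taxon]

    positions: list[UniquePosition] = []
    focal_pos = 0
    ref_pos = 0
    for col, focal_res in enumerate(focal_seq):
        if focal_res != GAP:
            focal_pos += 1
        if ref_seq is not None and ref_seq[col] != GAP:
            ref_pos += 1
        other_res = [s[col] for _, s in others]
        if focal_res in (GAP, UNKNOWN):
            continue
        if not skip_gapped_taxa and GAP in other_res:
            continue
        if skip_gapped_taxa:
            other_res = [r for r in other_res if r != GAP]
            if len(other_res) < 2:
                continue
        known = [r for r in other_res if r != UNKNOWN]
        if len(other_res) - len(known) > max_unknown_others:
            continue
        if not known or focal_res in known:
            continue
        if require_others_identical and len(set(known)) != 1:
            continue
        positions.append(
            UniquePosition(
                focal_position=focal_pos,
                alignment_column=col + 1,
                focal_residue=focal_res,
                other_residues="".join(other_res),
                reference_position=(
                    ref_pos if ref_seq is not None and ref_seq[col] != GAP else None
                ),
            )
        )
    focal_length = sum(1 for c in focal_seq if c != GAP)
    return ResidueReport(
        protein_id=protein_id or focal,
        unique_positions=positions,
        focal_length=focal_length,
    )


def residue_density_rank(
    reports: Sequence[ResidueReport], top_fraction: float = 0.05
) -> list[ResidueReport]:
    """Rank proteins by unique-residue density (descending).

    Ties break by raw count (descending) then protein id; the top
    ceil(top_fraction * N) are flagged.  Proteins with zero density are
    never flagged while any positive density exists.
    """
    if not reports:
        raise ValueError("no reports to rank")
    ordered = sorted(reports, key=lambda r: (-r.density, -r.u, r.protein_id))
    n_top = math.ceil(top_fraction * len(ordered))
    any_positive = any(r.density > 0 for r in ordered)
    for i, report in enumerate(ordered):
        report.rank = i + 1
        report.top5 = i < n_top and (report.density > 0 or not any_positive)
    return ordered


def residue_report_table(reports: Sequence[ResidueReport]) -> pd.DataFrame:
    rows = [
        (
            r.protein_id,
            r.u,
            r.focal_length,
            r.density,
            r.rank,
            r.top5,
            ";".join(
                f"{p.focal_position}{p.focal_residue}" for p in r.unique_positions
            ),
        )
        for r in reports
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "protein_id", "unique_residues", "length", "density", "rank",
            "top5", "positions",
        ],
    )
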