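"""Alignment quality filters gating the selection analyses.

Two filters act on multiple sequence alignments: one rejects alignments
containing long insertions unique to a focal taxon (assembly or annotation
artifacts show up this way), the other rejects alignments in which a focal
sequence covers less than half of the alignment.  A third filter acts on
pairwise comparisons, dropping pairs whose lengths differ more than twofold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

DEFAULT_MAX_INSERT_BP = 12
DEFAULT_MIN_FOCAL_FRACTION = 0.5
DEFAULT_MIN_PAIRWISE_FRACTION = 0.5

GAP = "-"


@dataclass
class FilterDetail:
    name: str
    passed: bool
    detail: str = ""


@dataclass
class QcVerdict:
    alignment_id: str
    filters: list[FilterDetail] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return all(f.passed for f in self.filters)

    @property
    def failed_filters(self) -> list[str]:
        return [f.name for f in self.filters if not f.passed]


def _check_msa(msa: Sequence[tuple[str, str]], focal_taxa: set[str]) -> None:
    if not msa:
        raise ValueError("empty alignment")
    lengths = {len(s) for _, s in msa}
    if len(lengths) != 1:
        raise ValueError("alignment rows differ in length")
    names = {n for n, _ in msa}
    missing = focal_taxa - names
    if missing:
        raise ValueError(f"focal taxa absent from alignment: {sorted(missing)}")


def unique_insertion_filter(
    msa: Sequence[tuple[str, str]],
    focal_taxa: set[str],
    max_insert_bp: int = DEFAULT_MAX_INSERT_BP,
    alignment_id: str = "",
) -> QcVerdict:
    """Fail if any focal taxon carries a unique insertion longer than
    ``max_insert_bp`` nucleotides.

    A unique insertion is a maximal run of columns in which exactly one
    focal taxon has residues while every other taxon is gapped.  An
    insertion shared between two focal taxa (or with any background taxon)
    is not unique and does not fail the filter.  Runs of exactly
    ``max_insert_bp`` pass.
    """
    _check_msa(msa, focal_taxa)
    length = len(msa[0][1])
    worst: tuple[int, str] | None = None
    for focal in sorted(focal_taxa):
        focal_seq = dict(msa)[focal]
        others = [s for n, s in msa if n != focal]
        run = 0
        for col in range(length + 1):
            unique_here = (
                col < length
                and focal_seq[col] != GAP
                and all(o[col] == GAP for o in others)
            )
            if unique_here:
                run += 1
            else:
                if run > max_insert_bp and (worst is None or run > worst[0]):
                    worst = (run, focal)
                run = 0
    passed = worst is None
    detail = "" if passed else f"{worst[0]} bp insertion unique to {worst[1]}"
    return QcVerdict(
        alignment_id=alignment_id,
        filters=[FilterDetail("unique_insertion", passed, detail)],
    )


def focal_length_filter(
    msa: Sequence[tuple[str, str]],
    focal_taxa: set[str],
    min_fraction: float = DEFAULT_MIN_FOCAL_FRACTION,
    alignment_id: str = "",
) -> QcVerdict:
    """Fail if any focal taxon's ungapped length is below ``min_fraction``
    of the alignment length (boundary passes)."""
    _check_msa(msa, focal_taxa)
    length = len(msa[0][1])
    if length == 0:
        raise ValueError("zero-length alignment")
    seqs = dict(msa)
    failing = []
    for focal in sorted(focal_taxa):
        ungapped = sum(1 for c in seqs[focal] if c != GAP)
        if ungapped < min_fraction * length:
            failing.append(f"{focal}:{ungapped}/{length}")
    passed = not failing
    return QcVerdict(
        alignment_id=alignment_id,
        filters=[FilterDetail("focal_length", passed, ";".join(failing))],
    )


def msa_verdict(
    msa: Sequence[tuple[str, str]],
    focal_taxa: set[str],
    max_insert_bp: int = DEFAULT_MAX_INSERT_BP,
    min_focal_fraction: float = DEFAULT_MIN_FOCAL_FRACTION,
    alignment_id: str = "",
) -> QcVerdict:
    """Both MSA filters, evaluated independently and reported together."""
    v1 = unique_insertion_filter(msa, focal_taxa, max_insert_bp, alignment_id)
    v2 = focal_length_filter(msa, focal_taxa, min_focal_fraction, alignment_id)
    return QcVerdict(alignment_id=alignment_id, filters=v1.filters + v2.filters)


def pairwise_length_filter(
    cds_a: str,
    cds_b: str,
    min_fraction: float = DEFAULT_MIN_PAIRWISE_FRACTION,
) -> tuple[bool, float]:
    """Keep a pair unless the shorter sequence is under ``min_fraction`` of
    the longer one (boundary kept).  Returns (keep, length ratio)."""
    if not cds_a or not cds_b:
        raise ValueError("zero-length sequence")
    ratio = min(len(cds_a), len(cds_b)) / max(len(cds_a), len(cds_b))
    return ratio >= min_fraction, ratio
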