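"""Nei-Gojobori (1986) pairwise dN/dS by site counting.

Counts synonymous and nonsynonymous sites per codon (fraction of the three
possible changes at each position that are synonymous), averages observed
synonymous/nonsynonymous differences over all equal-weight mutational
pathways for multi-difference codons (pathways through stop codons are
excluded when any stop-free pathway exists), and applies the Jukes-Cantor
multiple-hit correction to both proportions.

This counting estimator is deliberately independent of the maximum-likelihood
machinery in :mod:`balaena.selection`; the two serve as cross-checks.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

from .genetics import GeneticCode, STANDARD_CODE

_NUCS = "ACGT"


@dataclass
class PairwiseDnDs:
    """dN/dS estimate for one orthologous sequence pair."""

    gene_id: str
    species_a: str
    species_b: str
    dn: float | None
    ds: float | None
    omega: float | None
    method: str = "NG86"
    flags: list[str] = field(default_factory=list)

    @property
    def defined(self) -> bool:
        return self.omega is not None


def synonymous_site_fraction(codon: str, code: GeneticCode) -> float:
    """Synonymous sites in one codon (0..3).

    Changes producing stop codons count as nonsynonymous.
    """
    if code.is_stop(codon):
        raise ValueError(f"stop codon {codon!r} has no site counts")
    aa = code.aa(codon)
    syn = 0.0
    for pos in range(3):
        for nuc in _NUCS:
            if nuc == codon[pos]:
                continue
            alt = codon[:pos] + nuc + codon[pos + 1 :]
            if not code.is_stop(alt) and code.aa(alt) == aa:
                syn += 1.0 / 3.0
    return syn


def pathway_differences(
    codon_a: str, codon_b: str, code: GeneticCode
) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences averaged over pathways."""
    diffs = [k for k in range(3) if codon_a[k] != codon_b[k]]
    if not diffs:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diffs):
        current = codon_a
        sd = nd = 0.0
        through_stop = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if code.is_stop(nxt):
                through_stop = True
            if code.aa(current) == code.aa(nxt):
                sd += 1
            else:
                nd += 1
            current = nxt
        paths.append((through_stop, sd, nd))
    valid = [(sd, nd) for stop, sd, nd in paths if not stop]
    if not valid:  # all pathways cross a stop; fall back to all of them
        valid = [(sd, nd) for _, sd, nd in paths]
    sd = sum(v[0] for v in valid) / len(valid)
    nd = sum(v[1] for v in valid) / len(valid)
    return sd, nd


def jukes_cantor(p: float) -> float:
    """JC69 distance from a proportion of differences; undefined for p >= 3/4."""
    if p < 0:
        raise ValueError("negative proportion")
    if p == 0:
        return 0.0
    if p >= 0.75:
        raise ValueError("proportion >= 3/4: Jukes-Cantor correction undefined")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng86_pairwise(
    cds_a: str,
    cds_b: str,
    code: GeneticCode = STANDARD_CODE,
    gene_id: str = "",
    species_a: str = "a",
    species_b: str = "b",
) -> PairwiseDnDs:
    """NG86 dN/dS between two equal-length, gap-free, in-frame CDS."""
    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    if len(cds_a) != len(cds_b):
        raise ValueError("sequences differ in length")
    if len(cds_a) % 3 or not cds_a:
        raise ValueError("sequence length not a positive multiple of 3")
    if "-" in cds_a or "-" in cds_b:
        raise ValueError("gap characters not allowed; strip gap columns first")

    s_sites = n_sites = 0.0
    sd = nd = 0.0
    n_codons = 0
    for i in range(0, len(cds_a), 3):
        ca, cb = cds_a[i : i + 3], cds_b[i : i + 3]
        if set(ca + cb) - set(_NUCS):
            continue  # skip codons with ambiguous bases
        if code.is_stop(ca) or code.is_stop(cb):
            continue
        s_sites += (synonymous_site_fraction(ca, code) + synonymous_site_fraction(cb, code)) / 2.0
        d = pathway_differences(ca, cb, code)
        sd += d[0]
        nd += d[1]
        n_codons += 1
    if n_codons == 0:
        raise ValueError("no comparable codons")
    n_sites = 3.0 * n_codons - s_sites

    flags: list[str] = []
    try:
        ds = jukes_cantor(sd / s_sites) if s_sites > 0 else None
    except ValueError:
        ds, flags = None, flags + ["dS_saturated"]
    try:
        dn = jukes_cantor(nd / n_sites) if n_sites > 0 else None
    except ValueError:
        dn, flags = None, flags + ["dN_saturated"]
    omega = None
    if dn is not None and ds is not None:
        if ds > 0:
            omega = dn / ds
        else:
            flags.append("dS_zero")
    return PairwiseDnDs(
        gene_id=gene_id,
        species_a=species_a,
        species_b=species_b,
        dn=dn,
        ds=ds,
        omega=omega,
        flags=flags,
    )
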