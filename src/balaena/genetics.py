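"""Genetic-code logic and coding-sequence records.

Everything downstream (orthology screening, codon models, simulation)
translates CDS through a :class:`GeneticCode`.  The default is the standard
nuclear code (NCBI translation table 1), appropriate for mammalian nuclear
genes; other tables can be loaded by id.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping

from Bio.Data import CodonTable

STOP = "*"
NUCLEOTIDES = "TCAG"
CDS_ALPHABET = frozenset("ACGTN")

ALL_CODONS = tuple(
    "".join(c) for c in itertools.product("ACGT", repeat=3)
)


@dataclass(frozen=True)
class GeneticCode:
    """A codon -> amino-acid map over all 64 triplets; stops map to ``*``."""

    table_id: int
    codon_to_aa: Mapping[str, str]

    def __post_init__(self) -> None:
        if len(self.codon_to_aa) != 64:
            raise ValueError(
                f"genetic code must cover all 64 codons, got {len(self.codon_to_aa)}"
            )

    @classmethod
    def from_table(cls, table_id: int = 1) -> "GeneticCode":
        table = CodonTable.unambiguous_dna_by_id[table_id]
        mapping = {codon: aa for codon, aa in table.forward_table.items()}
        for codon in table.stop_codons:
            mapping[codon] = STOP
        return cls(table_id=table_id, codon_to_aa=dict(mapping))

    @property
    def sense_codons(self) -> tuple[str, ...]:
        """Non-stop codons in lexicographic order (61 for the standard code)."""
        return tuple(
            sorted(c for c, aa in self.codon_to_aa.items() if aa != STOP)
        )

    @property
    def stop_codons(self) -> tuple[str, ...]:
        return tuple(
            sorted(c for c, aa in self.codon_to_aa.items() if aa == STOP)
        )

    def is_stop(self, codon: str) -> bool:
        return self.codon_to_aa.get(codon) == STOP

    def aa(self, codon: str) -> str:
        """Amino acid for a codon; ``X`` for codons with ambiguous bases."""
        try:
            return self.codon_to_aa[codon]
        except KeyError:
            return "X"


STANDARD_CODE = GeneticCode.from_table(1)


@dataclass
class CdsRecord:
    """An in-frame coding sequence for one gene in one species."""

    gene_id: str
    species: str
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if len(self.sequence) < 3:
            raise ValueError(f"{self.gene_id}: CDS shorter than one codon")
        bad = set(self.sequence) - CDS_ALPHABET
        if bad:
            raise ValueError(
                f"{self.gene_id}: illegal characters in CDS: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def codons(self) -> list[str]:
        if len(self.sequence) % 3:
            raise ValueError(
                f"{self.gene_id}: CDS length {len(self.sequence)} not divisible by 3"
            )
        return [self.sequence[i : i + 3] for i in range(0, len(self.sequence), 3)]


@dataclass
class Translation:
    protein: str
    has_internal_stop: bool
    internal_stop_positions: list[int] = field(default_factory=list)


def strip_terminal_stop(sequence: str, code: GeneticCode = STANDARD_CODE) -> str:
    """Drop a trailing stop codon if present (analysis works on sense codons)."""
    if len(sequence) % 3 == 0 and len(sequence) >= 3 and code.is_stop(sequence[-3:]):
        return sequence[:-3]
    return sequence


def translate_cds(cds: CdsRecord, code: GeneticCode = STANDARD_CODE) -> Translation:
    """Translate an in-frame CDS, flagging internal (non-terminal) stops.

    A terminal stop codon is excluded from the protein.  Codons containing
    ambiguous bases translate to ``X``.  Internal stops are translated as
    ``*`` and reported via the flag rather than raising: the caller decides
    whether an internal stop disqualifies the gene.
    """
    codons = cds.codons()
    if code.is_stop(codons[-1]):
        codons = codons[:-1]
    protein = []
    stops: list[int] = []
    for i, codon in enumerate(codons):
        aa = code.aa(codon)
        if aa == STOP:
            stops.append(i + 1)  # 1-based codon position
        protein.append(aa)
    return Translation(
        protein="".join(protein),
        has_internal_stop=bool(stops),
        internal_stop_positions=stops,
    )
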