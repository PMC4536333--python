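"""FASTA and tabular similarity-hit I/O.

FASTA goes through Biopython; hit tables are the 12-column tabular dialect
(query, subject, percent identity, alignment length, mismatches, gap opens,
query/subject coordinates, e-value, bit score) read into a pandas frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

HIT_COLUMNS = [
    "query_id",
    "subject_id",
    "percent_identity",
    "alignment_length",
    "mismatches",
    "gap_opens",
    "query_start",
    "query_end",
    "subject_start",
    "subject_end",
    "e_value",
    "bit_score",
]


@dataclass
class FastaRecord:
    id: str
    sequence: str
    description: str = ""


def read_fasta(path: str | Path) -> list[FastaRecord]:
    """Read a FASTA file; duplicate ids and empty files are errors."""
    records = [
        FastaRecord(
            id=rec.id,
            sequence=str(rec.seq).upper(),
            description=rec.description[len(rec.id) :].strip(),
        )
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate FASTA ids in {path}: {dupes}")
    return records


def write_fasta(records: Iterable[FastaRecord], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_hit_table(path: str | Path) -> pd.DataFrame:
    """Read a 12-column tabular hit file into a validated DataFrame."""
    df = pd.read_csv(path, sep="\t", header=None, names=HIT_COLUMNS, comment="#")
    return validate_hit_table(df)


def validate_hit_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in HIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"hit table missing columns: {missing}")
    if df["query_id"].isna().any() or df["subject_id"].isna().any():
        raise ValueError("hit table has empty query or subject ids")
    if (df["e_value"] < 0).any():
        raise ValueError("negative e-values in hit table")
    import numpy as np

    if not np.isfinite(df["bit_score"]).all():
        raise ValueError("non-finite bit scores in hit table")
    return df


def write_hit_table(df: pd.DataFrame, path: str | Path) -> None:
    df[HIT_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def records_by_id(records: Sequence[FastaRecord]) -> dict[str, FastaRecord]:
    return {r.id: r for r in records}
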