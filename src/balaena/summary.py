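"""Genome summary statistics: repeat-class diversity and sequencing coverage.

Shannon's index summarizes how evenly a genome's transposable-element
content is spread over repeat classes; coverage arithmetic converts
per-library sequence totals into fold-coverage of a genome size.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import pandas as pd
from scipy.stats import entropy


def shannon_index(counts: Mapping[str, float], base: float | None = None) -> float:
    """Shannon diversity H = -sum p_i log p_i over classes with p_i > 0.

    Natural log by default; pass ``base`` to change units.  Zero-count
    classes contribute nothing; an all-zero table is an error.
    """
    values = [c for c in counts.values() if c > 0]
    if any(c < 0 for c in counts.values()):
        raise ValueError("negative class counts")
    if not values:
        raise ValueError("Shannon index undefined for all-zero counts")
    return float(entropy(values, base=base))


def max_shannon_index(n_classes: int, base: float | None = None) -> float:
    """H at perfectly even counts: log(K)."""
    if n_classes < 1:
        raise ValueError("need at least one class")
    h = math.log(n_classes)
    return h / math.log(base) if base else h


def coverage_table(
    libraries: Sequence[tuple[str, float]], genome_size_gb: float
) -> pd.DataFrame:
    """Per-library and total fold-coverage for a genome size in Gb.

    Coverage values are rounded to one decimal, matching how sequencing
    reports print them; the total row sums the library totals.
    """
    if genome_size_gb <= 0:
        raise ValueError("genome size must be positive")
    rows = []
    for name, total_gb in libraries:
        if total_gb < 0:
            raise ValueError(f"negative data total for library {name!r}")
        rows.append((name, total_gb, round(total_gb / genome_size_gb, 1)))
    grand = sum(t for _, t in libraries)
    rows.append(("Total", round(grand, 1), round(grand / genome_size_gb, 1)))
    return pd.DataFrame(rows, columns=["library", "total_gb", "coverage_x"])


def read_te_counts(path) -> dict[str, float]:
    """TSV with columns class, count (or class, bp)."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("TE table needs a class column and a count column")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
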