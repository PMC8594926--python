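"""Sequence-based counting: unique-sequence count tables, filters, cpm.

Counting is over unique read *sequences*, not genomic features — the read's
sequence is the row key, so annotation mismatches never alter the count
matrix. Tables are pandas DataFrames (rows = sequences, columns = samples)
with a per-sample library total carried alongside; the total is fixed at
counting time and is never recomputed after filtering, so abundance
thresholds expressed in cpm keep their meaning.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .records import ReadRecord

#: canonical per-sample metadata columns
SAMPLE_COLUMNS = ("sample_id", "sublibrary", "method")


@dataclass
class SequenceCountTable:
    """Unique sequence x sample matrix of raw counts.

    counts
        DataFrame indexed by sequence string, one integer column per sample.
    samples
        DataFrame of per-sample metadata (index = sample_id; columns at least
        ``sublibrary`` and ``method``).
    library_totals
        Per-sample retained-read totals used as the cpm denominator; fixed at
        counting time.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    library_totals: pd.Series

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate sequence rows")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample columns")
        missing = set(self.counts.columns) - set(self.library_totals.index)
        if missing:
            raise ValueError(f"library_totals missing samples: {sorted(missing)}")

    @property
    def sequences(self) -> pd.Index:
        return self.counts.index

    @property
    def n_flagged(self) -> pd.Series:
        """Boolean per-sequence flag: sequence contains an N base."""
        return pd.Series(
            [("N" in s) for s in self.counts.index], index=self.counts.index, dtype=bool
        )


@dataclass
class CpmTable:
    """Counts-per-million table; same shape as its source count table."""

    values: pd.DataFrame
    samples: pd.DataFrame
    library_totals: pd.Series


def count_unique(
    sample_reads: Mapping[str, Iterable[ReadRecord | str]],
    sample_meta: pd.DataFrame | None = None,
) -> SequenceCountTable:
    """Count unique (case-normalised) sequences per sample.

    ``sample_reads`` maps sample_id to an iterable of reads or raw sequence
    strings. The library total of each sample is its number of retained
    reads. An empty sample yields a zero column with total 0 (cpm
    normalisation will then refuse it).
    """
    counters: dict[str, Counter] = {}
    totals: dict[str, int] = {}
    for sample_id, reads in sample_reads.items():
        c: Counter = Counter()
        n = 0
        for r in reads:
            seq = (r.sequence if isinstance(r, ReadRecord) else r).upper()
            c[seq] += 1
            n += 1
        counters[sample_id] = c
        totals[sample_id] = n
    counts = pd.DataFrame(counters).fillna(0).astype(np.int64)
    counts = counts.reindex(columns=list(sample_reads))
    counts.index.name = "sequence"
    if sample_meta is None:
        sample_meta = pd.DataFrame(
            {"sublibrary": "", "method": ""}, index=pd.Index(list(sample_reads), name="sample_id")
        )
    return SequenceCountTable(
        counts=counts.sort_index(),
        samples=sample_meta,
        library_totals=pd.Series(totals, name="library_total"),
    )


def _check_scope(columns: pd.Index, scope: Sequence[str] | None) -> list[str]:
    if scope is None:
        scope = list(columns)
    scope = list(scope)
    if not scope:
        raise ValueError("scope must be a non-empty set of sample columns")
    unknown = set(scope) - set(columns)
    if unknown:
        raise ValueError(f"scope names unknown samples: {sorted(unknown)}")
    return scope


def filter_min_count(
    table: SequenceCountTable, min_count: int = 5, scope: Sequence[str] | None = None
) -> SequenceCountTable:
    """Keep sequences with at least ``min_count`` in *every* scoped sample.

    The scope is typically all samples of one library method, matching the
    "at least 5 counts in 100% of samples within a method" noise filter.
    Library totals are untouched.
    """
    scope = _check_scope(table.counts.columns, scope)
    keep = (table.counts[scope] >= min_count).all(axis=1)
    return SequenceCountTable(table.counts.loc[keep], table.samples, table.library_totals)


def normalize_cpm(table: SequenceCountTable) -> CpmTable:
    """counts / library_total x 1e6 per sample column."""
    totals = table.library_totals.reindex(table.counts.columns)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"zero library total for sample(s): {list(zero.index)}")
    values = table.counts / totals * 1e6
    return CpmTable(values=values, samples=table.samples, library_totals=table.library_totals)


def filter_min_cpm(
    cpm: CpmTable, min_cpm: float = 10.0, scope: Sequence[str] | None = None
) -> CpmTable:
    """Keep sequences with at least ``min_cpm`` in every scoped sample."""
    scope = _check_scope(cpm.values.columns, scope)
    keep = (cpm.values[scope] >= min_cpm).all(axis=1)
    return CpmTable(cpm.values.loc[keep], cpm.samples, cpm.library_totals)


def write_count_table(table: SequenceCountTable, counts_path, totals_path) -> None:
    """TSV pair: the counts matrix and a sidecar of totals + metadata."""
    table.counts.to_csv(counts_path, sep="\t")
    side = table.samples.copy()
    side.insert(0, "library_total", table.library_totals.reindex(side.index))
    side.to_csv(totals_path, sep="\t", index_label="sample_id")


def read_count_table(counts_path, totals_path) -> SequenceCountTable:
    counts = pd.read_csv(counts_path, sep="\t", index_col="sequence")
    side = pd.read_csv(totals_path, sep="\t", index_col="sample_id")
    totals = side["library_total"]
    meta = side.drop(columns=["library_total"])
    return SequenceCountTable(counts=counts, samples=meta, library_totals=totals)
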