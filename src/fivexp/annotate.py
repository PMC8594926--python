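"""Hierarchical mismatch annotation of unique sequences.

Each unique sequence is searched, full-length and ungapped, against seven
biotype reference sets in annotation cycles of increasing Hamming-mismatch
allowance (tier 0 up to tier 3). A sequence enters the next cycle only if no
reference set matched in the current one; when several sets match within the
same cycle, a fixed biotype priority ladder decides
(miRNA > Mt_tRNA > tRNA > MT_rRNA > rRNA > piRNA > other_sncRNA).
So a piRNA hit at 0 mismatches beats a miRNA hit that needs 1, while at
equal mismatch tier miRNA wins on priority.

Alignment is exact full-query Hamming placement (no indels, no clipping),
which suits the short-fragment / short-reference regime and keeps a
brute-force oracle exact. N never matches anything, including another N.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

BIOTYPES = ("miRNA", "Mt_tRNA", "tRNA", "MT_rRNA", "rRNA", "piRNA", "other_sncRNA")
#: default priority ladder, rank 1 = highest
DEFAULT_PRIORITY = {b: i + 1 for i, b in enumerate(BIOTYPES)}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_N = ord("N")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AlignmentHit:
    """One ungapped placement of a full query on a reference (1-based, inclusive)."""

    query: str
    ref_id: str
    biotype: str
    start: int
    end: int
    strand: str
    mismatches: int


@dataclass
class ReferenceSet:
    """Biotype-labelled references with their rank in the priority ladder."""

    biotype: str
    priority_rank: int
    entries: list[tuple[str, str]]

    def __post_init__(self) -> None:
        self.entries = [(rid, seq.upper()) for rid, seq in self.entries]
        # encoded uint8 views, computed once per reference
        self._encoded = [
            (rid, np.frombuffer(seq.encode("ascii"), dtype=np.uint8), len(seq))
            for rid, seq in self.entries
        ]


@dataclass
class AnnotationRecord:
    query: str
    status: str  # "annotated" | "unannotated"
    biotype: Optional[str] = None
    mismatch_tier: Optional[int] = None
    hit: Optional[AlignmentHit] = None


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def _hamming_offsets(query_arr: np.ndarray, ref_arr: np.ndarray, max_mm: int) -> list[tuple[int, int]]:
    """All 0-based offsets where the query fits the reference with <= max_mm
    mismatches; N in either string mismatches everything (N vs N included)."""
    m = len(query_arr)
    if m > len(ref_arr) or m == 0:
        return []
    windows = sliding_window_view(ref_arr, m)
    diff = windows != query_arr
    if (query_arr == _N).any() or (ref_arr == _N).any():
        diff = diff | ((windows == _N) & (query_arr == _N))
    mm = diff.sum(axis=1)
    offsets = np.nonzero(mm <= max_mm)[0]
    return [(int(o), int(mm[o])) for o in offsets]


def align_with_mismatches(
    query: str,
    reference: str,
    max_mm: int,
    ref_id: str = "",
    biotype: str = "",
    both_strands: bool = False,
) -> list[AlignmentHit]:
    """All ungapped placements of ``query`` within ``reference``.

    Sense strand only by default (small-RNA fragments derive from the mature
    reference's sense); ``both_strands=True`` also searches the reverse
    complement, reporting minus-strand hits in reference coordinates.
    A query longer than the reference yields an empty list.
    """
    query = query.upper()
    ref_arr = _encode(reference)
    hits = [
        AlignmentHit(query, ref_id, biotype, o + 1, o + len(query), "+", mm)
        for o, mm in _hamming_offsets(_encode(query), ref_arr, max_mm)
    ]
    if both_strands:
        rc = reverse_complement(query)
        hits += [
            AlignmentHit(query, ref_id, biotype, o + 1, o + len(query), "-", mm)
            for o, mm in _hamming_offsets(_encode(rc), ref_arr, max_mm)
        ]
    hits.sort(key=lambda h: (h.mismatches, h.start, h.strand))
    return hits


def resolve_within_biotype(hits: Sequence[AlignmentHit]) -> AlignmentHit:
    """Deterministic representative among same-biotype hits:
    fewest mismatches, then lexicographically smallest ref_id, then smallest start."""
    if not hits:
        raise ValueError("empty hit list")
    return min(hits, key=lambda h: (h.mismatches, h.ref_id, h.start))


def _set_hits(
    query_arr: np.ndarray, query: str, refset: ReferenceSet, max_mm: int, both_strands: bool
) -> list[AlignmentHit]:
    hits: list[AlignmentHit] = []
    arrs = [(query_arr, "+")]
    if both_strands:
        arrs.append((_encode(reverse_complement(query)), "-"))
    for rid, ref_arr, _ in refset._encoded:
        for arr, strand in arrs:
            for o, mm in _hamming_offsets(arr, ref_arr, max_mm):
                hits.append(
                    AlignmentHit(query, rid, refset.biotype, o + 1, o + len(query), strand, mm)
                )
    return hits


def annotate_hierarchical(
    sequences: Iterable[str],
    reference_sets: Sequence[ReferenceSet],
    max_tier: int = 3,
    both_strands: bool = False,
) -> dict[str, AnnotationRecord]:
    """Annotate sequences through mismatch cycles 0..``max_tier``.

    In each cycle every still-unresolved sequence is searched against all
    reference sets at the cycle's mismatch allowance; if any set matches, the
    set with the best (lowest) priority rank wins and the sequence leaves the
    queue with ``mismatch_tier`` = the cycle number. Sequences unresolved
    after the last cycle are returned ``unannotated``.
    """
    sets = sorted(reference_sets, key=lambda rs: rs.priority_rank)
    ranks = [rs.priority_rank for rs in sets]
    if len(set(ranks)) != len(ranks):
        raise ValueError("reference sets must carry distinct priority ranks")
    all_ids = [rid for rs in sets for rid, _ in rs.entries]
    if len(set(all_ids)) != len(all_ids):
        raise ValueError("duplicate ref_ids across reference sets")

    pending = list(dict.fromkeys(s.upper() for s in sequences))
    records: dict[str, AnnotationRecord] = {}
    for tier in range(0, max_tier + 1):
        still: list[str] = []
        for seq in pending:
            q_arr = _encode(seq)
            rec = None
            for rs in sets:  # priority order: first matching set wins
                hits = _set_hits(q_arr, seq, rs, tier, both_strands)
                if hits:
                    rec = AnnotationRecord(
                        seq, "annotated", rs.biotype, tier, resolve_within_biotype(hits)
                    )
                    break
            if rec is None:
                still.append(seq)
            else:
                records[seq] = rec
        pending = still
    for seq in pending:
        records[seq] = AnnotationRecord(seq, "unannotated")
    return records


def annotation_table(records: Mapping[str, AnnotationRecord]) -> pd.DataFrame:
    """Flatten annotation records to the TSV-ready table."""
    rows = []
    for seq, rec in records.items():
        h = rec.hit
        rows.append(
            {
                "sequence": seq,
                "status": rec.status,
                "biotype": rec.biotype,
                "mismatch_tier": rec.mismatch_tier,
                "ref_id": h.ref_id if h else None,
                "start": h.start if h else None,
                "end": h.end if h else None,
                "strand": h.strand if h else None,
                "mismatches": h.mismatches if h else None,
            }
        )
    return pd.DataFrame(rows).set_index("sequence")


def composition(cpm_values: pd.DataFrame, records: Mapping[str, AnnotationRecord]) -> pd.DataFrame:
    """Per-sample percentage of cpm per biotype, including ``unannotated``.

    Columns sum to 100 for samples with non-zero cpm.
    """
    biotype = pd.Series(
        {seq: (records[seq].biotype if records[seq].status == "annotated" else "unannotated")
         for seq in cpm_values.index}
    )
    grouped = cpm_values.groupby(biotype.reindex(cpm_values.index)).sum()
    return grouped / grouped.sum(axis=0) * 100.0
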