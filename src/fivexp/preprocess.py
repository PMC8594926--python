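"""Read preprocessing: quality trimming, 3' adapter removal, tag splitting.

The pipeline mirrors a standard small-RNA trimming recipe for two-colour
(NextSeq-type) chemistry:

1. :func:`trim_two_color_tail` — 3'-end quality trimming in which G bases are
   treated as quality 0 (dark cycles on two-colour instruments read as G, so
   a trailing G run carries no evidence).
2. :func:`trim_three_prime_adapter` — ungapped search for the 3' adapter
   (full adapter internally, or a prefix of at least ``min_overlap`` bases
   ending the read); reads without a qualifying adapter hit are discarded, as
   are inserts outside ``[min_len, max_len]``.
3. :func:`split_by_tag` — route reads into the 5P-tag sub-library (read
   starts with the 11-nt 5' oligo tag, which is removed) or the 5X-notag
   sub-library (everything else).
4. :func:`quality_filter` — whole-read filter requiring Phred >= ``qf_min_q``
   in at least ``qf_min_frac`` of bases.

:func:`preprocess_sample` composes the four stages in that order and accounts
for every input read exactly once (one sub-library or one named discard
reason).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

from .records import PHRED_OFFSET, ReadRecord

DEFAULT_ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCACAT"
DEFAULT_TAG = "TGGCAACGATC"

P_TAG = "P_TAG"
X_NOTAG = "X_NOTAG"


@dataclass
class PreprocessParams:
    """Tunable thresholds for the preprocessing pipeline.

    Defaults reproduce the canonical sRNA trimming command line:
    ``--nextseq-trim=20 -O 5 -m 5`` with a 5–70 nt insert window, a
    ``-q 20 -p 80`` whole-read quality filter, and an exact-prefix 5' tag
    match.
    """

    adapter: str = DEFAULT_ADAPTER
    min_overlap: int = 5
    max_error_rate: float = 0.1
    qcut: int = 20
    min_len: int = 5
    max_len: int = 70
    qf_min_q: int = 20
    qf_min_frac: float = 0.8
    tag: str = DEFAULT_TAG
    tag_max_mismatch: int = 0

    def __post_init__(self) -> None:
        if not self.adapter:
            raise ValueError("adapter must be non-empty")
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")
        for name in ("min_overlap", "qcut", "min_len", "qf_min_q", "tag_max_mismatch"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def trim_two_color_tail(read: ReadRecord, qcut: int = 20) -> ReadRecord:
    """Quality-trim the 3' end with G treated as quality 0.

    Uses the running-sum rule: walking from the 3' end accumulating
    ``qcut - q_effective``, the read is cut at the position where the
    accumulated sum is maximal (equivalently, the trailing segment whose
    removal minimises the remaining sum). Stops once the sum turns negative,
    i.e. the tail is dominated by confident bases.
    """
    seq = read.sequence
    qual = read.quality
    running = 0
    best = 0
    cut = len(seq)
    for i in range(len(seq) - 1, -1, -1):
        q_eff = 0 if seq[i] == "G" else ord(qual[i]) - PHRED_OFFSET
        running += qcut - q_eff
        if running < 0:
            break
        if running > best:
            best = running
            cut = i
    return read.slice(0, cut) if cut < len(seq) else read


def _mismatches(a: str, b: str, limit: int) -> int:
    """Hamming mismatches between equal-length strings; N never matches.

    Stops counting once ``limit`` is exceeded (returns ``limit + 1``).
    """
    mm = 0
    for x, y in zip(a, b):
        if x != y or x == "N":
            mm += 1
            if mm > limit:
                return mm
    return mm


def find_adapter(
    sequence: str,
    adapter: str,
    min_overlap: int = 5,
    max_error_rate: float = 0.1,
) -> Optional[tuple[int, int, int]]:
    """Locate the best ungapped adapter occurrence in ``sequence``.

    Candidates are every start position ``p`` where either the full adapter
    fits, or a prefix of the adapter (length >= ``min_overlap``) runs to the
    read's 3' end. A candidate qualifies when its mismatch count is at most
    ``floor(max_error_rate * matched_length)`` (N counts as a mismatch).
    The best candidate is the longest match, then the fewest mismatches,
    then the leftmost. Returns ``(start, matched_length, mismatches)`` in
    0-based coordinates or ``None``.
    """
    n, alen = len(sequence), len(adapter)
    best: Optional[tuple[int, int, int]] = None
    for p in range(0, n - min_overlap + 1):
        length = min(alen, n - p)
        allowed = int(max_error_rate * length)
        mm = _mismatches(sequence[p : p + length], adapter[:length], allowed)
        if mm > allowed:
            continue
        if best is None or (length, -mm, -p) > (best[1], -best[2], -best[0]):
            best = (p, length, mm)
        if length == alen and mm == 0:
            break  # cannot be beaten: longest possible match, zero errors
    return best


def trim_three_prime_adapter(
    read: ReadRecord, params: PreprocessParams
) -> Optional[ReadRecord]:
    """Remove the 3' adapter and everything downstream of it.

    Returns the insert, or ``None`` (discard) when no qualifying adapter
    occurrence exists or the insert falls outside ``[min_len, max_len]``.
    """
    hit = find_adapter(read.sequence, params.adapter, params.min_overlap, params.max_error_rate)
    if hit is None:
        return None
    insert = read.slice(0, hit[0])
    if not params.min_len <= len(insert) <= params.max_len:
        return None
    return insert


def quality_filter(read: ReadRecord, qf_min_q: int = 20, qf_min_frac: float = 0.8) -> bool:
    """True (KEEP) iff the fraction of bases with Q >= ``qf_min_q`` is >= ``qf_min_frac``."""
    if len(read) == 0:
        return False
    threshold_char = qf_min_q + PHRED_OFFSET
    n_ok = sum(1 for c in read.quality if ord(c) >= threshold_char)
    return n_ok / len(read) >= qf_min_frac


def split_by_tag(
    read: ReadRecord, params: PreprocessParams
) -> Optional[tuple[str, ReadRecord]]:
    """Assign a read to the 5P-tag or 5X-notag sub-library.

    A read beginning with the tag (at most ``tag_max_mismatch`` substitutions;
    N never matches) is emitted as ``(P_TAG, read minus tag)``; any other read
    is ``(X_NOTAG, read)`` unchanged. De-tagged reads shorter than ``min_len``
    are discarded (``None``). Reads shorter than the tag cannot carry it and
    are routed to the no-tag sub-library.
    """
    tag = params.tag
    if len(read) >= len(tag):
        mm = _mismatches(read.sequence[: len(tag)], tag, params.tag_max_mismatch)
        if mm <= params.tag_max_mismatch:
            detagged = read.slice(len(tag))
            if len(detagged) < params.min_len:
                return None
            return (P_TAG, detagged)
    return (X_NOTAG, read)


#: discard reasons reported by :func:`preprocess_sample`
DISCARD_REASONS = ("no_adapter", "insert_length", "detag_short", "low_quality")


@dataclass
class PreprocessStats:
    """Per-stage accounting; ``n_in`` always equals retained + discarded."""

    n_in: int = 0
    n_p_tag: int = 0
    n_x_notag: int = 0
    discards: dict[str, int] = field(
        default_factory=lambda: {r: 0 for r in DISCARD_REASONS}
    )

    @property
    def n_retained(self) -> int:
        return self.n_p_tag + self.n_x_notag

    @property
    def n_discarded(self) -> int:
        return sum(self.discards.values())

    def as_dict(self) -> dict[str, int]:
        out = {"n_in": self.n_in, "n_p_tag": self.n_p_tag, "n_x_notag": self.n_x_notag}
        out.update({f"discard_{k}": v for k, v in self.discards.items()})
        return out


def preprocess_read(
    read: ReadRecord, params: PreprocessParams
) -> tuple[Optional[str], Optional[ReadRecord], Optional[str]]:
    """Run one read through all four stages.

    Returns ``(sublibrary, read, discard_reason)`` where exactly one of
    ``sublibrary`` / ``discard_reason`` is set.
    """
    read = trim_two_color_tail(read, params.qcut)
    insert = trim_three_prime_adapter(read, params)
    if insert is None:
        reason = (
            "no_adapter"
            if find_adapter(read.sequence, params.adapter, params.min_overlap, params.max_error_rate) is None
            else "insert_length"
        )
        return None, None, reason
    split = split_by_tag(insert, params)
    if split is None:
        return None, None, "detag_short"
    label, final = split
    if not quality_filter(final, params.qf_min_q, params.qf_min_frac):
        return None, None, "low_quality"
    return label, final, None


def preprocess_sample(
    reads: Iterable[ReadRecord], params: PreprocessParams | None = None
) -> tuple[list[ReadRecord], list[ReadRecord], PreprocessStats]:
    """Preprocess a full sample into (P_TAG reads, X_NOTAG reads, stats)."""
    params = params or PreprocessParams()
    stats = PreprocessStats()
    p_tag: list[ReadRecord] = []
    x_notag: list[ReadRecord] = []
    for read in reads:
        stats.n_in += 1
        label, final, reason = preprocess_read(read, params)
        if reason is not None:
            stats.discards[reason] += 1
        elif label == P_TAG:
            stats.n_p_tag += 1
            p_tag.append(final)
        else:
            stats.n_x_notag += 1
            x_notag.append(final)
    return p_tag, x_notag, stats
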