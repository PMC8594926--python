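"""tRNA/rRNA fragment classification, loop mapping and coverage profiles.

Fragments aligned to a mature reference are stratified by their terminals:

* ``five_prime`` — starts at the reference's first base,
* ``three_prime`` — ends at its last base,
* ``internal`` — neither,
* ``full`` — both (full-length mature molecule).

For tRNA references with a parsed cloverleaf secondary structure the
cleavage boundaries are mapped onto loops (D, anticodon, variable, T), which
drives two subtype flags:

* ``tiRNA_half`` — a 5' fragment ending in, or a 3' fragment starting from,
  the anticodon loop (the angiogenin-style tRNA half);
* ``nitRNA_like`` — an internal fragment with a boundary in the T loop
  (internal T-loop cleavage product).

rRNA fragments are assigned to a mature subunit of a precursor by their
midpoint and then terminal-classified against that subunit's boundaries.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .annotate import AlignmentHit

D_LOOP = "D_loop"
ANTICODON_LOOP = "anticodon_loop"
VARIABLE_LOOP = "variable_loop"
T_LOOP = "T_loop"

FIVE_PRIME = "five_prime"
THREE_PRIME = "three_prime"
INTERNAL = "internal"
FULL = "full"

#: minimum length for the unpaired run between the anticodon and T stems to
#: be reported as a variable loop (shorter runs are connector nucleotides)
MIN_VARIABLE_LOOP = 4


@dataclass
class SecondaryStructure:
    """A cloverleaf pairing string aligned to a mature tRNA sequence.

    ``pairing`` uses '>' (paired downstream), '<' (paired upstream) and '.'
    (unpaired). ``loops`` are 1-based inclusive ``(label, start, end)``
    intervals in 5'->3' order. ``usable`` is False when the record does not
    expose the three hairpin loops of a cloverleaf.
    """

    ref_id: str
    length: int
    pairing: str
    loops: list[tuple[str, int, int]] = field(default_factory=list)
    usable: bool = True

    def loop_at(self, pos: int) -> Optional[str]:
        """Loop label containing 1-based position ``pos``, else None."""
        for label, start, end in self.loops:
            if start <= pos <= end:
                return label
        return None

    def loop_interval(self, label: str) -> Optional[tuple[int, int]]:
        for lab, start, end in self.loops:
            if lab == label:
                return (start, end)
        return None


class SsParseError(ValueError):
    pass


def _find_loops(pairing: str) -> list[tuple[int, int, str, str]]:
    """Maximal unpaired runs with their flanking characters.

    Returns 0-based inclusive ``(start, end, left_char, right_char)``; runs
    touching either terminus get '^'/'$' sentinels.
    """
    runs = []
    for m in re.finditer(r"\.+", pairing):
        left = pairing[m.start() - 1] if m.start() > 0 else "^"
        right = pairing[m.end()] if m.end() < len(pairing) else "$"
        runs.append((m.start(), m.end() - 1, left, right))
    return runs


def parse_ss_record(ref_id: str, sequence: str, pairing: str) -> SecondaryStructure:
    """Build a SecondaryStructure from one sequence + pairing line pair.

    Hairpin loops are unpaired runs strictly enclosed by a '>' run and its
    matching '<' run (for an immediately flanked run the flanking characters
    are necessarily partners). With three hairpins they are labelled D,
    anticodon and T in 5'->3' order; an unpaired run of length >=
    ``MIN_VARIABLE_LOOP`` between the anticodon and T hairpins, flanked by
    '<' and '>', is the variable loop. Records without three hairpins are
    flagged unusable (no loops reported).
    """
    if len(sequence) != len(pairing):
        raise SsParseError(f"{ref_id}: sequence and pairing lengths differ")
    if pairing.count(">") != pairing.count("<"):
        raise SsParseError(f"{ref_id}: unbalanced pairing string")
    depth = 0
    for c in pairing:
        if c == ">":
            depth += 1
        elif c == "<":
            depth -= 1
            if depth < 0:
                raise SsParseError(f"{ref_id}: '<' without matching '>'")
        elif c != ".":
            raise SsParseError(f"{ref_id}: invalid pairing character {c!r}")

    runs = _find_loops(pairing)
    hairpins = [(s, e) for s, e, l, r in runs if l == ">" and r == "<"]
    ss = SecondaryStructure(ref_id=ref_id, length=len(sequence), pairing=pairing)
    if len(hairpins) != 3:
        ss.usable = False
        return ss
    d, ac, t = hairpins
    loops = [
        (D_LOOP, d[0] + 1, d[1] + 1),
        (ANTICODON_LOOP, ac[0] + 1, ac[1] + 1),
    ]
    for s, e, l, r in runs:  # variable loop sits between the AC and T hairpins
        if l == "<" and r == ">" and s > ac[1] and e < t[0] and e - s + 1 >= MIN_VARIABLE_LOOP:
            loops.append((VARIABLE_LOOP, s + 1, e + 1))
            break
    loops.append((T_LOOP, t[0] + 1, t[1] + 1))
    ss.loops = loops
    return ss


def parse_ss_text(text: str) -> dict[str, SecondaryStructure]:
    """Parse an ss file: per record a ``>ref_id`` header, a sequence line and
    an aligned pairing line."""
    structures: dict[str, SecondaryStructure] = {}
    lines = [ln.rstrip() for ln in text.splitlines() if ln.strip()]
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise SsParseError(f"expected '>' header at line {i + 1}: {lines[i]!r}")
        if i + 2 >= len(lines):
            raise SsParseError(f"truncated record for {lines[i]!r}")
        ref_id = lines[i][1:].split()[0]
        ss = parse_ss_record(ref_id, lines[i + 1].upper(), lines[i + 2])
        structures[ref_id] = ss
        i += 3
    return structures


def write_ss_file(structures: Mapping[str, str | SecondaryStructure], sequences: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for ref_id, ss in structures.items():
            pairing = ss.pairing if isinstance(ss, SecondaryStructure) else ss
            fh.write(f">{ref_id}\n{sequences[ref_id]}\n{pairing}\n")


def classify_terminal(start: int, end: int, ref_length: int) -> str:
    """Terminal class of a fragment spanning [start, end] (1-based inclusive)."""
    at5 = start == 1
    at3 = end == ref_length
    if at5 and at3:
        return FULL
    if at5:
        return FIVE_PRIME
    if at3:
        return THREE_PRIME
    return INTERNAL


def label_cleavage(
    start: int, end: int, ss: SecondaryStructure
) -> tuple[Optional[str], Optional[str], bool, bool]:
    """Map a fragment's cleavage boundaries onto loops and derive subtype flags.

    The 5' boundary of a fragment is the phosphodiester bond before ``start``;
    a boundary lies "in a loop" when the nucleotide on its 5' side (position
    ``start - 1`` for the 5' boundary, ``end`` for the 3' boundary) falls
    inside the loop interval. Boundaries at the molecule's termini carry no
    loop label. Returns ``(start_loop, end_loop, tiRNA_half, nitRNA_like)``.
    """
    start_loop = ss.loop_at(start - 1) if start > 1 else None
    end_loop = ss.loop_at(end) if end < ss.length else None
    terminal = classify_terminal(start, end, ss.length)
    tirna = (terminal == FIVE_PRIME and end_loop == ANTICODON_LOOP) or (
        terminal == THREE_PRIME and start_loop == ANTICODON_LOOP
    )
    nitrna = terminal == INTERNAL and (start_loop == T_LOOP or end_loop == T_LOOP)
    return start_loop, end_loop, tirna, nitrna


@dataclass
class FragmentClassification:
    query: str
    ref_id: str
    terminal_class: str
    start_loop: Optional[str] = None
    end_loop: Optional[str] = None
    tiRNA_half: bool = False
    nitRNA_like: bool = False


def classify_fragment(
    hit: AlignmentHit, ref_length: int, ss: Optional[SecondaryStructure] = None
) -> FragmentClassification:
    """Full classification of one aligned fragment; loop labels require a
    usable secondary structure."""
    terminal = classify_terminal(hit.start, hit.end, ref_length)
    fc = FragmentClassification(hit.query, hit.ref_id, terminal)
    if ss is not None and ss.usable:
        fc.start_loop, fc.end_loop, fc.tiRNA_half, fc.nitRNA_like = label_cleavage(
            hit.start, hit.end, ss
        )
    return fc


def classify_rrf(
    start: int, end: int, subunit_intervals: Sequence[tuple[str, int, int]]
) -> tuple[Optional[str], Optional[str]]:
    """Assign an rRNA fragment to a mature subunit and terminal-classify it.

    The subunit whose (1-based inclusive, disjoint) interval contains the
    fragment midpoint wins; a fragment whose midpoint falls in a spacer gets
    ``(None, None)``. Terminal class is computed against the subunit's own
    boundaries.
    """
    ordered = sorted(subunit_intervals, key=lambda t: t[1])
    for (_, s1, e1), (_, s2, _) in zip(ordered, ordered[1:]):
        if e1 >= s2:
            raise ValueError("overlapping subunit intervals")
    mid = (start + end) // 2
    for sub_id, s, e in ordered:
        if s <= mid <= e:
            at5 = start == s
            at3 = end == e
            if at5 and at3:
                return sub_id, FULL
            if at5:
                return sub_id, FIVE_PRIME
            if at3:
                return sub_id, THREE_PRIME
            return sub_id, INTERNAL
    return None, None


@dataclass
class CoverageProfile:
    ref_id: str
    values: np.ndarray  # per-position cpm, index 0 == reference position 1
    n_fragments: int


def compute_coverage(
    fragments: Iterable[tuple[int, int, float]], ref_length: int, ref_id: str = ""
) -> CoverageProfile:
    """Per-position cpm coverage: values[p] = sum of cpm of fragments covering p.

    ``fragments`` are ``(start, end, cpm)`` with 1-based inclusive coordinates.
    """
    values = np.zeros(ref_length, dtype=float)
    n = 0
    for start, end, cpm in fragments:
        if start < 1 or end > ref_length or start > end:
            raise ValueError(f"fragment [{start},{end}] outside reference of length {ref_length}")
        values[start - 1 : end] += cpm
        n += 1
    return CoverageProfile(ref_id=ref_id, values=values, n_fragments=n)


def mean_coverage(
    per_sample_fragments: Mapping[str, Iterable[tuple[int, int, float]]],
    ref_length: int,
    ref_id: str = "",
) -> CoverageProfile:
    """Across-sample mean of per-sample coverage profiles."""
    if not per_sample_fragments:
        raise ValueError("no samples")
    profiles = [
        compute_coverage(frags, ref_length, ref_id)
        for frags in per_sample_fragments.values()
    ]
    mean = np.mean([p.values for p in profiles], axis=0)
    return CoverageProfile(ref_id=ref_id, values=mean, n_fragments=sum(p.n_fragments for p in profiles))


def terminal_enrichment(
    classes: Sequence[str], cpm: Sequence[float], groups: Sequence[str]
) -> pd.DataFrame:
    """cpm-weighted 5'/i'/3' fractions per group.

    ``full`` fragments are excluded from the three-way split (they are not
    fragments in the 5'/i'/3' sense); fractions sum to 1 per group. Groups
    with no fragment mass are absent from the result.
    """
    df = pd.DataFrame({"terminal": classes, "cpm": cpm, "group": groups})
    df = df[df["terminal"].isin([FIVE_PRIME, INTERNAL, THREE_PRIME])]
    totals = df.groupby("group")["cpm"].sum()
    pivot = df.pivot_table(index="group", columns="terminal", values="cpm", aggfunc="sum", fill_value=0.0)
    pivot = pivot.reindex(columns=[FIVE_PRIME, INTERNAL, THREE_PRIME], fill_value=0.0)
    pivot = pivot.loc[totals[totals > 0].index]
    return pivot.div(totals[totals > 0], axis=0)


_ISODECODER_RE = re.compile(r"tRNA-([A-Za-z]{3}[ACGTU]{3})")


def isodecoder(ref_id: str, pattern: re.Pattern | str = _ISODECODER_RE) -> Optional[str]:
    """Anticodon family parsed from a tRNA ref_id (``tRNA-AspGCU-1`` -> ``AspGCU``)."""
    if isinstance(pattern, str):
        pattern = re.compile(pattern)
    m = pattern.search(ref_id)
    return m.group(1) if m else None
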