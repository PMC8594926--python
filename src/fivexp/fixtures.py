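"""Seeded synthetic data: reference bundles, cloverleaf structures, and
simulated tagged/untagged reads with ground-truth labels.

The generator emulates the input of a 5'XP small-RNA sequencing run: each
read is ``[5' tag if tagged] + insert + 3' adapter + random tail`` truncated
to the instrument read length, where the insert is a substring of a known
reference with per-base substitution errors. Insert intervals are drawn per
biotype so that every downstream classifier branch is exercised:

* miRNA / piRNA — 5'-anchored mature-length inserts (~22 +- 1 and ~28 +- 2 nt;
  piRNA references carry the canonical 5'-U bias);
* tRNA / Mt_tRNA — a 5'/internal/3' fragment mixture with loop-anchored
  cleavage breakpoints on a generated cloverleaf (anticodon-loop halves,
  T-loop internal fragments, ...);
* rRNA / MT_rRNA — fragments placed relative to mature subunit boundaries
  of a precursor-style reference;
* other_sncRNA — uniform internal substrings.

All randomness flows through a single ``numpy.random.default_rng(seed)``;
identical parameters produce byte-identical FASTQ and truth tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import io as fio
from .annotate import BIOTYPES, DEFAULT_PRIORITY, ReferenceSet, reverse_complement
from .fragments import (
    ANTICODON_LOOP,
    D_LOOP,
    FIVE_PRIME,
    INTERNAL,
    SecondaryStructure,
    T_LOOP,
    THREE_PRIME,
    VARIABLE_LOOP,
)
from .preprocess import DEFAULT_ADAPTER, DEFAULT_TAG
from .records import ReadRecord, quality_string

_BASES = np.array(list("ACGT"))
_AMINO_ACIDS = (
    "Ala Arg Asn Asp Cys Gln Glu Gly His Ile Leu Lys Met Phe Pro Ser Thr Trp Tyr Val"
).split()

#: truth-table columns (extra per-biotype columns may follow)
TRUTH_COLUMNS = (
    "read_id",
    "source_ref",
    "biotype",
    "insert_start",
    "insert_end",
    "tagged",
    "n_seq_errors",
)


@dataclass
class SimulationParams:
    """Knobs of the read simulator.

    ``p_tagged`` is the probability a simulated molecule carried a 5'
    phosphate and received the tag; it is a free experimental parameter
    (default 0.15, in the range sequenced tag sub-libraries typically
    occupy). ``error_rate`` is a per-base substitution probability applied to
    the insert. Quality strings are Phred+33, drawn per base from a normal
    clamped to [2, 40]; ``low_quality_fraction`` of reads are drawn around
    ``low_quality_mean`` instead, to exercise the whole-read quality filter.
    """

    seed: int = 0
    n_reads: int = 10000
    p_tagged: float = 0.15
    error_rate: float = 0.001
    adapter: str = DEFAULT_ADAPTER
    tag: str = DEFAULT_TAG
    read_length: int = 75
    quality_mean: float = 36.0
    quality_sd: float = 3.0
    low_quality_fraction: float = 0.0
    low_quality_mean: float = 12.0
    #: (five_prime, internal, three_prime) draw weights for tRNA fragments
    trf_class_weights: tuple[float, float, float] = (0.4, 0.2, 0.4)
    #: same for rRNA fragments (relative to a mature subunit)
    rrf_class_weights: tuple[float, float, float] = (0.4, 0.2, 0.4)
    #: mean/sd of anchored insert lengths per simple biotype
    mirna_len: tuple[float, float] = (22.0, 1.0)
    pirna_len: tuple[float, float] = (28.0, 2.0)
    rrf_len: tuple[float, float] = (25.0, 4.0)
    other_len: tuple[float, float] = (30.0, 5.0)
    #: per-biotype sampling weights (None = uniform over present biotypes)
    biotype_weights: Optional[Mapping[str, float]] = None

    def __post_init__(self) -> None:
        if self.n_reads <= 0:
            raise ValueError("n_reads must be positive")
        if not 0.0 <= self.p_tagged <= 1.0:
            raise ValueError("p_tagged must lie in [0, 1]")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must lie in [0, 1)")
        for name in ("trf_class_weights", "rrf_class_weights"):
            w = getattr(self, name)
            if len(w) != 3 or min(w) < 0 or sum(w) == 0:
                raise ValueError(f"{name} must be three non-negative weights")
        for name in ("mirna_len", "pirna_len", "rrf_len", "other_len"):
            if getattr(self, name)[0] < 1:
                raise ValueError(f"{name}: mean insert length below 1")
        if self.read_length < len(self.tag) + 1:
            raise ValueError("read_length too short to hold the tag")


@dataclass
class ReferenceBundle:
    """References plus their per-biotype metadata, ready to write out."""

    reference_sets: dict[str, ReferenceSet]
    structures: dict[str, SecondaryStructure] = field(default_factory=dict)
    subunits: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)

    @property
    def sequences(self) -> dict[str, str]:
        return {rid: seq for rs in self.reference_sets.values() for rid, seq in rs.entries}

    def biotype_of(self) -> dict[str, str]:
        return {rid: rs.biotype for rs in self.reference_sets.values() for rid, _ in rs.entries}


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _make_cloverleaf(rng: np.random.Generator, anticodon: str) -> tuple[str, str, list[tuple[str, int, int]]]:
    """One tRNA-like sequence with its pairing string and loop intervals.

    Layout (5'->3'): acceptor stem (7 bp), D arm (4 bp stem, 8-14 nt loop),
    anticodon arm (5 bp stem, 7 nt loop with the anticodon at its centre),
    4 nt variable region, T arm (5 bp stem, 7 nt loop), acceptor-stem close
    and an NCCA tail. Loop intervals are computed from the layout itself so
    they are independent of the structure parser.
    """
    d_len = int(rng.integers(8, 15))
    acc = _random_seq(rng, 7)
    d_stem = _random_seq(rng, 4)
    ac_stem = _random_seq(rng, 5)
    t_stem = _random_seq(rng, 5)
    d_loop = _random_seq(rng, d_len)
    ac_loop = _random_seq(rng, 2) + anticodon + _random_seq(rng, 2)
    t_loop = _random_seq(rng, 7)
    var = _random_seq(rng, 4)
    spacer1, spacer2 = _random_seq(rng, 2), _random_seq(rng, 1)
    tail = _random_seq(rng, 1) + "CCA"

    seq = (
        acc + spacer1
        + d_stem + d_loop + reverse_complement(d_stem) + spacer2
        + ac_stem + ac_loop + reverse_complement(ac_stem)
        + var
        + t_stem + t_loop + reverse_complement(t_stem)
        + reverse_complement(acc) + tail
    )
    pairing = (
        ">" * 7 + ".." + ">" * 4 + "." * d_len + "<" * 4 + "."
        + ">" * 5 + "." * 7 + "<" * 5 + "." * 4
        + ">" * 5 + "." * 7 + "<" * 5 + "<" * 7 + "...."
    )
    d_start = 7 + 2 + 4 + 1  # 1-based
    ac_start = d_start + d_len + 4 + 1 + 5
    var_start = ac_start + 7 + 5
    t_start = var_start + 4 + 5
    loops = [
        (D_LOOP, d_start, d_start + d_len - 1),
        (ANTICODON_LOOP, ac_start, ac_start + 6),
        (VARIABLE_LOOP, var_start, var_start + 3),
        (T_LOOP, t_start, t_start + 6),
    ]
    return seq, pairing, loops


#: subunit layout carved into each generated rRNA precursor (1-based inclusive)
RRNA_SUBUNITS = (("18S", 21, 120), ("5.8S", 141, 180), ("28S", 201, 290))
RRNA_LENGTH = 300


def make_reference_bundle(seed: int, counts_per_biotype: Mapping[str, int]) -> ReferenceBundle:
    """Generate labelled references (and structures) for the given biotypes.

    miRNA references are ~22 nt, piRNA 26-30 nt with an 80% 5'-U(T) start
    bias, tRNA/Mt_tRNA 75-81 nt cloverleaves with paired secondary
    structures, rRNA a 300-nt precursor with mature 18S/5.8S/28S-style
    subunit intervals, MT_rRNA 120-200 nt, other_sncRNA 60-120 nt.
    """
    rng = np.random.default_rng(seed)
    unknown = set(counts_per_biotype) - set(BIOTYPES)
    if unknown:
        raise ValueError(f"unknown biotype(s): {sorted(unknown)}")
    for b, n in counts_per_biotype.items():
        if n <= 0:
            raise ValueError(f"count for {b} must be positive, got {n}")

    bundle = ReferenceBundle(reference_sets={})
    for biotype in BIOTYPES:  # fixed iteration order for determinism
        if biotype not in counts_per_biotype:
            continue
        n = counts_per_biotype[biotype]
        entries: list[tuple[str, str]] = []
        for i in range(1, n + 1):
            if biotype == "miRNA":
                entries.append((f"mir-{i}", _random_seq(rng, 22)))
            elif biotype == "piRNA":
                length = int(rng.integers(26, 31))
                first = "T" if rng.random() < 0.8 else str(rng.choice(list("ACG")))
                entries.append((f"piRNA-{i}", first + _random_seq(rng, length - 1)))
            elif biotype in ("tRNA", "Mt_tRNA"):
                aa = str(rng.choice(_AMINO_ACIDS))
                anticodon = _random_seq(rng, 3)
                prefix = "tRNA" if biotype == "tRNA" else "Mt-tRNA"
                rid = f"{prefix}-{aa}{anticodon}-{i}"
                seq, pairing, loops = _make_cloverleaf(rng, anticodon)
                entries.append((rid, seq))
                bundle.structures[rid] = SecondaryStructure(
                    ref_id=rid, length=len(seq), pairing=pairing, loops=loops
                )
            elif biotype == "rRNA":
                rid = f"rRNA-45S-{i}"
                entries.append((rid, _random_seq(rng, RRNA_LENGTH)))
                bundle.subunits[rid] = [tuple(s) for s in RRNA_SUBUNITS]
            elif biotype == "MT_rRNA":
                rid = f"MT-rRNA-{i}"
                length = int(rng.integers(120, 201))
                entries.append((rid, _random_seq(rng, length)))
                bundle.subunits[rid] = [(rid, 1, length)]
            else:  # other_sncRNA
                entries.append((f"sncRNA-{i}", _random_seq(rng, int(rng.integers(60, 121)))))
        bundle.reference_sets[biotype] = ReferenceSet(
            biotype=biotype, priority_rank=DEFAULT_PRIORITY[biotype], entries=entries
        )
    return bundle


def _anchored_length(rng: np.random.Generator, model: tuple[float, float], lo: int, hi: int) -> int:
    return int(np.clip(round(rng.normal(model[0], model[1])), lo, hi))


def _draw_insert(
    rng: np.random.Generator,
    biotype: str,
    ref_id: str,
    seq: str,
    bundle: ReferenceBundle,
    params: SimulationParams,
) -> tuple[int, int, dict]:
    """Insert interval (1-based inclusive) plus biotype-specific truth extras."""
    extras: dict = {"frag_class": "", "tiRNA_half": False, "nitRNA_like": False, "subunit": ""}
    L = len(seq)
    if biotype == "miRNA":
        return 1, _anchored_length(rng, params.mirna_len, 18, L), extras
    if biotype == "piRNA":
        return 1, _anchored_length(rng, params.pirna_len, 24, L), extras
    if biotype in ("tRNA", "Mt_tRNA"):
        ss = bundle.structures[ref_id]
        loops = {lab: (s, e) for lab, s, e in ss.loops}
        weights = np.asarray(params.trf_class_weights, dtype=float)
        cls = [FIVE_PRIME, INTERNAL, THREE_PRIME][rng.choice(3, p=weights / weights.sum())]
        extras["frag_class"] = cls

        def cut_in(label: str) -> int:
            s, e = loops[label]
            return int(rng.integers(s, e + 1))

        if cls == FIVE_PRIME:
            # canonical 5' tRFs end in the D or anticodon loop
            label = [ANTICODON_LOOP, D_LOOP][rng.choice(2, p=[0.7, 0.3])]
            start, end = 1, cut_in(label)
            extras["tiRNA_half"] = label == ANTICODON_LOOP
        elif cls == THREE_PRIME:
            label = [ANTICODON_LOOP, T_LOOP][rng.choice(2, p=[0.7, 0.3])]
            start, end = cut_in(label) + 1, L
            extras["tiRNA_half"] = label == ANTICODON_LOOP
        else:
            pair = [(D_LOOP, ANTICODON_LOOP), (ANTICODON_LOOP, T_LOOP), (D_LOOP, T_LOOP)][
                rng.choice(3, p=[0.4, 0.4, 0.2])
            ]
            start, end = cut_in(pair[0]) + 1, cut_in(pair[1])
            extras["nitRNA_like"] = T_LOOP in pair
        return start, end, extras
    if biotype in ("rRNA", "MT_rRNA"):
        subs = bundle.subunits[ref_id]
        sub_id, s, e = subs[int(rng.integers(len(subs)))]
        weights = np.asarray(params.rrf_class_weights, dtype=float)
        cls = [FIVE_PRIME, INTERNAL, THREE_PRIME][rng.choice(3, p=weights / weights.sum())]
        flen = _anchored_length(rng, params.rrf_len, 15, min(40, e - s - 1))
        if cls == FIVE_PRIME:
            start, end = s, s + flen - 1
        elif cls == THREE_PRIME:
            start, end = e - flen + 1, e
        else:  # strictly inside the subunit: start > s and end < e
            start = int(rng.integers(s + 1, e - flen + 1))
            end = start + flen - 1
        extras["frag_class"] = cls
        extras["subunit"] = sub_id
        return start, end, extras
    # other_sncRNA: uniform internal substring
    flen = _anchored_length(rng, params.other_len, 15, min(50, L))
    start = int(rng.integers(1, L - flen + 2))
    return start, start + flen - 1, extras


def _apply_errors(rng: np.random.Generator, seq: str, error_rate: float) -> tuple[str, int]:
    if error_rate <= 0:
        return seq, 0
    arr = np.array(list(seq))
    hit = np.nonzero(rng.random(len(arr)) < error_rate)[0]
    for i in hit:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return "".join(arr), int(len(hit))


def simulate_reads(
    bundle: ReferenceBundle, params: SimulationParams
) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Simulate a tagged/untagged read set with its ground-truth table.

    Returns the reads and a truth DataFrame with the canonical columns
    (read_id, source_ref, biotype, insert_start, insert_end, tagged,
    n_seq_errors) plus fragment-truth extras for tRNA/rRNA reads.
    """
    if not bundle.reference_sets:
        raise ValueError("reference bundle is empty")
    rng = np.random.default_rng(params.seed)
    biotypes = [b for b in BIOTYPES if b in bundle.reference_sets]
    if params.biotype_weights is not None:
        w = np.array([params.biotype_weights.get(b, 0.0) for b in biotypes], dtype=float)
        if w.sum() <= 0:
            raise ValueError("biotype_weights give zero mass to present biotypes")
    else:
        w = np.ones(len(biotypes))
    w = w / w.sum()

    reads: list[ReadRecord] = []
    rows: list[dict] = []
    for i in range(params.n_reads):
        biotype = biotypes[rng.choice(len(biotypes), p=w)]
        entries = bundle.reference_sets[biotype].entries
        ref_id, ref_seq = entries[rng.integers(len(entries))]
        start, end, extras = _draw_insert(rng, biotype, ref_id, ref_seq, bundle, params)
        insert, n_err = _apply_errors(rng, ref_seq[start - 1 : end], params.error_rate)
        tagged = bool(rng.random() < params.p_tagged)

        core = (params.tag if tagged else "") + insert + params.adapter
        if len(core) < params.read_length:
            core += _random_seq(rng, params.read_length - len(core))
        seq = core[: params.read_length]

        low = rng.random() < params.low_quality_fraction
        mean = params.low_quality_mean if low else params.quality_mean
        if params.quality_sd > 0:
            scores = rng.normal(mean, params.quality_sd, size=len(seq))
        else:
            scores = np.full(len(seq), mean)
        qual = quality_string(np.rint(scores), clamp=(2, 40))

        read_id = f"read_{i + 1:07d}"
        reads.append(ReadRecord(read_id, seq, qual))
        rows.append(
            {
                "read_id": read_id,
                "source_ref": ref_id,
                "biotype": biotype,
                "insert_start": start,
                "insert_end": end,
                "tagged": tagged,
                "n_seq_errors": n_err,
                **extras,
            }
        )
    truth = pd.DataFrame(rows)
    return reads, truth


def write_bundle(bundle: ReferenceBundle, out_dir) -> dict[str, Path]:
    """Write FASTA per biotype, the ss file and the subunit table; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for biotype, rs in bundle.reference_sets.items():
        p = out / f"{biotype}.fa"
        fio.write_fasta(rs.entries, p)
        paths[biotype] = p
    if bundle.structures:
        p = out / "tRNA.ss"
        seqs = bundle.sequences
        with open(p, "w") as fh:
            for rid, ss in bundle.structures.items():
                fh.write(f">{rid}\n{seqs[rid]}\n{ss.pairing}\n")
        paths["ss"] = p
    if bundle.subunits:
        p = out / "subunits.tsv"
        with open(p, "w") as fh:
            fh.write("# 1-based inclusive coordinates\nref_id\tstart\tend\tsubunit_id\n")
            for rid, subs in bundle.subunits.items():
                for sub_id, s, e in subs:
                    fh.write(f"{rid}\t{s}\t{e}\t{sub_id}\n")
        paths["subunits"] = p
    return paths


def write_simulation(reads: Sequence[ReadRecord], truth: pd.DataFrame, out_dir) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fq = out / "reads.fastq"
    fio.write_fastq(reads, fq)
    tt = out / "truth.tsv"
    truth.to_csv(tt, sep="\t", index=False)
    return {"fastq": fq, "truth": tt}
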