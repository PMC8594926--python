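# Methods

This note documents the models, conventions and numerical choices behind
`fivexp`, and what the synthetic-data generator does and does not emulate.

## Preprocessing model

Reads are processed in four stages, in this order: two-colour quality trim →
3´ adapter trim → 5´ tag split → whole-read quality filter. The order of
quality filtering relative to tag splitting is not uniquely determined by
the underlying trimming recipes; we filter last so both sub-libraries pass
through identical criteria, and document that choice here.

**Two-colour (NextSeq-type) quality trimming.** On two-colour instruments a
dark cycle reads as G, so G carries no evidence at the 3´ end. Each base is
given an effective quality (0 for G, its Phred score otherwise), and the
read is cut by the standard running-sum rule: walking from the 3´ end
accumulating `qcut − q_effective` (default `qcut`=20), the cut is placed
where the running sum is maximal; the walk stops once the sum turns
negative. Consequence worth knowing: a confident non-G base *between* two
trailing G runs can be removed together with them — that is the rule, not a
bug.

**Adapter search.** Ungapped comparison of the 36-nt adapter against every
start position: the full adapter anywhere, or an adapter *prefix* of at
least `min_overlap` (5) bases running to the read's 3´ end. A candidate
qualifies when its mismatch count ≤ `floor(max_error_rate × matched
length)` with `max_error_rate`=0.1 (the conventional trimmer default; the
source recipe prints no rate). Among qualifying candidates the longest
match wins, then the fewest mismatches, then the leftmost position. N never
matches anything. Reads with no qualifying occurrence are discarded
("untrimmed"), as are inserts outside 5–70 nt. The search is verified
against a brute-force scan over all (position, length) candidates.

**Tag split.** Exact prefix match of the 11-nt tag by default
(`tag_max_mismatch`=0). An 11-nt tag at a 10% error tolerance would admit
one mismatch; we default strict because a mis-assigned read corrupts *both*
sub-libraries, and expose the relaxed behaviour as a parameter. De-tagged
reads shorter than `min_len` are discarded.

**Quality filter.** Keep iff the fraction of bases with Q ≥ 20 is ≥ 0.8.
The comparison is ≥/≥ (the semantics of the classic FASTX filter), although
prose descriptions of this filter often say "> 20 in more than 80%"; both
thresholds are parameters.

Accounting is exact by construction: each input read is either emitted in
one sub-library or attributed to exactly one named discard reason
(`no_adapter`, `insert_length`, `detag_short`, `low_quality`).

## Counting and normalisation

Counting is sequence-based: the unique read string is the unit, so
annotation mismatches never alter the count matrix. Per-sample library
totals are fixed at counting time (retained reads), and cpm = count /
library total × 10⁶ always uses that denominator — recomputing totals after
abundance filtering would silently change what "10 cpm" means. The two
standard filters (≥5 counts in 100% of scoped samples; ≥10 cpm in 100% of
scoped samples) are per-row predicates and therefore order-independent.
Sequences containing N are counted verbatim and flagged.

## Annotation ladder

Full-query, ungapped Hamming placement only (no indels, no clipping, no
seed heuristics): in the short-fragment/short-reference regime this is both
adequate and exactly checkable against a brute-force oracle. Annotation
proceeds in cycles t = 0..3; a sequence is searched in cycle t only if no
reference set matched it in cycle t−1, so `mismatch_tier` is the minimal
Hamming distance tier. Within a cycle, the set with the best priority rank
wins (`miRNA > Mt_tRNA > tRNA > MT_rRNA > rRNA > piRNA > other_sncRNA`).
Within the winning set the representative hit is deterministic: fewest
mismatches, then lexicographically smallest `ref_id`, then smallest start.
Searches run on the sense strand by default (fragments derive from the
mature reference's sense); reverse-complement search is a flag. N counts as
a mismatch at every position, including N–N.

## Fragment classification

**Terminals.** `five_prime` starts at base 1 of the mature reference,
`three_prime` ends at its last base, `full` does both, `internal` neither.
"Terminal" means the exact first/last base; no tolerance is applied (a
configurable ±k offset was considered and left at 0 because no principled
default exists). `full` fragments form their own class rather than being
double-counted, and are excluded from the 5´/i´/3´ enrichment fractions.

**Loops.** The `ss` parser takes unpaired runs whose immediate neighbours
are `>` and `<` as hairpin loops — such flanking positions are necessarily
pairing partners — and labels them D, anticodon, T in 5´→3´ order; an
unpaired run of length ≥4 between the anticodon and T hairpins, flanked by
`<`…`>`, is the variable loop. Records without exactly three hairpins are
flagged unusable. Balance of the pairing string is validated.

**Cleavage convention.** A fragment's 5´ boundary is the phosphodiester
bond before `start`; a boundary lies "in a loop" when the nucleotide on the
bond's 5´ side (position `start−1`, resp. `end`) falls inside the loop
interval. Boundaries at the molecule's termini carry no loop label. Then:
`tiRNA_half` = a 5´ fragment ending in the anticodon loop or a 3´ fragment
starting from it (the angiogenin-style half); `nitRNA_like` = an internal
fragment with a boundary in the T loop. The nitRNA definition in the
literature is qualitative; this flag is a declared operational rule and is
labelled as such in outputs.

**rRFs.** A fragment is assigned to the mature subunit containing its
midpoint (`(start+end)//2`); fragments whose midpoint falls in a spacer are
unassigned. This spanning-fragment rule is our choice — subunit-annotated
references do not dictate one. Terminal class is then computed against the
subunit's own boundaries.

**Coverage.** `values[p] = Σ cpm` over fragments covering p;
multi-sample profiles are per-sample means. Conservation
(`Σ_p values[p] = Σ cpm·length`) is tested.

## Summaries

* Size distribution and first-nt bias are cpm-weighted and conserve total
  cpm / normalise to 1 per biotype (N reported separately, T displayed
  as U).
* log2 fold difference per sequence: `log2((mean_A + pc)/(mean_B + pc))`
  with pseudocount 1 cpm (sources reporting >20-fold tails for
  absent-in-one-method sequences print no pseudocount; 1 cpm is the
  conventional choice and is a parameter). Direction is sign-only by
  default, with an optional dead-band threshold.
* Correlation: Pearson on log2(cpm+1), average linkage on 1−r (both
  configurable). A constant sample column raises an error naming the
  sample.
* Saturation: subsample without replacement at a grid of fractions (3
  replicates averaged, seeded), count distinct sequences reaching the count
  threshold, and fit `Asym + (R0 − Asym)·exp(−exp(lrc)·d)` by nonlinear
  least squares. Initial values are self-starting: `Asym₀` = 1.05 × max
  richness, `R0₀` = richness at the shallowest depth, `lrc₀` from a
  log-linear probe of the residual decay. A perfectly flat richness profile
  (e.g. a single-sequence library) short-circuits to `Asym = R0 =`
  the observed constant. Non-convergence returns the raw points with a
  diagnostic flag instead of parameters.

## The synthetic-data generator

The generator emulates the *input* of a tagged sRNA run: each read is
`[tag if tagged] + insert + adapter + random tail`, truncated to the read
length (default 75 nt), with per-base substitution errors applied to the
insert and Phred qualities drawn from a clamped normal. Defaults: tag
`TGGCAACGATC`, adapter `AGATCGGAAGAGCACACGTCTGAACTCCAGTCACAT`,
`p_tagged` = 0.15 (tag sub-libraries typically run 10–20% of a library;
the true tagging efficiency is a free experimental parameter, not something
the generator estimates), `error_rate` = 0.001.

Insert models per biotype are chosen to hit every classifier branch:
miRNA 22±1 and piRNA 28±2 nt anchored at base 1 (piRNA references carry an
80% 5´-U bias); tRNA/Mt_tRNA fragments use loop-anchored breakpoints on a
generated cloverleaf (5´ fragments end in the anticodon or D loop, 3´
fragments start from the anticodon or T loop, internal fragments span
D→anticodon, anticodon→T or D→T) with class weights defaulting to
0.4/0.2/0.4; rRNA fragments are placed 5´/internal/3´ relative to a mature
subunit of a 300-nt precursor (18S/5.8S/28S-style intervals). Cloverleaf
geometry: 7-bp acceptor stem, 4-bp D stem with an 8–14 nt loop, 5-bp
anticodon stem with a 7-nt loop holding the anticodon at the molecule's
centre, 4-nt variable region, 5-bp T stem with a 7-nt loop, NCCA tail
(total 75–81 nt). Loop intervals are computed from this layout
arithmetically, so the structure parser can be tested against them
independently.

Substitution errors are applied to the insert only — the tag and adapter
are copied faithfully. This keeps the tag split and adapter trim exercised
separately from the error model; a tag sequencing error under the strict
split would demote a read to the no-tag library, which is a real failure
mode of the assay that the generator deliberately does not model (no
quantitative error model for it exists). Also not modelled: PCR
duplicates, ligation bias, RNA-modification-induced misincorporation, and
5´-ligation efficiency. Passing tests on these fixtures therefore
demonstrates the correctness of the *computational* pipeline, not
robustness to those bench-side biases.

All randomness flows through a single `numpy.random.default_rng(seed)`;
identical parameters give byte-identical FASTQ and truth tables.

## Problem sizes

The test suite and the acceptance script run at desk scale: 10⁴–10⁵
simulated reads per scenario, 10³ aligner-oracle pairs, a 500-sequence pool
at 10× depth for saturation. These sizes keep every stochastic check well
inside its tolerance (binomial noise at n = 10⁴ is ~0.5 percentage points
for the 60/10/30 fragment-split recovery, against a 2-point band) while the
whole suite completes in well under a minute of compute.

## Known limitations

* Single-end reads only; no UMIs, no paired-end, no vendor barcode
  demultiplexing.
* No genome mapping or spliced alignment; annotation is against mature
  sRNA references only.
* The annotation ladder reports one representative hit; multi-mapping
  ambiguity within a biotype is resolved deterministically, not
  probabilistically.
* isodecoder parsing assumes `tRNA-<AminoAcid><Anticodon>-<n>` reference
  ids; other dialects need a user-supplied regex.
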