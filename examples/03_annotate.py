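"""Hierarchical mismatch annotation and its tie-break rules.

Sequences are searched against biotype references in cycles of increasing
mismatch allowance (0..3). Fewer mismatches always win; within a cycle the
priority ladder miRNA > Mt_tRNA > tRNA > MT_rRNA > rRNA > piRNA >
other_sncRNA decides.
"""

from fivexp import ReferenceSet, annotate_hierarchical

seq = "ACGTACGTACGTACGTACGTAC"
one_mismatch_away = "T" + seq[1:]

# case 1: the sequence is an exact piRNA but one mismatch from a miRNA
sets = [ReferenceSet("miRNA", 1, [("mir-1", one_mismatch_away)]),
        ReferenceSet("piRNA", 6, [("piRNA-1", seq)])]
rec = annotate_hierarchical([seq], sets)[seq]
print(f"piRNA exact vs miRNA 1mm -> {rec.biotype} (tier {rec.mismatch_tier})")

# case 2: exact hit in both databases -> the ladder prefers miRNA
sets = [ReferenceSet("miRNA", 1, [("mir-1", seq)]),
        ReferenceSet("piRNA", 6, [("piRNA-1", seq)])]
rec = annotate_hierarchical([seq], sets)[seq]
print(f"both exact               -> {rec.biotype} (tier {rec.mismatch_tier})")

# a sequence matching nothing within 3 mismatches stays unannotated
rec = annotate_hierarchical(["TTTTTTTTTTTTTTTTTTTTTT"], sets)["TTTTTTTTTTTTTTTTTTTTTT"]
print(f"no reference match       -> {rec.status}")
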