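"""Unique-sequence counting, the 5-count / 10-cpm filters and cpm scaling.

Counts are keyed by the read sequence itself, so annotation never changes
the matrix; library totals are fixed before filtering so cpm thresholds keep
their meaning.
"""

from fivexp import (
    PreprocessParams,
    SimulationParams,
    count_unique,
    filter_min_count,
    filter_min_cpm,
    make_reference_bundle,
    normalize_cpm,
    preprocess_sample,
    simulate_reads,
)

bundle = make_reference_bundle(seed=2, counts_per_biotype={"miRNA": 6, "piRNA": 8})
reads, _ = simulate_reads(bundle, SimulationParams(seed=2, n_reads=10_000, p_tagged=0.5))
p_tag, x_notag, _ = preprocess_sample(reads, PreprocessParams())

table = count_unique({"tag": p_tag, "notag": x_notag})
print("unique sequences:", len(table.sequences))
print("library totals  :", dict(table.library_totals))

cpm = normalize_cpm(table)
print("cpm column sums :", cpm.values.sum(axis=0).round(3).to_dict())  # = 1e6

noise_filtered = filter_min_count(table, min_count=5)
abundant = filter_min_cpm(normalize_cpm(noise_filtered), min_cpm=10)
print("pass >=5 counts in all samples:", len(noise_filtered.sequences))
print("pass >=10 cpm in all samples  :", len(abundant.values))
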