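"""Library summaries: sizes, 5'-U bias, fold changes, clustering, saturation.

Runs the descriptive analytics on a zero-noise simulated run and prints the
numbers a method-comparison figure would be built from.
"""

import numpy as np

from fivexp import (
    PreprocessParams,
    SimulationParams,
    annotate_hierarchical,
    correlation_cluster,
    count_unique,
    first_nt_bias,
    log2_fold,
    make_reference_bundle,
    normalize_cpm,
    preprocess_sample,
    saturation_curve,
    simulate_reads,
    size_distribution,
)

bundle = make_reference_bundle(seed=5, counts_per_biotype={
    "miRNA": 6, "piRNA": 8, "tRNA": 4, "rRNA": 2})
reads, _ = simulate_reads(bundle, SimulationParams(
    seed=5, n_reads=10_000, p_tagged=0.5, error_rate=0.0,
    quality_sd=0.0, quality_mean=40.0))
p_tag, x_notag, _ = preprocess_sample(reads, PreprocessParams())

cpm = normalize_cpm(count_unique({"tag": p_tag, "notag": x_notag}))
records = annotate_hierarchical(list(cpm.values.index),
                                list(bundle.reference_sets.values()))

dist = size_distribution(cpm.values, records)["mean_cpm"]
print("modal miRNA length:", dist.loc["miRNA"].idxmax(), "nt")
print("modal piRNA length:", dist.loc["piRNA"].idxmax(), "nt")

bias = first_nt_bias(cpm.values, records)
print("piRNA 1st-nt U fraction:", round(float(bias.loc['piRNA', 'U']), 3))

fc = log2_fold(cpm.values, ["tag"], ["notag"], pseudocount=1.0)
print(f"tag vs notag: {fc.pct_up:.1f}% up, {fc.pct_down:.1f}% down, "
      f"{fc.pct_unchanged:.1f}% unchanged")

corr, order = correlation_cluster(cpm.values.assign(
    tag2=lambda d: d["tag"] * 1.01, notag2=lambda d: d["notag"] * 0.99))
print("cluster leaf order:", order)

rng = np.random.default_rng(5)
pool = [f"seq{i}" for i in range(500)]
lib = [pool[i] for i in rng.integers(0, 500, size=5000)]
fit = saturation_curve(lib, seed=6)
print(f"saturation: Asym={fit.Asym:.1f} (true pool 500), "
      f"richness at full depth={fit.richness[-1]:.0f}")
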