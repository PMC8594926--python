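"""Descriptive analytics: size distributions, 1st-nt bias, fold changes,
correlation/clustering and saturation fitting."""

import numpy as np
import pandas as pd
import pytest

from fivexp import (
    AnnotationRecord,
    correlation_cluster,
    first_nt_bias,
    log2_fold,
    saturation_curve,
    size_distribution,
)


def annotated(seq, biotype):
    return AnnotationRecord(seq, "annotated", biotype, 0)


class TestSizeDistribution:
    def test_single_sequence_lands_in_its_cell(self):
        seq = "A" * 22
        cpm = pd.DataFrame({"s1": [50.0]}, index=[seq])
        records = {seq: annotated(seq, "miRNA")}
        dist = size_distribution(cpm, records)
        assert dist.loc[("miRNA", 22), "mean_cpm"] == 50.0
        assert dist["mean_cpm"].sum() == 50.0

    def test_total_cpm_conserved(self):
        seqs = ["A" * 20, "C" * 25, "G" * 30]
        cpm = pd.DataFrame({"s1": [10.0, 20.0, 30.0], "s2": [5.0, 5.0, 5.0]}, index=seqs)
        records = {seqs[0]: annotated(seqs[0], "miRNA"),
                   seqs[1]: annotated(seqs[1], "piRNA"),
                   seqs[2]: AnnotationRecord(seqs[2], "unannotated")}
        dist = size_distribution(cpm, records)
        assert dist["mean_cpm"].sum() == pytest.approx(cpm.mean(axis=1).sum())
        assert dist.loc[("unannotated", 30), "mean_cpm"] == pytest.approx(17.5)

    def test_fixture_mirna_mode_at_22(self, bundle, zero_noise_run):
        from fivexp import count_unique, normalize_cpm, preprocess_sample, annotate_hierarchical
        reads, truth = zero_noise_run
        p_tag, x_notag, _ = preprocess_sample(reads)
        cpm = normalize_cpm(count_unique({"tag": p_tag, "notag": x_notag}))
        records = annotate_hierarchical(list(cpm.values.index),
                                        list(bundle.reference_sets.values()))
        dist = size_distribution(cpm.values, records)["mean_cpm"]
        mirna = dist.loc["miRNA"]
        assert mirna.idxmax() == 22  # insert lengths drawn ~N(22, 1)


class TestFirstNtBias:
    def test_all_t_starts_report_full_u(self):
        seqs = ["TAAA", "TCCC"]
        cpm = pd.DataFrame({"s1": [1.0, 1.0]}, index=seqs)
        records = {s: annotated(s, "piRNA") for s in seqs}
        bias = first_nt_bias(cpm, records)
        assert bias.loc["piRNA", "U"] == pytest.approx(1.0)

    def test_equal_split(self):
        seqs = ["TAAA", "AAAA"]
        cpm = pd.DataFrame({"s1": [3.0, 3.0]}, index=seqs)
        records = {s: annotated(s, "piRNA") for s in seqs}
        bias = first_nt_bias(cpm, records)
        assert bias.loc["piRNA", "U"] == pytest.approx(0.5)
        assert bias.loc["piRNA", "A"] == pytest.approx(0.5)

    def test_fixture_pirna_u_bias_near_80pct(self, bundle, zero_noise_run):
        from fivexp import count_unique, normalize_cpm, preprocess_sample, annotate_hierarchical
        reads, _ = zero_noise_run
        p_tag, x_notag, _ = preprocess_sample(reads)
        cpm = normalize_cpm(count_unique({"tag": p_tag, "notag": x_notag}))
        records = annotate_hierarchical(list(cpm.values.index),
                                        list(bundle.reference_sets.values()))
        bias = first_nt_bias(cpm.values, records)
        # piRNA references are built with an 80% 5'-U start bias; with 8
        # references the realised fraction is binomial around 0.8
        assert bias.loc["piRNA", "U"] > 0.5


class TestLog2Fold:
    def cpm(self):
        return pd.DataFrame({"a1": [10.0, 0.0, 7.0], "a2": [10.0, 0.0, 9.0],
                             "b1": [10.0, 15.0, 1.0], "b2": [10.0, 15.0, 3.0]},
                            index=["X", "Y", "Z"])

    def test_equal_means_give_zero(self):
        res = log2_fold(self.cpm(), ["a1", "a2"], ["b1", "b2"])
        assert res.table.loc["X", "log2fc"] == 0.0
        assert res.table.loc["X", "direction"] == "unchanged"

    def test_absent_in_one_group_with_pseudocount(self):
        res = log2_fold(self.cpm(), ["a1", "a2"], ["b1", "b2"], pseudocount=1.0)
        assert res.table.loc["Y", "log2fc"] == pytest.approx(-4.0)  # log2(1/16)
        assert res.table.loc["Y", "direction"] == "down"

    def test_antisymmetry(self):
        ab = log2_fold(self.cpm(), ["a1", "a2"], ["b1", "b2"]).table["log2fc"]
        ba = log2_fold(self.cpm(), ["b1", "b2"], ["a1", "a2"]).table["log2fc"]
        assert np.allclose(ab, -ba)

    def test_percentages_cover_all_sequences(self):
        res = log2_fold(self.cpm(), ["a1", "a2"], ["b1", "b2"])
        assert res.pct_up + res.pct_down + res.pct_unchanged == pytest.approx(100.0)

    def test_magnitude_grows_with_present_group_cpm(self):
        cpm = pd.DataFrame({"a": [0.0, 0.0], "b": [20.0, 2000.0]}, index=["lo", "hi"])
        res = log2_fold(cpm, ["a"], ["b"], pseudocount=1.0)
        assert abs(res.table.loc["hi", "log2fc"]) > abs(res.table.loc["lo", "log2fc"])

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            log2_fold(self.cpm(), [], ["b1"])


class TestCorrelationCluster:
    def make_blocks(self):
        rng = np.random.default_rng(5)
        block1 = rng.random(40) * 100
        block2 = rng.random(40) * 100
        data = {
            "a1": np.concatenate([block1, np.zeros(40)]) + rng.random(80),
            "a2": np.concatenate([block1 * 1.1, np.zeros(40)]) + rng.random(80),
            "b1": np.concatenate([np.zeros(40), block2]) + rng.random(80),
            "b2": np.concatenate([np.zeros(40), block2 * 0.9]) + rng.random(80),
        }
        return pd.DataFrame(data)

    def test_duplicated_sample_has_unit_correlation(self):
        df = self.make_blocks()
        df["a1_copy"] = df["a1"]
        corr, _ = correlation_cluster(df)
        assert corr.loc["a1", "a1_copy"] == pytest.approx(1.0)

    def test_symmetric_unit_diagonal(self):
        corr, _ = correlation_cluster(self.make_blocks())
        assert np.allclose(corr, corr.T)
        assert np.allclose(np.diag(corr), 1.0)

    def test_blocks_cluster_together(self):
        corr, order = correlation_cluster(self.make_blocks())
        groups = ["".join(s[0]) for s in order]
        assert "".join(groups) in ("aabb", "bbaa")

    def test_sample_permutation_leaves_r_values(self):
        df = self.make_blocks()
        corr1, _ = correlation_cluster(df)
        corr2, _ = correlation_cluster(df[["b2", "a1", "b1", "a2"]])
        assert corr2.loc["a1", "b1"] == pytest.approx(corr1.loc["a1", "b1"])

    def test_constant_column_rejected_by_name(self):
        df = self.make_blocks()
        df["flat"] = 3.0
        with pytest.raises(ValueError, match="flat"):
            correlation_cluster(df)


class TestSaturation:
    def test_single_sequence_library(self):
        fit = saturation_curve(["ACGT"] * 500, seed=1)
        assert all(r == 1.0 for r in fit.richness)
        if fit.converged:
            assert fit.Asym == pytest.approx(1.0, abs=0.05)

    def test_full_fraction_equals_library_distinct_count(self):
        reads = ["A", "B", "C", "A", "A", "B"]
        fit = saturation_curve(reads, fractions=(0.5, 1.0), threshold=1, seed=2)
        assert fit.richness[-1] == 3.0
        fit2 = saturation_curve(reads, fractions=(1.0,), threshold=2, seed=2)
        assert fit2.richness[-1] == 2.0  # only A and B reach 2 counts

    def test_recovers_pool_size_from_deep_library(self):
        """Reads drawn uniformly from a 500-sequence pool at 10x depth:
        the fitted asymptote approximates the pool size."""
        rng = np.random.default_rng(3)
        pool = [f"seq{i}" for i in range(500)]
        reads = [pool[i] for i in rng.integers(0, 500, size=5000)]
        fit = saturation_curve(reads, fractions=(0.02, 0.05, 0.1, 0.2, 0.4, 0.7, 1.0),
                               threshold=1, n_reps=3, seed=4)
        assert fit.converged
        assert fit.Asym == pytest.approx(500, rel=0.15)

    def test_richness_non_decreasing_in_expectation(self):
        rng = np.random.default_rng(6)
        reads = [f"s{i}" for i in rng.integers(0, 200, size=2000)]
        fit = saturation_curve(reads, n_reps=5, seed=7)
        assert all(b >= a - 1 for a, b in zip(fit.richness, fit.richness[1:]))
        if fit.converged and fit.Asym > fit.R0:
            assert all(fit.Asym >= f - 1e-6 for f in fit.fitted)

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            saturation_curve(["A"], fractions=(0.0, 1.0))
        with pytest.raises(ValueError):
            saturation_curve([], fractions=(1.0,))
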