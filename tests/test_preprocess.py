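"""Preprocessing: two-colour trimming, adapter removal, tag split, QC filter."""

import random

import pytest

from fivexp import (
    DEFAULT_ADAPTER,
    DEFAULT_TAG,
    P_TAG,
    X_NOTAG,
    PreprocessParams,
    ReadRecord,
    preprocess_sample,
    quality_filter,
    split_by_tag,
    trim_three_prime_adapter,
    trim_two_color_tail,
)
from fivexp.preprocess import find_adapter
from fivexp.records import quality_string


def read(seq: str, quals=None) -> ReadRecord:
    if quals is None:
        quals = [40] * len(seq)
    elif isinstance(quals, int):
        quals = [quals] * len(seq)
    return ReadRecord("r1", seq, quality_string(quals))


class TestTwoColorTrim:
    def test_confident_read_unchanged(self):
        r = read("ACGTACGTAC", 40)
        assert trim_two_color_tail(r).sequence == "ACGTACGTAC"

    def test_trailing_g_run_removed_despite_reported_quality(self):
        # G bases are treated as quality 0, so a trailing G run is cut even at Q35
        r = read("ACGTACGT" + "GGGG", [40] * 8 + [35] * 4)
        assert trim_two_color_tail(r, qcut=20).sequence == "ACGTACGT"

    def test_all_g_low_quality_read_trims_to_empty(self):
        r = read("GGGGGGGG", 2)
        assert trim_two_color_tail(r).sequence == ""

    def test_low_quality_tail_removed(self):
        r = read("ACGTACATAC", [40] * 7 + [2, 2, 2])
        assert trim_two_color_tail(r, qcut=20).sequence == "ACGTACA"

    def test_never_lengthens_and_quality_stays_aligned(self):
        rng = random.Random(0)
        for _ in range(200):
            n = rng.randint(1, 60)
            r = read("".join(rng.choice("ACGT") for _ in range(n)),
                     [rng.randint(2, 40) for _ in range(n)])
            t = trim_two_color_tail(r)
            assert len(t) <= len(r)
            assert t.sequence == r.sequence[: len(t)]
            assert len(t.sequence) == len(t.quality)


class TestAdapterTrim:
    def test_full_adapter_removed(self, params):
        insert = "ACGTACGTACGTACGTACGTAC"
        r = read(insert + DEFAULT_ADAPTER)
        assert trim_three_prime_adapter(r, params).sequence == insert

    def test_five_nt_adapter_prefix_suffices(self, params):
        insert = "ACGTACGTACGTACGTACGTAC"
        r = read(insert + DEFAULT_ADAPTER[:5])
        assert trim_three_prime_adapter(r, params).sequence == insert

    def test_four_nt_prefix_is_untrimmed_discard(self, params):
        r = read("ACGTACGTACGTACGTACGTAC" + DEFAULT_ADAPTER[:4])
        assert trim_three_prime_adapter(r, params) is None

    def test_short_insert_discarded(self, params):
        r = read("ACGT" + DEFAULT_ADAPTER)
        assert trim_three_prime_adapter(r, params) is None

    def test_long_insert_discarded(self, params):
        r = read("A" * 71 + DEFAULT_ADAPTER)
        assert trim_three_prime_adapter(r, params) is None

    def test_everything_past_adapter_removed(self, params):
        insert = "TTTTTCCCCCAAAAA"
        r = read(insert + DEFAULT_ADAPTER + "GATTACAGATTACA")
        assert trim_three_prime_adapter(r, params).sequence == insert

    def test_mismatch_tolerance_scales_with_matched_length(self, params):
        insert = "ACGTACGTACGTACGTACGTAC"
        adapter = list(DEFAULT_ADAPTER)
        adapter[3] = "C" if adapter[3] != "C" else "G"
        adapter[20] = "C" if adapter[20] != "C" else "G"
        # 2 errors in 36 matched bases <= floor(0.1*36)=3 -> trimmed
        assert trim_three_prime_adapter(read(insert + "".join(adapter)), params).sequence == insert
        # but 1 error in a 5-nt overlap (floor(0.1*5)=0) -> discard
        r = read(insert + "C" + DEFAULT_ADAPTER[1:5])
        assert trim_three_prime_adapter(r, params) is None

    def test_n_never_matches(self, params):
        insert = "ACGTACGTACGTACGTACGTAC"
        r = read(insert + "N" + DEFAULT_ADAPTER[1:5])
        assert trim_three_prime_adapter(r, params) is None

    def test_idempotent_on_own_output(self, params):
        rng = random.Random(1)
        for _ in range(100):
            insert = "".join(rng.choice("ACGT") for _ in range(rng.randint(5, 40)))
            r = read(insert + DEFAULT_ADAPTER[: rng.randint(5, 36)])
            out = trim_three_prime_adapter(r, params)
            if out is None:
                continue
            # adapter never survives trimming: re-trimming discards or is identity
            out2 = trim_three_prime_adapter(out, params)
            assert out2 is None or out2.sequence == out.sequence


def brute_force_adapter(seq, adapter, min_overlap, rate):
    """Independent oracle: scan all (position, matched-length) candidates."""
    best = None
    for p in range(len(seq)):
        for L in range(min_overlap, len(adapter) + 1):
            if p + L > len(seq):
                continue
            if L < len(adapter) and p + L != len(seq):
                continue  # partial adapter must end the read
            window = seq[p : p + L]
            mm = sum(1 for a, b in zip(window, adapter[:L]) if a != b or a == "N")
            if mm <= int(rate * L):
                cand = (L, -mm, -p)
                if best is None or cand > best:
                    best = cand
    return None if best is None else (-best[2], best[0], -best[1])


def test_adapter_search_matches_brute_force_oracle():
    """On random reads <=70 nt the fast search equals an all-(position,length) scan."""
    rng = random.Random(42)
    for _ in range(400):
        n = rng.randint(5, 70)
        seq = "".join(rng.choice("ACGTN" if rng.random() < 0.05 else "ACGT") for _ in range(n))
        if rng.random() < 0.5:  # plant a (possibly mutated) adapter piece
            piece = list(DEFAULT_ADAPTER[: rng.randint(3, 36)])
            for _ in range(rng.randint(0, 3)):
                piece[rng.randrange(len(piece))] = rng.choice("ACGT")
            keep = rng.randint(0, max(0, n - len(piece)))
            seq = seq[:keep] + "".join(piece) + seq[keep + len(piece):]
            seq = seq[:n]
        got = find_adapter(seq, DEFAULT_ADAPTER, 5, 0.1)
        expected = brute_force_adapter(seq, DEFAULT_ADAPTER, 5, 0.1)
        assert got == expected, seq


class TestQualityFilter:
    def test_nine_of_ten_good_bases_kept(self):
        assert quality_filter(read("ACGTACGTAC", [30] * 9 + [10]))

    def test_all_high_quality_kept(self):
        assert quality_filter(read("ACGTACGTAC", 40))

    def test_seven_of_ten_discarded(self):
        assert not quality_filter(read("ACGTACGTAC", [30] * 7 + [10] * 3))

    def test_boundary_is_inclusive(self):
        # exactly 80% at exactly Q20 keeps (tool semantics: >=/>=)
        assert quality_filter(read("ACGTA", [20, 20, 20, 20, 10]))


class TestTagSplit:
    def test_tagged_read_detagged(self, params):
        insert = "ACGTACGTACGTACGTACGTA"
        label, out = split_by_tag(read(DEFAULT_TAG + insert), params)
        assert (label, out.sequence) == (P_TAG, insert)

    def test_untagged_read_unchanged(self, params):
        r = read("ACGTACGTACGTACGTACGTA")
        label, out = split_by_tag(r, params)
        assert (label, out.sequence) == (X_NOTAG, r.sequence)

    def test_short_detagged_read_discarded(self, params):
        assert split_by_tag(read(DEFAULT_TAG + "AAA"), params) is None

    def test_read_shorter_than_tag_is_notag(self, params):
        r = read(DEFAULT_TAG[:6])
        assert split_by_tag(r, params)[0] == X_NOTAG

    def test_one_mismatch_rejected_by_default_but_allowed_when_relaxed(self):
        insert = "ACGTACGTACGTACGTACGTA"
        mutated = "A" + DEFAULT_TAG[1:] if DEFAULT_TAG[0] != "A" else "C" + DEFAULT_TAG[1:]
        strict = PreprocessParams()
        relaxed = PreprocessParams(tag_max_mismatch=1)
        assert split_by_tag(read(mutated + insert), strict)[0] == X_NOTAG
        assert split_by_tag(read(mutated + insert), relaxed)[0] == P_TAG


class TestPreprocessSample:
    def test_partition_exact(self, bundle):
        from fivexp import simulate_reads
        from conftest import ideal_params
        reads, _ = simulate_reads(bundle, ideal_params(
            seed=3, n_reads=1500, error_rate=0.01, quality_sd=3.0,
            quality_mean=33.0, low_quality_fraction=0.1))
        _, _, stats = preprocess_sample(reads)
        assert stats.n_in == 1500
        assert stats.n_in == stats.n_p_tag + stats.n_x_notag + stats.n_discarded

    def test_no_tagged_reads_when_p_tagged_zero(self, bundle):
        from fivexp import simulate_reads
        from conftest import ideal_params
        reads, truth = simulate_reads(bundle, ideal_params(seed=4, n_reads=500, p_tagged=0.0))
        assert not truth.tagged.any()
        p_tag, _, _ = preprocess_sample(reads)
        assert p_tag == []

    def test_retention_derivable_from_truth(self, zero_noise_run):
        reads, truth = zero_noise_run
        _, _, stats = preprocess_sample(reads)
        lengths = truth.insert_end - truth.insert_start + 1
        expected = ((lengths >= 5) & (lengths <= 70)).sum()
        assert stats.n_retained == expected

    def test_empty_input(self):
        p_tag, x_notag, stats = preprocess_sample([])
        assert (p_tag, x_notag, stats.n_in) == ([], [], 0)

    def test_malformed_fastq_reports_location(self, tmp_path):
        from fivexp.io import read_fastq
        bad = tmp_path / "bad.fq"
        bad.write_text("@r1\nACGT\n+\nIIII\n@r2\nACGT\nxxx\n")
        with pytest.raises(ValueError, match="record 2"):
            list(read_fastq(bad))

    def test_no_stage_lengthens_a_read(self, bundle):
        from fivexp import simulate_reads
        from fivexp.preprocess import preprocess_read
        from conftest import ideal_params
        reads, _ = simulate_reads(bundle, ideal_params(seed=5, n_reads=300,
                                                       error_rate=0.02, quality_sd=4.0))
        for r in reads:
            _, final, reason = preprocess_read(r, PreprocessParams())
            if final is not None:
                assert len(final) <= len(r)
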