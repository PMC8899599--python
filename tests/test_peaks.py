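import numpy as np
import pytest

from meripkit.intervals import GenomicInterval, ReadSet, TranscriptModel, merge
from meripkit.peaks import (Peak, call_peaks_window, combine_across_samples,
                            consensus_two_callers, filter_tss_m6am,
                            locate_summits, poisson_tail)
from oracles import (brute_intersect, brute_support, exact_poisson_tail,
                     random_intervals)


# ------------------------------------------------------------ Poisson test
def test_poisson_tail_matches_exact_sum():
    """Window p-values agree with a 50-digit tail sum to 1e-12 for
    counts up to 200."""
    rng = np.random.default_rng(0)
    ks = rng.integers(0, 201, size=60)
    lams = rng.uniform(0.1, 200.0, size=60)
    for k, lam in zip(ks, lams):
        assert poisson_tail(int(k), float(lam)) == pytest.approx(
            exact_poisson_tail(int(k), float(lam)), abs=1e-12)


def test_count_equal_to_expectation_is_not_significant():
    # P(X >= 10 | lam = 10) ~ 0.542: never significant at any sane alpha
    p = float(poisson_tail(10, 10.0))
    assert p == pytest.approx(0.5421, abs=1e-4)


def _uniform_readset(rng, n, span, read_len=50):
    starts = rng.integers(0, span - read_len, n)
    return ReadSet.from_arrays({"c": (starts, starts + read_len)})


def test_caller_type_one_error_is_controlled():
    """With IP and input drawn from the same uniform model, false-positive
    windows stay at or below alpha (one-sided, 3 SE slack)."""
    span, alpha = 100_000, 0.01
    total_windows = 0
    false_pos = 0
    for seed in range(5):
        rng = np.random.default_rng(100 + seed)
        ip = _uniform_readset(rng, 20_000, span)
        inp = _uniform_readset(rng, 20_000, span)
        peaks = call_peaks_window(ip, inp, {"c": span}, window=100, step=100,
                                  alpha=alpha)
        n_windows = span // 100
        total_windows += n_windows
        false_pos += sum(p.interval.length // 100 for p in peaks)
    expected = alpha * total_windows
    assert false_pos <= expected + 3 * np.sqrt(expected)


def test_planted_excess_detected_at_stringent_alpha():
    """An 8-fold IP excess over ~50 input reads per window is found at
    alpha 1e-6."""
    span = 10_000
    rng = np.random.default_rng(42)
    inp = _uniform_readset(rng, 3300, span)
    bg = rng.integers(0, span - 50, 3300)
    extra = rng.integers(4975, 5050, 350)  # reads overlapping [5000, 5100)
    starts = np.concatenate([bg, extra])
    ip = ReadSet.from_arrays({"c": (starts, starts + 50)})
    peaks = call_peaks_window(ip, inp, {"c": span}, alpha=1e-6)
    target = GenomicInterval("c", 5000, 5100)
    assert any(p.interval.overlaps(target) for p in peaks)


def test_zero_library_rejected():
    rs = ReadSet.from_arrays({"c": (np.array([0]), np.array([50]))})
    with pytest.raises(ValueError):
        call_peaks_window(rs, ReadSet(), {"c": 1000})


def test_summits_sit_on_signal_maximum():
    span = 2000
    rng = np.random.default_rng(7)
    inp = _uniform_readset(rng, 500, span)
    peak_reads = np.full(200, 975)  # all IP excess piled at [975, 1025)
    starts = np.concatenate([rng.integers(0, span - 50, 500), peak_reads])
    ip = ReadSet.from_arrays({"c": (starts, starts + 50)})
    peaks = call_peaks_window(ip, inp, {"c": span}, alpha=1e-4)
    peaks = locate_summits(peaks, [ip], [inp], {"c": span})
    target = next(p for p in peaks if p.interval.start <= 1000 < p.interval.end)
    assert 975 <= target.summit < 1025
    assert target.interval.start <= target.summit < target.interval.end


# ------------------------------------------------------------- consensus
def test_consensus_example():
    a = [GenomicInterval("c", 100, 300)]
    b = [GenomicInterval("c", 200, 400)]
    assert consensus_two_callers(a, b) == [GenomicInterval("c", 200, 300)]


def test_consensus_with_empty_side_is_empty():
    assert consensus_two_callers([GenomicInterval("c", 0, 10)], []) == []
    assert consensus_two_callers([], []) == []


def test_consensus_matches_perbase_oracle(rng):
    span = 1500
    for _ in range(30):
        a = random_intervals(rng, 25, span)
        b = random_intervals(rng, 25, span)
        assert consensus_two_callers(a, b) == \
            merge(brute_intersect(a, b, "chr1", span))


# -------------------------------------------------------- support filter
def test_support_threshold_examples():
    region = GenomicInterval("c", 100, 200)
    per_sample = {f"s{i}": [] for i in range(16)}
    per_sample["s0"] = [region]
    assert combine_across_samples(per_sample, min_support=2) == []
    per_sample["s1"] = [GenomicInterval("c", 150, 250)]
    peaks = combine_across_samples(per_sample, min_support=2)
    assert len(peaks) == 1
    assert peaks[0].n_support == 2
    assert peaks[0].support == ("s0", "s1")


def test_min_support_validation():
    with pytest.raises(ValueError):
        combine_across_samples({"s": []}, min_support=0)


def test_support_counts_match_bruteforce(rng):
    span = 2000
    for _ in range(20):
        per_sample = {f"s{i}": random_intervals(rng, int(rng.integers(1, 15)), span)
                      for i in range(5)}
        candidates = merge([iv for ivs in per_sample.values() for iv in ivs])
        retained = {p.interval: p for p in
                    combine_across_samples(per_sample, min_support=2)}
        for cand in candidates:
            expected = brute_support(cand, per_sample)
            if expected >= 2:
                assert retained[cand].n_support == expected
            else:
                assert cand not in retained


# ------------------------------------------------------------ TSS filter
def _chr_p_setup(tss_context: str):
    """Plus-strand transcript on chrP with a controlled TSS context;
    ``tss_context`` gives bases at genomic 49, 50 (= TSS), 51."""
    tm = TranscriptModel("txP", "gP", "chrP", "+",
                         (GenomicInterval("chrP", 50, 650, "+"),),
                         cds_start=150, cds_end=450)
    seq = list("G" * 700)
    seq[49:52] = list(tss_context)
    return [tm], {"chrP": "".join(seq)}


def test_tss_a_start_peak_removed():
    tms, seqs = _chr_p_setup("GAG")  # first transcribed base is A
    peak = Peak(GenomicInterval("chrP", 40, 120))
    kept, removed = filter_tss_m6am([peak], tms, seqs)
    assert kept == [] and removed == [peak]


def test_tss_bca_peak_removed():
    tms, seqs = _chr_p_setup("GCA")  # -1..+1 = G,C,A matches BCA
    peak = Peak(GenomicInterval("chrP", 40, 120))
    kept, removed = filter_tss_m6am([peak], tms, seqs)
    assert kept == [] and len(removed) == 1


def test_tss_neutral_context_kept():
    tms, seqs = _chr_p_setup("GGG")
    peak = Peak(GenomicInterval("chrP", 40, 120))
    kept, removed = filter_tss_m6am([peak], tms, seqs)
    assert removed == [] and kept == [peak]


def test_cds_peak_kept_regardless_of_sequence():
    tms, seqs = _chr_p_setup("GAG")
    peak = Peak(GenomicInterval("chrP", 200, 300))
    kept, removed = filter_tss_m6am([peak], tms, seqs)
    assert kept == [peak]


def test_5utr_peak_not_covering_tss_kept():
    tms, seqs = _chr_p_setup("GAG")
    peak = Peak(GenomicInterval("chrP", 80, 140))  # 5'UTR but TSS not covered
    kept, removed = filter_tss_m6am([peak], tms, seqs)
    assert kept == [peak]
    # the config switch drops it when coverage is not required
    kept2, removed2 = filter_tss_m6am([peak], tms, seqs, require_tss_cover=False)
    assert removed2 == [peak]


def test_tss_filter_minus_strand_orientation():
    """BCA is read in transcript orientation on the minus strand."""
    tm = TranscriptModel("txM", "gM", "chrM", "-",
                         (GenomicInterval("chrM", 50, 650, "-"),),
                         cds_start=250, cds_end=550)
    seq = list("G" * 700)
    # transcript-orientation -1..+1 = revcomp(seq[648:651]) -> want B,C,A
    seq[648] = "T"   # +1 -> A
    seq[649] = "G"   # TSS -> C
    seq[650] = "C"   # -1 -> G (a valid B)
    peak = Peak(GenomicInterval("chrM", 600, 660))
    kept, removed = filter_tss_m6am([peak], [tm], {"chrM": "".join(seq)})
    assert removed == [peak]


def test_unassigned_peak_passes_with_warning():
    tms, seqs = _chr_p_setup("GGG")
    peak = Peak(GenomicInterval("chrOther", 0, 50))
    with pytest.warns(UserWarning):
        kept, _ = filter_tss_m6am([peak], tms, seqs)
    assert kept == [peak]
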