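import numpy as np
import pytest
from scipy import stats

from meripkit.annotate import (REGION_NONCODING, REGION_START, REGION_STOP,
                               REGION_UNASSIGNED, TranscriptIndex,
                               assign_region, compare_to_reference,
                               metagene_profile, motif_enrichment,
                               scan_motif)
from meripkit.intervals import (GenomicInterval, TranscriptModel, REGION_5UTR,
                                REGION_CDS, REGION_3UTR)
from meripkit.peaks import Peak
from meripkit.seq import revcomp
from oracles import brute_region_map, random_intervals


def _big_transcript():
    # 5'UTR 300, CDS 3000, 3'UTR 500 on contig [100, 3900+100)
    return TranscriptModel("txB", "gB", "chrB", "+",
                           (GenomicInterval("chrB", 100, 3900, "+"),),
                           cds_start=400, cds_end=3400)


def test_assign_region_interior_and_windows():
    tm = _big_transcript()
    index = TranscriptIndex([tm])
    mid_cds = 400 + 1500
    assert assign_region(Peak(GenomicInterval("chrB", mid_cds - 50, mid_cds + 50),
                              summit=mid_cds), index) == REGION_CDS
    ten_past_stop = 3399 + 10  # 10 nt 3' of the stop codon
    assert assign_region(
        Peak(GenomicInterval("chrB", ten_past_stop - 20, ten_past_stop + 20),
             summit=ten_past_stop), index) == REGION_STOP
    assert assign_region(Peak(GenomicInterval("chrB", 420, 460), summit=440),
                         index) == REGION_START
    assert assign_region(Peak(GenomicInterval("chr_none", 0, 10)),
                         index) == REGION_UNASSIGNED


def test_assign_region_noncoding():
    nc = TranscriptModel("nc", "g", "c", "+", (GenomicInterval("c", 0, 500, "+"),))
    assert assign_region(Peak(GenomicInterval("c", 100, 150)),
                         TranscriptIndex([nc])) == REGION_NONCODING


@pytest.mark.parametrize("fixture", ["plus_transcript", "minus_transcript",
                                     "multiexon_transcript"])
def test_assign_region_matches_perbase_oracle(fixture, request, rng):
    """1000 random summits labelled identically to a spliced-coordinate walk."""
    tm = request.getfixturevalue(fixture)
    index = TranscriptIndex([tm])
    oracle = brute_region_map(tm, codon_window=50)
    positions = list(oracle)
    for pos in rng.choice(positions, size=1000):
        pk = Peak(GenomicInterval(tm.chrom, int(pos), int(pos) + 1),
                  summit=int(pos))
        assert assign_region(pk, index, codon_window=50) == oracle[int(pos)]


def test_longest_coding_transcript_wins():
    short = TranscriptModel("short", "g", "c", "+",
                            (GenomicInterval("c", 0, 500, "+"),), 100, 400)
    long = TranscriptModel("long", "g", "c", "+",
                           (GenomicInterval("c", 0, 900, "+"),), 100, 700)
    nc = TranscriptModel("nc", "g", "c", "+", (GenomicInterval("c", 0, 2000, "+"),))
    index = TranscriptIndex([short, long, nc])
    assert index.assign(GenomicInterval("c", 200, 250)).transcript_id == "long"


# ----------------------------------------------------------------- metagene
def test_metagene_point_mass(plus_transcript):
    tm = plus_transcript
    pos = tm.spliced_to_genomic(100 + 150)  # CDS fraction 0.5
    profile = metagene_profile([Peak(GenomicInterval(tm.chrom, pos, pos + 1),
                                     summit=pos)], [tm])
    assert profile.density.sum() == pytest.approx(1.0)
    assert profile.n_mapped == 1
    assert profile.density[20 + 25] == pytest.approx(1.0)  # middle CDS bin


def test_metagene_uniform_summits_are_flat(plus_transcript, rng):
    """Uniform spliced positions give within-region flat densities
    (chi-square GOF not rejected at 0.01, n = 5000)."""
    tm = plus_transcript
    peaks = []
    for idx in rng.integers(0, tm.mature_length, 5000):
        g = tm.spliced_to_genomic(int(idx))
        peaks.append(Peak(GenomicInterval(tm.chrom, g, g + 1), summit=g))
    profile = metagene_profile(peaks, [tm])
    assert profile.density.sum() == pytest.approx(1.0)
    counts = profile.density * profile.n_mapped
    for lo, hi in ((0, 20), (20, 70), (70, 100)):
        observed = counts[lo:hi]
        _, p = stats.chisquare(observed)
        assert p > 0.01


def test_metagene_skips_nonmapping_peaks(plus_transcript):
    profile = metagene_profile([Peak(GenomicInterval("elsewhere", 0, 10))],
                               [plus_transcript])
    assert profile.n_mapped == 0 and profile.n_skipped == 1
    assert profile.density.sum() == 0.0


# ------------------------------------------------------------------- motifs
def test_scan_motif_examples():
    assert scan_motif("TTGGACTT", "GGACT") == [2]
    assert scan_motif("GGACT", "DRACH") == [0]
    assert scan_motif("AAAA", "AA") == [0, 1, 2]  # overlapping matches


def test_scan_motif_minus_strand_coordinates():
    seq = "TTAGTCCTT"  # revcomp contains GGACT at rc position 2
    hits = scan_motif(seq, "GGACT", strand="-")
    assert hits == [2]
    assert revcomp(seq[2:7]) == "GGACT"


def test_scan_motif_matches_sliding_window_oracle(rng):
    seq = "".join(rng.choice(list("ACGT"), size=10_000))
    iupac = {"D": "AGT", "R": "AG", "H": "ACT", "A": "A", "C": "C"}
    pattern = "DRACH"
    expected = [i for i in range(len(seq) - 4)
                if all(seq[i + j] in iupac[pattern[j]] for j in range(5))]
    assert scan_motif(seq, pattern) == expected
    # strand symmetry: minus-strand scan equals plus-strand scan of revcomp
    minus = scan_motif(seq, pattern, strand="-")
    rc_hits = scan_motif(revcomp(seq), pattern)
    assert sorted(len(seq) - h - 5 for h in rc_hits) == minus


def test_motif_enrichment_null_behavior(rng):
    seqs = ["".join(rng.choice(list("ACGT"), size=80)) for _ in range(40)]
    fold, p = motif_enrichment(seqs, "GGACT", n_shuffles=100, seed=1)
    assert 1 / 101 <= p <= 1.0
    assert p > 0.01
    assert 0.3 < fold < 3.0


def test_motif_enrichment_detects_planted_motifs(rng):
    seqs = []
    for _ in range(200):
        s = list(rng.choice(list("ACG"), size=50))  # T-free background
        s[20:25] = list("GGACT")
        seqs.append("".join(s))
    fold, p = motif_enrichment(seqs, "GGACT", n_shuffles=100, seed=2)
    assert fold > 2.0
    assert p == pytest.approx(1 / 101)


def test_motif_enrichment_validation():
    with pytest.raises(ValueError):
        motif_enrichment([], "GGACT")
    with pytest.raises(ValueError):
        motif_enrichment(["ACGT"], "GGACT", n_shuffles=10)


# --------------------------------------------------------------- reference
def test_reference_overlap_printed_parity():
    """6,546 of 6,877 peaks containing a recorded site is 95.19%."""
    peaks = [GenomicInterval("c", i * 100, i * 100 + 50) for i in range(6877)]
    sites = [GenomicInterval("c", i * 100 + 10, i * 100 + 11)
             for i in range(6546)]
    assert compare_to_reference(peaks, sites) == (6546, 95.19)


def test_reference_overlap_empty_cases():
    peaks = [GenomicInterval("c", 0, 100)]
    assert compare_to_reference(peaks, []) == (0, 0.0)
    with pytest.raises(ValueError):
        compare_to_reference([], peaks)


def test_reference_overlap_matches_bruteforce(rng):
    span = 3000
    for _ in range(30):
        peaks = random_intervals(rng, 30, span, max_len=120)
        sites = random_intervals(rng, 40, span, max_len=3)
        expected = sum(
            1 for p in peaks
            if any(s.chrom == p.chrom and s.start < p.end and p.start < s.end
                   for s in sites))
        n, pct = compare_to_reference(peaks, sites)
        assert n == expected
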