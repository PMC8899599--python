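"""Independent brute-force oracles used across the test suite.

Every oracle works per-base or by exhaustive enumeration and shares no
code with the implementation it checks.
"""

from __future__ import annotations

import itertools
from fractions import Fraction

import mpmath
import numpy as np

from meripkit.intervals import GenomicInterval


def covered_bases(intervals, span: int) -> np.ndarray:
    """Boolean per-base membership over [0, span) for a single chromosome."""
    mask = np.zeros(span, dtype=bool)
    for iv in intervals:
        mask[iv.start:min(iv.end, span)] = True
    return mask


def runlength_intervals(mask: np.ndarray, chrom: str) -> list[GenomicInterval]:
    """Maximal runs of True as intervals."""
    out = []
    in_run = False
    start = 0
    for i, v in enumerate(mask):
        if v and not in_run:
            start, in_run = i, True
        elif not v and in_run:
            out.append(GenomicInterval(chrom, start, i))
            in_run = False
    if in_run:
        out.append(GenomicInterval(chrom, start, len(mask)))
    return out


def brute_union(intervals, chrom: str, span: int) -> list[GenomicInterval]:
    return runlength_intervals(covered_bases(intervals, span), chrom)


def brute_intersect(a, b, chrom: str, span: int) -> list[GenomicInterval]:
    mask = covered_bases(a, span) & covered_bases(b, span)
    return runlength_intervals(mask, chrom)


def brute_overlap_count(queries, reads) -> list[int]:
    """All-pairs >=1 bp overlap counting."""
    out = []
    for q in queries:
        n = 0
        for r in reads:
            if r.chrom == q.chrom and r.start < q.end and q.start < r.end:
                n += 1
        out.append(n)
    return out


def brute_support(candidate, per_sample) -> int:
    """Number of samples with >= 1 bp overlap of the candidate region."""
    n = 0
    for ivs in per_sample.values():
        if any(iv.chrom == candidate.chrom and iv.start < candidate.end
               and candidate.start < iv.end for iv in ivs):
            n += 1
    return n


def exact_poisson_tail(k: int, lam: float) -> float:
    """P(X >= k) for X ~ Poisson(lam) at 50-digit precision."""
    with mpmath.workdps(50):
        if k <= 0:
            return 1.0
        s = mpmath.mpf(0)
        for j in range(k):
            s += mpmath.exp(-lam) * mpmath.mpf(lam) ** j / mpmath.factorial(j)
        return float(1 - s)


def hypergeom_tail_enumerated(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) by counting all C(N, n) draws, exactly (rationals)."""
    total = Fraction(0)
    comb = _comb
    denom = comb(N, n)
    for j in range(k, min(K, n) + 1):
        total += Fraction(comb(K, j) * comb(N - K, n - j), denom)
    return float(total)


def hypergeom_tail_itertools(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) by literally enumerating every n-subset of the universe."""
    hits = 0
    total = 0
    members = set(range(K))
    for draw in itertools.combinations(range(N), n):
        total += 1
        if len(members.intersection(draw)) >= k:
            hits += 1
    return hits / total


def _comb(n: int, k: int) -> int:
    import math

    return math.comb(n, k)


def brute_region_map(tm, codon_window: int = 100) -> dict[int, str]:
    """Genomic position -> region label by walking every spliced base."""
    from meripkit.annotate import (REGION_START, REGION_STOP)
    from meripkit.intervals import REGION_5UTR, REGION_CDS, REGION_3UTR

    u5, cds, u3 = tm.region_lengths()
    out = {}
    for idx in range(tm.mature_length):
        d_start = idx - u5
        d_stop = idx - (u5 + cds - 1)
        if abs(d_start) <= codon_window and abs(d_stop) <= codon_window:
            lab = REGION_START if abs(d_start) <= abs(d_stop) else REGION_STOP
        elif abs(d_start) <= codon_window:
            lab = REGION_START
        elif abs(d_stop) <= codon_window:
            lab = REGION_STOP
        elif idx < u5:
            lab = REGION_5UTR
        elif idx < u5 + cds:
            lab = REGION_CDS
        else:
            lab = REGION_3UTR
        out[tm.spliced_to_genomic(idx)] = lab
    return out


def brute_profile(signal_intervals, anchors, flank: int, bin_width: int) -> np.ndarray:
    """Per-bin mean per-base coverage, summed per anchor then averaged."""
    n_bins = 2 * flank // bin_width
    acc = np.zeros(n_bins)
    for chrom, pos, *rest in anchors:
        strand = rest[0] if rest else "."
        cov = np.zeros(2 * flank)
        for off in range(-flank, flank):
            g = pos + off
            c = sum(1 for iv in signal_intervals
                    if iv.chrom == chrom and iv.start <= g < iv.end)
            cov[off + flank] = c
        if strand == "-":
            cov = cov[::-1]
        acc += cov.reshape(n_bins, bin_width).mean(axis=1)
    return acc / len(anchors)


def random_intervals(rng, n: int, span: int, chrom: str = "chr1",
                     max_len: int = 60) -> list[GenomicInterval]:
    out = []
    for _ in range(n):
        s = int(rng.integers(0, span - 1))
        ln = int(rng.integers(1, max_len))
        out.append(GenomicInterval(chrom, s, min(s + ln, span)))
    return out
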