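"""Peak construction: Poisson window caller, two-caller consensus,
cross-sample support filtering and the 5'UTR TSS m6Am filter.

The built-in caller is a deliberately simple sliding-window test — for
each window the IP read count is compared against the library-size-scaled
input count under a one-sided exact Poisson tail — standing in for
external callers whose peak BEDs can equally be imported. Everything
downstream (consensus, support, filters) is identical for imported and
built-in peaks.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .intervals import GenomicInterval, ReadSet, TranscriptModel, intersect, merge

logger = logging.getLogger(__name__)


@dataclass
class Peak:
    """A (consensus) peak interval with provenance and per-sample support."""

    interval: GenomicInterval
    summit: int | None = None
    support: tuple[str, ...] = ()
    provenance: tuple[str, ...] = ()
    score: float = 0.0  # -log10 of the best window p-value, if called here

    def __post_init__(self) -> None:
        if self.summit is not None and not (
                self.interval.start <= self.summit < self.interval.end):
            raise ValueError("summit outside peak interval")

    @property
    def n_support(self) -> int:
        return len(self.support)

    @property
    def anchor(self) -> int:
        """Position used for annotation: the summit, else the midpoint."""
        return self.summit if self.summit is not None else self.interval.midpoint


def poisson_tail(k: int | np.ndarray, lam: float | np.ndarray):
    """Exact one-sided upper tail P(X >= k) for X ~ Poisson(lam)."""
    return stats.poisson.sf(np.asarray(k) - 1, lam)


def call_peaks_window(ip: ReadSet, inp: ReadSet, chrom_sizes: Mapping[str, int],
                      window: int = 100, step: int = 50,
                      alpha: float = 1e-6, bg_flank: int = 2500,
                      caller: str = "window-poisson") -> list[Peak]:
    """One-sided Poisson window test of IP excess over scaled input.

    The expected IP count of a window is estimated from the input reads
    in a wider local background region (the window extended by
    ``bg_flank`` on each side, clipped to the chromosome), rescaled to
    the window's read-capture length and the IP/input library-size
    ratio, and floored at one read. Using a wide background keeps the
    input-count noise from inflating the test's size while still
    tracking transcript-level expression differences. Windows with
    exact Poisson upper-tail p < ``alpha`` are merged into peaks.
    Summits are left unset (use :func:`locate_summits` with the
    underlying reads).
    """
    if not (window >= step > 0):
        raise ValueError("need window >= step > 0")
    if ip.n_reads == 0 or inp.n_reads == 0:
        raise ValueError("zero library size")
    lib_ratio = ip.n_reads / inp.n_reads
    rl = inp.mean_read_length
    peaks: list[Peak] = []
    for chrom in sorted(chrom_sizes):
        size = chrom_sizes[chrom]
        if size < window:
            continue
        win_starts = np.arange(0, size - window + 1, step, dtype=np.int64)
        win_ends = win_starts + window
        k_ip = ip.window_counts(chrom, win_starts, win_ends)
        bg_starts = np.maximum(win_starts - bg_flank, 0)
        bg_ends = np.minimum(win_ends + bg_flank, size)
        k_bg = inp.window_counts(chrom, bg_starts, bg_ends)
        # capture length of a window for reads of mean length rl
        scale = (window + rl - 1) / (bg_ends - bg_starts + rl - 1)
        lam = np.maximum(k_bg * scale, 1.0) * lib_ratio
        with np.errstate(divide="ignore"):
            p = poisson_tail(k_ip, lam)
        sig = p < alpha
        if not sig.any():
            continue
        # merge significant (overlapping or book-ended) windows
        ivs = [GenomicInterval(chrom, int(s), int(e))
               for s, e in zip(win_starts[sig], win_ends[sig])]
        merged = merge(ivs)
        best = {}
        for iv, pv in zip(ivs, p[sig]):
            for m in merged:
                if iv.overlaps(m):
                    best[m] = min(best.get(m, 1.0), float(pv))
        for m in merged:
            score = float(-np.log10(max(best[m], 1e-300)))
            peaks.append(Peak(m, provenance=(caller,), score=score))
    return peaks


def consensus_two_callers(peaks_a: Sequence[Peak | GenomicInterval],
                          peaks_b: Sequence[Peak | GenomicInterval]
                          ) -> list[GenomicInterval]:
    """Regions identified by both callers in one sample: base-wise
    intersection, then merged."""
    a = [_as_interval(p) for p in peaks_a]
    b = [_as_interval(p) for p in peaks_b]
    if not a or not b:
        return []
    return merge(intersect(a, b))


def _as_interval(p) -> GenomicInterval:
    return p.interval if isinstance(p, Peak) else p


def combine_across_samples(per_sample: Mapping[str, Sequence[Peak | GenomicInterval]],
                           min_support: int = 2) -> list[Peak]:
    """Merge per-sample peak sets and keep regions detected in at least
    ``min_support`` samples (>= 1 bp overlap counts as detection)."""
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    if not per_sample:
        return []
    all_ivs = [_as_interval(p) for ivs in per_sample.values() for p in ivs]
    candidates = merge(all_ivs)
    # per-sample sorted interval bounds for overlap queries
    indexed: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    for sample, ivs in per_sample.items():
        per_chrom: dict[str, tuple[list, list]] = {}
        for p in ivs:
            iv = _as_interval(p)
            s, e = per_chrom.setdefault(iv.chrom, ([], []))
            s.append(iv.start)
            e.append(iv.end)
        indexed[sample] = {c: (np.sort(np.array(s)), np.sort(np.array(e)))
                           for c, (s, e) in per_chrom.items()}
    out: list[Peak] = []
    for cand in candidates:
        supp = []
        for sample, chroms in indexed.items():
            if cand.chrom not in chroms:
                continue
            starts, ends = chroms[cand.chrom]
            n = (np.searchsorted(starts, cand.end, side="left")
                 - np.searchsorted(ends, cand.start, side="right"))
            if n > 0:
                supp.append(sample)
        if len(supp) >= min_support:
            out.append(Peak(cand, support=tuple(sorted(supp))))
    return out


def locate_summits(peaks: Sequence[Peak], ip_reads: Iterable[ReadSet],
                   input_reads: Iterable[ReadSet],
                   chrom_sizes: Mapping[str, int]) -> list[Peak]:
    """Set each peak's summit to the maximum of pooled IP minus
    library-scaled pooled input coverage (leftmost base on ties)."""
    ip_reads = list(ip_reads)
    input_reads = list(input_reads)
    lib_ip = sum(r.n_reads for r in ip_reads)
    lib_in = sum(r.n_reads for r in input_reads)
    scale = lib_ip / lib_in if lib_in else 1.0
    cov_cache: dict[str, np.ndarray] = {}
    out = []
    for pk in peaks:
        chrom = pk.interval.chrom
        if chrom not in cov_cache:
            n = chrom_sizes[chrom]
            ipc = np.zeros(n, dtype=float)
            inc = np.zeros(n, dtype=float)
            for r in ip_reads:
                ipc += r.coverage(chrom, n)
            for r in input_reads:
                inc += r.coverage(chrom, n)
            cov_cache[chrom] = ipc - scale * inc
        diff = cov_cache[chrom][pk.interval.start:pk.interval.end]
        summit = pk.interval.start + int(np.argmax(diff))
        out.append(replace(pk, summit=summit))
    return out


def filter_tss_m6am(peaks: Sequence[Peak], transcripts: Sequence[TranscriptModel],
                    sequences: Mapping[str, str],
                    require_tss_cover: bool = True) -> tuple[list[Peak], list[Peak]]:
    """Remove 5'UTR peaks attributable to cap-adjacent m6Am at the TSS.

    A peak is dropped when it is assigned to the 5'UTR and (with
    ``require_tss_cover``, the default) its interval covers the TSS of
    its transcript, and the first transcribed base is A, or the
    TSS-centered trinucleotide (positions -1..+1 in transcript
    orientation) matches B-C-A (IUPAC B = C/G/T). Returns
    (kept, removed).
    """
    from .annotate import TranscriptIndex
    from .seq import revcomp

    index = TranscriptIndex(transcripts)
    kept: list[Peak] = []
    removed: list[Peak] = []
    for pk in peaks:
        tm = index.assign(pk.interval)
        if tm is None:
            warnings.warn(f"peak {pk.interval} has no transcript assignment; kept")
            kept.append(pk)
            continue
        is_m6am = False
        if tm.is_coding:
            try:
                region, _ = tm.genomic_to_metagene(pk.anchor)
            except ValueError:
                region = None
            tss = tm.tss
            covers = pk.interval.start <= tss < pk.interval.end
            if region == "5'UTR" and (covers or not require_tss_cover):
                seq = sequences[tm.chrom]
                if tm.strand == "+":
                    first = seq[tss]
                    tri = seq[tss - 1:tss + 2] if tss >= 1 else ""
                else:
                    first = revcomp(seq[tss])
                    tri = revcomp(seq[tss - 1:tss + 2]) if tss + 2 <= len(seq) else ""
                if first == "A":
                    is_m6am = True
                elif len(tri) == 3 and tri[0] in "CGT" and tri[1] == "C" and tri[2] == "A":
                    is_m6am = True
        (removed if is_m6am else kept).append(pk)
    return kept, removed
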