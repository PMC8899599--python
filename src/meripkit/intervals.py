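"""Genomic interval arithmetic and transcript coordinate geometry.

Every coordinate inside the package is 0-based, half-open (the BED
convention). GTF input, which is 1-based and closed, is converted at read
time in :mod:`meripkit.io` so that no other module ever sees a 1-based
number.

``intersect`` and ``merge`` are strand-blind by default because peak calls
are genomic features; transcript anatomy (``TranscriptModel``) is always
strand-aware.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

STRANDS = ("+", "-", ".")

REGION_5UTR = "5'UTR"
REGION_CDS = "CDS"
REGION_3UTR = "3'UTR"


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic span: ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(f"empty or inverted interval: [{self.start}, {self.end})")
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval", stranded: bool = False) -> bool:
        if self.chrom != other.chrom:
            return False
        if stranded and self.strand != other.strand and "." not in (self.strand, other.strand):
            return False
        return self.start < other.end and other.start < self.end


def _group_key(iv: GenomicInterval, stranded: bool):
    return (iv.chrom, iv.strand) if stranded else (iv.chrom,)


def _sweep_union(pairs: list[tuple[int, int]], gap: int) -> list[tuple[int, int]]:
    pairs.sort()
    out: list[tuple[int, int]] = []
    cs, ce = pairs[0]
    for s, e in pairs[1:]:
        if s <= ce + gap:
            ce = max(ce, e)
        else:
            out.append((cs, ce))
            cs, ce = s, e
    out.append((cs, ce))
    return out


def merge(intervals: Iterable[GenomicInterval], gap: int = 0,
          stranded: bool = False) -> list[GenomicInterval]:
    """Union overlapping or near-by intervals.

    Intervals closer than or exactly ``gap`` bases apart are joined;
    ``gap=0`` joins book-ended intervals (``[0,10)`` + ``[10,20)`` →
    ``[0,20)``). Output is disjoint and sorted, and covers exactly the
    same bases as the input (plus bridged gaps).
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    groups: dict[tuple, list[tuple[int, int]]] = {}
    for iv in intervals:
        groups.setdefault(_group_key(iv, stranded), []).append((iv.start, iv.end))
    out: list[GenomicInterval] = []
    for key in sorted(groups):
        strand = key[1] if stranded else "."
        for s, e in _sweep_union(groups[key], gap):
            out.append(GenomicInterval(key[0], s, e, strand))
    return out


def intersect(a: Iterable[GenomicInterval], b: Iterable[GenomicInterval],
              stranded: bool = False) -> list[GenomicInterval]:
    """Base-wise intersection of two interval sets.

    Returns the maximal intervals covered by at least one member of each
    set; output is disjoint and sorted.
    """
    ga: dict[tuple, list[tuple[int, int]]] = {}
    gb: dict[tuple, list[tuple[int, int]]] = {}
    for iv in a:
        ga.setdefault(_group_key(iv, stranded), []).append((iv.start, iv.end))
    for iv in b:
        gb.setdefault(_group_key(iv, stranded), []).append((iv.start, iv.end))
    out: list[GenomicInterval] = []
    for key in sorted(set(ga) & set(gb)):
        ua = _sweep_union(ga[key], 0)
        ub = _sweep_union(gb[key], 0)
        strand = key[1] if stranded else "."
        i = j = 0
        while i < len(ua) and j < len(ub):
            s = max(ua[i][0], ub[j][0])
            e = min(ua[i][1], ub[j][1])
            if s < e:
                out.append(GenomicInterval(key[0], s, e, strand))
            if ua[i][1] <= ub[j][1]:
                i += 1
            else:
                j += 1
    return out


def total_length(intervals: Iterable[GenomicInterval]) -> int:
    return sum(iv.length for iv in merge(intervals))


@dataclass
class TranscriptModel:
    """Exon/CDS anatomy of one transcript.

    ``cds_start``/``cds_end`` delimit the genomic CDS span (half-open,
    including the stop codon) and are ``None`` for non-coding
    transcripts. Spliced ("mature transcript") coordinates run 5'→3' on
    the transcript strand, position 0 being the first transcribed base
    (the TSS).
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[GenomicInterval, ...]
    cds_start: int | None = None
    cds_end: int | None = None

    _cum: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"transcript strand must be +/-: {self.strand!r}")
        exons = tuple(sorted(self.exons, key=lambda e: e.start))
        for prev, nxt in zip(exons, exons[1:]):
            if nxt.start < prev.end:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        object.__setattr__(self, "exons", exons)
        lens = np.array([e.length for e in exons], dtype=np.int64)
        object.__setattr__(self, "_cum", np.concatenate([[0], np.cumsum(lens)]))
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError("cds_start and cds_end must both be set or both be None")
        if self.cds_start is not None:
            if not self.cds_start < self.cds_end:
                raise ValueError("empty CDS")
            # both CDS boundaries must fall inside exons
            self.genomic_to_spliced(self.cds_start)
            self.genomic_to_spliced(self.cds_end - 1)

    # -- basic anatomy -------------------------------------------------
    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None

    @property
    def mature_length(self) -> int:
        return int(self._cum[-1])

    @property
    def tss(self) -> int:
        """Genomic coordinate of the first transcribed base."""
        if self.strand == "+":
            return self.exons[0].start
        return self.exons[-1].end - 1

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.exons[0].start,
                               self.exons[-1].end, self.strand)

    # -- coordinate conversion -----------------------------------------
    def genomic_to_spliced(self, pos: int) -> int:
        """Map a genomic position inside an exon to a spliced coordinate."""
        for i, ex in enumerate(self.exons):
            if ex.start <= pos < ex.end:
                plus_idx = int(self._cum[i]) + (pos - ex.start)
                if self.strand == "+":
                    return plus_idx
                return self.mature_length - 1 - plus_idx
        raise ValueError(
            f"position {pos} is intronic or outside transcript {self.transcript_id}")

    def spliced_to_genomic(self, idx: int) -> int:
        if not 0 <= idx < self.mature_length:
            raise ValueError(f"spliced index {idx} out of range")
        plus_idx = idx if self.strand == "+" else self.mature_length - 1 - idx
        i = int(np.searchsorted(self._cum, plus_idx, side="right")) - 1
        return self.exons[i].start + (plus_idx - int(self._cum[i]))

    # -- CDS anatomy in spliced coordinates ----------------------------
    def region_lengths(self) -> tuple[int, int, int]:
        """(5'UTR, CDS, 3'UTR) lengths in mature-transcript nt."""
        if not self.is_coding:
            raise ValueError(f"{self.transcript_id} is non-coding")
        if self.strand == "+":
            first_cds = self.genomic_to_spliced(self.cds_start)
            last_cds = self.genomic_to_spliced(self.cds_end - 1)
        else:
            first_cds = self.genomic_to_spliced(self.cds_end - 1)
            last_cds = self.genomic_to_spliced(self.cds_start)
        u5 = first_cds
        cds = last_cds - first_cds + 1
        u3 = self.mature_length - u5 - cds
        return u5, cds, u3

    def genomic_to_metagene(self, pos: int) -> tuple[str, float]:
        """Map an exonic genomic position to (region, fractional position).

        The fraction is the position's offset within its region divided
        by the region length, measured 5'→3' on the transcript strand;
        the first base of a region maps to fraction 0.0.
        """
        idx = self.genomic_to_spliced(pos)
        u5, cds, u3 = self.region_lengths()
        if idx < u5:
            return REGION_5UTR, idx / u5
        if idx < u5 + cds:
            return REGION_CDS, (idx - u5) / cds
        return REGION_3UTR, (idx - u5 - cds) / u3

    def spliced_sequence(self, genome: dict[str, str]) -> str:
        from .seq import revcomp

        seq = "".join(genome[self.chrom][e.start:e.end] for e in self.exons)
        return revcomp(seq) if self.strand == "-" else seq


class ReadSet:
    """A set of read intervals on a genome, the unit of library storage.

    Internally two sorted arrays per chromosome (starts and ends,
    independently sorted) so that the number of reads overlapping
    ``[s, e)`` is ``#(start < e) - #(end <= s)`` — exact ≥1 bp overlap
    counting in O(log n) per query.
    """

    def __init__(self) -> None:
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self.n_reads = 0
        self._total_bases = 0

    @property
    def mean_read_length(self) -> float:
        return self._total_bases / self.n_reads if self.n_reads else 0.0

    @classmethod
    def from_arrays(cls, per_chrom: dict[str, tuple[np.ndarray, np.ndarray]]) -> "ReadSet":
        rs = cls()
        for chrom, (starts, ends) in per_chrom.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            if starts.size:
                rs._starts[chrom] = np.sort(starts)
                rs._ends[chrom] = np.sort(ends)
                rs.n_reads += int(starts.size)
                rs._total_bases += int(ends.sum() - starts.sum())
        return rs

    @classmethod
    def from_intervals(cls, intervals: Iterable[GenomicInterval]) -> "ReadSet":
        per: dict[str, tuple[list[int], list[int]]] = {}
        for iv in intervals:
            s, e = per.setdefault(iv.chrom, ([], []))
            s.append(iv.start)
            e.append(iv.end)
        return cls.from_arrays(
            {c: (np.array(s), np.array(e)) for c, (s, e) in per.items()})

    @property
    def chroms(self) -> list[str]:
        return sorted(self._starts)

    def count_overlapping(self, intervals: Sequence[GenomicInterval]) -> np.ndarray:
        """Reads overlapping each query by >= 1 bp (a read may count twice
        across two queries)."""
        out = np.zeros(len(intervals), dtype=np.int64)
        for i, iv in enumerate(intervals):
            starts = self._starts.get(iv.chrom)
            if starts is None:
                continue
            ends = self._ends[iv.chrom]
            out[i] = (np.searchsorted(starts, iv.end, side="left")
                      - np.searchsorted(ends, iv.start, side="right"))
        return out

    def window_counts(self, chrom: str, win_starts: np.ndarray,
                      win_ends: np.ndarray) -> np.ndarray:
        starts = self._starts.get(chrom)
        if starts is None:
            return np.zeros(len(win_starts), dtype=np.int64)
        ends = self._ends[chrom]
        return (np.searchsorted(starts, win_ends, side="left")
                - np.searchsorted(ends, win_starts, side="right"))

    def coverage(self, chrom: str, length: int) -> np.ndarray:
        """Per-base read coverage over ``[0, length)`` of one chromosome."""
        cov = np.zeros(length + 1, dtype=np.int64)
        starts = self._starts.get(chrom)
        if starts is not None:
            ends = self._ends[chrom]
            np.add.at(cov, np.clip(starts, 0, length), 1)
            np.add.at(cov, np.clip(ends, 0, length), -1)
        return np.cumsum(cov)[:length]

    def iter_intervals(self, chrom: str):
        """Yield (start, end) pairs; only valid when all reads on the
        chromosome have equal length (starts and ends then pair up after
        independent sorting)."""
        starts = self._starts.get(chrom)
        if starts is None:
            return
        yield from zip(starts.tolist(), self._ends[chrom].tolist())


@dataclass
class CoverageTrack:
    """Per-base non-negative counts per chromosome plus the library size."""

    data: dict[str, np.ndarray]
    library_size: int

    def __post_init__(self) -> None:
        for chrom, arr in self.data.items():
            arr = np.asarray(arr)
            if (arr < 0).any():
                raise ValueError(f"negative coverage on {chrom}")
            self.data[chrom] = arr

    @classmethod
    def from_reads(cls, reads: ReadSet, chrom_sizes: dict[str, int]) -> "CoverageTrack":
        data = {c: reads.coverage(c, n) for c, n in chrom_sizes.items()}
        return cls(data=data, library_size=reads.n_reads)
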