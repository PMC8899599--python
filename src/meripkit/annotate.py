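"""Peak annotation: transcript assignment, metagene profiles, motif
scanning/enrichment, and overlap with a reference site catalogue.

Peaks are located by their summit (signal maximum) rather than their
midpoint; a peak overlapping several transcripts is attributed to the
longest coding transcript, a deterministic tie-break. The metagene axis
rescales the 5'UTR, CDS and 3'UTR of each transcript to fixed bin counts
so that peak density is comparable across transcripts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import re

from .intervals import (GenomicInterval, TranscriptModel, merge,
                        REGION_5UTR, REGION_CDS, REGION_3UTR)
from .io import atomic_write
from .peaks import Peak
from .seq import dinucleotide_shuffle, iupac_to_regex, revcomp
from .utils import percent

REGION_START = "start-codon"
REGION_STOP = "stop-codon"
REGION_NONCODING = "noncoding"
REGION_UNASSIGNED = "unassigned"


class TranscriptIndex:
    """Chromosome-bucketed transcript lookup with the longest-coding rule."""

    def __init__(self, transcripts: Iterable[TranscriptModel]):
        self._by_chrom: dict[str, list[TranscriptModel]] = {}
        for tm in transcripts:
            self._by_chrom.setdefault(tm.chrom, []).append(tm)

    def overlapping(self, iv: GenomicInterval) -> list[TranscriptModel]:
        return [tm for tm in self._by_chrom.get(iv.chrom, ())
                if tm.span.start < iv.end and iv.start < tm.span.end]

    def assign(self, iv: GenomicInterval) -> TranscriptModel | None:
        """Longest coding transcript overlapping ``iv`` (mature length,
        transcript_id as tie-break); falls back to the longest non-coding."""
        cands = self.overlapping(iv)
        if not cands:
            return None
        coding = [t for t in cands if t.is_coding]
        pool = coding or cands
        return min(pool, key=lambda t: (-t.mature_length, t.transcript_id))


def assign_region(peak: Peak | GenomicInterval, index: TranscriptIndex,
                  codon_window: int = 100) -> str:
    """Label a peak by its summit position within its assigned transcript.

    Start-/stop-codon windows are +-``codon_window`` nt around the codon
    in spliced coordinates and take precedence over the plain region
    labels; a summit inside both windows gets the nearer codon.
    """
    iv = peak.interval if isinstance(peak, Peak) else peak
    pos = peak.anchor if isinstance(peak, Peak) else iv.midpoint
    tm = index.assign(iv)
    if tm is None:
        return REGION_UNASSIGNED
    if not tm.is_coding:
        return REGION_NONCODING
    try:
        idx = tm.genomic_to_spliced(pos)
    except ValueError:
        return REGION_UNASSIGNED
    u5, cds, u3 = tm.region_lengths()
    d_start = idx - u5                 # signed distance to first CDS base
    d_stop = idx - (u5 + cds - 1)      # signed distance to last CDS base
    in_start = abs(d_start) <= codon_window
    in_stop = abs(d_stop) <= codon_window
    if in_start and in_stop:
        return REGION_START if abs(d_start) <= abs(d_stop) else REGION_STOP
    if in_start:
        return REGION_START
    if in_stop:
        return REGION_STOP
    if idx < u5:
        return REGION_5UTR
    if idx < u5 + cds:
        return REGION_CDS
    return REGION_3UTR


@dataclass
class MetageneProfile:
    """Peak density over a normalized 5'UTR | CDS | 3'UTR axis."""

    bins_per_region: tuple[int, int, int]
    density: np.ndarray
    n_mapped: int
    n_skipped: int

    @property
    def region_edges(self) -> tuple[int, int, int]:
        b = self.bins_per_region
        return b[0], b[0] + b[1], b[0] + b[1] + b[2]

    def to_tsv(self, path: str | Path) -> None:
        labels = ([REGION_5UTR] * self.bins_per_region[0]
                  + [REGION_CDS] * self.bins_per_region[1]
                  + [REGION_3UTR] * self.bins_per_region[2])
        with atomic_write(path) as fh:
            fh.write("bin\tregion\tdensity\n")
            for i, (lab, d) in enumerate(zip(labels, self.density)):
                fh.write(f"{i}\t{lab}\t{d:.6g}\n")

    def plot(self, path: str | Path) -> None:  # pragma: no cover - cosmetic
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 3))
        ax.plot(np.arange(len(self.density)), self.density)
        for edge in self.region_edges[:2]:
            ax.axvline(edge, color="grey", ls="--", lw=0.8)
        ax.set_xticks([self.bins_per_region[0] / 2,
                       self.bins_per_region[0] + self.bins_per_region[1] / 2,
                       sum(self.bins_per_region[:2]) + self.bins_per_region[2] / 2])
        ax.set_xticklabels([REGION_5UTR, REGION_CDS, REGION_3UTR])
        ax.set_ylabel("peak density")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def metagene_profile(peaks: Sequence[Peak | GenomicInterval],
                     transcripts: Sequence[TranscriptModel] | TranscriptIndex,
                     bins_per_region: tuple[int, int, int] = (20, 50, 30)
                     ) -> MetageneProfile:
    """Map each peak summit onto the rescaled transcript axis and bin.

    Density is normalized to sum to 1 over all bins when at least one
    peak maps; peaks outside coding transcripts are skipped and counted.
    """
    index = (transcripts if isinstance(transcripts, TranscriptIndex)
             else TranscriptIndex(transcripts))
    offsets = np.cumsum([0, *bins_per_region])
    counts = np.zeros(int(offsets[-1]), dtype=float)
    n_mapped = n_skipped = 0
    for pk in peaks:
        iv = pk.interval if isinstance(pk, Peak) else pk
        pos = pk.anchor if isinstance(pk, Peak) else iv.midpoint
        tm = index.assign(iv)
        if tm is None or not tm.is_coding:
            n_skipped += 1
            continue
        try:
            region, frac = tm.genomic_to_metagene(pos)
        except ValueError:
            n_skipped += 1
            continue
        ridx = {REGION_5UTR: 0, REGION_CDS: 1, REGION_3UTR: 2}[region]
        b = int(offsets[ridx]) + min(int(frac * bins_per_region[ridx]),
                                     bins_per_region[ridx] - 1)
        counts[b] += 1
        n_mapped += 1
    density = counts / counts.sum() if counts.sum() else counts
    return MetageneProfile(tuple(bins_per_region), density, n_mapped, n_skipped)


# ------------------------------------------------------------------ motifs
def scan_motif(sequence: str, pattern: str, strand: str = "+") -> list[int]:
    """All match start positions of an IUPAC pattern, overlapping included.

    Minus-strand matches are found on the reverse complement and reported
    as plus-strand (left-most) coordinates.
    """
    seq = sequence.upper().replace("U", "T")
    rx = re.compile("(?=" + iupac_to_regex(pattern) + ")")
    if strand == "+":
        return [m.start() for m in rx.finditer(seq)]
    if strand == "-":
        L, k = len(seq), len(pattern)
        hits = [m.start() for m in rx.finditer(revcomp(seq))]
        return sorted(L - p - k for p in hits)
    raise ValueError(f"invalid strand {strand!r}")


def motif_enrichment(peak_sequences: Sequence[str], pattern: str,
                     n_shuffles: int = 200, seed: int = 0
                     ) -> tuple[float, float]:
    """Observed motif density vs dinucleotide-preserving shuffles.

    Returns (fold enrichment, empirical p) where fold is observed match
    density over the mean shuffle density and
    p = (1 + #shuffles >= observed) / (n_shuffles + 1).
    """
    if not peak_sequences:
        raise ValueError("empty sequence set")
    if n_shuffles < 100:
        raise ValueError("need at least 100 shuffles")
    rng = np.random.default_rng(seed)
    total_len = sum(len(s) for s in peak_sequences)
    observed = sum(len(scan_motif(s, pattern)) for s in peak_sequences) / total_len
    null = np.empty(n_shuffles)
    for i in range(n_shuffles):
        null[i] = sum(len(scan_motif(dinucleotide_shuffle(s, rng), pattern))
                      for s in peak_sequences) / total_len
    mean_null = float(null.mean())
    fold = observed / mean_null if mean_null > 0 else np.inf
    p = (1 + int((null >= observed).sum())) / (n_shuffles + 1)
    return fold, p


def peak_sequences(peaks: Sequence[Peak | GenomicInterval],
                   sequences: Mapping[str, str]) -> list[str]:
    out = []
    for pk in peaks:
        iv = pk.interval if isinstance(pk, Peak) else pk
        out.append(sequences[iv.chrom][iv.start:iv.end])
    return out


# --------------------------------------------------- reference catalogue
def compare_to_reference(peaks: Sequence[Peak | GenomicInterval],
                         reference_sites: Sequence[GenomicInterval]
                         ) -> tuple[int, float]:
    """How many peaks contain a recorded reference site.

    Returns (n_overlapping, percentage of peaks rounded to 2 decimals);
    a peak overlaps when at least one reference site intersects it.
    """
    if not peaks:
        raise ValueError("empty peak set")
    ref = merge(reference_sites) if reference_sites else []
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {r.chrom for r in ref}:
        rs = [r for r in ref if r.chrom == chrom]
        by_chrom[chrom] = (np.array([r.start for r in rs]),
                           np.array([r.end for r in rs]))
    n = 0
    for pk in peaks:
        iv = pk.interval if isinstance(pk, Peak) else pk
        if iv.chrom not in by_chrom:
            continue
        starts, ends = by_chrom[iv.chrom]
        if (np.searchsorted(starts, iv.end, side="left")
                - np.searchsorted(np.sort(ends), iv.start, side="right")) > 0:
            n += 1
    return n, percent(n, len(peaks))
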