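"""Per-peak IP/input read counting, RPKM normalization and enrichment.

The relative m6A level of a peak in a sample is the ratio of IP RPKM to
input RPKM. Counting is read-level: a read contributes to a peak iff it
overlaps it by at least one base (a read spanning two peaks contributes
to both); RPKM uses the library's total read count, not reads-in-peaks.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, ReadSet
from .io import atomic_write
from .peaks import Peak


def count_reads(peaks: Sequence[Peak | GenomicInterval], reads: ReadSet) -> np.ndarray:
    """Number of reads overlapping each peak by >= 1 bp."""
    ivs = [p.interval if isinstance(p, Peak) else p for p in peaks]
    return reads.count_overlapping(ivs)


def rpkm(count, peak_length_bp, library_size):
    """Reads per kilobase of peak per million mapped library reads."""
    length = np.asarray(peak_length_bp, dtype=float)
    lib = np.asarray(library_size, dtype=float)
    if (length <= 0).any() if length.ndim else length <= 0:
        raise ValueError("peak length must be > 0")
    if (lib <= 0).any() if lib.ndim else lib <= 0:
        raise ValueError("library size must be > 0")
    return np.asarray(count, dtype=float) / (length / 1e3) / (lib / 1e6)


def enrichment(ip_rpkm, input_rpkm, pseudocount: float = 0.0):
    """(IP RPKM + c) / (input RPKM + c); NaN where undefined (c = 0 and
    input RPKM = 0)."""
    ip = np.asarray(ip_rpkm, dtype=float)
    inp = np.asarray(input_rpkm, dtype=float)
    if (ip < 0).any() or (inp < 0).any():
        raise ValueError("RPKM values must be non-negative")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    denom = inp + pseudocount
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (ip + pseudocount) / denom
    return np.where(denom > 0, out, np.nan)


@dataclass
class EnrichmentMatrix:
    """Peaks x samples table of counts, RPKMs and enrichment ratios."""

    peaks: list[Peak]
    samples: pd.DataFrame               # sample_id, patient, condition
    ip_counts: pd.DataFrame
    input_counts: pd.DataFrame
    ip_rpkm: pd.DataFrame
    input_rpkm: pd.DataFrame
    enrichment: pd.DataFrame

    def __post_init__(self) -> None:
        pairing = self.samples.pivot_table(index="patient", columns="condition",
                                           values="sample_id", aggfunc="count")
        if not ((pairing.get("tumor", 0) == 1).all()
                and (pairing.get("normal", 0) == 1).all()):
            raise ValueError("tumor and normal samples must pair 1:1 by patient")

    @property
    def peak_ids(self) -> pd.Index:
        return self.enrichment.index

    def pairs(self) -> pd.DataFrame:
        """One row per patient with tumor/normal sample ids."""
        wide = self.samples.pivot(index="patient", columns="condition",
                                  values="sample_id")
        return wide[["tumor", "normal"]]

    @classmethod
    def from_tsv(cls, path: str | Path, samples: pd.DataFrame) -> "EnrichmentMatrix":
        """Rebuild from the long-format TSV written by :meth:`to_tsv`
        (peak intervals are not stored there, so ``peaks`` is empty)."""
        long = pd.read_csv(path, sep="\t")
        cols = list(samples.sample_id)
        frames = {}
        for k in ("ip_count", "input_count", "ip_rpkm", "input_rpkm", "enrichment"):
            frames[k] = long.pivot(index="peak_id", columns="sample_id",
                                   values=k)[cols]
        return cls([], samples.copy(), frames["ip_count"], frames["input_count"],
                   frames["ip_rpkm"], frames["input_rpkm"], frames["enrichment"])

    def to_tsv(self, path: str | Path) -> None:
        frames = {"ip_count": self.ip_counts, "input_count": self.input_counts,
                  "ip_rpkm": self.ip_rpkm, "input_rpkm": self.input_rpkm,
                  "enrichment": self.enrichment}
        long = pd.concat({k: v.stack(future_stack=True) for k, v in frames.items()},
                         axis=1)
        long.index.names = ["peak_id", "sample_id"]
        with atomic_write(path) as fh:
            long.reset_index().to_csv(fh, sep="\t", index=False)


def build_enrichment_matrix(peaks: Sequence[Peak],
                            reads: Mapping[str, Mapping[str, ReadSet]],
                            samples: pd.DataFrame,
                            pseudocount: float = 0.0) -> EnrichmentMatrix:
    """Count IP/input reads per peak per sample and form enrichment ratios."""
    peak_ids = [f"peak{i:05d}" for i in range(len(peaks))]
    lengths = np.array([p.interval.length for p in peaks], dtype=float)
    cols = list(samples.sample_id)
    ipc, inc, ipr, inr, enr = ({} for _ in range(5))
    for sid in cols:
        ip_rs, in_rs = reads[sid]["ip"], reads[sid]["input"]
        ipc[sid] = count_reads(peaks, ip_rs)
        inc[sid] = count_reads(peaks, in_rs)
        ipr[sid] = rpkm(ipc[sid], lengths, ip_rs.n_reads) if len(peaks) else np.array([])
        inr[sid] = rpkm(inc[sid], lengths, in_rs.n_reads) if len(peaks) else np.array([])
        enr[sid] = enrichment(ipr[sid], inr[sid], pseudocount)
    mk = lambda d: pd.DataFrame(d, index=pd.Index(peak_ids, name="peak_id"),
                                columns=cols)
    return EnrichmentMatrix(list(peaks), samples.copy(), mk(ipc), mk(inc),
                            mk(ipr), mk(inr), mk(enr))
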