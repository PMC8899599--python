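"""Readers and writers for the standard formats the pipeline consumes.

BED3/BED6 (0-based half-open), GTF in the GENCODE dialect (1-based closed,
converted on read), multi-record wrapped FASTA, bedGraph, and GMT gene-set
files. GTF parsing is delegated to gffutils; FASTA to Biopython.
"""

from __future__ import annotations

import os
import tempfile
from contextlib import contextmanager
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import CoverageTrack, GenomicInterval, TranscriptModel


@contextmanager
def atomic_write(path: str | Path, mode: str = "w"):
    """Write to a temp file in the target directory, then rename into place."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, mode) as fh:
            yield fh
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


# ---------------------------------------------------------------------- BED
def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6 into intervals (name/score columns are ignored)."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            strand = f[5] if len(f) >= 6 else "."
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand))
    return out


def write_bed(intervals: Sequence[GenomicInterval], path: str | Path,
              names: Sequence[str] | None = None,
              scores: Sequence | None = None) -> None:
    with atomic_write(path) as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else f"iv{i}"
            score = scores[i] if scores is not None else 0
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")


# ---------------------------------------------------------------------- GTF
def read_gtf(path: str | Path) -> list[TranscriptModel]:
    """Read GENCODE-dialect GTF (exon/CDS features, gene_id/transcript_id
    attributes) into transcript models, converting to 0-based half-open."""
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True,
        disable_infer_genes=True, disable_infer_transcripts=True)
    exons: dict[str, list[GenomicInterval]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        tid = feat.attributes["transcript_id"][0]
        gid = feat.attributes["gene_id"][0]
        meta[tid] = (gid, feat.seqid, feat.strand)
        start, end = feat.start - 1, feat.end  # 1-based closed -> half-open
        if feat.featuretype == "exon":
            exons.setdefault(tid, []).append(
                GenomicInterval(feat.seqid, start, end, feat.strand))
        else:
            cds.setdefault(tid, []).append((start, end))
    out = []
    for tid in sorted(exons):
        gid, chrom, strand = meta[tid]
        cs = ce = None
        if tid in cds:
            cs = min(s for s, _ in cds[tid])
            ce = max(e for _, e in cds[tid])
        out.append(TranscriptModel(tid, gid, chrom, strand,
                                   tuple(exons[tid]), cs, ce))
    return out


def write_gtf(transcripts: Iterable[TranscriptModel], path: str | Path,
              source: str = "meripkit") -> None:
    with atomic_write(path) as fh:
        for t in transcripts:
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            span = t.span
            fh.write(f"{t.chrom}\t{source}\ttranscript\t{span.start + 1}\t{span.end}"
                     f"\t.\t{t.strand}\t.\t{attrs}\n")
            for ex in t.exons:
                fh.write(f"{t.chrom}\t{source}\texon\t{ex.start + 1}\t{ex.end}"
                         f"\t.\t{t.strand}\t.\t{attrs}\n")
            if t.is_coding:
                for ex in t.exons:
                    s = max(ex.start, t.cds_start)
                    e = min(ex.end, t.cds_end)
                    if s < e:
                        fh.write(f"{t.chrom}\t{source}\tCDS\t{s + 1}\t{e}"
                                 f"\t.\t{t.strand}\t.\t{attrs}\n")


# -------------------------------------------------------------------- FASTA
def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in sequences.items()]
    with atomic_write(path) as fh:
        SeqIO.write(records, fh, "fasta")


# ----------------------------------------------------------------- bedGraph
def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Write per-base coverage as run-length-collapsed bedGraph lines."""
    with atomic_write(path) as fh:
        for chrom in sorted(track.data):
            arr = np.asarray(track.data[chrom])
            if arr.size == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [arr.size]])
            for s, e in zip(starts, ends):
                v = int(arr[s])
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v}\n")


# --------------------------------------------------------------------- GMT
def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT: one gene set per line, ``name<TAB>description<TAB>gene...``."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3 or not fields[0]:
                continue
            sets[fields[0]] = {g for g in fields[2:] if g}
    return sets


def write_gmt(sets: dict[str, Iterable[str]], path: str | Path) -> None:
    with atomic_write(path) as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *sorted(genes)]) + "\n")
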