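"""Synthetic paired tumor/normal MeRIP-seq experiments with known truth.

The generator builds a small transcriptome (one contig per transcript,
single-exon by default), plants m6A sites on exact motif occurrences with
a preference for stop-codon-proximal positions, and draws IP and input
read sets for ``n_pairs`` tumor/normal sample pairs:

* input read counts per transcript are negative binomial (Poisson-gamma)
  around a depth proportional to the transcript's expression level, with
  read starts uniform along the mature transcript;
* IP reads receive a multiplicative boost wherever a fragment overlaps
  the ±``site_window`` nt window around a planted site — the boost is the
  site's true IP enrichment, multiplied (divided) by ``tumor_fold_change``
  in tumor samples for sites labelled increased (decreased).

Because downstream enrichment is an RPKM ratio, dividing by the realized
IP library size, a sample-wide gain in methylation slightly deflates all
ratios in that sample; the defaults keep planted windows a small share of
library mass so the effect stays mild (see docs/methods.md).

Randomness is organised as one master seed split into independent child
streams (truth / per-library / CLIP) via ``numpy.random.SeedSequence``,
so adding samples never perturbs earlier samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, ReadSet, TranscriptModel
from .io import write_bed, write_fasta, write_gtf, atomic_write
from .seq import revcomp

LABEL_INCREASED = "increased"
LABEL_DECREASED = "decreased"
LABEL_UNCHANGED = "unchanged"

_FLANK = 50  # genomic flank around each transcript on its contig


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic experiment.

    Defaults emulate the profiled study design: 8 tumor/normal pairs,
    100 planted m6A sites on GGACT motifs (DNA sense strand), 30% of
    sites differential with a 3-fold tumor change, ~100 input reads per
    site window, and mild extra-Poisson noise (NB size 100).
    """

    n_transcripts: int = 300
    n_m6a_sites: int = 100
    motif: str = "GGACT"
    n_pairs: int = 8
    fraction_differential: float = 0.30
    fraction_decreased: float = 0.075  # share of differential sites lower in tumor
    tumor_fold_change: float = 3.0
    baseline_ip_enrichment: float = 4.0
    site_window: int = 100            # half-width of the enrichment window, nt
    reads_per_site_window: float = 100.0  # expected input reads per site window
    dispersion: float = 100.0         # NB size; -> infinity recovers Poisson
    read_length: int = 50
    # transcript anatomy (nt; CDS drawn in codons)
    utr5_mean: float = 180.0
    utr5_sd: float = 40.0
    cds_codons_mean: float = 250.0
    cds_codons_sd: float = 60.0
    utr3_mean: float = 350.0
    utr3_sd: float = 80.0
    expression_sigma: float = 0.5     # lognormal sd of per-transcript expression
    region_weights: tuple[float, float, float] = (0.1, 0.3, 0.6)
    # multi-exon mode (default single-exon)
    n_exons: int = 1
    intron_length: int = 200
    minus_strand_fraction: float = 0.0
    # RBP (CLIP-like) site placement
    clip_fraction_anchored: float = 0.8
    clip_jitter_sd: float = 10.0
    clip_width: int = 30
    n_clip_background: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        self.region_weights = tuple(self.region_weights)
        if min(self.n_transcripts, self.n_m6a_sites, self.n_pairs,
               self.n_exons, self.read_length) < 0:
            raise ValueError("counts must be non-negative")
        for name in ("fraction_differential", "fraction_decreased",
                     "clip_fraction_anchored", "minus_strand_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.tumor_fold_change <= 0:
            raise ValueError("tumor_fold_change must be > 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.baseline_ip_enrichment <= 0:
            raise ValueError("baseline_ip_enrichment must be > 0")
        a_off = len(self.motif) // 2
        if self.motif.upper()[a_off] != "A":
            raise ValueError("the central base of the motif must be A (the "
                             "methylated residue)")
        if self.reads_per_site_window <= 0 and self.n_m6a_sites > 0:
            raise ValueError("degenerate design: zero depth with planted sites")

    def sample_ids(self) -> pd.DataFrame:
        rows = []
        for i in range(1, self.n_pairs + 1):
            rows.append((f"P{i:02d}T", f"P{i:02d}", "tumor"))
            rows.append((f"P{i:02d}N", f"P{i:02d}", "normal"))
        return pd.DataFrame(rows, columns=["sample_id", "patient", "condition"])


@dataclass
class GroundTruth:
    """Simulation manifest: transcriptome, planted sites, true enrichments."""

    transcripts: list[TranscriptModel]
    sequences: dict[str, str]
    transcript_table: pd.DataFrame  # transcript_id, chrom, lengths, expression
    sites: pd.DataFrame             # site_id, transcript_id, positions, label
    site_enrichment: pd.DataFrame   # site_id x sample_id true IP enrichment
    rbp_sites: pd.DataFrame | None = None

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def site_intervals(self, half_width: int = 0) -> list[GenomicInterval]:
        return [GenomicInterval(r.chrom, max(0, r.genomic_pos - half_width),
                                r.genomic_pos + half_width + 1)
                for r in self.sites.itertuples()]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_gtf(self.transcripts, outdir / "transcripts.gtf")
        write_fasta(self.sequences, outdir / "genome.fa")
        with atomic_write(outdir / "truth_sites.tsv") as fh:
            self.sites.to_csv(fh, sep="\t", index=False)
        with atomic_write(outdir / "truth_enrichment.tsv") as fh:
            self.site_enrichment.to_csv(fh, sep="\t")
        with atomic_write(outdir / "truth_transcripts.tsv") as fh:
            self.transcript_table.to_csv(fh, sep="\t", index=False)
        if self.rbp_sites is not None:
            with atomic_write(outdir / "truth_rbp_sites.tsv") as fh:
                self.rbp_sites.to_csv(fh, sep="\t", index=False)


@dataclass
class MeripExperiment:
    """Per-sample IP and input read sets plus sample metadata."""

    samples: pd.DataFrame
    reads: dict[str, dict[str, ReadSet]]  # sample_id -> {"ip": ..., "input": ...}
    chrom_sizes: dict[str, int]

    def write_beds(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for sample_id, libs in self.reads.items():
            for kind, rs in libs.items():
                path = outdir / f"{sample_id}_{kind}.bed"
                with atomic_write(path) as fh:
                    for chrom in rs.chroms:
                        for s, e in rs.iter_intervals(chrom):
                            fh.write(f"{chrom}\t{s}\t{e}\n")


def _seed_streams(config: SimulationConfig):
    root = np.random.SeedSequence(config.seed)
    truth_ss, exp_ss, clip_ss = root.spawn(3)
    return truth_ss, exp_ss, clip_ss


# ------------------------------------------------------------ transcriptome
def _draw_anatomy(cfg: SimulationConfig, rng: np.random.Generator):
    u5 = max(60, int(round(rng.normal(cfg.utr5_mean, cfg.utr5_sd))))
    codons = max(100, int(round(rng.normal(cfg.cds_codons_mean, cfg.cds_codons_sd))))
    u3 = max(100, int(round(rng.normal(cfg.utr3_mean, cfg.utr3_sd))))
    return u5, 3 * codons, u3


def _eligible_ranges(u5: int, cds: int, u3: int, L: int, sw: int,
                     motif_len: int) -> list[tuple[int, int]]:
    """Spliced-coordinate candidate ranges for (5'UTR, CDS body,
    stop-proximal) site placement; each range is half-open and already
    clipped so the whole motif fits inside the transcript."""
    a = motif_len // 2
    lo, hi = a, L - (motif_len - a)  # valid positions for the methylated A
    stop = u5 + cds - 1              # last CDS base (transcript orientation)
    ranges = [
        (max(lo, 0), min(hi, u5)),                       # 5'UTR
        (max(lo, u5), min(hi, max(u5, stop - sw))),      # CDS body
        (max(lo, stop - sw), min(hi, stop + sw + 1)),    # stop-proximal
    ]
    return [(s, e) for (s, e) in ranges]


def simulate_transcriptome(config: SimulationConfig) -> GroundTruth:
    """Build transcript models, contig sequences and planted m6A sites."""
    truth_ss, _, _ = _seed_streams(config)
    rng = np.random.default_rng(truth_ss)
    motif = config.motif.upper()
    a_off = len(motif) // 2
    sw = config.site_window

    transcripts: list[TranscriptModel] = []
    seqs: dict[str, list[str]] = {}
    rows = []
    for i in range(config.n_transcripts):
        tid, gid = f"tx{i:04d}", f"g{i:04d}"
        u5, cds, u3 = _draw_anatomy(config, rng)
        L = u5 + cds + u3
        strand = "-" if rng.random() < config.minus_strand_fraction else "+"
        exons = []
        if config.n_exons <= 1:
            exons = [GenomicInterval(tid, _FLANK, _FLANK + L, strand)]
        else:
            # split the mature length into n_exons roughly equal pieces
            cuts = np.linspace(0, L, config.n_exons + 1).astype(int)
            g = _FLANK
            for a, b in zip(cuts[:-1], cuts[1:]):
                exons.append(GenomicInterval(tid, g, g + (b - a), strand))
                g += (b - a) + config.intron_length
        span_end = exons[-1].end
        # genomic CDS bounds from spliced bounds
        tm = TranscriptModel(tid, gid, tid, strand, tuple(exons))
        if strand == "+":
            cs = tm.spliced_to_genomic(u5)
            ce = tm.spliced_to_genomic(u5 + cds - 1) + 1
        else:
            cs = tm.spliced_to_genomic(u5 + cds - 1)
            ce = tm.spliced_to_genomic(u5) + 1
        tm = TranscriptModel(tid, gid, tid, strand, tuple(exons), cs, ce)
        transcripts.append(tm)
        contig_len = span_end + _FLANK
        seqs[tid] = list(rng.choice(list("ACGT"), size=contig_len))
        expression = float(rng.lognormal(0.0, config.expression_sigma))
        rows.append((tid, gid, tid, L, u5, cds, u3, strand, expression))
    transcript_table = pd.DataFrame(
        rows, columns=["transcript_id", "gene_id", "chrom", "mature_length",
                       "utr5", "cds", "utr3", "strand", "expression"])

    # ---- plant sites -------------------------------------------------
    site_rows = []
    if config.n_m6a_sites > 0:
        if config.n_transcripts == 0:
            raise ValueError("cannot plant sites without transcripts")
        if len(motif) > int(transcript_table.mature_length.min()):
            raise ValueError("motif longer than the shortest transcript")
        order = rng.permutation(config.n_transcripts)
        placed: dict[int, list[int]] = {}
        weights = np.asarray(config.region_weights, dtype=float)
        weights = weights / weights.sum()
        min_dist = 2 * sw + config.read_length
        cursor = 0
        attempts_left = 20 * config.n_m6a_sites
        while len(site_rows) < config.n_m6a_sites:
            if attempts_left <= 0:
                raise ValueError("could not place all sites; transcriptome "
                                 "too small for the requested site count")
            attempts_left -= 1
            ti = int(order[cursor % config.n_transcripts])
            cursor += 1
            tm = transcripts[ti]
            row = transcript_table.iloc[ti]
            ranges = _eligible_ranges(int(row.utr5), int(row.cds), int(row.utr3),
                                      int(row.mature_length), sw, len(motif))
            region_idx = int(rng.choice(3, p=weights))
            ok_pos = None
            for ridx in [region_idx] + [j for j in range(3) if j != region_idx]:
                s, e = ranges[ridx]
                if e <= s:
                    continue
                for _ in range(30):
                    pos = int(rng.integers(s, e))
                    if all(abs(pos - q) >= min_dist for q in placed.get(ti, [])):
                        ok_pos = (pos, ridx)
                        break
                if ok_pos:
                    break
            if ok_pos is None:
                continue
            pos, ridx = ok_pos
            placed.setdefault(ti, []).append(pos)
            # overwrite the sequence with the motif (transcript orientation)
            for j, base in enumerate(motif):
                g = tm.spliced_to_genomic(pos - a_off + j)
                seqs[tm.chrom][g] = base if tm.strand == "+" else revcomp(base)
            gpos = tm.spliced_to_genomic(pos)
            region = ("5'UTR", "CDS-body", "stop-proximal")[ridx]
            site_rows.append((f"site{len(site_rows):04d}", tm.transcript_id,
                              tm.chrom, gpos, pos, region))

    sites = pd.DataFrame(
        site_rows, columns=["site_id", "transcript_id", "chrom",
                            "genomic_pos", "spliced_pos", "region"])

    # ---- differential labels and per-sample true enrichment ----------
    n_sites = len(sites)
    labels = np.array([LABEL_UNCHANGED] * n_sites, dtype=object)
    if n_sites:
        n_diff = int(round(config.fraction_differential * n_sites))
        n_dec = int(round(config.fraction_decreased * n_diff))
        n_inc = n_diff - n_dec
        pick = rng.permutation(n_sites)
        labels[pick[:n_inc]] = LABEL_INCREASED
        labels[pick[n_inc:n_inc + n_dec]] = LABEL_DECREASED
    sites["label"] = labels
    sites["baseline_enrichment"] = config.baseline_ip_enrichment

    samples = config.sample_ids()
    enr = pd.DataFrame(config.baseline_ip_enrichment,
                       index=sites.site_id if n_sites else pd.Index([], name="site_id"),
                       columns=samples.sample_id)
    enr.index.name = "site_id"
    fc = config.tumor_fold_change
    for col, cond in zip(samples.sample_id, samples.condition):
        if cond != "tumor" or n_sites == 0:
            continue
        enr.loc[sites.label.values == LABEL_INCREASED, col] *= fc
        enr.loc[sites.label.values == LABEL_DECREASED, col] /= fc

    sequences = {c: "".join(s) for c, s in seqs.items()}
    return GroundTruth(transcripts, sequences, transcript_table, sites, enr)


# --------------------------------------------------------------- experiment
def _site_weight(L_starts: int, read_length: int, sw: int,
                 site_positions: list[int], multipliers: list[float]) -> np.ndarray:
    """Per-read-start IP weight along one transcript (spliced coords)."""
    w = np.ones(L_starts)
    for pos, mult in zip(site_positions, multipliers):
        lo = max(0, pos - sw - read_length + 1)
        hi = min(L_starts, pos + sw + 1)
        if hi > lo:
            w[lo:hi] = np.maximum(w[lo:hi], mult)
    return w


def _spliced_reads_to_blocks(tm: TranscriptModel, starts: np.ndarray,
                             read_length: int):
    """Convert spliced read start positions to genomic (start, end) blocks."""
    if len(tm.exons) == 1:
        ex = tm.exons[0]
        if tm.strand == "+":
            gs = ex.start + starts
        else:
            gs = ex.end - (starts + read_length)
        return gs, gs + read_length
    gs_all, ge_all = [], []
    for p in starts.tolist():
        idxs = [tm.spliced_to_genomic(q) for q in range(p, p + read_length)]
        idxs.sort()
        s = prev = idxs[0]
        for g in idxs[1:]:
            if g == prev + 1:
                prev = g
                continue
            gs_all.append(s)
            ge_all.append(prev + 1)
            s = prev = g
        gs_all.append(s)
        ge_all.append(prev + 1)
    return np.array(gs_all, dtype=np.int64), np.array(ge_all, dtype=np.int64)


def _nb_draw(rng: np.random.Generator, mean: float, size_param: float) -> int:
    if mean <= 0:
        return 0
    p = size_param / (size_param + mean)
    return int(rng.negative_binomial(size_param, p))


def simulate_merip_experiment(config: SimulationConfig,
                              truth: GroundTruth) -> MeripExperiment:
    """Draw IP and input read sets for every sample from the ground truth."""
    if config.reads_per_site_window <= 0 and len(truth.sites) > 0:
        raise ValueError("degenerate design: zero depth with planted sites")
    _, exp_ss, _ = _seed_streams(config)
    samples = config.sample_ids()
    lib_streams = exp_ss.spawn(2 * len(samples))  # ip, input per sample

    rl = config.read_length
    sw = config.site_window
    r0 = config.reads_per_site_window / (2 * sw + rl)
    sites_by_tx: dict[str, pd.DataFrame] = (
        dict(tuple(truth.sites.groupby("transcript_id", sort=False)))
        if len(truth.sites) else {})

    reads: dict[str, dict[str, ReadSet]] = {}
    for si, sample in enumerate(samples.itertuples()):
        ip_rng = np.random.default_rng(lib_streams[2 * si])
        in_rng = np.random.default_rng(lib_streams[2 * si + 1])
        ip_per: dict[str, tuple[list, list]] = {}
        in_per: dict[str, tuple[list, list]] = {}
        for tm, trow in zip(truth.transcripts, truth.transcript_table.itertuples()):
            L = tm.mature_length
            n_start = L - rl + 1
            if n_start <= 0:
                continue
            mu = r0 * trow.expression * n_start
            # ---- input library ------------------------------------------
            n_in = _nb_draw(in_rng, mu, config.dispersion)
            s_in = in_rng.integers(0, n_start, n_in)
            # ---- IP library ---------------------------------------------
            tsites = sites_by_tx.get(tm.transcript_id)
            if tsites is None or len(tsites) == 0:
                w = None
                mean_w = 1.0
            else:
                mults = truth.site_enrichment.loc[
                    tsites.site_id, sample.sample_id].tolist()
                w = _site_weight(n_start, rl, sw,
                                 tsites.spliced_pos.tolist(), mults)
                mean_w = float(w.mean())
            n_ip = _nb_draw(ip_rng, mu * mean_w, config.dispersion)
            if w is None:
                s_ip = ip_rng.integers(0, n_start, n_ip)
            else:
                s_ip = ip_rng.choice(n_start, size=n_ip, p=w / w.sum())
            for rng_starts, store in ((s_in, in_per), (s_ip, ip_per)):
                if len(rng_starts) == 0:
                    continue
                gs, ge = _spliced_reads_to_blocks(tm, np.asarray(rng_starts), rl)
                lst = store.setdefault(tm.chrom, ([], []))
                lst[0].append(gs)
                lst[1].append(ge)
        reads[sample.sample_id] = {
            "ip": ReadSet.from_arrays({c: (np.concatenate(s), np.concatenate(e))
                                       for c, (s, e) in ip_per.items()}),
            "input": ReadSet.from_arrays({c: (np.concatenate(s), np.concatenate(e))
                                          for c, (s, e) in in_per.items()}),
        }
    return MeripExperiment(samples, reads, truth.chrom_sizes)


# ------------------------------------------------------------------- CLIP
def simulate_clip_sites(config: SimulationConfig,
                        truth: GroundTruth) -> pd.DataFrame:
    """Place RBP binding intervals, a fraction anchored on m6A sites.

    Anchored intervals are centered on the site's genomic position plus
    Gaussian jitter (``clip_jitter_sd``); the remaining
    ``n_clip_background`` intervals land uniformly on random contigs.
    Returns a table with columns chrom/start/end/anchor_site_id/offset
    and stores it on ``truth.rbp_sites``.
    """
    _, _, clip_ss = _seed_streams(config)
    rng = np.random.default_rng(clip_ss)
    w = config.clip_width
    rows = []
    n_sites = len(truth.sites)
    n_anchored = int(round(config.clip_fraction_anchored * n_sites))
    if n_anchored:
        pick = rng.choice(n_sites, size=n_anchored, replace=False)
        for k in np.sort(pick):
            site = truth.sites.iloc[int(k)]
            size = truth.chrom_sizes[site.chrom]
            off = int(round(rng.normal(0.0, config.clip_jitter_sd)))
            center = int(np.clip(site.genomic_pos + off, w // 2 + 1,
                                 size - w // 2 - 1))
            rows.append((f"rbp{len(rows):04d}", site.chrom,
                         center - w // 2, center - w // 2 + w,
                         site.site_id, center - int(site.genomic_pos)))
    chroms = sorted(truth.chrom_sizes)
    for _ in range(config.n_clip_background):
        if not chroms:
            break
        chrom = chroms[int(rng.integers(len(chroms)))]
        size = truth.chrom_sizes[chrom]
        start = int(rng.integers(0, max(1, size - w)))
        rows.append((f"rbp{len(rows):04d}", chrom, start, start + w, "", np.nan))
    table = pd.DataFrame(rows, columns=["rbp_id", "chrom", "start", "end",
                                        "anchor_site_id", "offset"])
    truth.rbp_sites = table
    return table


def rbp_intervals(table: pd.DataFrame) -> list[GenomicInterval]:
    return [GenomicInterval(r.chrom, int(r.start), int(r.end))
            for r in table.itertuples()]


def simulate_all(config: SimulationConfig):
    """Convenience: transcriptome + experiment + CLIP sites."""
    truth = simulate_transcriptome(config)
    experiment = simulate_merip_experiment(config, truth)
    simulate_clip_sites(config, truth)
    return truth, experiment
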