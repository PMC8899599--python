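"""End-to-end orchestration of the synthetic MeRIP-seq analysis.

``analyze_experiment`` runs every analysis stage in memory and returns a
result object; ``run_pipeline`` wraps it with simulation, file output and
stage-level logging. Orchestrated and manual stagewise execution produce
identical outputs for identical configs and seeds because every stage is
a pure function of its inputs plus the derived seeds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate as ann
from . import diffmeth as dm
from .config import PipelineConfig
from .cooccupancy import AnchorProfile, aggregate_profile, overlap_permutation_test
from .intervals import GenomicInterval
from .io import atomic_write, write_bed, write_gmt
from .pathway import GeneSetCollection, hypergeom_enrich
from .peaks import (Peak, call_peaks_window, combine_across_samples,
                    consensus_two_callers, filter_tss_m6am, locate_summits)
from .quantify import EnrichmentMatrix, build_enrichment_matrix
from .simulate import (GroundTruth, MeripExperiment, SimulationConfig,
                       simulate_clip_sites, simulate_merip_experiment,
                       simulate_transcriptome, rbp_intervals,
                       LABEL_INCREASED, LABEL_DECREASED)
from .utils import percent, round_half_up

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    peaks: list[Peak]                  # retained consensus peaks, summit set
    removed_tss: list[Peak]
    matrix: EnrichmentMatrix
    fold_changes: pd.DataFrame
    classes: pd.DataFrame
    metagene: ann.MetageneProfile
    region_labels: pd.Series
    rbp_profile: AnchorProfile | None
    pathway_results: pd.DataFrame | None
    summary: dict


def call_sample_consensus(experiment: MeripExperiment, cfg: PipelineConfig
                          ) -> dict[str, list[GenomicInterval]]:
    """Per-sample two-caller consensus using the built-in caller under two
    window parameterizations (external caller BEDs can replace either)."""
    out: dict[str, list[GenomicInterval]] = {}
    for sid in experiment.samples.sample_id:
        ip = experiment.reads[sid]["ip"]
        inp = experiment.reads[sid]["input"]
        pa = call_peaks_window(ip, inp, experiment.chrom_sizes,
                               cfg.window, cfg.step, cfg.alpha, caller="A")
        pb = call_peaks_window(ip, inp, experiment.chrom_sizes,
                               cfg.caller_b_window, cfg.caller_b_step,
                               cfg.alpha, caller="B")
        out[sid] = consensus_two_callers(pa, pb)
        logger.info("sample %s: caller A %d, caller B %d, consensus %d",
                    sid, len(pa), len(pb), len(out[sid]))
    return out


def evaluate_against_truth(peaks: list[Peak], classes: pd.DataFrame,
                           truth: GroundTruth) -> dict:
    """Planted-truth recovery metrics for simulated runs."""
    sites = truth.sites
    peak_ivs = [p.interval for p in peaks]
    site_peak: dict[str, int] = {}
    for _, site in sites.iterrows():
        for j, iv in enumerate(peak_ivs):
            if iv.chrom == site.chrom and iv.start <= site.genomic_pos < iv.end:
                site_peak[site.site_id] = j
                break
    n_sites = len(sites)
    recall = len(site_peak) / n_sites if n_sites else float("nan")
    covered = set(site_peak.values())
    false_peaks = [j for j in range(len(peaks)) if j not in covered]
    false_frac = len(false_peaks) / len(peaks) if peaks else float("nan")

    klass = classes["klass"]
    peak_ids = list(classes.index)
    inc_sites = sites[sites.label == LABEL_INCREASED]
    n_inc_recovered = sum(
        1 for sid in inc_sites.site_id
        if sid in site_peak and klass[peak_ids[site_peak[sid]]] == dm.CLASS_INCREASED)
    inc_recall = n_inc_recovered / len(inc_sites) if len(inc_sites) else float("nan")

    diff_sites = sites[sites.label.isin([LABEL_INCREASED, LABEL_DECREASED])]
    diff_peaks = {site_peak[s] for s in diff_sites.site_id if s in site_peak}
    null_peaks = [j for j in range(len(peaks)) if j not in diff_peaks]
    n_false_dys = sum(
        1 for j in null_peaks
        if klass[peak_ids[j]] in (dm.CLASS_INCREASED, dm.CLASS_DECREASED,
                                  dm.CLASS_AMBIGUOUS))
    false_dys = n_false_dys / len(null_peaks) if null_peaks else float("nan")
    return {
        "n_planted_sites": n_sites,
        "n_planted_increased": int(len(inc_sites)),
        "site_recall": round_half_up(recall, 4),
        "false_peak_fraction": round_half_up(false_frac, 4),
        "increased_class_recall": round_half_up(inc_recall, 4),
        "n_null_peaks": len(null_peaks),
        "false_dysregulation_fraction": round_half_up(false_dys, 4),
    }


def _toy_gene_sets(truth: GroundTruth, universe: set[str], seed: int) -> dict:
    """Gene sets for the pathway stage of simulated runs: the genes whose
    transcripts carry planted increased sites, plus random decoys."""
    rng = np.random.default_rng(seed)
    tx2gene = dict(zip(truth.transcript_table.transcript_id,
                       truth.transcript_table.gene_id))
    inc_genes = {tx2gene[t] for t in
                 truth.sites.loc[truth.sites.label == LABEL_INCREASED,
                                 "transcript_id"]}
    sets = {"planted_increased_pathway": inc_genes & universe}
    uni = sorted(universe)
    for i in range(5):
        k = min(len(uni), 25)
        sets[f"decoy_pathway_{i}"] = set(
            rng.choice(uni, size=k, replace=False)) if uni else set()
    return sets


def analyze_experiment(truth: GroundTruth, experiment: MeripExperiment,
                       cfg: PipelineConfig) -> PipelineResult:
    """All analysis stages on one (simulated or imported) experiment."""
    per_sample = call_sample_consensus(experiment, cfg)
    combined = combine_across_samples(per_sample, cfg.min_support)
    n_candidates = len(combine_across_samples(per_sample, 1))
    combined = locate_summits(
        combined,
        [experiment.reads[s]["ip"] for s in experiment.samples.sample_id],
        [experiment.reads[s]["input"] for s in experiment.samples.sample_id],
        experiment.chrom_sizes)
    peaks, removed = filter_tss_m6am(combined, truth.transcripts,
                                     truth.sequences, cfg.require_tss_cover)
    logger.info("peaks: %d candidate regions, %d with support >= %d, "
                "%d after TSS m6Am filter", n_candidates, len(combined),
                cfg.min_support, len(peaks))

    matrix = build_enrichment_matrix(peaks, experiment.reads,
                                     experiment.samples, cfg.pseudocount)
    fcs = dm.pair_fold_changes(matrix)
    classes = dm.classify_dysregulated(fcs, cfg.fc_threshold, cfg.min_pairs)
    dys_summary = dm.summarize_dysregulation(classes)
    shift_counts, shift_edges, n_shift_excluded = dm.global_shift(matrix)

    index = ann.TranscriptIndex(truth.transcripts)
    region_labels = pd.Series(
        [ann.assign_region(p, index, cfg.codon_window) for p in peaks],
        index=matrix.peak_ids, name="region")
    metagene = ann.metagene_profile(peaks, index, cfg.metagene_bins)
    motif_fold = motif_p = None
    if peaks:
        seqs = ann.peak_sequences(peaks, truth.sequences)
        motif_fold, motif_p = ann.motif_enrichment(
            seqs, cfg.simulation.motif, cfg.n_shuffles, seed=cfg.simulation.seed)
    ref_sites = truth.site_intervals()
    n_ref, pct_ref = (ann.compare_to_reference(peaks, ref_sites)
                      if peaks else (0, None))

    rbp_profile = None
    cooccupancy_p = None
    if truth.rbp_sites is not None and len(truth.rbp_sites) and len(truth.sites):
        rbp = rbp_intervals(truth.rbp_sites)
        anchors = [(r.chrom, int(r.genomic_pos), "+")
                   for r in truth.sites.itertuples()]
        rbp_profile = aggregate_profile(rbp, anchors, cfg.flank, cfg.bin_width)
        domain = [GenomicInterval(c, 0, n)
                  for c, n in experiment.chrom_sizes.items()]
        _, cooccupancy_p = overlap_permutation_test(
            rbp, ref_sites, domain, window=cfg.flank // 4, n_perm=200,
            seed=cfg.simulation.seed)

    pathway_results = None
    tx2gene = dict(zip(truth.transcript_table.transcript_id,
                       truth.transcript_table.gene_id))
    peak_genes: dict[str, str] = {}
    for pid, pk in zip(matrix.peak_ids, peaks):
        tm = index.assign(pk.interval)
        if tm is not None:
            peak_genes[pid] = tx2gene.get(tm.transcript_id, tm.gene_id)
    universe = set(peak_genes.values())
    query = {peak_genes[pid] for pid in classes.index
             if pid in peak_genes and classes.loc[pid, "klass"] == dm.CLASS_INCREASED}
    if universe and query:
        collection = GeneSetCollection(
            _toy_gene_sets(truth, universe, cfg.simulation.seed), universe)
        pathway_results = hypergeom_enrich(query, collection)

    summary = {
        "n_candidate_regions": n_candidates,
        "n_peaks_supported": len(combined),
        "n_peaks_removed_tss_m6am": len(removed),
        "n_consensus_peaks": len(peaks),
        "dysregulation": dys_summary,
        "global_shift_histogram": {
            "counts": [int(c) for c in shift_counts],
            "edges": [float(e) for e in shift_edges],
            "n_excluded": n_shift_excluded,
        },
        "region_counts": region_labels.value_counts().to_dict(),
        "motif": {"pattern": cfg.simulation.motif,
                  "fold_enrichment": motif_fold, "empirical_p": motif_p},
        "reference_overlap": {"n_overlapping": n_ref, "pct": pct_ref,
                              "n_reference_sites": len(ref_sites)},
        "cooccupancy_permutation_p": cooccupancy_p,
        "truth_recovery": evaluate_against_truth(peaks, classes, truth),
    }
    return PipelineResult(peaks, removed, matrix, fcs, classes, metagene,
                          region_labels, rbp_profile, pathway_results, summary)


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> PipelineResult:
    """Simulate, analyze and write every artifact plus a summary JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    handler = logging.FileHandler(outdir / "run.log")
    logging.getLogger("meripkit").addHandler(handler)
    try:
        cfg.to_yaml(outdir / "config.yaml")
        logger.info("simulating transcriptome and experiment (seed %d)",
                    cfg.simulation.seed)
        truth = simulate_transcriptome(cfg.simulation)
        experiment = simulate_merip_experiment(cfg.simulation, truth)
        simulate_clip_sites(cfg.simulation, truth)
        truth.write(outdir)
        if cfg.write_reads:
            experiment.write_beds(outdir / "reads")
        result = analyze_experiment(truth, experiment, cfg)
        write_bed([p.interval for p in result.peaks], outdir / "consensus_peaks.bed",
                  names=list(result.matrix.peak_ids),
                  scores=[p.n_support for p in result.peaks])
        with atomic_write(outdir / "peak_support.tsv") as fh:
            fh.write("peak_id\tchrom\tstart\tend\tsummit\tn_support\tsamples\n")
            for pid, p in zip(result.matrix.peak_ids, result.peaks):
                fh.write(f"{pid}\t{p.interval.chrom}\t{p.interval.start}\t"
                         f"{p.interval.end}\t{p.summit}\t{p.n_support}\t"
                         f"{','.join(p.support)}\n")
        result.matrix.to_tsv(outdir / "enrichment_matrix.tsv")
        with atomic_write(outdir / "differential.tsv") as fh:
            pd.concat([result.fold_changes.add_prefix("fc_"), result.classes],
                      axis=1).to_csv(fh, sep="\t")
        result.metagene.to_tsv(outdir / "metagene_profile.tsv")
        with atomic_write(outdir / "peak_regions.tsv") as fh:
            result.region_labels.to_csv(fh, sep="\t")
        if result.rbp_profile is not None:
            result.rbp_profile.to_tsv(outdir / "rbp_profile.tsv")
        if result.pathway_results is not None:
            with atomic_write(outdir / "pathway_enrichment.tsv") as fh:
                result.pathway_results.to_csv(fh, sep="\t", index=False)
        with atomic_write(outdir / "summary.json") as fh:
            json.dump(result.summary, fh, indent=2, sort_keys=True)
        return result
    finally:
        logging.getLogger("meripkit").removeHandler(handler)
        handler.close()
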