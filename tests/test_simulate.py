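import numpy as np
import pandas as pd
import pytest

from meripkit.intervals import GenomicInterval
from meripkit.quantify import rpkm
from meripkit.simulate import (SimulationConfig, simulate_clip_sites,
                               simulate_merip_experiment,
                               simulate_transcriptome, LABEL_INCREASED,
                               LABEL_DECREASED, LABEL_UNCHANGED)


def _window_ratio(truth, exp, sample, iv):
    """Empirical IP/input RPKM ratio of one window in one sample."""
    ip = exp.reads[sample]["ip"]
    inp = exp.reads[sample]["input"]
    ipk = rpkm(ip.count_overlapping([iv])[0], iv.length, ip.n_reads)
    ink = rpkm(inp.count_overlapping([iv])[0], iv.length, inp.n_reads)
    return ipk / ink


def test_empty_transcriptome():
    truth = simulate_transcriptome(SimulationConfig(n_transcripts=0,
                                                    n_m6a_sites=0))
    assert truth.transcripts == [] and len(truth.sites) == 0


def test_degenerate_zero_depth_rejected():
    with pytest.raises(ValueError):
        SimulationConfig(reads_per_site_window=0.0, n_m6a_sites=5)


def test_motif_must_center_on_a():
    with pytest.raises(ValueError):
        SimulationConfig(motif="GGCTT")


def test_sites_sit_on_planted_motifs(small_sim_config):
    """Every ground-truth site's +-2 nt spliced context is the motif."""
    truth = simulate_transcriptome(small_sim_config)
    by_id = {t.transcript_id: t for t in truth.transcripts}
    for site in truth.sites.itertuples():
        tm = by_id[site.transcript_id]
        seq = tm.spliced_sequence(truth.sequences)
        assert seq[site.spliced_pos - 2:site.spliced_pos + 3] == \
            small_sim_config.motif


def test_differential_labels_consistent_with_enrichment(small_sim_config):
    truth = simulate_transcriptome(small_sim_config)
    cfg = small_sim_config
    for site in truth.sites.itertuples():
        row = truth.site_enrichment.loc[site.site_id]
        for sid in row.index:
            expected = cfg.baseline_ip_enrichment
            if sid.endswith("T"):
                if site.label == LABEL_INCREASED:
                    expected *= cfg.tumor_fold_change
                elif site.label == LABEL_DECREASED:
                    expected /= cfg.tumor_fold_change
            assert row[sid] == pytest.approx(expected)


def test_determinism_and_seed_sensitivity(small_sim_config):
    """Identical seed gives byte-identical reads; a new seed does not."""
    t1 = simulate_transcriptome(small_sim_config)
    t2 = simulate_transcriptome(small_sim_config)
    assert t1.sites.equals(t2.sites)
    assert t1.sequences == t2.sequences
    e1 = simulate_merip_experiment(small_sim_config, t1)
    e2 = simulate_merip_experiment(small_sim_config, t2)
    chrom = t1.transcripts[0].chrom
    size = t1.chrom_sizes[chrom]
    for sid in e1.reads:
        for kind in ("ip", "input"):
            a, b = e1.reads[sid][kind], e2.reads[sid][kind]
            assert a.n_reads == b.n_reads
            assert (a.coverage(chrom, size) == b.coverage(chrom, size)).all()
    other = simulate_transcriptome(
        SimulationConfig(**{**small_sim_config.__dict__, "seed": 8}))
    assert t1.sequences != other.sequences


def test_adding_pairs_preserves_earlier_samples(small_sim_config):
    """The per-library seed streams are prefix-stable in the sample count."""
    truth = simulate_transcriptome(small_sim_config)
    bigger = SimulationConfig(**{**small_sim_config.__dict__, "n_pairs": 3})
    # ground truth anatomy does not depend on n_pairs
    truth_b = simulate_transcriptome(bigger)
    assert truth.sites.drop(columns=[]).equals(truth_b.sites)
    e_small = simulate_merip_experiment(small_sim_config, truth)
    e_big = simulate_merip_experiment(bigger, truth_b)
    chrom = truth.transcripts[0].chrom
    size = truth.chrom_sizes[chrom]
    for sid in e_small.reads:
        for kind in ("ip", "input"):
            assert (e_small.reads[sid][kind].coverage(chrom, size)
                    == e_big.reads[sid][kind].coverage(chrom, size)).all()


def test_region_weight_sampling():
    """Observed site-region fractions at n=2000 lie within 3 SE of the
    configured placement weights."""
    cfg = SimulationConfig(n_transcripts=2000, n_m6a_sites=2000, n_pairs=1,
                           seed=11)
    truth = simulate_transcriptome(cfg)
    frac = truth.sites.region.value_counts(normalize=True)
    for region, weight in zip(("5'UTR", "CDS-body", "stop-proximal"),
                              cfg.region_weights):
        se = np.sqrt(weight * (1 - weight) / len(truth.sites))
        assert abs(frac.get(region, 0.0) - weight) < 3 * se


def test_enrichment_ratio_calibration():
    """Over 50 replicate simulations the empirical IP/input RPKM ratio is
    ~1 away from sites and ~baseline (4) at a planted site, within 3 SE."""
    null_ratios, site_ratios = [], []
    for seed in range(50):
        cfg = SimulationConfig(n_transcripts=40, n_m6a_sites=1, n_pairs=1,
                               fraction_differential=0.0,
                               reads_per_site_window=200.0, seed=1000 + seed)
        truth = simulate_transcriptome(cfg)
        exp = simulate_merip_experiment(cfg, truth)
        site = truth.sites.iloc[0]
        sw = cfg.site_window
        site_iv = GenomicInterval(site.chrom, max(0, site.genomic_pos - sw),
                                  site.genomic_pos + sw)
        site_ratios.append(_window_ratio(truth, exp, "P01N", site_iv))
        # same-size window in the middle of a transcript without a site
        other = next(t for t in truth.transcripts
                     if t.transcript_id != site.transcript_id)
        mid = (other.span.start + other.span.end) // 2
        null_iv = GenomicInterval(other.chrom, mid - sw, mid + sw)
        null_ratios.append(_window_ratio(truth, exp, "P01N", null_iv))
    for values, target in ((null_ratios, 1.0), (site_ratios, 4.0)):
        arr = np.array(values)
        sem = arr.std(ddof=1) / np.sqrt(len(arr))
        assert abs(arr.mean() - target) < 3 * sem


def test_planted_pair_fold_change_recovers_tumor_fold():
    """With few planted sites (negligible library-normalization shift) the
    mean empirical tumor/normal ratio at differential sites is ~ the
    configured fold change."""
    cfg = SimulationConfig(n_transcripts=60, n_m6a_sites=2,
                           fraction_differential=1.0, fraction_decreased=0.0,
                           reads_per_site_window=150.0, seed=5)
    truth = simulate_transcriptome(cfg)
    exp = simulate_merip_experiment(cfg, truth)
    sw = cfg.site_window
    ratios = []
    for site in truth.sites.itertuples():
        iv = GenomicInterval(site.chrom, site.genomic_pos - sw,
                             site.genomic_pos + sw)
        for pair in range(1, cfg.n_pairs + 1):
            t = _window_ratio(truth, exp, f"P{pair:02d}T", iv)
            n = _window_ratio(truth, exp, f"P{pair:02d}N", iv)
            ratios.append(t / n)
    arr = np.array(ratios)
    sem = arr.std(ddof=1) / np.sqrt(len(arr))
    assert abs(arr.mean() - cfg.tumor_fold_change) < 3 * sem + 0.2


# ----------------------------------------------------------------- CLIP
def test_clip_fully_anchored_no_jitter(small_sim_config):
    cfg = SimulationConfig(**{**small_sim_config.__dict__,
                              "clip_fraction_anchored": 1.0,
                              "clip_jitter_sd": 0.0, "n_clip_background": 0})
    truth = simulate_transcriptome(cfg)
    table = simulate_clip_sites(cfg, truth)
    pos = truth.sites.set_index("site_id").genomic_pos
    assert len(table) == len(truth.sites)
    for row in table.itertuples():
        mid = row.start + cfg.clip_width // 2
        assert mid == pos[row.anchor_site_id]


def test_clip_unanchored_null(small_sim_config):
    cfg = SimulationConfig(**{**small_sim_config.__dict__,
                              "clip_fraction_anchored": 0.0})
    truth = simulate_transcriptome(cfg)
    table = simulate_clip_sites(cfg, truth)
    assert (table.anchor_site_id == "").all()
    assert len(table) == cfg.n_clip_background


def test_clip_jitter_sd_recovered():
    """Offset SD over 1000 anchored sites within 10% of the configured SD."""
    cfg = SimulationConfig(n_transcripts=1000, n_m6a_sites=1000, n_pairs=1,
                           clip_fraction_anchored=1.0, clip_jitter_sd=10.0,
                           n_clip_background=0, seed=3)
    truth = simulate_transcriptome(cfg)
    table = simulate_clip_sites(cfg, truth)
    sd = table.offset.std(ddof=1)
    assert abs(sd - 10.0) < 1.0
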