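"""End-to-end orchestration on the synthetic diploid chromosome.

``run`` drives every stage — simulate, assign reads, ChIP tracks and
depletion domains, methylation, expression classes, Hi-C statistics,
replication timing, cross-assay contrasts — from a single YAML-style
configuration, writes stage outputs with stable filenames, and returns a
machine-readable report. The same config (including its seed) always
reproduces the same report.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from pathlib import Path
from typing import Optional

import numpy as np

from . import __version__
from . import allelic, epigenome, expression, hic, io, repliseq, simulate
from . import statstests
from .core import ConfigurationError, GenomicDomain
from .simulate import SimulationConfig, default_config

#: pipeline-level keys accepted on top of the SimulationConfig fields
_PIPELINE_KEYS = {"n_reads", "autosome_length", "insulation_window",
                  "insulation_delta_span", "compartment_bin"}
_SIM_KEYS = {f.name for f in dataclasses.fields(SimulationConfig)} \
    - {"planted_domains", "tad_set"}


def load_config(source) -> dict:
    """Validate a config mapping (or YAML path); unknown keys are errors."""
    if not isinstance(source, dict):
        source = io.read_yaml(source)
    cfg = dict(source or {})
    for key in cfg:
        if key not in _SIM_KEYS | _PIPELINE_KEYS:
            raise ConfigurationError(f"unknown config field {key!r}")
    sim_kwargs = {k: v for k, v in cfg.items() if k in _SIM_KEYS}
    track_bin = sim_kwargs.get("track_bin", 10_000)
    fine = sim_kwargs.get("chip_fine_bin", 500)
    if track_bin % fine != 0:
        raise ConfigurationError(
            f"track_bin ({track_bin}) must be a multiple of "
            f"chip_fine_bin ({fine})")
    return cfg


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    return obj


def run(config, outdir: Optional[str] = None) -> dict:
    """Run the full analysis; returns the report dict (also written as JSON)."""
    cfg_map = load_config(config)
    seed = int(cfg_map.get("seed", 0))
    n_reads = int(cfg_map.get("n_reads", 20_000))
    autosome_length = int(cfg_map.get("autosome_length", 10_000_000))
    ins_window = int(cfg_map.get("insulation_window", 500_000))
    ins_delta = int(cfg_map.get("insulation_delta_span", 200_000))
    sim_kwargs = {k: v for k, v in cfg_map.items()
                  if k in _SIM_KEYS and k not in ("seed", "chrom",
                                                  "chrom_length")}
    config_x = default_config(seed=seed,
                              chrom_length=int(cfg_map.get("chrom_length",
                                                           20_000_000)),
                              **sim_kwargs)
    comp_bin = int(cfg_map.get("compartment_bin", 500_000))
    if comp_bin % config_x.hic_bin != 0:
        raise ConfigurationError(
            f"compartment_bin ({comp_bin}) must be a multiple of "
            f"hic_bin ({config_x.hic_bin})")

    out = Path(outdir) if outdir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    report: dict = {"version": __version__, "seed": seed,
                    "config": {k: _jsonable(v) for k, v in cfg_map.items()},
                    "stages": {}}

    # -- stage: simulate + allelic assignment -------------------------------
    snps = simulate.generate_snp_table(config_x)
    flat = np.ones(config_x.n_bins(config_x.track_bin))
    reads = simulate.simulate_reads(config_x, snps, flat, flat,
                                    n_reads=n_reads)
    partition = allelic.sort_reads(reads, snps)
    truth = {r.read_id: r.true_origin for r in reads}
    track = allelic.bin_reads(partition, config_x.track_bin,
                              config_x.chrom_length)
    acc = allelic.assignment_accuracy(partition, truth)
    report["stages"]["allelic"] = {**partition.summary(), **acc}
    if out:
        io.write_snp_table(snps, out / "snps.tsv")
        io.write_reads(reads, out / "reads.tsv")
        io.write_read_truth(reads, out / "reads.truth.tsv")
        for lab in ("hap1", "hap2", "unassigned"):
            io.write_bedgraph(track.chrom, track.bin_size, track.values(lab),
                              out / f"reads.{lab}.bedgraph")

    # -- stage: ChIP depletion domains --------------------------------------
    # library-size factor from an unenriched autosome control, mirroring
    # genome-wide normalisation (scaling to the coated chromosome's own
    # totals would cancel its chromosome-wide enrichment)
    config_ctrl = SimulationConfig(chrom="chr7",
                                   chrom_length=autosome_length,
                                   seed=seed + 1, baseline_enrichment=0.0)
    ip_ctrl, in_ctrl = simulate.simulate_chip_tracks(config_ctrl, "wild-type")
    lib_scale = float(in_ctrl.values_hap2.sum() / ip_ctrl.values_hap2.sum())
    ip_mut, in_mut = simulate.simulate_chip_tracks(config_x, "mutant")
    chip_mut = epigenome.enrichment_track(ip_mut, in_mut,
                                          coarse_bin=config_x.track_bin,
                                          scale=lib_scale)
    domains, dom_summary = epigenome.call_depletion_domains(chip_mut)
    overlap = statstests.domain_overlap(domains, config_x.planted_domains)
    report["stages"]["depletion_domains"] = {
        "count": dom_summary.count,
        "mean_length_kb": dom_summary.mean_length / 1000.0,
        "jaccard_vs_planted": overlap.jaccard,
    }
    if out:
        io.write_bed(domains, out / "depletion_domains.bed")
        io.write_bedgraph(chip_mut.chrom, chip_mut.bin_size,
                          chip_mut.log2_ratio, out / "k27me3_mut_xi.bedgraph")

    # -- stage: methylation --------------------------------------------------
    meth_domains = [GenomicDomain(d.chrom, d.start, d.end, d.label,
                                  config_x.meth_domain_gain)
                    for d in config_x.planted_domains]
    meth_mut = simulate.simulate_methylation(config_x, config_x.meth_xi,
                                             meth_domains)
    meth_track = epigenome.methylation_track(
        meth_mut, config_x.track_bin,
        n_bins=config_x.n_bins(config_x.track_bin))
    meth_contrast = statstests.contrast_by_regions(meth_track, domains,
                                                   track_id="CpGme_mut_xi")
    report["stages"]["methylation"] = {
        "mean_pct": float(np.nanmean(meth_track.log2_ratio)),
        "contrast_inside_median": meth_contrast.median_inside,
        "contrast_outside_median": meth_contrast.median_outside,
        "contrast_p": meth_contrast.p_value,
    }
    if out:
        io.write_methylation_calls(meth_mut, out / "meth_mut_xi.tsv")
        io.write_bedgraph(meth_track.chrom, meth_track.bin_size,
                          meth_track.log2_ratio,
                          out / "meth_mut_xi_pct.bedgraph")

    # -- stage: expression ----------------------------------------------------
    config_auto = SimulationConfig(chrom="chr7",
                                   chrom_length=autosome_length,
                                   seed=seed + 1)
    _, input_x = simulate.simulate_chip_tracks(
        config_x, "wild-type", bin_size=config_x.track_bin, stream=7)
    _, input_auto = simulate.simulate_chip_tracks(
        config_auto, "wild-type", bin_size=config_auto.track_bin, stream=7)
    factors = expression.estimate_copy_number(
        {"chrX": input_x, "chr7": input_auto}, reference="chr7")
    genes = simulate.generate_genes(config_x)
    counts = simulate.simulate_expression(config_x, genes)
    normed = expression.normalize_expression(counts, factors)
    classified = expression.classify_genes(normed)
    cls_counts = expression.class_counts(classified)
    planted = genes["planted_class"]
    recovery = {
        c: float((classified.loc[planted == c, "class"] == c).mean())
        for c in expression.CLASSES
    }
    # derepression co-locates with depletion domains: mutant Xi % of Xa,
    # genes inside vs outside the called domains
    mids = (classified["start"] + classified["end"]) // 2
    inside = np.zeros(len(classified), dtype=bool)
    for d in domains:
        inside |= ((mids >= d.start) & (mids < d.end)).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        mut_pct = 100.0 * classified["expr_mut_hap2"] / \
            classified["expr_mut_hap1"]
    ok = np.isfinite(mut_pct)
    stat, p_expr = statstests.rank_sum_test(mut_pct[ok & inside],
                                            mut_pct[ok & ~inside])
    report["stages"]["expression"] = {
        "class_counts": cls_counts,
        "per_class_recovery": recovery,
        "n_derepressed": cls_counts["dependent"] + cls_counts["partial"],
        "copy_number_factors": {
            f"{r.chrom}/{r.haplotype}": r.factor
            for r in factors.itertuples()},
        "derepression_domain_contrast_p": p_expr,
    }
    if out:
        classified.to_csv(out / "genes_classified.tsv", sep="\t", index=False)
        with open(out / "class_summary.json", "w") as fh:
            json.dump(_jsonable(cls_counts), fh)

    # -- stage: Hi-C ----------------------------------------------------------
    mats = {
        "wt_xa": simulate.simulate_hic(config_x, "active-like"),
        "wt_xi": simulate.simulate_hic(config_x, "inactive-like"),
        "mut_xi": simulate.simulate_hic(config_x, "mutant-inactive-like"),
    }
    equalized = hic.downsample_equalize(
        {name: {"chrX": m} for name, m in mats.items()}, seed=seed)
    mats = {name: equalized[name]["chrX"] for name in mats}
    balanced = {name: hic.kr_balance(m) for name, m in mats.items()}

    decay = {name: hic.distance_decay(m) for name, m in balanced.items()}
    insul = {name: hic.insulation_score(m, window=ins_window,
                                        delta_span=ins_delta)
             for name, m in balanced.items()}
    # insulation at wt Xa boundaries, wt Xi vs mut Xi
    boundaries = insul["wt_xa"].boundaries
    ins_table = hic.insulation_at_boundaries(boundaries, insul)
    if boundaries:
        stat_b, p_bound = statstests.rank_sum_test(
            ins_table["mut_xi"], ins_table["wt_xi"], alternative="less")
    else:
        p_bound = float("nan")

    gene_density = np.zeros(config_x.n_bins(comp_bin))
    for _, g in genes.iterrows():
        gene_density[((g.start + g.end) // 2) // comp_bin] += 1
    factor = comp_bin // config_x.hic_bin
    profiles = {name: hic.compartment_eigenvector(m.coarsen(factor),
                                                  gene_density=gene_density)
                for name, m in mats.items()}
    ev_corr = {
        "wt_xa_vs_wt_xi": hic.eigenvector_correlation(profiles["wt_xa"],
                                                      profiles["wt_xi"]),
        "wt_xa_vs_mut_xi": hic.eigenvector_correlation(profiles["wt_xa"],
                                                       profiles["mut_xi"]),
    }
    tad_table = hic.tad_reestablishment(config_x.tad_set, mats["wt_xi"],
                                        mats["mut_xi"])
    restored = tad_table["label"] == "restored"
    tad_classes = tad_table.groupby(["label", "class"]).size()
    mega = {name: hic.mega_domain_contrast(m, config_x.mega_domain_boundary)
            for name, m in balanced.items()}
    report["stages"]["hic"] = {
        "decay_slope": {name: d.slope for name, d in decay.items()},
        "far_cis_fraction": {name: d.far_cis_fraction
                             for name, d in decay.items()},
        "n_wt_xa_boundaries": len(boundaries),
        "boundary_insulation_p_mut_deeper": p_bound,
        "boundary_insulation_median": {
            name: float(np.median(ins_table[name])) if boundaries else None
            for name in mats},
        "eigenvector_correlation": ev_corr,
        "tad_reestablishment": {
            "restored_above_q1": float(
                (tad_table.loc[restored, "class"] != "weak").mean()),
            "static_weak": float(
                (tad_table.loc[~restored, "class"] == "weak").mean()),
            "class_table": {f"{lab}/{cls}": int(nn)
                            for (lab, cls), nn in tad_classes.items()},
        },
        "mega_domain_cross_within_ratio": {
            name: m["mean_cross_within_ratio"] for name, m in mega.items()},
    }
    if out:
        for name, m in mats.items():
            io.write_contact_matrix(m, out / f"hic_{name}.triplet")
            io.write_bedgraph(m.chrom, m.bin_size, insul[name].score,
                              out / f"insulation_{name}.bedgraph")
            io.write_bedgraph(m.chrom, comp_bin, profiles[name].eigenvector,
                              out / f"eigenvector_{name}.bedgraph")
        tad_table.to_csv(out / "tad_reestablishment.tsv", sep="\t",
                         index=False)
        io.write_bed([GenomicDomain(config_x.chrom,
                                    b * config_x.hic_bin,
                                    (b + 1) * config_x.hic_bin, "boundary")
                      for b in boundaries], out / "wt_xa_boundaries.bed")

    # -- stage: replication timing -------------------------------------------
    repli_bin = config_x.repli_bin
    fine_repli = min(repli_bin, 100_000)
    prof = {}
    for name, mode in [("wt_xa", "active-like"), ("wt_xi", "inactive-like"),
                       ("mut_xi", "mutant-inactive-like")]:
        rate = simulate.timing_rate_profile(config_x, mode,
                                            bin_size=fine_repli)
        scale = fine_repli / repli_bin
        s, g1 = simulate.simulate_repliseq(
            dataclasses.replace(config_x,
                                repli_depth=config_x.repli_depth * scale),
            rate, stream=zlib.crc32(name.encode()) % 1000)
        prof[name] = repliseq.timing_profile(s, g1, fine_repli,
                                             chrom=config_x.chrom,
                                             haplotype=name)
    shift = repliseq.timing_shift(prof["mut_xi"], prof["wt_xi"], domains)
    report["stages"]["repliseq"] = {
        "delta_z_median_within": shift.median_within,
        "delta_z_median_outside": shift.median_outside,
        "delta_z_gap": shift.median_within - shift.median_outside,
        "rank_sum_p": shift.p_value,
    }
    if out:
        for name, pr in prof.items():
            io.write_bedgraph(pr.chrom, pr.bin_size, pr.zscore,
                              out / f"repli_z_{name}.bedgraph")

    # -- stage: integration ---------------------------------------------------
    raw_p = [meth_contrast.p_value, p_expr, shift.p_value]
    corrected = statstests.bonferroni(raw_p)
    report["stages"]["integration"] = {
        "contrasts": {
            "methylation_in_domains": {"p": meth_contrast.p_value,
                                       "p_bonferroni": float(corrected[0])},
            "derepression_in_domains": {"p": p_expr,
                                        "p_bonferroni": float(corrected[1])},
            "timing_advance_in_domains": {"p": shift.p_value,
                                          "p_bonferroni": float(corrected[2])},
        },
    }

    report = _jsonable(report)
    if out:
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        with open(out / "truth.json", "w") as fh:
            json.dump(_jsonable(simulate.truth_summary(config_x)), fh,
                      indent=2)
    return report
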