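"""Synthetic diploid chromosome with planted allele-specific structure.

The generator emulates the data landscape of a hybrid female fibroblast in
which the two X haplotypes can be told apart by strain SNPs:

* an "Xa-like" (active) haplotype — genes expressed, high gene-body CpG
  methylation, TADs and A/B compartments present;
* an "Xi-like" (inactive) haplotype — genes silenced, chromosome-wide CpG
  hypomethylation, H3K27me3-coated, mid/late replication, two Hi-C
  mega-domains with attenuated TADs and compartments;
* a "mutant Xi" variant — sub-megabase derepression domains planted on the
  Xi-like background (gene reactivation, gene-body CpG gain, H3K27me3
  depletion, advanced replication timing) together with restored TADs and
  compartmentalisation.

Every planted feature is recorded as ground truth so downstream callers
have a recoverable answer. Ground-truth read origins are written to a
separate truth file; analysis modules never see them.

All randomness flows from ``SimulationConfig.seed`` through per-assay
seed streams, so a fixed config yields byte-identical output.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import (AllelicTrack, ConfigurationError, ContactMatrix,
                   GenomicDomain, Read, SnpTable, domain_mask)

_BASES = np.array(["A", "C", "G", "T"])

#: planted Xi gene classes and their cohort proportions (dependent genes
#: reactivate fully in the mutant, partial genes reactivate to a low level,
#: escapees are expressed from Xi already in wild type, independent genes
#: stay silent).
DEFAULT_CLASS_COUNTS = {"dependent": 67, "partial": 163,
                        "escapee": 28, "independent": 142}

HIC_MODES = ("active-like", "inactive-like", "mutant-inactive-like")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic diploid chromosome.

    Bin sizes are in bp; depths are mean read counts per bin (or per gene
    for expression, per CpG for methylation coverage). ``dispersion`` is
    the negative-binomial dispersion used for count noise (0 = Poisson);
    expression counts use their own, smaller dispersion because gene-level
    allelic counts are aggregated over many fragments.
    """

    chrom: str = "chrX"
    chrom_length: int = 20_000_000
    seed: int = 0

    # SNPs / reads
    snp_density: float = 1 / 500
    read_length: int = 100
    base_error_rate: float = 0.0

    # bin sizes per assay
    chip_fine_bin: int = 500
    track_bin: int = 10_000
    hic_bin: int = 100_000
    repli_bin: int = 500_000

    # depths
    chip_depth: float = 30.0            # input reads per track_bin
    hic_depth: float = 100.0            # expected contacts at 1-bin separation
    meth_coverage: float = 10.0         # reads per CpG
    repli_depth: float = 100.0          # reads per repli_bin per fraction
    expr_depth: float = 200.0           # Xa reads per gene

    # noise
    dispersion: float = 0.05
    expression_dispersion: float = 0.02

    # planted epigenomic structure
    planted_domains: list[GenomicDomain] = field(default_factory=list)
    baseline_enrichment: float = 1.0    # Xi H3K27me3 log2(IP/input) background
    domain_enrichment: float = -1.0     # log2 level inside depletion domains

    # methylation (% methylated)
    meth_xa: float = 75.0
    meth_xi: float = 20.0
    meth_domain_gain: float = 60.0      # mutant Xi inside depletion domains
    cpg_density: float = 1 / 200

    # Hi-C structure
    tad_set: list[GenomicDomain] = field(default_factory=list)
    compartment_block: int = 2_000_000
    mega_domain_boundary: int = 10_000_000
    decay_exponent: float = -1.0
    tad_factor: float = 3.0
    compartment_factor: float = 2.0     # active-like and mutant-inactive-like
    compartment_factor_inactive: float = 1.0
    cross_mega_factor: float = 0.5

    # replication timing
    timing_advance_factor: float = 2.0  # S-phase enrichment in advanced regions

    # expression cohort
    n_genes: int = 400
    class_counts: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_COUNTS))
    silenced_leakage: float = 0.02      # residual Xi fraction of a silenced gene
    partial_level: float = 0.15         # mutant-Xi fraction of Xa for partial genes

    def __post_init__(self) -> None:
        if self.chrom_length <= 0:
            raise ConfigurationError("chrom_length must be positive")
        for d in self.planted_domains + self.tad_set:
            if d.end > self.chrom_length:
                raise ConfigurationError(
                    f"planted interval {d.start}-{d.end} exceeds chromosome")
        if not 0 <= self.base_error_rate < 1:
            raise ConfigurationError("base_error_rate must be in [0, 1)")

    def n_bins(self, bin_size: int) -> int:
        return -(-self.chrom_length // bin_size)


def default_config(seed: int = 0, chrom_length: int = 20_000_000,
                   **overrides) -> SimulationConfig:
    """A fully populated study-like configuration.

    Plants 10 depletion domains of 150-400 kb, 20 TADs of ~0.9 Mb (75%
    flagged ``restored`` in the mutant), alternating 2 Mb A/B compartment
    blocks, and a mega-domain boundary at the chromosome midpoint.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, _salt("layout")]))
    domains: list[GenomicDomain] = []
    n_dom = 10
    slot = chrom_length // n_dom
    for k in range(n_dom):
        length = min(int(rng.integers(150_000, 400_000)), slot // 2)
        length = (length // 10_000) * 10_000
        start = k * slot + int(rng.integers(0, max(1, slot - length - 10_000)))
        start = (start // 10_000) * 10_000
        domains.append(GenomicDomain("chrX", start, start + length, "depletion"))

    tads = []
    n_tads = 20
    tad_span = chrom_length // n_tads
    margin = min(50_000, tad_span // 10)
    restored = rng.permutation(n_tads) < int(0.75 * n_tads)
    for k in range(n_tads):
        start = k * tad_span + margin
        end = (k + 1) * tad_span - margin
        tads.append(GenomicDomain("chrX", start, end,
                                  "restored" if restored[k] else "static"))

    cfg = SimulationConfig(chrom_length=chrom_length, seed=seed,
                           planted_domains=domains, tad_set=tads,
                           mega_domain_boundary=chrom_length // 2,
                           **overrides)
    return cfg


def _salt(name: str) -> int:
    return zlib.crc32(name.encode()) & 0x7FFFFFFF


def _rng(config: SimulationConfig, name: str, stream: int = 0):
    return np.random.default_rng(
        np.random.SeedSequence([config.seed, _salt(name), stream]))


def _nb(rng, mean, dispersion: float):
    """Negative-binomial counts with var = mu + dispersion * mu^2."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


# ---------------------------------------------------------------------------
# SNPs


def generate_snp_table(config: SimulationConfig) -> SnpTable:
    """Poisson-placed informative SNPs with two distinct alleles each."""
    if config.snp_density <= 0:
        raise ConfigurationError("snp_density must be positive")
    rng = _rng(config, "snp")
    n = rng.poisson(config.snp_density * config.chrom_length)
    positions = np.sort(rng.choice(config.chrom_length, size=n, replace=False))
    a1 = rng.integers(0, 4, size=n)
    shift = rng.integers(1, 4, size=n)
    a2 = (a1 + shift) % 4
    return SnpTable(config.chrom, positions, _BASES[a1], _BASES[a2])


# ---------------------------------------------------------------------------
# reads


def simulate_reads(config: SimulationConfig, snps: SnpTable,
                   weights_hap1: np.ndarray,
                   weights_hap2: Optional[np.ndarray] = None,
                   n_reads: int = 10_000,
                   bin_size: Optional[int] = None,
                   stream: int = 0) -> list[Read]:
    """Reads drawn proportionally to per-bin rate tracks, one per haplotype.

    Each read records the allele of its true haplotype at every covered
    SNP; with ``config.base_error_rate > 0`` an observation flips to the
    other haplotype's allele independently per SNP.
    """
    w1 = np.asarray(weights_hap1, dtype=float)
    w2 = w1 if weights_hap2 is None else np.asarray(weights_hap2, dtype=float)
    if np.any(w1 < 0) or np.any(w2 < 0):
        raise ConfigurationError("weights must be non-negative")
    total = w1.sum() + w2.sum()
    if total == 0:
        raise ConfigurationError("all-zero weight tracks")
    if bin_size is None:
        bin_size = -(-config.chrom_length // len(w1))
    rng = _rng(config, "reads", stream)

    p = np.concatenate([w1, w2]) / total
    picks = rng.choice(len(p), size=n_reads, p=p)
    hap_idx = picks >= len(w1)
    bins = np.where(hap_idx, picks - len(w1), picks)
    offsets = rng.integers(0, bin_size, size=n_reads)
    starts = np.minimum(bins * bin_size + offsets,
                        config.chrom_length - config.read_length)
    alleles = {"hap1": snps.allele_hap1, "hap2": snps.allele_hap2}

    reads = []
    for k in range(n_reads):
        start = int(starts[k])
        end = start + config.read_length
        origin = "hap2" if hap_idx[k] else "hap1"
        other = "hap1" if origin == "hap2" else "hap2"
        lo = np.searchsorted(snps.positions, start)
        hi = np.searchsorted(snps.positions, end)
        obs = []
        for s in range(lo, hi):
            base = alleles[origin][s]
            if config.base_error_rate > 0 and rng.random() < config.base_error_rate:
                base = alleles[other][s]
            obs.append((int(snps.positions[s]), str(base)))
        reads.append(Read(config.chrom, start, end, tuple(obs),
                          read_id=f"r{stream}_{k}", true_origin=origin))
    return reads


# ---------------------------------------------------------------------------
# ChIP enrichment


def enrichment_profile(config: SimulationConfig, mode: str,
                       bin_size: Optional[int] = None) -> np.ndarray:
    """Planted per-bin log2(IP/input) profile for the Xi haplotype.

    ``wild-type``: uniform H3K27me3 coating at ``baseline_enrichment``;
    ``mutant``: coating with depletion domains dropped to
    ``domain_enrichment``.
    """
    if mode not in ("wild-type", "mutant"):
        raise ConfigurationError(f"unknown ChIP mode {mode!r}")
    bin_size = bin_size or config.track_bin
    n = config.n_bins(bin_size)
    profile = np.full(n, config.baseline_enrichment)
    if mode == "mutant":
        inside = domain_mask(config.planted_domains, n, bin_size, config.chrom)
        profile[inside] = config.domain_enrichment
    return profile


def simulate_chip_tracks(config: SimulationConfig, mode: str,
                         bin_size: Optional[int] = None,
                         depth: Optional[float] = None,
                         stream: int = 0) -> tuple[AllelicTrack, AllelicTrack]:
    """(IP, input) allelic count tracks for an Xi-coating ChIP experiment.

    Xi (hap2 by convention) IP counts follow the planted enrichment
    profile; the Xa haplotype (hap1) carries no enrichment. Input counts
    are flat at ``depth`` for both haplotypes.

    Defaults emulate the fine-binned protocol: counts at ``chip_fine_bin``
    resolution with ``chip_depth`` (which is quoted per ``track_bin``)
    scaled down proportionally; log-ratios are then averaged into coarse
    intervals downstream, which suppresses single-bin count noise.
    """
    bin_size = bin_size or config.chip_fine_bin
    if depth is None:
        depth = config.chip_depth * bin_size / config.track_bin
    n = config.n_bins(bin_size)
    rng = _rng(config, "chip-" + mode, stream)
    profile = enrichment_profile(config, mode, bin_size)
    ip_xi = _nb(rng, depth * 2.0 ** profile, config.dispersion)
    ip_xa = _nb(rng, np.full(n, depth), config.dispersion)
    in_xi = _nb(rng, np.full(n, depth), config.dispersion)
    in_xa = _nb(rng, np.full(n, depth), config.dispersion)
    zeros = np.zeros(n)
    ip = AllelicTrack(config.chrom, bin_size, ip_xa, ip_xi, zeros)
    inp = AllelicTrack(config.chrom, bin_size, in_xa, in_xi, zeros.copy())
    return ip, inp


# ---------------------------------------------------------------------------
# Hi-C


def compartment_labels(config: SimulationConfig, bin_size: int) -> np.ndarray:
    """Alternating A/B block labels; A blocks are even-indexed."""
    n = config.n_bins(bin_size)
    mids = (np.arange(n) + 0.5) * bin_size
    block = (mids // config.compartment_block).astype(int)
    return np.where(block % 2 == 0, "A", "B")


def simulate_hic(config: SimulationConfig, mode: str,
                 stream: int = 0) -> ContactMatrix:
    """Contact matrix for one of the three chromatin regimes.

    Expected count for bins i != j is
    ``hic_depth * |i-j|^decay_exponent`` times structure factors:
    same-TAD boost (active-like always; mutant-inactive-like only for TADs
    labelled ``restored``), same-compartment boost (attenuated on the
    inactive-like Xi), and a cross-mega-domain depletion on both
    inactive regimes. Counts are negative-binomial and symmetric.
    """
    if mode not in HIC_MODES:
        raise ConfigurationError(f"unknown Hi-C mode {mode!r}")
    if config.decay_exponent >= 0:
        raise ConfigurationError("decay_exponent must be negative")
    bin_size = config.hic_bin
    n = config.n_bins(bin_size)
    rng = _rng(config, "hic-" + mode, stream)

    idx = np.arange(n)
    sep = np.abs(idx[:, None] - idx[None, :]).astype(float)
    expected = config.hic_depth * np.maximum(sep, 1.0) ** config.decay_exponent

    mids = (idx + 0.5) * bin_size
    if mode == "active-like":
        boosted_tads = config.tad_set
    elif mode == "mutant-inactive-like":
        boosted_tads = [t for t in config.tad_set if t.label == "restored"]
    else:
        boosted_tads = []
    for t in boosted_tads:
        inb = (mids >= t.start) & (mids < t.end)
        expected[np.ix_(inb, inb)] *= config.tad_factor

    cfac = (config.compartment_factor_inactive if mode == "inactive-like"
            else config.compartment_factor)
    if cfac != 1.0:
        labels = compartment_labels(config, bin_size)
        same = labels[:, None] == labels[None, :]
        expected[same] *= cfac

    if mode in ("inactive-like", "mutant-inactive-like"):
        right = mids >= config.mega_domain_boundary
        cross = right[:, None] != right[None, :]
        expected[cross] *= config.cross_mega_factor

    iu = np.triu_indices(n)
    counts = np.zeros((n, n))
    counts[iu] = _nb(rng, expected[iu], config.dispersion)
    counts = counts + np.triu(counts, 1).T
    return ContactMatrix(config.chrom, mode, bin_size, counts)


# ---------------------------------------------------------------------------
# methylation


def simulate_methylation(config: SimulationConfig, baseline_pct: float,
                         domains: Sequence[GenomicDomain] = (),
                         domain_pct: Optional[float] = None,
                         stream: int = 0) -> pd.DataFrame:
    """CpG-site methylation calls for one haplotype.

    Sites are Poisson-placed at ``cpg_density``; coverage is Poisson at
    ``meth_coverage``; methylated counts are Binomial(coverage, p) with p
    set to ``domain_pct`` inside ``domains`` (a per-domain ``score``
    overrides it) and ``baseline_pct`` elsewhere.
    """
    for pct in [baseline_pct] + [d.score for d in domains if d.score is not None]:
        if not 0 <= pct <= 100:
            raise ConfigurationError(f"methylation % {pct} outside [0, 100]")
    if domain_pct is not None and not 0 <= domain_pct <= 100:
        raise ConfigurationError(f"methylation % {domain_pct} outside [0, 100]")
    rng = _rng(config, "meth", stream)
    n_sites = rng.poisson(config.cpg_density * config.chrom_length)
    pos = np.sort(rng.choice(config.chrom_length, size=n_sites, replace=False))
    p = np.full(n_sites, baseline_pct / 100.0)
    for d in domains:
        pct = d.score if d.score is not None else domain_pct
        if pct is None:
            raise ConfigurationError("domain methylation % not specified")
        inside = (pos >= d.start) & (pos < d.end)
        p[inside] = pct / 100.0
    coverage = rng.poisson(config.meth_coverage, size=n_sites)
    meth = rng.binomial(coverage, p)
    return pd.DataFrame({"chrom": config.chrom, "pos": pos,
                         "meth_count": meth, "total_count": coverage})


# ---------------------------------------------------------------------------
# replication timing


def timing_rate_profile(config: SimulationConfig, mode: str,
                        bin_size: Optional[int] = None) -> np.ndarray:
    """Relative S-phase read rate per bin (1 = neutral).

    ``active-like``: early replication in A compartment blocks;
    ``inactive-like``: uniformly mid/late; ``mutant-inactive-like``:
    mid/late with timing advanced inside the planted depletion domains.
    """
    if mode not in HIC_MODES:
        raise ConfigurationError(f"unknown timing mode {mode!r}")
    bin_size = bin_size or config.repli_bin
    n = config.n_bins(bin_size)
    rate = np.ones(n)
    if mode == "active-like":
        rate[compartment_labels(config, bin_size)[:n] == "A"] = \
            config.timing_advance_factor
    elif mode == "mutant-inactive-like":
        inside = domain_mask(config.planted_domains, n, bin_size, config.chrom)
        rate[inside] = config.timing_advance_factor
    return rate


def simulate_repliseq(config: SimulationConfig, rate_profile: np.ndarray,
                      stream: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """(S counts, G1 counts) per bin given a relative S-rate profile."""
    rate = np.asarray(rate_profile, dtype=float)
    if np.any(rate < 0):
        raise ConfigurationError("rate profile must be non-negative")
    rng = _rng(config, "repli", stream)
    s = _nb(rng, config.repli_depth * rate, config.dispersion)
    g1 = _nb(rng, np.full(len(rate), config.repli_depth), config.dispersion)
    return s.astype(float), g1.astype(float)


# ---------------------------------------------------------------------------
# expression


def generate_genes(config: SimulationConfig) -> pd.DataFrame:
    """Gene annotation with planted Xi classes.

    Dependent and partial genes (the derepression-prone classes) are
    placed inside the planted depletion domains; escapees and independent
    genes outside — emulating the observed co-location of derepressed
    genes with H3K27me3 depletion domains. Genes placed outside the
    domains preferentially land in A-compartment blocks (roughly 4:1),
    reproducing the gene-density/compartment correlation that anchors
    eigenvector orientation.
    """
    rng = _rng(config, "genes")
    counts = dict(config.class_counts)
    total = sum(counts.values())
    if total != config.n_genes:
        raise ConfigurationError(
            f"class counts sum to {total}, expected n_genes={config.n_genes}")
    classes = [c for c, k in counts.items() for _ in range(k)]
    rows = []
    inside_classes = {"dependent", "partial"}
    dom_cycle = 0
    for gid, cls in enumerate(classes):
        length = int(np.clip(rng.lognormal(np.log(15_000), 0.5), 2_000, 80_000))
        if cls in inside_classes and config.planted_domains:
            d = config.planted_domains[dom_cycle % len(config.planted_domains)]
            dom_cycle += 1
            length = min(length, d.length - 200)
            start = d.start + int(rng.integers(0, d.length - length))
        else:
            block = config.compartment_block
            for _ in range(200):
                start = int(rng.integers(0, config.chrom_length - length))
                g = GenomicDomain(config.chrom, start, start + length)
                if any(g.overlaps(d) for d in config.planted_domains):
                    continue
                in_a = ((start + length // 2) // block) % 2 == 0
                if in_a or rng.random() < 0.25:
                    break
        rows.append({"gene_id": f"g{gid:04d}", "chrom": config.chrom,
                     "start": start, "end": start + length,
                     "strand": "+" if rng.random() < 0.5 else "-",
                     "planted_class": cls})
    return pd.DataFrame(rows).sort_values("start").reset_index(drop=True)


def simulate_expression(config: SimulationConfig, genes: pd.DataFrame,
                        stream: int = 0) -> pd.DataFrame:
    """Allelic nascent-RNA counts per gene in both conditions.

    hap1 = Xa, hap2 = Xi. Xi counts per class, relative to the gene's Xa
    level: escapee wt/mut ~ Xa; dependent wt ~ leakage, mut ~ Xa; partial
    wt ~ leakage, mut ~ ``partial_level`` of Xa; independent ~ leakage in
    both conditions.
    """
    rng = _rng(config, "expr", stream)
    leak = config.silenced_leakage
    rel = {"escapee": (0.9, 0.9),
           "dependent": (leak, 1.0),
           "partial": (leak, config.partial_level),
           "independent": (leak, leak)}
    out = genes.copy()
    base = rng.lognormal(np.log(config.expr_depth), 0.5, size=len(genes))
    wt_xi_rel = np.array([rel[c][0] for c in genes["planted_class"]])
    mut_xi_rel = np.array([rel[c][1] for c in genes["planted_class"]])
    disp = config.expression_dispersion
    out["wt_hap1"] = _nb(rng, base, disp)
    out["wt_hap2"] = _nb(rng, base * wt_xi_rel, disp)
    out["mut_hap1"] = _nb(rng, base, disp)
    out["mut_hap2"] = _nb(rng, base * mut_xi_rel, disp)
    return out


# ---------------------------------------------------------------------------
# truth export


def truth_summary(config: SimulationConfig) -> dict:
    """JSON-serialisable record of every planted feature."""
    return {
        "chrom": config.chrom,
        "chrom_length": config.chrom_length,
        "seed": config.seed,
        "depletion_domains": [[d.start, d.end] for d in config.planted_domains],
        "tads": [[t.start, t.end, t.label] for t in config.tad_set],
        "mega_domain_boundary": config.mega_domain_boundary,
        "compartment_block": config.compartment_block,
        "class_counts": dict(config.class_counts),
    }
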