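"""ChIP enrichment tracks, depletion-domain calling, peak allele
specificity, and bisulfite methylation summaries.

The central caller reproduces the bespoke Xi depletion-domain definition:
maximal runs of bins with mean log2(IP/input) below 0, with adjacent
negative runs merged whenever the gap separating them is no more than
20 kb (inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import (AllelicTrack, ConfigurationError, DataError,
                   EnrichmentTrack, GenomicDomain)


# ---------------------------------------------------------------------------
# enrichment tracks


def enrichment_track(ip: AllelicTrack, input_: AllelicTrack,
                     haplotype: str = "hap2",
                     coarse_bin: int = 10_000,
                     pseudocount: float = 1.0,
                     scale: Optional[float] = None) -> EnrichmentTrack:
    """log2(IP/input) per fine bin, averaged within coarse bins.

    IP counts are library-size scaled to the input total before the
    pseudocounted log-ratio; the coarse value is the mean of defined fine
    values, NaN when a coarse bin contains none.

    ``scale`` overrides the library-size factor. On a chromosome with
    genuine chromosome-wide enrichment, scaling IP to the local input
    total would cancel the coating itself; pass a factor estimated
    genome-wide (in practice: from an unenriched control chromosome).
    """
    if ip.bin_size != input_.bin_size or ip.n_bins != input_.n_bins:
        raise ConfigurationError("IP and input tracks must share bin structure")
    if coarse_bin % ip.bin_size != 0:
        raise ConfigurationError("coarse_bin must be a multiple of the fine bin")
    ip_v = ip.values(haplotype).astype(float)
    in_v = input_.values(haplotype).astype(float)
    ip_total, in_total = ip_v.sum(), in_v.sum()
    if ip_total == 0 or in_total == 0:
        raise DataError("IP or input track has zero total coverage")
    if scale is None:
        scale = in_total / ip_total
    fine = np.log2((ip_v * scale + pseudocount) / (in_v + pseudocount))
    fine[(ip_v == 0) & (in_v == 0)] = np.nan  # no coverage at all -> undefined

    k = coarse_bin // ip.bin_size
    n_coarse = -(-len(fine) // k)
    padded = np.full(n_coarse * k, np.nan)
    padded[:len(fine)] = fine
    with np.errstate(invalid="ignore"):
        coarse = np.nanmean(padded.reshape(n_coarse, k), axis=1)
    return EnrichmentTrack(ip.chrom, coarse_bin, coarse)


# ---------------------------------------------------------------------------
# depletion domains


@dataclass
class DomainSummary:
    count: int
    mean_length: float   # bp; NaN when no domains


def call_depletion_domains(track: EnrichmentTrack, threshold: float = 0.0,
                           max_gap: int = 20_000, min_len: int = 0,
                           ) -> tuple[list[GenomicDomain], DomainSummary]:
    """Runs of bins below ``threshold``, merged across gaps <= ``max_gap``.

    Missing (NaN) bins are never part of a run but do count toward the
    gap separating two runs. Domains shorter than ``min_len`` bp are
    dropped after merging.
    """
    if max_gap < 0:
        raise ConfigurationError("max_gap must be non-negative")
    bs = track.bin_size
    values = track.log2_ratio
    below = np.zeros(track.n_bins, dtype=bool)
    defined = ~np.isnan(values)
    below[defined] = values[defined] < threshold

    runs: list[tuple[int, int]] = []       # bin-index half-open runs
    start = None
    for i, b in enumerate(below):
        if b and start is None:
            start = i
        elif not b and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(below)))

    merged: list[tuple[int, int]] = []
    for s, e in runs:
        if merged and (s - merged[-1][1]) * bs <= max_gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))

    domains = [GenomicDomain(track.chrom, s * bs, e * bs, "depletion")
               for s, e in merged if (e - s) * bs >= min_len]
    lengths = [d.length for d in domains]
    summary = DomainSummary(len(domains),
                            float(np.mean(lengths)) if lengths else float("nan"))
    return domains, summary


def call_peaks_simple(track: EnrichmentTrack, threshold: float,
                      min_bins: int = 1) -> list[GenomicDomain]:
    """Plumbing peak caller: maximal runs of bins >= threshold."""
    values = track.log2_ratio
    above = np.zeros(track.n_bins, dtype=bool)
    defined = ~np.isnan(values)
    above[defined] = values[defined] >= threshold
    peaks = []
    start = None
    for i in range(len(above) + 1):
        if i < len(above) and above[i]:
            if start is None:
                start = i
        elif start is not None:
            if i - start >= min_bins:
                peaks.append(GenomicDomain(track.chrom,
                                           start * track.bin_size,
                                           i * track.bin_size, "peak"))
            start = None
    return peaks


# ---------------------------------------------------------------------------
# allelic peaks


@dataclass
class AllelicPeak:
    """A peak with input-corrected allelic read counts (Xi, Xa)."""

    interval: GenomicDomain
    reads_xi: float
    reads_xa: float

    def __post_init__(self) -> None:
        if self.reads_xi < 0 or self.reads_xa < 0:
            raise DataError("peak read counts must be non-negative")

    @property
    def total(self) -> float:
        return self.reads_xi + self.reads_xa


def allelic_specificity_score(peak: AllelicPeak) -> float:
    """Occupancy-ratio score: 100 = fully Xi-specific, -100 = fully Xa."""
    if peak.total == 0:
        raise DataError("specificity score undefined for a zero-read peak")
    return 100.0 * (peak.reads_xi - peak.reads_xa) / peak.total


def classify_peak_allelicity(peak: AllelicPeak,
                             exclusivity: float = 0.90) -> str:
    """Xi-specific / Xa-specific when one haplotype holds > 90% of reads.

    The threshold is a strict inequality: a peak with exactly 90% on one
    haplotype counts as present on both.
    """
    if peak.total == 0:
        raise DataError("allelicity undefined for a zero-read peak")
    frac_xi = peak.reads_xi / peak.total
    if frac_xi > exclusivity:
        return "Xi-specific"
    if 1.0 - frac_xi > exclusivity:
        return "Xa-specific"
    return "both"


def input_corrected_peaks(intervals: Sequence[GenomicDomain],
                          ip: AllelicTrack, input_: AllelicTrack,
                          xi: str = "hap2", xa: str = "hap1",
                          ) -> list[AllelicPeak]:
    """Allelic IP counts per peak, scaled by the haplotype input ratio.

    The Xi IP count is multiplied by (Xa input)/(Xi input) over the peak,
    cancelling haplotype coverage bias before the specificity ratio.
    """
    peaks = []
    for iv in intervals:
        lo, hi = iv.start // ip.bin_size, -(-iv.end // ip.bin_size)
        ip_xi = float(ip.values(xi)[lo:hi].sum())
        ip_xa = float(ip.values(xa)[lo:hi].sum())
        in_xi = float(input_.values(xi)[lo:hi].sum())
        in_xa = float(input_.values(xa)[lo:hi].sum())
        corr = (in_xa / in_xi) if in_xi > 0 and in_xa > 0 else 1.0
        peaks.append(AllelicPeak(iv, ip_xi * corr, ip_xa))
    return peaks


# ---------------------------------------------------------------------------
# methylation


def methylation_track(sites: pd.DataFrame, bin_size: int = 10_000,
                      min_coverage: int = 3,
                      n_bins: Optional[int] = None) -> EnrichmentTrack:
    """Per-bin % methylation, averaging sites covered by >= ``min_coverage``.

    The bin value is the unweighted mean over retained sites of
    100 * meth/total; bins without a retained site are NaN. Returned as an
    ``EnrichmentTrack`` whose values are percentages, not log-ratios.
    """
    if (sites["meth_count"] > sites["total_count"]).any():
        raise DataError("methylated count exceeds total coverage")
    kept = sites[sites["total_count"] >= min_coverage]
    chrom = str(sites["chrom"].iloc[0]) if len(sites) else ""
    if n_bins is None:
        n_bins = int(sites["pos"].max()) // bin_size + 1 if len(sites) else 0
    values = np.full(n_bins, np.nan)
    if len(kept):
        pct = 100.0 * kept["meth_count"].to_numpy() / kept["total_count"].to_numpy()
        bins = kept["pos"].to_numpy() // bin_size
        sums = np.bincount(bins, weights=pct, minlength=n_bins)
        counts = np.bincount(bins, minlength=n_bins)
        nz = counts > 0
        values[nz] = sums[nz] / counts[nz]
    return EnrichmentTrack(chrom, bin_size, values)


# ---------------------------------------------------------------------------
# profiles over annotated sites


def values_at_sites(sites: Sequence[GenomicDomain],
                    track: EnrichmentTrack) -> np.ndarray:
    """Mean defined track value over the bins overlapping each site."""
    out = np.full(len(sites), np.nan)
    for k, s in enumerate(sites):
        lo = s.start // track.bin_size
        hi = -(-s.end // track.bin_size)
        vals = track.log2_ratio[lo:hi]
        if np.any(~np.isnan(vals)):
            out[k] = np.nanmean(vals)
    return out


def order_sites_by_value(sites: Sequence[GenomicDomain],
                         values: np.ndarray,
                         descending: bool = True) -> list[int]:
    """Stable ordering of site indices by value; ties broken by coordinate."""
    keys = [(-v if descending else v, s.start, s.end)
            for v, s in zip(np.nan_to_num(values, nan=-np.inf if descending
                                          else np.inf), sites)]
    return sorted(range(len(sites)), key=lambda i: keys[i])


def metagene_profile(genes: Sequence[GenomicDomain], track: EnrichmentTrack,
                     flank: int = 5_000, n_body_bins: int = 20,
                     strands: Optional[Sequence[str]] = None,
                     ) -> np.ndarray:
    """Missing-aware average profile over scaled gene bodies plus flanks.

    Each gene body is rescaled to ``n_body_bins`` equal sub-intervals;
    flanks are binned at the track's native bin size. Minus-strand genes
    are reversed so the profile runs 5' -> 3'. Genes shorter than one
    body sub-interval (less than one track bin per sub-interval would
    still be fine; the limit is a zero-length sub-interval) are skipped.
    Returns an array of length ``n_flank + n_body_bins + n_flank``.
    """
    bs = track.bin_size
    n_flank = flank // bs
    width = 2 * n_flank + n_body_bins
    profiles = []
    for k, g in enumerate(genes):
        if g.length < n_body_bins:
            continue
        row = np.full(width, np.nan)
        for f in range(n_flank):  # upstream flank (left in + orientation)
            start = g.start - (n_flank - f) * bs
            row[f] = _segment_mean(track, start, start + bs)
        for b in range(n_body_bins):
            lo = g.start + (b * g.length) // n_body_bins
            hi = g.start + ((b + 1) * g.length) // n_body_bins
            row[n_flank + b] = _segment_mean(track, lo, hi)
        for f in range(n_flank):
            start = g.end + f * bs
            row[n_flank + n_body_bins + f] = _segment_mean(track, start,
                                                           start + bs)
        strand = strands[k] if strands is not None else "+"
        if strand == "-":
            row = row[::-1]
        profiles.append(row)
    if not profiles:
        return np.full(width, np.nan)
    with np.errstate(invalid="ignore"):
        return np.nanmean(np.vstack(profiles), axis=0)


def _segment_mean(track: EnrichmentTrack, start: int, end: int) -> float:
    if end <= start or end <= 0 or start >= track.n_bins * track.bin_size:
        return float("nan")
    lo = max(start, 0) // track.bin_size
    hi = -(-min(end, track.n_bins * track.bin_size) // track.bin_size)
    vals = track.log2_ratio[lo:hi]
    if np.all(np.isnan(vals)):
        return float("nan")
    return float(np.nanmean(vals))
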