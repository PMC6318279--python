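"""Replication timing from S- and G1-fraction read counts.

The per-bin timing index is the read-number-normalised S/G1 ratio,
z-scored over the defined bins of one chromosome-haplotype; a higher
z-score means earlier replication.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import ConfigurationError, DataError, GenomicDomain, TimingProfile
from .core import domain_mask


def timing_profile(s_counts: np.ndarray, g1_counts: np.ndarray,
                   bin_size: int, chrom: str = "",
                   haplotype: str = "") -> TimingProfile:
    """S/G1 ratio and z-score per bin.

    Each fraction is first scaled by its total read count; a bin enters
    the profile only when both fractions have at least one read, and is
    NaN otherwise. Z-scores use the sample s.d. over defined bins.
    """
    s = np.asarray(s_counts, dtype=float)
    g1 = np.asarray(g1_counts, dtype=float)
    if len(s) != len(g1):
        raise ConfigurationError("S and G1 tracks must have equal length")
    if s.sum() <= 0 or g1.sum() <= 0:
        raise DataError("both fractions need nonzero totals")
    ratio = np.full(len(s), np.nan)
    ok = (s > 0) & (g1 > 0)
    if not ok.any():
        raise DataError("no bin has reads in both fractions")
    ratio[ok] = (s[ok] / s.sum()) / (g1[ok] / g1.sum())
    mean = np.nanmean(ratio)
    sd = np.nanstd(ratio, ddof=1) if ok.sum() > 1 else 0.0
    z = np.full(len(s), np.nan)
    z[ok] = 0.0 if sd == 0 else (ratio[ok] - mean) / sd
    return TimingProfile(chrom, haplotype, bin_size, s, g1, ratio, z)


@dataclass
class TimingShift:
    delta_z: np.ndarray          # z_a - z_b per common defined bin (NaN else)
    median_within: float
    median_outside: float
    statistic: float
    p_value: float


def timing_shift(profile_a: TimingProfile, profile_b: TimingProfile,
                 domains: list[GenomicDomain],
                 alternative: str = "two-sided") -> TimingShift:
    """Per-bin timing difference, contrasted within vs outside domains.

    Delta-z is z(a) - z(b) over bins defined in both profiles; the two
    groups (bins inside vs outside ``domains``) are compared with a
    Mann-Whitney rank-sum test.
    """
    if profile_a.bin_size != profile_b.bin_size or \
            len(profile_a.zscore) != len(profile_b.zscore):
        raise ConfigurationError("profiles must share the bin grid")
    dz = profile_a.zscore - profile_b.zscore
    defined = np.isfinite(dz)
    if not defined.any():
        raise DataError("no common defined bins")
    inside = domain_mask(domains, len(dz), profile_a.bin_size,
                         profile_a.chrom or None)
    within = dz[defined & inside]
    outside = dz[defined & ~inside]
    if len(outside) == 0 or len(within) == 0:
        return TimingShift(dz, float(np.median(within)) if len(within)
                           else float("nan"),
                           float(np.median(outside)) if len(outside)
                           else float("nan"),
                           float("nan"), float("nan"))
    res = stats.mannwhitneyu(within, outside, alternative=alternative)
    return TimingShift(dz, float(np.median(within)),
                       float(np.median(outside)),
                       float(res.statistic), float(res.pvalue))
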