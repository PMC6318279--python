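"""Cross-assay comparison machinery: rank tests, Bonferroni correction,
region-set contrasts and domain-overlap statistics."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .core import ConfigurationError, EnrichmentTrack, GenomicDomain
from .core import domain_mask, merge_domains


def rank_sum_test(values_a: Sequence[float], values_b: Sequence[float],
                  alternative: str = "two-sided") -> tuple[float, float]:
    """Mann-Whitney U test; returns (U statistic for group a, p-value).

    Exact null distribution when the pooled sample has no ties and at
    most 20 observations; otherwise the normal approximation with
    mid-rank tie correction.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ConfigurationError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def bonferroni(p_values: Iterable[float], m: int | None = None) -> np.ndarray:
    """min(1, m * p) per value; m defaults to the number of tests."""
    p = np.asarray(list(p_values), dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ConfigurationError("p-values must lie in [0, 1]")
    if m is None:
        m = len(p)
    return np.minimum(1.0, m * p)


@dataclass
class RegionContrast:
    """Inside-vs-outside comparison of a binned track over a domain set."""

    track_id: str
    n_inside: int
    n_outside: int
    median_inside: float
    median_outside: float
    quartiles_inside: tuple[float, float]
    quartiles_outside: tuple[float, float]
    statistic: float
    p_value: float
    p_corrected: float | None = None


def contrast_by_regions(track: EnrichmentTrack,
                        domains: Sequence[GenomicDomain],
                        track_id: str = "",
                        alternative: str = "two-sided") -> RegionContrast:
    """Rank-sum contrast of defined bins inside vs outside a domain set."""
    values = track.log2_ratio
    defined = np.isfinite(values)
    inside = domain_mask(domains, track.n_bins, track.bin_size,
                         track.chrom or None)
    vin = values[defined & inside]
    vout = values[defined & ~inside]
    if len(vin) == 0 or len(vout) == 0:
        raise ConfigurationError("one contrast group is empty")
    stat, p = rank_sum_test(vin, vout, alternative=alternative)
    q_in = tuple(np.percentile(vin, [25, 75]))
    q_out = tuple(np.percentile(vout, [25, 75]))
    return RegionContrast(track_id, len(vin), len(vout),
                          float(np.median(vin)), float(np.median(vout)),
                          (float(q_in[0]), float(q_in[1])),
                          (float(q_out[0]), float(q_out[1])),
                          stat, p)


def boxplot_summary(values: Sequence[float]) -> dict:
    """Quartiles, median and 1.5*IQR outliers (the figure-style summary)."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return {"q1": float(q1), "median": float(med), "q3": float(q3),
            "whisker_low": float(v[v >= lo].min()),
            "whisker_high": float(v[v <= hi].max()),
            "outliers": [float(x) for x in v[(v < lo) | (v > hi)]]}


@dataclass
class OverlapResult:
    jaccard: float                    # |A n B| / |A u B| in bp
    bp_intersection: int
    bp_union: int
    matched_a: list[bool]             # reciprocal-overlap flags per domain
    matched_b: list[bool]


def domain_overlap(set_a: Sequence[GenomicDomain],
                   set_b: Sequence[GenomicDomain],
                   reciprocal: float = 0.25) -> OverlapResult:
    """Base-pair Jaccard index and per-domain reciprocal-overlap matches.

    Sets are merged internally first so self-overlap cannot inflate the
    union. A domain is "matched" when some domain of the other set
    covers at least ``reciprocal`` of BOTH lengths.
    """
    a = merge_domains(list(set_a)) if set_a else []
    b = merge_domains(list(set_b)) if set_b else []
    inter = 0
    for da in a:
        for db in b:
            if da.chrom == db.chrom:
                inter += max(0, min(da.end, db.end) - max(da.start, db.start))
    len_a = sum(d.length for d in a)
    len_b = sum(d.length for d in b)
    union = len_a + len_b - inter
    jacc = inter / union if union > 0 else 0.0

    def _matched(xs, ys):
        flags = []
        for dx in xs:
            ok = False
            for dy in ys:
                if dx.chrom != dy.chrom:
                    continue
                ov = max(0, min(dx.end, dy.end) - max(dx.start, dy.start))
                if ov >= reciprocal * dx.length and ov >= reciprocal * dy.length:
                    ok = True
                    break
            flags.append(ok)
        return flags

    return OverlapResult(jacc, inter, union, _matched(a, b), _matched(b, a))
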