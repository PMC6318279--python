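"""Core data containers shared across the toolkit.

All genomic coordinates are 0-based, half-open. Binned tracks hold one
value per bin; bin ``i`` covers ``[i * bin_size, (i + 1) * bin_size)``.
Missing values are represented as NaN throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np


class ConfigurationError(ValueError):
    """Raised when a configuration or precondition is invalid."""


class DataError(ValueError):
    """Raised when input data violate a format-level invariant."""


# ---------------------------------------------------------------------------
# intervals


@dataclass(frozen=True)
class GenomicDomain:
    """Half-open genomic interval with an optional label and score."""

    chrom: str
    start: int
    end: int
    label: str = ""
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise DataError(
                f"domain start must be < end, got [{self.start}, {self.end})"
            )
        if self.start < 0:
            raise DataError(f"negative domain start {self.start}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicDomain") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def with_score(self, score: float) -> "GenomicDomain":
        return replace(self, score=score)


def merge_domains(domains: Sequence[GenomicDomain], gap: int = 0) -> list[GenomicDomain]:
    """Merge overlapping or near-adjacent domains (per chromosome).

    Domains whose gap is <= ``gap`` bp are merged; labels of merged
    domains are dropped.
    """
    out: list[GenomicDomain] = []
    for chrom in sorted({d.chrom for d in domains}):
        ds = sorted((d for d in domains if d.chrom == chrom), key=lambda d: d.start)
        cur_start, cur_end = ds[0].start, ds[0].end
        for d in ds[1:]:
            if d.start - cur_end <= gap:
                cur_end = max(cur_end, d.end)
            else:
                out.append(GenomicDomain(chrom, cur_start, cur_end))
                cur_start, cur_end = d.start, d.end
        out.append(GenomicDomain(chrom, cur_start, cur_end))
    return out


def domain_mask(domains: Iterable[GenomicDomain], n_bins: int, bin_size: int,
                chrom: Optional[str] = None) -> np.ndarray:
    """Boolean per-bin mask: True where the bin midpoint falls in a domain."""
    mask = np.zeros(n_bins, dtype=bool)
    mids = (np.arange(n_bins) + 0.5) * bin_size
    for d in domains:
        if chrom is not None and d.chrom != chrom:
            continue
        mask |= (mids >= d.start) & (mids < d.end)
    return mask


# ---------------------------------------------------------------------------
# SNPs and reads


@dataclass
class SnpTable:
    """Positions distinguishing the two parental haplotypes."""

    chrom: str
    positions: np.ndarray          # int64, sorted, unique
    allele_hap1: np.ndarray        # unit-length strings
    allele_hap2: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.allele_hap1 = np.asarray(self.allele_hap1)
        self.allele_hap2 = np.asarray(self.allele_hap2)
        if not (len(self.positions) == len(self.allele_hap1) == len(self.allele_hap2)):
            raise DataError("SNP table columns have unequal lengths")
        if len(self.positions) > 1 and np.any(np.diff(self.positions) <= 0):
            raise DataError("SNP positions must be strictly increasing")
        if np.any(self.allele_hap1 == self.allele_hap2):
            raise DataError("hap1 and hap2 alleles must differ at every SNP")

    def __len__(self) -> int:
        return len(self.positions)

    def swapped(self) -> "SnpTable":
        """Table with haplotype-1 and haplotype-2 alleles exchanged."""
        return SnpTable(self.chrom, self.positions.copy(),
                        self.allele_hap2.copy(), self.allele_hap1.copy())


@dataclass
class Read:
    """A (synthetic) aligned read carrying observed bases at SNP positions.

    ``true_origin`` is simulation ground truth used only for scoring
    assignment accuracy; analysis code never inspects it.
    """

    chrom: str
    start: int
    end: int
    snp_observations: tuple[tuple[int, str], ...] = ()
    read_id: str = ""
    pair_id: Optional[str] = None
    true_origin: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise DataError("read start must be < end")
        for pos, _ in self.snp_observations:
            if not (self.start <= pos < self.end):
                raise DataError(
                    f"SNP observation at {pos} outside read [{self.start}, {self.end})"
                )


# ---------------------------------------------------------------------------
# binned tracks


@dataclass
class AllelicTrack:
    """Per-bin values carried separately for both haplotypes and unassigned."""

    chrom: str
    bin_size: int
    values_hap1: np.ndarray
    values_hap2: np.ndarray
    values_unassigned: np.ndarray

    def __post_init__(self) -> None:
        self.values_hap1 = np.asarray(self.values_hap1, dtype=float)
        self.values_hap2 = np.asarray(self.values_hap2, dtype=float)
        self.values_unassigned = np.asarray(self.values_unassigned, dtype=float)
        if self.bin_size <= 0:
            raise ConfigurationError("bin_size must be positive")
        n = len(self.values_hap1)
        if not (len(self.values_hap2) == len(self.values_unassigned) == n):
            raise DataError("allelic track vectors have unequal lengths")

    @property
    def n_bins(self) -> int:
        return len(self.values_hap1)

    def values(self, haplotype: str) -> np.ndarray:
        return {"hap1": self.values_hap1, "hap2": self.values_hap2,
                "unassigned": self.values_unassigned}[haplotype]


@dataclass
class EnrichmentTrack:
    """log2(IP/input) per bin; NaN where coverage was absent."""

    chrom: str
    bin_size: int
    log2_ratio: np.ndarray

    def __post_init__(self) -> None:
        self.log2_ratio = np.asarray(self.log2_ratio, dtype=float)
        if self.bin_size <= 0:
            raise ConfigurationError("bin_size must be positive")

    @property
    def n_bins(self) -> int:
        return len(self.log2_ratio)


# ---------------------------------------------------------------------------
# Hi-C


@dataclass
class ContactMatrix:
    """Symmetric binned contact counts for one chromosome and haplotype."""

    chrom: str
    haplotype: str
    bin_size: int
    counts: np.ndarray
    weights: Optional[np.ndarray] = None   # KR balancing weights, NaN where masked
    mask: Optional[np.ndarray] = None      # True = excluded from balancing

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise DataError("contact matrix must be square")
        if not np.allclose(self.counts, self.counts.T):
            raise DataError("contact matrix must be symmetric")
        if np.any(self.counts < 0):
            raise DataError("contact counts must be non-negative")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> float:
        """Total count over distinct pairs (upper triangle incl. diagonal)."""
        return float(np.triu(self.counts).sum())

    def balanced(self) -> np.ndarray:
        """diag(w) . counts . diag(w); NaN rows/cols where masked."""
        if self.weights is None:
            raise ValueError("matrix has no balancing weights; run kr_balance first")
        w = self.weights
        return self.counts * w[:, None] * w[None, :]

    def coarsen(self, factor: int) -> "ContactMatrix":
        """Aggregate counts into bins ``factor`` times larger."""
        if factor <= 0:
            raise ConfigurationError("coarsening factor must be positive")
        n = self.n_bins
        m = -(-n // factor)
        pad = m * factor - n
        c = np.pad(self.counts, ((0, pad), (0, pad)))
        c = c.reshape(m, factor, m, factor).sum(axis=(1, 3))
        return ContactMatrix(self.chrom, self.haplotype,
                             self.bin_size * factor, c)


@dataclass
class InsulationTrack:
    """Insulation scores (log2 relative to chromosome mean) and boundary calls."""

    chrom: str
    bin_size: int
    score: np.ndarray
    delta: np.ndarray
    boundaries: list[int] = field(default_factory=list)


@dataclass
class CompartmentProfile:
    """First eigenvector of the Hi-C O/E correlation matrix plus A/B labels."""

    chrom: str
    bin_size: int
    eigenvector: np.ndarray          # NaN where masked
    labels: np.ndarray               # 'A', 'B' or '' where masked


@dataclass
class TimingProfile:
    """Replication-timing profile from S and G1 fraction read counts."""

    chrom: str
    haplotype: str
    bin_size: int
    s_counts: np.ndarray
    g1_counts: np.ndarray
    ratio: np.ndarray
    zscore: np.ndarray
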