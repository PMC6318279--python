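"""SNP-based partitioning of reads between parental haplotypes.

A read is assigned to haplotype 1 when at least one observed base matches
the haplotype-1 allele at a covered SNP and none matches haplotype 2 (and
symmetrically for haplotype 2); reads covering no informative SNP, or
whose observed bases match neither allele, are unassigned; reads with
support for both haplotypes are flagged conflicting. Paired-end mates
sharing a pair id are labelled as a unit by pooling their observations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .core import AllelicTrack, ConfigurationError, Read, SnpTable

LABELS = ("hap1", "hap2", "unassigned", "conflicting")


def assign_read(read: Read, snps: SnpTable) -> str:
    """Label one read (or one pooled observation set) by its SNP content."""
    return _assign_obs(read.snp_observations, snps)


def _assign_obs(observations: Sequence[tuple[int, str]], snps: SnpTable) -> str:
    support1 = support2 = 0
    for pos, base in observations:
        i = np.searchsorted(snps.positions, pos)
        if i >= len(snps) or snps.positions[i] != pos:
            continue  # observation at a non-SNP position carries no information
        if base == snps.allele_hap1[i]:
            support1 += 1
        elif base == snps.allele_hap2[i]:
            support2 += 1
    if support1 and support2:
        return "conflicting"
    if support1:
        return "hap1"
    if support2:
        return "hap2"
    return "unassigned"


@dataclass
class ReadPartition:
    """Reads split into the four assignment subsets, plus label fractions."""

    subsets: dict[str, list[Read]] = field(
        default_factory=lambda: {lab: [] for lab in LABELS})

    @property
    def n_reads(self) -> int:
        return sum(len(v) for v in self.subsets.values())

    @property
    def fractions(self) -> dict[str, float]:
        n = self.n_reads
        return {lab: (len(v) / n if n else 0.0)
                for lab, v in self.subsets.items()}

    def summary(self) -> dict:
        return {"n_reads": self.n_reads,
                "counts": {lab: len(v) for lab, v in self.subsets.items()},
                "fractions": self.fractions}


def sort_reads(reads: Iterable[Read], snps: SnpTable) -> ReadPartition:
    """Partition reads into hap1 / hap2 / unassigned / conflicting subsets.

    Mates with the same ``pair_id`` are assigned jointly from their pooled
    SNP observations and both receive the joint label.
    """
    reads = list(reads)
    partition = ReadPartition()
    pairs: dict[str, list[Read]] = {}
    for r in reads:
        if r.pair_id is not None:
            pairs.setdefault(r.pair_id, []).append(r)
        else:
            partition.subsets[assign_read(r, snps)].append(r)
    for mates in pairs.values():
        obs = tuple(o for m in mates for o in m.snp_observations)
        label = _assign_obs(obs, snps)
        partition.subsets[label].extend(mates)
    return partition


def bin_reads(partition: ReadPartition, bin_size: int,
              chrom_length: int | None = None) -> AllelicTrack:
    """Count reads per bin by start coordinate, one layer per label.

    Conflicting reads are pooled with unassigned in the output track (they
    are excluded from both allelic subsets downstream) but remain separate
    in the partition for diagnostics.
    """
    if bin_size <= 0:
        raise ConfigurationError("bin_size must be positive")
    all_reads = [r for lab in LABELS for r in partition.subsets[lab]]
    if chrom_length is None:
        chrom_length = max((r.end for r in all_reads), default=bin_size)
    chrom = all_reads[0].chrom if all_reads else ""
    n_bins = -(-chrom_length // bin_size)
    layers = {}
    for lab in LABELS:
        counts = np.zeros(n_bins)
        for r in partition.subsets[lab]:
            counts[r.start // bin_size] += 1
        layers[lab] = counts
    return AllelicTrack(chrom, bin_size, layers["hap1"], layers["hap2"],
                        layers["unassigned"] + layers["conflicting"])


def assignment_accuracy(partition: ReadPartition,
                        truth: dict[str, str]) -> dict[str, float]:
    """Score hap1/hap2 assignments against a ground-truth origin map.

    ``misassignment`` is the fraction of assigned reads whose label
    contradicts the truth; ``accuracy`` is 1 minus that.
    """
    assigned = correct = 0
    for lab in ("hap1", "hap2"):
        for r in partition.subsets[lab]:
            assigned += 1
            if truth.get(r.read_id) == lab:
                correct += 1
    return {"n_assigned": assigned,
            "accuracy": correct / assigned if assigned else float("nan"),
            "misassignment": (assigned - correct) / assigned
            if assigned else float("nan")}
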