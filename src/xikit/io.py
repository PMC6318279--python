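"""Readers and writers for the plain-text formats used throughout.

Formats:

* SNP table — tab-separated ``chrom  pos  hap1_base  hap2_base``
* reads — tab-separated ``read_id  chrom  start  end  obs  pair_id`` where
  ``obs`` encodes SNP observations as ``pos:base;pos:base;...`` (``.`` if none)
* BED — ``chrom  start  end  name  score``
* bedGraph — ``chrom  start  end  value``
* contact matrix — triplet text ``bin_i  bin_j  count`` with a JSON sidecar
  header (chrom, haplotype, bin_size, n_bins)
* methylation calls — ``chrom  pos  meth_count  total_count``
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import yaml

from .core import ContactMatrix, DataError, GenomicDomain, Read, SnpTable


# -- SNP tables -------------------------------------------------------------

def write_snp_table(snps: SnpTable, path) -> None:
    df = pd.DataFrame({
        "chrom": snps.chrom,
        "pos": snps.positions,
        "hap1_base": snps.allele_hap1,
        "hap2_base": snps.allele_hap2,
    })
    df.to_csv(path, sep="\t", index=False, header=False)


def read_snp_table(path) -> SnpTable:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "pos", "hap1_base", "hap2_base"],
                     dtype={"hap1_base": str, "hap2_base": str})
    chroms = df["chrom"].unique()
    if len(chroms) != 1:
        raise DataError(f"expected a single chromosome per SNP table, got {chroms}")
    return SnpTable(str(chroms[0]), df["pos"].to_numpy(),
                    df["hap1_base"].to_numpy(), df["hap2_base"].to_numpy())


# -- reads ------------------------------------------------------------------

def _encode_obs(obs: tuple[tuple[int, str], ...]) -> str:
    return ";".join(f"{p}:{b}" for p, b in obs) if obs else "."


def _decode_obs(s: str) -> tuple[tuple[int, str], ...]:
    if s == "." or s == "":
        return ()
    out = []
    for item in s.split(";"):
        p, b = item.split(":")
        out.append((int(p), b))
    return tuple(out)


def write_reads(reads: Iterable[Read], path) -> None:
    """Write reads WITHOUT their true origin (kept in a separate truth file)."""
    with open(path, "w") as fh:
        for r in reads:
            pair = r.pair_id if r.pair_id is not None else "."
            fh.write(f"{r.read_id}\t{r.chrom}\t{r.start}\t{r.end}\t"
                     f"{_encode_obs(r.snp_observations)}\t{pair}\n")


def read_reads(path) -> list[Read]:
    reads = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 6:
                raise DataError(f"{path}: malformed read record at line {lineno}")
            rid, chrom, start, end, obs, pair = parts
            reads.append(Read(chrom, int(start), int(end), _decode_obs(obs),
                              read_id=rid, pair_id=None if pair == "." else pair))
    return reads


def write_read_truth(reads: Iterable[Read], path) -> None:
    """Ground-truth origins, one ``read_id  origin`` line per read."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"{r.read_id}\t{r.true_origin}\n")


def read_read_truth(path) -> dict[str, str]:
    truth = {}
    with open(path) as fh:
        for line in fh:
            rid, origin = line.split()
            truth[rid] = origin
    return truth


# -- BED / bedGraph ---------------------------------------------------------

def write_bed(domains: Iterable[GenomicDomain], path,
              score_scale: float = 1.0) -> None:
    with open(path, "w") as fh:
        for d in domains:
            score = 0 if d.score is None else int(round(d.score * score_scale))
            name = d.label if d.label else "."
            fh.write(f"{d.chrom}\t{d.start}\t{d.end}\t{name}\t{score}\n")


def read_bed(path) -> list[GenomicDomain]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DataError(f"{path}: malformed BED at line {lineno}")
            label = parts[3].strip() if len(parts) > 3 else ""
            score = float(parts[4]) if len(parts) > 4 else None
            out.append(GenomicDomain(parts[0], int(parts[1]), int(parts[2]),
                                     "" if label == "." else label, score))
    return out


def write_bedgraph(chrom: str, bin_size: int, values: np.ndarray, path) -> None:
    """One line per defined (non-NaN) bin."""
    with open(path, "w") as fh:
        for i, v in enumerate(np.asarray(values, dtype=float)):
            if np.isnan(v):
                continue
            fh.write(f"{chrom}\t{i * bin_size}\t{(i + 1) * bin_size}\t{v:.6g}\n")


def read_bedgraph(path, bin_size: Optional[int] = None,
                  n_bins: Optional[int] = None) -> tuple[str, int, np.ndarray]:
    """Return (chrom, bin_size, values); undefined bins are NaN."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise DataError(f"{path}: malformed bedGraph at line {lineno}")
            rows.append((parts[0], int(parts[1]), int(parts[2]), float(parts[3])))
    if not rows:
        raise DataError(f"{path}: empty bedGraph")
    chrom = rows[0][0]
    if bin_size is None:
        bin_size = rows[0][2] - rows[0][1]
    if n_bins is None:
        n_bins = max(r[2] for r in rows) // bin_size
    values = np.full(n_bins, np.nan)
    for _, start, _, v in rows:
        values[start // bin_size] = v
    return chrom, bin_size, values


# -- contact matrices -------------------------------------------------------

def write_contact_matrix(matrix: ContactMatrix, path) -> None:
    """Triplet text (upper triangle, nonzero entries) plus a JSON sidecar."""
    path = Path(path)
    i, j = np.nonzero(np.triu(matrix.counts))
    with open(path, "w") as fh:
        for a, b in zip(i, j):
            fh.write(f"{a}\t{b}\t{matrix.counts[a, b]:.6g}\n")
    header = {"chrom": matrix.chrom, "haplotype": matrix.haplotype,
              "bin_size": matrix.bin_size, "n_bins": matrix.n_bins}
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(header, fh)


def read_contact_matrix(path) -> ContactMatrix:
    path = Path(path)
    with open(path.with_suffix(path.suffix + ".json")) as fh:
        header = json.load(fh)
    n = header["n_bins"]
    counts = np.zeros((n, n))
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) != 3:
                raise DataError(f"{path}: malformed triplet at line {lineno}")
            i, j, c = int(parts[0]), int(parts[1]), float(parts[2])
            counts[i, j] = c
            counts[j, i] = c
    return ContactMatrix(header["chrom"], header["haplotype"],
                         header["bin_size"], counts)


# -- methylation ------------------------------------------------------------

def write_methylation_calls(df: pd.DataFrame, path) -> None:
    df[["chrom", "pos", "meth_count", "total_count"]].to_csv(
        path, sep="\t", index=False, header=False)


def read_methylation_calls(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "pos", "meth_count", "total_count"])
    if (df["meth_count"] > df["total_count"]).any():
        raise DataError(f"{path}: methylated count exceeds coverage")
    return df


# -- config -----------------------------------------------------------------

def read_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_yaml(obj: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)
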