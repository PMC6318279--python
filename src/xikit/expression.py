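"""Copy-number-normalised allelic expression and Xi gene classification.

Gene tables are pandas DataFrames with columns ``gene_id, chrom, start,
end, strand`` and allelic counts ``<condition>_<haplotype>`` (e.g.
``wt_hap1``). By convention hap1 is the active X (Xa) and hap2 the
inactive X (Xi).

The classifier splits X-linked genes expressed on Xa into four classes by
their Xi behaviour across wild type (wt) and mutant (mut):

* ``escapee`` — expressed from Xi already in wt;
* ``dependent`` — silent on wt Xi, reactivated in the mutant to a level
  not significantly different from Xa;
* ``partial`` — reactivated in the mutant but significantly below Xa;
* ``independent`` — silent on Xi in both conditions.

Significance uses per-gene beta-binomial tests on the Xi fraction of
allelic counts (overdispersion absorbs gene-level biological noise) with
Benjamini-Hochberg correction across genes, plus a one-sided Fisher test
for the wt-to-mutant increase in Xi fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import AllelicTrack, ConfigurationError, DataError

CLASSES = ("escapee", "dependent", "partial", "independent")


# ---------------------------------------------------------------------------
# copy number


def estimate_copy_number(input_tracks: dict[str, AllelicTrack],
                         reference: str) -> pd.DataFrame:
    """Per (chromosome, haplotype) coverage factors from input tracks.

    The factor is the median per-bin allelic input coverage relative to
    the same haplotype of the reference chromosome, which is assumed to
    be a balanced diploid autosome; reference factors are exactly 1.
    """
    if reference not in input_tracks:
        raise ConfigurationError(f"reference chromosome {reference!r} missing")
    ref = input_tracks[reference]
    rows = []
    ref_medians = {}
    for hap in ("hap1", "hap2"):
        med = float(np.median(ref.values(hap)))
        if med <= 0:
            raise DataError(f"zero reference input coverage for {hap}")
        ref_medians[hap] = med
    for chrom, track in input_tracks.items():
        for hap in ("hap1", "hap2"):
            med = float(np.median(track.values(hap)))
            if med <= 0:
                raise DataError(f"zero input coverage for {chrom}/{hap}")
            rows.append({"chrom": chrom, "haplotype": hap,
                         "factor": med / ref_medians[hap]})
    return pd.DataFrame(rows)


def _factor(factors: pd.DataFrame, chrom: str, hap: str) -> float:
    sel = factors[(factors["chrom"] == chrom) & (factors["haplotype"] == hap)]
    if sel.empty:
        raise ConfigurationError(f"no copy-number factor for {chrom}/{hap}")
    return float(sel["factor"].iloc[0])


def normalize_expression(genes: pd.DataFrame, factors: pd.DataFrame,
                         conditions: tuple[str, ...] = ("wt", "mut"),
                         ) -> pd.DataFrame:
    """Expression = count / copy-number factor / gene length in kb."""
    out = genes.copy()
    length_kb = (out["end"] - out["start"]) / 1000.0
    for cond in conditions:
        for hap in ("hap1", "hap2"):
            col = f"{cond}_{hap}"
            fac = out["chrom"].map(
                lambda c, h=hap: _factor(factors, c, h))
            out[f"expr_{col}"] = out[col] / fac / length_kb
    return out


def xi_percent(record: pd.Series, condition: str,
               xi: str = "hap2", xa: str = "hap1") -> float:
    """Xi expression as a percentage of Xa for one gene and condition."""
    xa_expr = record[f"expr_{condition}_{xa}"]
    if xa_expr <= 0:
        raise DataError("Xi %% undefined when Xa expression is zero")
    return 100.0 * record[f"expr_{condition}_{xi}"] / xa_expr


# ---------------------------------------------------------------------------
# significance machinery


def betabinom_test(k: int, n: int, p: float, rho: float,
                   alternative: str = "two-sided") -> float:
    """Exact beta-binomial test of k successes in n at fraction ``p``.

    ``rho`` is the overdispersion (intra-class correlation); rho -> 0
    recovers the binomial. Two-sided p sums outcome probabilities not
    exceeding that of the observation.
    """
    if n == 0:
        return 1.0
    if not 0 < p < 1:
        raise ConfigurationError("null fraction must be in (0, 1)")
    if rho <= 0:
        dist = stats.binom(n, p)
    else:
        s = (1 - rho) / rho
        dist = stats.betabinom(n, p * s, (1 - p) * s)
    if alternative == "greater":
        return float(dist.sf(k - 1))
    if alternative == "less":
        return float(dist.cdf(k))
    pmf_k = dist.pmf(k)
    support = np.arange(n + 1)
    return float(dist.pmf(support)[dist.pmf(support) <= pmf_k * (1 + 1e-9)].sum())


@dataclass
class ClassifierConfig:
    """Thresholds of the four-way Xi classifier."""

    alpha: float = 0.05
    escape_threshold: float = 10.0   # minimum wt Xi %% of Xa to call escape
    background_fraction: float = 0.05  # Xi read fraction of a silenced gene
    overdispersion: float = 0.02     # beta-binomial rho for allelic counts
    min_xa_counts: int = 10          # eligibility: Xa expressed


def classify_genes(genes: pd.DataFrame,
                   config: ClassifierConfig | None = None,
                   expected_xi_fraction: float = 0.5) -> pd.DataFrame:
    """Four-way Xi classification of genes expressed on Xa.

    ``expected_xi_fraction`` is the copy-number-expected Xi share of
    allelic counts for equal biallelic expression (0.5 for a balanced
    diploid). Three BH-corrected test families across genes:

    1. wt Xi fraction above the silenced background (escape test);
    2. mutant Xi fraction above the wt Xi fraction (derepression,
       one-sided Fisher on the two allelic count pairs);
    3. mutant Xi fraction vs the Xa-equality fraction (beta-binomial,
       ``less`` = expressed below Xa).
    """
    cfg = config or ClassifierConfig()
    df = genes.copy()
    eligible = (df["wt_hap1"] + df["mut_hap1"]) >= cfg.min_xa_counts
    df["eligible"] = eligible

    p_escape, p_derep, p_below = [], [], []
    for _, g in df.iterrows():
        wt_xi, wt_xa = int(g["wt_hap2"]), int(g["wt_hap1"])
        mut_xi, mut_xa = int(g["mut_hap2"]), int(g["mut_hap1"])
        p_escape.append(betabinom_test(wt_xi, wt_xi + wt_xa,
                                       cfg.background_fraction,
                                       cfg.overdispersion, "greater"))
        p_derep.append(stats.fisher_exact(
            [[mut_xi, mut_xa], [wt_xi, wt_xa]], alternative="greater")[1])
        p_below.append(betabinom_test(mut_xi, mut_xi + mut_xa,
                                      expected_xi_fraction,
                                      cfg.overdispersion, "less"))
    for name, ps in [("p_escape", p_escape), ("p_derep", p_derep),
                     ("p_below_xa", p_below)]:
        df[name] = ps
        mask = eligible.to_numpy()
        adj = np.full(len(df), np.nan)
        if mask.any():
            adj[mask] = multipletests(np.asarray(ps)[mask],
                                      method="fdr_bh")[1]
        df["q" + name[1:]] = adj

    classes = []
    for _, g in df.iterrows():
        if not g["eligible"]:
            classes.append("excluded")
            continue
        wt_total = g["wt_hap1"] + g["wt_hap2"]
        wt_pct = 100.0 * g["wt_hap2"] / max(g["wt_hap1"], 1) \
            if wt_total else 0.0
        if g["q_escape"] < cfg.alpha and wt_pct >= cfg.escape_threshold:
            classes.append("escapee")
        elif g["q_derep"] < cfg.alpha:
            if g["q_below_xa"] < cfg.alpha:
                classes.append("partial")
            else:
                classes.append("dependent")
        else:
            classes.append("independent")
    df["class"] = classes
    return df


def class_counts(classified: pd.DataFrame) -> dict[str, int]:
    counts = {c: 0 for c in CLASSES}
    for c in classified.loc[classified["class"] != "excluded", "class"]:
        counts[c] = counts.get(c, 0) + 1
    return counts
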