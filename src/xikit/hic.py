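"""Hi-C contact-matrix analysis: depth equalisation, Knight-Ruiz
balancing, distance decay, insulation scores, A/B compartment
eigenvectors and the TAD re-establishment statistic.

Matrices are dense symmetric per-chromosome count arrays. Balancing
makes every unmasked row and column of ``diag(w) M diag(w)`` sum to 1;
bins with a zero marginal are masked first and reappear as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import (CompartmentProfile, ConfigurationError, ContactMatrix,
                   DataError, GenomicDomain, InsulationTrack)


class ConvergenceError(RuntimeError):
    """Knight-Ruiz iteration failed to reach the requested tolerance."""


# ---------------------------------------------------------------------------
# depth equalisation


def _subsample_matrix(matrix: ContactMatrix, target: int, rng) -> ContactMatrix:
    """Subsample counts without replacement to ``target`` total pairs."""
    n = matrix.n_bins
    iu = np.triu_indices(n)
    colors = np.rint(matrix.counts[iu]).astype(np.int64)
    total = int(colors.sum())
    if target > total:
        raise ConfigurationError(
            f"cannot subsample {total} contacts up to {target}")
    if target == total:
        return ContactMatrix(matrix.chrom, matrix.haplotype, matrix.bin_size,
                             matrix.counts.copy())
    kept = rng.multivariate_hypergeometric(colors, target, method="marginals")
    counts = np.zeros((n, n))
    counts[iu] = kept
    counts = counts + np.triu(counts, 1).T
    return ContactMatrix(matrix.chrom, matrix.haplotype, matrix.bin_size, counts)


def downsample_equalize(samples: dict[str, dict[str, ContactMatrix]],
                        seed: int = 0) -> dict[str, dict[str, ContactMatrix]]:
    """Match sequencing depth across samples, then per-chromosome totals.

    ``samples`` maps sample name -> chromosome -> matrix. Each sample is
    first randomly down-sampled (without replacement) to the genome-wide
    total of the smallest sample; a second per-chromosome pass then
    equalises chromosome totals across samples, normalising for copy
    number. Symmetry is preserved throughout.
    """
    if len(samples) < 2:
        raise ConfigurationError("need at least two samples to equalise")
    for name, chroms in samples.items():
        for chrom, m in chroms.items():
            if m.total == 0:
                raise DataError(f"empty matrix for {name}/{chrom}")
    rng = np.random.default_rng(seed)

    totals = {name: sum(int(round(m.total)) for m in chroms.values())
              for name, chroms in samples.items()}
    floor = min(totals.values())
    stage1: dict[str, dict[str, ContactMatrix]] = {}
    for name, chroms in samples.items():
        keep = floor / totals[name]
        out = {}
        for chrom, m in chroms.items():
            target = int(round(int(round(m.total)) * keep))
            out[chrom] = _subsample_matrix(m, target, rng)
        stage1[name] = out

    result: dict[str, dict[str, ContactMatrix]] = {name: {} for name in samples}
    chrom_names = next(iter(stage1.values())).keys()
    for chrom in chrom_names:
        floor_c = min(int(round(stage1[name][chrom].total)) for name in stage1)
        for name in stage1:
            result[name][chrom] = _subsample_matrix(stage1[name][chrom],
                                                    floor_c, rng)
    return result


# ---------------------------------------------------------------------------
# Knight-Ruiz balancing


def _bnewt(A: np.ndarray, tol: float, delta: float = 0.1, Delta: float = 3.0,
           max_outer: int = 100) -> np.ndarray:
    """Inner-outer Newton iteration for matrix balancing.

    Finds x > 0 with diag(x) A diag(x) doubly stochastic; the inner loop
    is conjugate gradient on the Newton system, damped so the iterates
    stay within [delta, Delta] of the current scaling.
    """
    n = A.shape[0]
    e = np.ones(n)
    x = e.copy()
    g, etamax = 0.9, 0.1
    eta = etamax
    stop_tol = tol * 0.5
    rt = tol ** 2
    v = x * (A @ x)
    rk = 1.0 - v
    rho_km1 = rk @ rk
    rout = rold = rho_km1
    outer = 0
    while rout > rt:
        outer += 1
        if outer > max_outer:
            raise ConvergenceError(
                f"KR balancing stalled: residual {np.sqrt(rout):.3e} "
                f"after {max_outer} outer iterations")
        k = 0
        y = e.copy()
        innertol = max(eta ** 2 * rout, rt)
        while rho_km1 > innertol:
            k += 1
            if k == 1:
                Z = rk / v
                p = Z.copy()
                rho_km1 = rk @ Z
            w = x * (A @ (x * p)) + v * p
            alpha = rho_km1 / (p @ w)
            ap = alpha * p
            ynew = y + ap
            if ynew.min() <= delta:
                ind = ap < 0
                gamma = np.min((delta - y[ind]) / ap[ind])
                y = y + gamma * ap
                break
            if ynew.max() >= Delta:
                ind = ynew > Delta
                gamma = np.min((Delta - y[ind]) / ap[ind])
                y = y + gamma * ap
                break
            y = ynew
            rk = rk - alpha * w
            rho_km2 = rho_km1
            Z = rk / v
            rho_km1 = rk @ Z
            p = Z + (rho_km1 / rho_km2) * p
        x = x * y
        v = x * (A @ x)
        rk = 1.0 - v
        rho_km1 = rk @ rk
        rout = rho_km1
        rat = rout / rold
        rold = rout
        res_norm = np.sqrt(rout)
        eta_o = eta
        eta = g * rat
        if g * eta_o ** 2 > 0.1:
            eta = max(eta, g * eta_o ** 2)
        eta = max(min(eta, etamax), stop_tol / max(res_norm, 1e-300))
    return x


def kr_balance(matrix: ContactMatrix, tol: float = 1e-6,
               max_iter: int = 100) -> ContactMatrix:
    """Knight-Ruiz balancing; unmasked rows of the balanced matrix sum to 1.

    Rows/columns with a zero marginal are masked out before balancing and
    carry NaN weights. Returns a new matrix with ``weights`` and ``mask``
    set; use :meth:`ContactMatrix.balanced` for the scaled counts.
    """
    counts = matrix.counts
    marginals = counts.sum(axis=1)
    keep = marginals > 0
    if not keep.any():
        raise DataError("cannot balance an all-zero matrix")
    sub = counts[np.ix_(keep, keep)]
    x = _bnewt(sub, tol=tol, max_outer=max_iter)
    weights = np.full(matrix.n_bins, np.nan)
    weights[keep] = x
    out = ContactMatrix(matrix.chrom, matrix.haplotype, matrix.bin_size,
                        counts.copy())
    out.weights = weights
    out.mask = ~keep
    return out


# ---------------------------------------------------------------------------
# distance decay


@dataclass
class DistanceDecay:
    separations_bp: np.ndarray
    prob: np.ndarray           # normalised to sum 1 over s > 0
    slope: float               # log-log slope over the fit range
    far_cis_fraction: float    # contact probability at separations > 10 Mb


def distance_decay(matrix: ContactMatrix,
                   fit_range: tuple[int, int] = (200_000, 5_000_000),
                   far_cis_cutoff: int = 10_000_000) -> DistanceDecay:
    """Contact probability P(s) by separation with a log-log slope fit."""
    n = matrix.n_bins
    if n < 3:
        raise ConfigurationError("need at least 3 bins for distance decay")
    m = matrix.balanced() if matrix.weights is not None else matrix.counts
    seps = np.arange(1, n)
    means = np.array([np.nanmean(np.diagonal(m, offset=int(s)))
                      for s in seps])
    defined = ~np.isnan(means)
    seps, means = seps[defined], means[defined]
    total = means.sum()
    if total <= 0:
        raise DataError("matrix has no off-diagonal signal")
    prob = means / total
    sep_bp = seps * matrix.bin_size

    in_range = (sep_bp >= fit_range[0]) & (sep_bp <= fit_range[1])
    if np.unique(sep_bp[in_range]).size < 3:
        raise ConfigurationError("fit_range contains fewer than 3 separations")
    in_fit = in_range & (prob > 0)
    if in_fit.sum() >= 2:
        slope = float(np.polyfit(np.log10(sep_bp[in_fit]),
                                 np.log10(prob[in_fit]), 1)[0])
    else:
        slope = float("nan")
    far = float(prob[sep_bp > far_cis_cutoff].sum())
    return DistanceDecay(sep_bp, prob, slope, far)


# ---------------------------------------------------------------------------
# insulation


def insulation_score(matrix: ContactMatrix, window: int = 500_000,
                     delta_span: int = 200_000,
                     boundary_strength: float = 0.1) -> InsulationTrack:
    """Sliding square-window insulation with log2-to-mean normalisation.

    The raw score at bin i is the mean of the (balanced, if weights are
    set) counts in the square [i-w, i) x (i, i+w]; the reported score is
    log2(raw / chromosome mean of raw). The delta track is the mean score
    over (i, i+d] minus the mean over [i-d, i); boundaries are score
    minima at upward zero-crossings of delta whose crossing strength
    (delta range over +-d bins) exceeds ``boundary_strength``.
    """
    bs = matrix.bin_size
    w = window // bs
    d = max(delta_span // bs, 1)
    n = matrix.n_bins
    if w < 2:
        raise ConfigurationError("window must span at least 2 bins")
    if 2 * w >= n:
        raise ConfigurationError("window does not fit within the chromosome")
    m = matrix.balanced() if matrix.weights is not None else matrix.counts

    raw = np.full(n, np.nan)
    for i in range(w, n - w):
        block = m[i - w:i, i + 1:i + w + 1]
        if np.any(~np.isnan(block)):
            raw[i] = np.nanmean(block)
    mean_raw = np.nanmean(raw)
    if not np.isfinite(mean_raw) or mean_raw <= 0:
        raise DataError("insulation undefined: no finite window means")
    with np.errstate(divide="ignore", invalid="ignore"):
        score = np.log2(raw / mean_raw)

    delta = np.full(n, np.nan)
    for i in range(n):
        right = score[i + 1:min(i + d, n - 1) + 1]
        left = score[max(i - d, 0):i]
        if len(right) and len(left) and (np.any(~np.isnan(right))
                                         and np.any(~np.isnan(left))):
            delta[i] = np.nanmean(right) - np.nanmean(left)

    boundaries = []
    for i in range(1, n):
        if not (np.isfinite(delta[i - 1]) and np.isfinite(delta[i])):
            continue
        if delta[i - 1] < 0 <= delta[i]:
            lo, hi = max(i - d, 0), min(i + d, n - 1) + 1
            strength = np.nanmax(delta[lo:hi]) - np.nanmin(delta[lo:hi])
            if strength >= boundary_strength:
                seg = score[lo:hi]
                if np.any(np.isfinite(seg)):
                    boundaries.append(lo + int(np.nanargmin(seg)))
    boundaries = sorted(set(boundaries))
    return InsulationTrack(matrix.chrom, bs, score, delta, boundaries)


def insulation_at_boundaries(boundaries: Sequence[int],
                             tracks: dict[str, InsulationTrack]) -> pd.DataFrame:
    """Insulation score at reference boundary bins, one column per sample."""
    rows = {}
    for name, track in tracks.items():
        for b in boundaries:
            if not 0 <= b < len(track.score):
                raise ConfigurationError(f"boundary bin {b} outside track")
        rows[name] = [float(track.score[b]) for b in boundaries]
    df = pd.DataFrame(rows)
    df.insert(0, "boundary_bin", list(boundaries))
    return df


# ---------------------------------------------------------------------------
# compartments


def compartment_eigenvector(matrix: ContactMatrix,
                            gene_density: Optional[np.ndarray] = None,
                            coverage_percentile: float = 0.5,
                            ) -> CompartmentProfile:
    """First eigenvector of the O/E Pearson correlation matrix.

    Bins with zero coverage, or coverage below the given percentile of
    nonzero marginals, are masked. The eigenvector sign is oriented so
    its correlation with ``gene_density`` (when given) is positive;
    positive entries are labelled A, negative B.
    """
    n = matrix.n_bins
    counts = matrix.counts
    marginal = counts.sum(axis=1)
    cutoff = np.percentile(marginal[marginal > 0], coverage_percentile) \
        if (marginal > 0).any() else 0
    keep = marginal >= max(cutoff, np.finfo(float).tiny)
    if keep.sum() < 10:
        raise DataError("fewer than 10 unmasked bins for compartment analysis")

    sub = counts[np.ix_(keep, keep)]
    k = sub.shape[0]
    idx = np.arange(k)
    sep = np.abs(idx[:, None] - idx[None, :])
    expected = np.array([sub.diagonal(offset=s).mean() for s in range(k)])
    exp_mat = expected[sep]
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(exp_mat > 0, sub / exp_mat, 0.0)

    if np.any(oe.std(axis=0) == 0):
        raise DataError("degenerate O/E matrix: constant columns")
    corr = np.corrcoef(oe, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(corr)
    ev = eigvecs[:, -1]

    vec = np.full(n, np.nan)
    vec[keep] = ev
    if gene_density is not None:
        gd = np.asarray(gene_density, dtype=float)
        ok = keep & np.isfinite(gd)
        r = np.corrcoef(vec[ok], gd[ok])[0, 1]
        if np.isfinite(r) and r < 0:
            vec = -vec
    labels = np.where(np.isnan(vec), "", np.where(vec >= 0, "A", "B"))
    return CompartmentProfile(matrix.chrom, matrix.bin_size, vec, labels)


def eigenvector_correlation(profile_1: CompartmentProfile,
                            profile_2: CompartmentProfile) -> float:
    """Pearson r between two eigenvectors over bins defined in both."""
    a, b = profile_1.eigenvector, profile_2.eigenvector
    common = np.isfinite(a) & np.isfinite(b)
    if common.sum() < 3:
        raise ConfigurationError("fewer than 3 common defined bins")
    return float(stats.pearsonr(a[common], b[common]).statistic)


# ---------------------------------------------------------------------------
# TAD re-establishment


def tad_reestablishment(tads: Sequence[GenomicDomain], wt: ContactMatrix,
                        mut: ContactMatrix, min_sep: int = 100_000,
                        ) -> pd.DataFrame:
    """Relative gain of within-TAD contacts in the mutant over wild type.

    Per TAD, C is the sum of counts over bin pairs inside the TAD with
    separation > ``min_sep``; the score is (C_mut - C_wt)/C_wt. TADs are
    classed by the quartiles of the score distribution: weak < Q1,
    medium in [Q1, Q3], strong > Q3. Matrices should have been depth
    equalised first.
    """
    if wt.bin_size != mut.bin_size or wt.n_bins != mut.n_bins:
        raise ConfigurationError("matrices must share bin structure")
    bs = wt.bin_size
    min_bins = min_sep // bs
    rows = []
    for t in tads:
        lo, hi = t.start // bs, t.end // bs
        c_wt = c_mut = 0.0
        for i in range(lo, hi):
            for j in range(i + min_bins + 1, hi):
                c_wt += wt.counts[i, j]
                c_mut += mut.counts[i, j]
        score = (c_mut - c_wt) / c_wt if c_wt > 0 else float("nan")
        rows.append({"chrom": t.chrom, "start": t.start, "end": t.end,
                     "label": t.label, "c_wt": c_wt, "c_mut": c_mut,
                     "score": score})
    df = pd.DataFrame(rows)
    defined = df["score"].notna()
    if defined.any():
        q1, q3 = np.percentile(df.loc[defined, "score"], [25, 75])
        cls = np.where(df["score"] < q1, "weak",
                       np.where(df["score"] > q3, "strong", "medium"))
        cls = np.where(defined, cls, "undefined")
    else:
        cls = ["undefined"] * len(df)
    df["class"] = cls
    return df


def mega_domain_contrast(matrix: ContactMatrix, boundary: int) -> dict:
    """Mean cross-boundary vs within-domain contact at matched separations.

    Diagnostic for the two-mega-domain Xi architecture: for each
    separation with both cross- and same-side pairs, compare mean
    (balanced) contact; reports the mean cross/within ratio.
    """
    m = matrix.balanced() if matrix.weights is not None else matrix.counts
    bs = matrix.bin_size
    bidx = boundary // bs
    n = matrix.n_bins
    ratios = []
    for s in range(1, n):
        diag = np.diagonal(m, offset=s)
        i = np.arange(len(diag))
        cross = (i < bidx) & (i + s >= bidx)
        within = ~cross
        c, w_ = diag[cross], diag[within]
        c, w_ = c[np.isfinite(c)], w_[np.isfinite(w_)]
        if len(c) and len(w_) and w_.mean() > 0:
            ratios.append(c.mean() / w_.mean())
    return {"mean_cross_within_ratio": float(np.mean(ratios)) if ratios
            else float("nan"), "n_separations": len(ratios)}
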