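# Methods

This note documents the models, conventions and numerical choices behind
`xikit`, in the order data flow through the pipeline. Coordinates are
0-based half-open everywhere in memory; BED/bedGraph conventions apply on
disk. Missing values are NaN. All counts are simulated as negative
binomial with variance μ + φμ² (φ = `dispersion`, Poisson at φ = 0).

## Synthetic diploid chromosome

The generator emulates a hybrid female fibroblast X chromosome in three
regimes: an active haplotype (Xa-like), an inactive haplotype (Xi-like)
and a "mutant Xi" in which loss of an Xi-maintenance factor has planted
sub-megabase derepression domains. Every planted feature is exported to a
separate truth file; analysis modules never read `true_origin` or the
truth JSON.

Default study conditions (chosen once, as plausible values for a
domesticus × castaneus hybrid and a 20 Mb model chromosome):

| parameter | default | rationale |
|---|---|---|
| SNP density | 1/500 bp | order of magnitude of strain divergence |
| read length | 100 bp | short-read assay |
| base error rate | 0 (configurable) | assignment-relevant errors only |
| ChIP fine bin / track bin | 500 bp / 10 kb | fine log-ratios averaged per interval |
| ChIP input depth | 30 reads per 10 kb | desk-scale coverage |
| Xi H3K27me3 baseline | +1 log₂(IP/input) | chromosome-wide coating |
| depletion-domain level | −1 log₂ | planted effect size |
| NB dispersion φ | 0.05 (counts), 0.02 (per-gene expression) | modest overdispersion; gene counts aggregate many fragments |
| methylation | Xa 75%, Xi 20%, mutant domains 60% | global Xi hypomethylation, domain-restricted gain |
| CpG density / coverage | 1/200 bp, 10× | genome-like site spacing |
| Hi-C bin / depth | 100 kb, 100 expected contacts at 1-bin separation | ≥10⁵ contacts per matrix |
| distance-decay exponent | −1.0 | canonical P(s) |
| TAD factor / layout | 3×, 20 TADs, 75% restored in the mutant | chromosome-wide TAD restoration |
| compartment factor | 2× same-label (1× = none on wt Xi) | attenuated Xi compartmentalisation |
| mega-domain cross factor | 0.5 | moderate hinge depletion |
| Repli-seq bin / depth | 500 kb (100 kb for shift contrasts), 100 reads per bin per fraction | matches the two analysis resolutions |
| timing advance factor | 2× S-rate in advanced regions | clear early shift |
| gene cohort | 400 genes: 67 dependent, 163 partial, 28 escapee, 142 independent | study-like class proportions |

Genes of the derepression-prone classes (dependent, partial) are placed
inside the planted depletion domains; the others outside, preferentially
(~4:1) in A-compartment blocks. The latter reproduces the gene-density /
compartment correlation that the eigenvector orientation rule relies on.
A second, structure-free chromosome serves as autosome control for
copy-number factors and ChIP library scaling.

What the generator does **not** emulate: sequence-level reads (FASTQ),
mapping bias and mappability holes, PCR duplicates, chromatin-state
heterogeneity between cells, distance-dependent Hi-C noise structure
beyond NB dispersion, or gene-length/expression covariation. Passing
recovery tests therefore demonstrates correctness of the estimators under
a clean generative model, not robustness to alignment artefacts.

## Read assignment

A read (or jointly, both mates of a pair) is `hap1` iff ≥1 observed base
matches the hap1 allele at a covered SNP and none matches hap2;
symmetrically `hap2`; `conflicting` when both haplotypes are supported;
otherwise `unassigned`. Observations at non-SNP positions carry no
information. Conflicting reads are kept as a separate diagnostic subset
but pooled with unassigned in binned tracks, preserving the three-way
downstream split. Binning is by read start coordinate — unbiased for
equal-length reads and independent of fragment overlap.

## ChIP tracks and the depletion-domain caller

Fine-bin values are log₂((IP·s + pc)/(input + pc)) with pseudocount
pc = 1 read; the 10 kb track is the mean of defined fine values in each
interval (averaging ~20 fine bins is what makes the interval-level caller
clean at desk-scale depth). The library factor `s` defaults to scaling IP
to the input total; on a chromosome with genuine chromosome-wide
enrichment that would cancel the coating itself, so the pipeline
estimates `s` on the unenriched autosome control — the single-chromosome
analogue of genome-wide library normalisation.

Depletion domains are maximal runs of intervals with value < 0; runs
separated by ≤ 20 kb are merged transitively ("no more than" is
inclusive: a gap of exactly 20 kb merges, 30 kb does not). Missing
intervals never start a run but count toward gap length. No minimum
length is enforced by default (`min_len` is exposed). The caller is
verified against an independent gap-grouping brute force.

Peak allele specificity divides input-corrected allelic IP counts:
the Xi count is rescaled by the peak's Xa/Xi input ratio (cancelling
coverage bias; the exact historical correction is not published, so this
rule is a documented choice). The score is 100·(Xi−Xa)/(Xi+Xa);
exclusivity calls use a strict > 90% fraction.

## Methylation

Sites with < 3 reads are discarded; a 10 kb bin is the unweighted mean of
100·meth/total over retained sites (so each site contributes equally,
matching per-site averaging rather than read pooling). Metagene profiles
rescale each gene body to a fixed number of sub-intervals, add
fixed-width flanks at the track's bin size, reverse minus-strand genes
and average with a missing-aware mean.

## Expression and the four-way Xi classification

Copy-number factors are median per-bin allelic input coverages relative
to the same haplotype of a reference autosome (assumed balanced diploid;
reference factors are exactly 1). Expression is count / factor / kb of
gene body.

Classification operates on allelic counts (Xi, Xa) per condition with
three BH-corrected test families across genes:

1. **escape** — wt Xi fraction above a silenced-background fraction
   (default 0.05), one-sided beta-binomial;
2. **derepression** — mutant Xi fraction above the wt fraction, one-sided
   Fisher exact on the two count pairs;
3. **below-Xa** — mutant Xi fraction below the copy-number-expected
   biallelic fraction (0.5 for balanced), beta-binomial.

escapee = escape-significant and wt Xi ≥ 10% of Xa; otherwise
dependent = derepressed and *not* below-Xa; partial = derepressed and
below-Xa; independent = the rest. Genes without Xa expression are
excluded. The beta-binomial overdispersion (ρ = 0.02 by default, ρ = 0
recovers the binomial) absorbs gene-level biological noise: a pure
binomial on overdispersed counts systematically rejects Xi = Xa and
miscalls fully reactivated genes as partial. α = 0.05 throughout;
classification is invariant under uniform count rescaling.

## Hi-C

**Equalisation.** Samples are first down-sampled without replacement
(multivariate hypergeometric on upper-triangle counts, preserving
symmetry) to the genome-wide total of the smallest sample, then a second
per-chromosome pass equalises chromosome totals across samples,
normalising copy number. Seeded; identical inputs reproduce identical
output.

**KR balancing.** The Knight–Ruiz inner–outer Newton iteration (conjugate
gradient inner loop, iterates damped to [0.1, 3] of the current scaling)
on the submatrix of bins with nonzero marginals; excluded bins carry NaN
weights. Convergence: ‖1 − rowsums‖₂ ≤ tol (10⁻⁶ relative, row sums
normalised to 1); non-convergence within `max_iter` outer iterations
raises with the residual. Balancing is idempotent and verified by
independent row summation.

**Insulation.** Raw score at bin *i* = mean of balanced counts in the
square [i−w, i) × (i, i+w], w = 500 kb; reported score =
log₂(raw / mean of raw over the chromosome) — the "interval mean"
normalisation mode. Delta = mean score over (i, i+d] minus [i−d, i),
d = 200 kb. Boundaries are score minima at upward zero crossings of
delta whose local delta range exceeds 0.1 (configurable); this
insulation-minimum rule replaces external TAD callers.

**Compartments.** Bins below the 0.5th percentile of nonzero marginal
coverage are masked (a documented stand-in for the historical
coverage-filter setting). O/E divides each entry by its diagonal mean;
the profile is the first eigenvector of the Pearson correlation matrix
of O/E columns, oriented so its correlation with gene density is
positive; A = positive, B = negative. Degenerate (constant-column)
correlation matrices raise with a diagnostic.

**Distance decay.** P(s) is the mean balanced count per separation,
normalised to sum 1 over s > 0; the slope is a least-squares fit of
log₁₀P on log₁₀s over a configurable range (default 0.2–5 Mb — the
published fits quote "linear parts of the curves" without stating the
range); the far-cis fraction is P at s > 10 Mb.

**TAD re-establishment.** Per TAD, C = Σ counts over within-TAD bin pairs
separated by > 100 kb on equalised matrices; score = (C_mut − C_wt)/C_wt;
classes by score quartiles (weak < Q1 < medium < Q3 < strong). Scores of
identical matrices are exactly 0 by construction.

## Replication timing

Ratio per bin = (s/Σs)/(g1/Σg1), defined only where both fractions have
≥ 1 read; z-scores use the sample s.d. over defined bins of one
chromosome-haplotype (the scoring scope is per chromosome-haplotype and
exposed). Higher z = earlier replication. S/G1 is used throughout. The
timing-shift contrast compares Δz = z_a − z_b within vs outside a domain
set with a Mann–Whitney test; Δz is antisymmetric in (a, b) by
construction.

## Rank tests

Mann–Whitney U with the exact null distribution when the pooled sample is
≤ 20 and untied, otherwise the normal approximation with mid-rank tie
correction. Two-sided by default (the published figures do not state
sidedness). Bonferroni = min(1, m·p). Box summaries report quartiles,
median and 1.5×IQR outliers.

## Pipeline problem sizes

The end-to-end demo runs a 20 Mb chromosome: 2,000 track bins (10 kb),
40,000 ChIP fine bins, ~100,000 CpGs, 20,000 reads, 200 Hi-C bins
(100 kb; compartments reported at 500 kb), 200 Repli-seq bins (100 kb)
and the 400-gene cohort — sizes at which every planted effect is
comfortably detectable and a full run plus all recovery analyses
completes in well under a minute on one core.

## Known limitations

* The insulation boundary-strength rule and the compartment coverage
  filter are documented interpretations of tool settings whose internals
  are not published.
* Copy-number estimation assumes a balanced diploid reference autosome.
* The classifier's background fraction and escape threshold are
  operational constants, not estimated from data.
* On a TAD-free matrix the boundary caller still reports weak
  noise-driven minima; downstream comparisons use boundary sets from the
  structured (Xa) reference for this reason.
* Trans-chromosomal Hi-C, loop calling and isoform-level expression are
  out of scope.
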