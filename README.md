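# xikit

Allele-specific epigenome, transcriptome and 3D-genome analysis of the
inactive X chromosome (Xi).

In female hybrid cells the two X chromosomes carry distinguishable strain
SNPs, so sequencing reads can be partitioned between the active (Xa) and
inactive (Xi) haplotypes. `xikit` implements the full allele-resolved
analysis stack used to characterise how a chromosomal protein (such as the
SMC-family protein SmcHD1) shapes Xi chromatin: where its loss lifts
H3K27me3, reactivates genes, redistributes CpG methylation, advances
replication timing and restores TADs and A/B compartments — together with
a synthetic diploid chromosome generator that plants recoverable ground
truth for every stage, so the whole pipeline is testable end to end
without any sequencing data.

## What it computes

* **Read sorting** — a read is assigned to haplotype *h* iff ≥1 observed
  base matches the *h* allele at a covered SNP and none matches the other
  haplotype; reads supporting both are `conflicting`, the rest
  `unassigned`. Paired mates are labelled jointly.
* **ChIP enrichment and depletion domains** — log₂(IP/input) in 500 bp
  fine bins averaged within 10 kb intervals; depletion domains are maximal
  runs of intervals with mean log₂(IP/input) < 0, merging runs separated
  by ≤ 20 kb (inclusive).
* **Peak allele specificity** — the occupancy-ratio score
  100·(Xi−Xa)/(Xi+Xa) ∈ [−100, 100], and the exclusivity rule calling a
  peak Xi- or Xa-specific when one haplotype holds > 90% of
  input-corrected reads.
* **Methylation** — % CpG methylation per 10 kb bin over sites covered by
  ≥ 3 reads; metagene profiles and CGI/CTCF-site summaries.
* **Expression** — copy-number-normalised reads per kb of gene body,
  Xi as % of Xa, and the four-way Xi classification
  (escapee / dependent / partial / independent) from allelic counts with
  beta-binomial and Fisher tests under Benjamini–Hochberg correction.
* **Hi-C** — depth down-sampling and per-chromosome equalisation,
  Knight–Ruiz balancing (every unmasked row/column of diag(w)·M·diag(w)
  sums to the same value), P(s) distance decay with log–log slope,
  insulation score (500 kb square window, 200 kb delta span, log₂ to the
  chromosome mean), A/B compartments as the first eigenvector of the O/E
  Pearson correlation matrix oriented by gene density, and the TAD
  re-establishment score (C_mut − C_wt)/C_wt over within-TAD contacts at
  > 100 kb separation, classed weak/medium/strong by score quartiles.
* **Repli-seq** — read-normalised S/G1 ratio per bin, z-scored per
  chromosome-haplotype (higher z = earlier replication), and the timing
  shift Δz contrasted within vs outside a domain set.
* **Statistics** — Mann–Whitney rank tests (exact for small untied
  samples), Bonferroni correction, inside/outside region contrasts and
  base-pair Jaccard overlap of domain sets.

## Worked example

```bash
xikit run --config demo.yaml --out demo_out     # or: python examples/06_full_pipeline.py
```

with `demo.yaml` containing `seed: 1` and `chrom_length: 20000000`
prints (abridged):

```
assigned reads: 17.9%, accuracy 100.0%
depletion domains: 13 (mean 178 kb, Jaccard vs planted 0.98)
derepressed genes: 219/400
eigenvector correlation: {"wt_xa_vs_wt_xi": 0.19, "wt_xa_vs_mut_xi": 0.83}
integration contrasts (Bonferroni-corrected p):
  methylation_in_domains: 1.19e-129
  derepression_in_domains: 1.40e-35
  timing_advance_in_domains: 1.25e-05
```

Meaning: with ~1 informative SNP per 500 bp, ~18% of 100 bp reads cover a
SNP and every one of them is assigned to its true haplotype; the domain
caller recovers the planted H3K27me3 depletion landscape almost
base-for-base; 219 of 400 Xi genes are called derepressed in the mutant;
compartmentalisation on the mutant Xi correlates with Xa (r = 0.83) while
the wild-type Xi does not (r = 0.19); and CpG hypermethylation, gene
derepression and advanced replication timing all concentrate inside the
called depletion domains (corrected p ≪ 10⁻⁴) — the qualitative triad
that defines the phenotype.

Each capability also has a narrative script under `examples/`, and every
stage is available as a CLI subcommand (`xikit simulate / assign / chip /
methyl / expr / hic / repli / stats`) on standalone files.

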