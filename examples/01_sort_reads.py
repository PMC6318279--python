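"""Sort synthetic diploid reads between parental haplotypes by SNP content.

Builds a 5 Mb chromosome with ~1 informative SNP per 500 bp, simulates
10,000 reads from both haplotypes, partitions them, and scores the
assignment against the generator's ground truth.
"""

import numpy as np

from xikit import allelic, simulate

cfg = simulate.default_config(seed=1, chrom_length=5_000_000)
snps = simulate.generate_snp_table(cfg)
weights = np.ones(cfg.n_bins(cfg.track_bin))
reads = simulate.simulate_reads(cfg, snps, weights, weights, n_reads=10_000)

partition = allelic.sort_reads(reads, snps)
truth = {r.read_id: r.true_origin for r in reads}
score = allelic.assignment_accuracy(partition, truth)

print(f"{len(snps)} SNPs on a {cfg.chrom_length/1e6:.0f} Mb chromosome")
for label, frac in partition.fractions.items():
    print(f"  {label:12s} {frac:6.1%}")
print(f"assignment accuracy vs truth: {score['accuracy']:.1%}")
# With 100 bp reads and 1 SNP / 500 bp, ~18% of reads cover an informative
# SNP; without base errors every assigned read matches its true haplotype.
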