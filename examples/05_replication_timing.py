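"""Replication-timing shift inside H3K27me3 depletion domains.

Builds Repli-seq S/G1 counts for the wild-type and mutant inactive X,
z-scores the normalised ratios, and contrasts the mutant-minus-wild-type
timing shift inside vs outside the planted depletion domains.
"""

from xikit import repliseq, simulate

cfg = simulate.default_config(seed=1, chrom_length=20_000_000,
                              repli_bin=100_000, repli_depth=50.0)

profiles = {}
for stream, (name, mode) in enumerate([("wt_xi", "inactive-like"),
                                       ("mut_xi", "mutant-inactive-like")]):
    rate = simulate.timing_rate_profile(cfg, mode, bin_size=cfg.repli_bin)
    s, g1 = simulate.simulate_repliseq(cfg, rate, stream=stream)
    profiles[name] = repliseq.timing_profile(s, g1, cfg.repli_bin,
                                             chrom="chrX")

shift = repliseq.timing_shift(profiles["mut_xi"], profiles["wt_xi"],
                              cfg.planted_domains)
print(f"median delta-z inside domains:  {shift.median_within:+.2f}")
print(f"median delta-z outside domains: {shift.median_outside:+.2f}")
print(f"rank-sum p = {shift.p_value:.2e}")
# A positive delta-z means the mutant Xi replicates earlier; the advance
# is confined to the depletion domains, mirroring the planted truth.
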