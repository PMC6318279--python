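seed: 1
chrom_length: 20000000
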