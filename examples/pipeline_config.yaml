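# Demo pipeline config: full allele geometry on a 20 kb locus so the
# whole run (18-sample panel, all stages) finishes in well under a
# minute on one CPU.
seed: 7
simulation:
  locus_length: 20000
  tss_offset: 8000
  coverage: 20.0
  error_rate: 0.01
  n_snp_samples: 120
  n_snps: 40
junction_flank: 50
ld_r2_threshold: 0.6
ld_max_gap: 5000
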