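# Extended (higher) heritability settings for robustness checks.
mode: power
assumption: pleiotropy
architectures:
  - additive2
  - additive5
  - additive10
  - single
  - epistatic
  - heterogeneous
  - compensatory
h2_pheno: [0.10, 0.20, 0.40, 0.60, 0.80]
h2_apa: [0.10, 0.20, 0.40, 0.60, 0.80]
trait_type: quantitative
ld_mode: random
n_samples: 670
n_genes: 100
seed: 0
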