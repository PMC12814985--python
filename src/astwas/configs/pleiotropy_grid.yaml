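# Pleiotropy power grid: 7 architectures x 6 phenotype x 6 APA heritabilities
# = 252 scenario cells.
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
h2_pheno: [0.01, 0.02, 0.04, 0.06, 0.08, 0.10]
h2_apa: [0.01, 0.02, 0.04, 0.06, 0.08, 0.10]
trait_type: quantitative
ld_mode: random
n_samples: 670
n_genes: 100
seed: 0
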