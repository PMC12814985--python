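# Causality power grid: 7 architectures x 5 phenotype x 5 APA heritabilities
# = 175 scenario cells.  Cells with h2_pheno > h2_apa are infeasible under
# the genotype -> PDUI -> phenotype chain and are logged + skipped at run
# time.
mode: power
assumption: causality
architectures:
  - additive2
  - additive5
  - additive10
  - single
  - epistatic
  - heterogeneous
  - compensatory
h2_pheno: [0.05, 0.1, 0.15, 0.2, 0.25]
h2_apa: [0.05, 0.1, 0.15, 0.2, 0.25]
trait_type: quantitative
ld_mode: random
n_samples: 670
n_genes: 100
seed: 0
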