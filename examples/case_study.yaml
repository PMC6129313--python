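# Case-study simulation at desk scale: 3 traits, 200 samples, 10 shared
# causal SNPs, 4 covariates, infinitesimal + correlated + observational
# noise; 40% genetic variance, 80% shared within each split component.
n_samples: 200
n_traits: 3
seed: 0

genotypes:
  source: simulate
  n_snps: 100
  allele_freq_range: [0.05, 0.5]

kinship:
  source: estimate
  standardize: true

causal:
  n_causal: 10
  theta: 1.0          # all causal SNPs shared across traits

effect_sizes:
  law: normal
  params: [0.0, 1.0]

covariates:
  gamma: 0.5          # 2 of 4 covariates shared
  specs:
    - {dist: binomial, p: 0.5}
    - {dist: normal, mean: 0.0, sd: 1.0}
    - {dist: binomial, p: 0.3}
    - {dist: normal, mean: 0.0, sd: 1.0}

trait_correlation:
  r: 0.7

variance:
  genetic_variant:     {total: 0.20, shared: 1.0}
  infinitesimal:       {total: 0.20, shared: 0.8}
  covariate:           {total: 0.20, shared: 0.8}
  correlated_noise:    {total: 0.10}
  observational_noise: {total: 0.30, shared: 0.8}

output:
  formats: [csv, gemma]
  precision: 6
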