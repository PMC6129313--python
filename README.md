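# phenosim

Simulation of multi-trait, multi-locus phenotypes for quantitative genetics.

Method developers who benchmark association models — single- and multi-trait
linear mixed models (LMMs), variance-decomposition and heritability methods —
need phenotypes whose generative structure is known exactly. `phenosim`
builds an N-samples × P-traits phenotype matrix **Y** as the additive
combination of five variance components:

    Y = X_s B_s + X_i B_i  +  U_s + U_i  +  W_s A_s + W_i A_i  +  T  +  Ψ_s + Ψ_i

* **genetic variant effects** `X B` — a causal subset of the genotype panel
  times an effect-size matrix;
* **infinitesimal genetic effects** `U` — a polygenic background with
  matrix-variate normal law `vec(U) ~ N(0, C ⊗ K)`, where `K` is the kinship
  (genetic relationship) matrix and `C` a trait covariance, realized as
  `U = B Z Aᵀ` with `K = B Bᵀ`, `C = A Aᵀ`, `Z` iid standard normal;
* **non-genetic covariate effects** `W A` — covariates drawn from normal,
  uniform, binomial or categorical distributions (sex, age, batch, ...);
* **correlated non-genetic effects** `T` — rows iid `N(0, C)`, with `C`
  user-supplied or the exponential-decay family `C_ij = r^|i−j|`;
* **observational noise** `Ψ`.

Every component except `T` can be split into a *shared* part that acts
identically across all traits (a rank-one effect design, giving perfectly
correlated trait columns — the way pleiotropy is simulated) and an
*independent* part acting on a trait subset. Each (sub)component is then
rescaled to explain exactly a user-chosen fraction `x` of total phenotypic
variance: with average column variance `V̄`, entries are multiplied by
`sqrt(a)` where `a = x / V̄`, so the realized mean column variance equals `x`
to machine precision.

Genotypes are either simulated (unlinked biallelic SNPs, dosage
`~ Binomial(2, f)`) or imported from PLINK text, Oxford/SNPTEST gen+sample,
BIMBAM mean-genotype or generic delimited dosage tables; kinship is
estimated as `K = X Xᵀ / m` with `m` the mean diagonal of `X Xᵀ` (so
`mean(diag K) = 1`), optionally from standardized genotypes. Outputs are
written for PLINK, GEMMA, BIMBAM and SNPTEST, alongside the per-component
matrices, effect sizes and scale factors — the ground truth for scoring
downstream methods.

## Worked example

The packaged case-study configuration simulates 3 traits for 200 samples
from a 100-SNP panel: ten causal SNPs with effects shared across all traits,
four covariates (two binary, two normal), an infinitesimal effect on the
kinship estimated from the panel, a correlated effect with `r = 0.7`
exponential-decay trait correlation, and observational noise. Total genetic
variance is 40% and every split component is 80% shared.

```python
from phenosim.casestudy import case_study_config
from phenosim.pipeline import run_simulation
from phenosim.assembly import variance_report, variance_report_table

result, files = run_simulation(case_study_config(seed=1),
                               out_dir="demo_out", formats=["csv", "gemma"])
report = variance_report(result)
print(variance_report_table(report).to_string(index=False))
print(f"genetic share: {report['phenotype']['genetic_variance_share']:.4f}")
print(f"noise share:   {report['phenotype']['noise_variance_share']:.4f}")
```

prints

```
                      component                role        part  target_variance  mean_column_variance  scale_factor
         genetic_variant:shared     genetic_variant      shared             0.20                  0.20      0.016622
    genetic_variant:independent     genetic_variant independent             0.00                  0.00      0.000000
               covariate:shared           covariate      shared             0.16                  0.16      0.537157
          covariate:independent           covariate independent             0.04                  0.04      0.019875
           infinitesimal:shared       infinitesimal      shared             0.16                  0.16      0.387714
      infinitesimal:independent       infinitesimal independent             0.04                  0.04      0.083557
         correlated_noise:whole    correlated_noise       whole             0.10                  0.10      0.103372
     observational_noise:shared observational_noise      shared             0.24                  0.24      0.181498
observational_noise:independent observational_noise independent             0.06                  0.06      0.076391
genetic share: 0.4000
noise share:   0.6000
```

Each row is one (sub)component: `target_variance` is its variance-budget
entry, `mean_column_variance` the realized share (exact by construction of
the scaling), and `scale_factor` the applied variance factor `a`. The
genetic components (variant + infinitesimal) sum to 0.40 of total variance,
the non-genetic ones to 0.60; within each split component the shared part
carries 80% (e.g. infinitesimal 0.16 / 0.20). `demo_out/` holds the
phenotypes, genotypes, covariates and kinship in CSV and GEMMA layouts plus
the per-component ground-truth matrices and a JSON manifest.

The same run from a shell:

```sh
phenosim simulate --config examples/case_study.yaml --seed 1 --out demo_out
phenosim validate --config examples/case_study.yaml
```

Two runs with the same configuration and seed produce byte-identical output
files.

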