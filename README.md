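# rgwas

Covariate-aware phenotypic subtyping with genetic validation.

**Step 1** learns latent subtypes from multi-trait data with a finite
mixture of multi-trait regressions (MFMR): quantitative traits are
Gaussian, binary traits use probit links, control covariates `X` have
effects shared across subtypes, and the heterogeneous design `G`
(including the intercept, which carries the subtype main effects) has
subtype-specific effects. Fitting is by Expectation
Conditional-Maximization with restarts, internal standardization, and
deterministic largest-first subtype ordering.

**Step 2** validates subtypes two ways:

- *SNP / covariate level*: interaction tests of the form
  `trait ~ background + z + g + g*z` using the soft membership
  probabilities `z` directly — homogeneity (1 df), heterogeneity (K−1 df)
  and global (K df) modes, genome scans, and genomic-control (λ_GC)
  diagnostics.
- *Polygenic level*: a two-kernel variance-component model
  `cov(y) = σ²_hom·K + σ²_het·(K∘ZZᵀ) + σ²_e·I` fit by AI-REML, giving
  homogeneous and subtype-specific heritability with a Wald test for
  total genetic variance and a boundary-aware LRT for the
  subtype-specific component.

The package also ships the full simulation framework used to benchmark
calibration and power (correlated noise, t₅ noise, nonlinear genotype
effects, continuous subtype scores, case/control ascertainment,
genotype–subtype correlation, two-population Balding–Nichols structure),
baseline subtype estimators (GMM, CCA, phenotypic/genetic PCs), and
pre-clustering imputation (multivariate-Gaussian EM and soft-threshold
SVD completion).

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the simulation-based acceptance
criteria (calibration of the heterogeneity test on no-subtype nulls,
power ordering across subtype estimators, the genotype–subtype
correlation inflation bound, F_ST recovery, oracle equivalences, ECM
monotonicity, variance-component recovery, CCA inflation, and the df
contract). The full suite runs in roughly 10–15 minutes on one CPU.

## CLI

```bash
rgwas simulate --scenario baseline_k2 --out sim/ --n-samples 3000 --seed 1
rgwas impute   --phenotypes sim/phenotypes.tsv --out sim/imputed.tsv
rgwas run      --config config.yaml --seed 1
rgwas fit      --config config.yaml --model-out model.json --posterior-out Z.tsv
rgwas scan     --genotypes sim/genotypes.tsv --phenotypes sim/phenotypes.tsv \
               --posterior Z.tsv --trait q1 --mode gxe_global --out scan.tsv
rgwas gxemm    --genotypes sim/genotypes.tsv --phenotypes sim/phenotypes.tsv \
               --posterior Z.tsv --trait q1 --out varcomp.tsv
```

A `run` config is a YAML file mapping onto `rgwas.pipeline.RunConfig`,
e.g.

```yaml
scenario: baseline_k2
scenario_overrides: {n_samples: 3000}
K: 2
focal_covariates: {snp1: mfmr}
scan_mode: het
outdir: out/
```

File-based runs replace `scenario` with `phenotypes:` / `genotypes:`
paths (TSV with a `sample_id` column, or a PLINK bed/bim/fam prefix) and
a `column_roles:` mapping assigning each column to
`trait_quant | trait_binary | covariate_hom | covariate_het | id | ignore`.

Focal covariates can be handled three ways in step 1: ignored
(`mfmrx`), included with a homogeneous effect (`mfmr`, the default), or
included with subtype-specific effects (`mfmr+`; prone to overfitting
and provided mainly for benchmarking).

## Layout

| module | contents |
| --- | --- |
| `rgwas.simulate` | generative framework, named scenarios, Weir–Cockerham F_ST |
| `rgwas.mfmr` | MFMR model, ECM fitting, K selection, prediction |
| `rgwas.assoc` | interaction tests, genome scans, λ_GC |
| `rgwas.gxemm` | GRM, two-kernel REML, component tests |
| `rgwas.baselines` | GMM / CCA / PC subtypes, ARI, co-clustering stability |
| `rgwas.impute` | MVN-EM and low-rank imputation |
| `rgwas.evaluation` | replicate-level FPR/TPR benchmark drivers |
| `rgwas.io`, `rgwas.pipeline`, `rgwas.cli` | formats, orchestration, CLI |
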