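# agnep

Cluster-then-test joint analysis of multiple phenotypes for GWAS.

Many association methods either scan one phenotype at a time or throw every
phenotype into a single multivariate model. `agnep` sits between the two: it

1. standardizes the phenotypes and clusters them by **agglomerative nesting**
   (bottom-up hierarchical clustering, single linkage by default),
2. picks the number of clusters **K** by the maximum mean silhouette
   coefficient (K searched over 2..d−1),
3. reduces each cluster to **representative phenotypes** — the top principal
   components whose cumulative explained variance exceeds 85% (or the
   per-cluster mean / median), and
4. tests every variant against the representatives with a per-variant
   **MANOVA** (Wilks' Λ, exact rank-one F transformation), with univariate
   ANOVA as the baseline.

A fully seeded simulation module (HWE genotypes, group factor-model
phenotypes with known causal variants) and an FDR-based power-evaluation
module make the whole pipeline testable offline.

## CLI

```bash
# simulate a dataset with 5 independent phenotype groups and 10 causal variants
agnep simulate --preset simI --n-qtn 10 --n 1000 --m 2000 --seed 1 --out sim/

# cluster phenotypes (K chosen by max silhouette) and build PC representatives
agnep cluster --pheno sim/phenotypes.tsv --k auto --out clusters.tsv
agnep represent --pheno sim/phenotypes.tsv --clusters clusters.tsv \
    --method pca --threshold 0.85 --out reps.tsv

# per-variant MANOVA scan
agnep scan --geno sim/genotypes.tsv --reps reps.tsv --test wilks --out scan.tsv

# everything in one go (adds a 10-permutation significance threshold)
agnep run --geno sim/genotypes.tsv --pheno sim/phenotypes.tsv \
    --method pca --k auto --seed 1 --out run/

# power comparison of methods on simulated replicates
agnep benchmark --preset simI --methods AGNEP,AGNEm,MANOVA,ANOVA \
    --replicates 20 --n 500 --m 1000 --qtn-h2 0.03 --seed 1 --out bench/
```

Genotypes are read from a dosage TSV (variants as columns, 0/1/2 minor-allele
counts) or PLINK bed/bim/fam; columns are oriented to the minor allele and an
optional MAF filter drops rare variants. Phenotype tables are TSV
(individuals × phenotypes); individuals with any missing value are dropped.

## Presets

| preset | phenotypes | groups |
|--------|-----------:|--------|
| simI   | 20 | five disjoint groups of four |
| simII  | 20 | five groups with shared phenotypes between neighbours |
| simIII | 100 | eight overlapping groups |

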