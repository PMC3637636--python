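# robustps

Robust correction for population stratification in case-control
genome-wide association (GWA) studies.

## The problem

In a case-control GWA study, systematic ancestry differences between
cases and controls shift allele frequencies at thousands of SNPs at
once and produce spurious associations.  The standard remedies —
genomic control, principal-component (EIGENSTRAT-style) adjustment,
multidimensional scaling with cluster indicators — all estimate the
ancestry structure from the genotype matrix itself.  A handful of
*subject outliers* (sample contamination, batch artefacts, unmodelled
ancestries) can hijack exactly the eigenvectors those methods rely on:
classical PCA rotates its leading axes toward the outliers, the
ancestry adjustment silently stops adjusting, and false positive rates
at strongly differentiated SNPs climb toward 100%.

`robustps` implements a robust two-stage correction:

1. **Detect and remove subject outliers** in the wide (`n << p`)
   genotype matrix, with either
   - *projection-pursuit robust PCA*: find directions `b` maximising a
     robust scale of the projected data, `b1 = argmax_{|a|=1}
     S_n(a'x_1, ..., a'x_n)` with `S_n` the scaled median absolute
     deviation, via a plane-cycling grid search (`grid`) or a
     candidate-set search (`cr`); flag subjects whose score distance
     `SD_i = sqrt(sum_j t_ij^2 / l_j)` or orthogonal distance
     `OD_i = ||x_i - x_hat_i||` exceeds chi-square / Wilson-Hilferty
     cutoffs (outlier types A, B, C); or
   - *resampling by half means (RHM)*: repeatedly standardise all
     subjects by half-sample column statistics and flag subjects whose
     mean scaled length exceeds `median + 3 * MAD`.
2. **Model the structure of the cleaned data**: classical PCA with the
   number of axes chosen by sequential Tracy-Widom tests, then
   k-medoids (PAM) clustering of the PC scores with the Gap statistic
   selecting the number of clusters.
3. **Test each SNP** with the logistic regression
   `logit P(Y=1) = beta*g + gamma'X + eta'Z` (`X` = PC scores, `Z` =
   cluster indicators) and a 1-df likelihood-ratio test on `beta`.

Six methods are exposed for comparison under a common interface:
`trend`, `gc`, `pca`, `mds`, `rpca_rhm`, `rpca_pp`.

The package also ships the simulation machinery to evaluate all of
this: Balding-Nichols discrete subpopulations (`Beta(p(1-F)/F,
(1-p)(1-F)/F)` allele frequencies), a two-way admixed population with
ancestry-linked disease risk `P(disease|a) = 0.5 log(r) r^a / (r-1)`,
three categories of testing SNPs (random, differentiated, causal with
per-allele relative risk `R`), SVD-based subject-outlier injection, and
a benchmark harness computing empirical false/true positive rates.

## Worked example

```python
import numpy as np
import robustps as rps

rng = np.random.default_rng(11)
scen = rps.scenario("S2", n_testing_snps=200)   # 2 populations, extreme
ds = rps.simulate_discrete(scen, rng)           # 500 cases / 500 controls
ds = rps.inject_dataset_outliers(ds, rps.OutlierInjectionConfig(), rng)

est = rps.PPRobustPCA(n_components=5).fit(ds.inference)
diag = est.outlier_diagnostics()
print("flagged:", diag.outlier_mask.sum(), "of", ds.n_subjects,
      "injected recovered:", (diag.outlier_mask & ds.outlier_flags).sum())

for method in ("pca", "rpca_pp"):
    res = rps.run_method(ds, method, rng=np.random.default_rng(0), gap_B=100)
    roles = ds.snp_role[np.isin(ds.snp_role,
                                ("random", "differentiated", "causal"))]
    p = np.array([r.p_value for r in res])
    fpr = 100 * np.mean(p[roles == "differentiated"] < 0.01)
    print(f"{method}: differentiated-SNP FPR at 0.01 = {fpr:.1f}%")
```

Output:

```
flagged: 55 of 1000 injected recovered: 50
pca: differentiated-SNP FPR at 0.01 = 79.0%
rpca_pp: differentiated-SNP FPR at 0.01 = 1.0%
```

All 50 injected outliers are recovered (plus five borderline regular
subjects).  The plain PCA adjustment is wrecked by the outliers — 79%
of the null-but-differentiated SNPs reach p < 0.01 — while the robust
pipeline (outlier removal, then PCs plus cluster indicators) keeps the
false positive rate at the nominal 1%.

A command-line interface mirrors the library:

```bash
robustps simulate --scenario S4 --outliers --seed 1 --out-dir data/
robustps detect-outliers --method grid --in data/s4_ds000.tsv --out diag.tsv
robustps stratify --in data/s4_ds000.tsv --remove diag.tsv --out strat.tsv
robustps assoc --method rpca_pp --genotypes data/s4_ds000.tsv --adjust bh --out assoc.tsv
robustps benchmark --scenario S2 --outliers both --n-datasets 10 --out table.tsv
```

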