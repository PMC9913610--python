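# recurve

Quantitative genetics of **reproductive efficiency (Re)** in beef cattle
along the calving trajectory: pedigree-based REML animal models
(repeatability and Legendre random regression), covariance-function
trajectory parameters, a principal-component composite breeding index, and
a univariate linear-mixed-model GWAS — plus a synthetic-data generator
with a known-truth ledger that validates the whole chain.

The package is written for animal breeders and quantitative geneticists
who want to analyse fertility in extensively raised herds, where direct
fertility phenotypes are hard to record but calving dates are routine.

## The science in brief

Re scores each calving as the percentage ratio of the optimal to the
realized age at that calving, given an optimal age at first calving of 24
months and a 12-month calving interval:

    Re_n = 100 · (24 + (n − 1)·12) / age_n   (capped at 100)

**Repeatability model.** Repeated Re records are one trait:
y = μ + Cn + Fc + a + p + hys + e, with Var(a) = σ²ₐA (A the pedigree
relationship matrix, inverted sparsely from Meuwissen–Luo inbreeding),
h² = σ²ₐ/σ²ₜₒₜ.

**Random-regression model.** The animal effect is a quadratic in the
standardized calving number on a normalized Legendre basis,
u_m(x) = Σₖ φₖ(x)a_{mk} with coefficients ~ N(0, Ka ⊗ A) and six residual
classes. Per-calving genetic variance is φᵢKaφᵢ′; heritability and genetic
correlations follow from the covariance function, and each animal gets
nine per-calving EGVs via Φaₘ′. REML uses EM warm-up with damped
average-information acceleration.

**Composite index.** The standardized per-calving EGVs are
eigen-decomposed; animals are scored on the first two components (size and
shape vectors) and IpcT = Ipc1 + Ipc2 summarizes the whole trajectory,
serving as the pseudo-phenotype of the association scan.

**GWAS.** PLINK-1 genotypes are QC'd (call rate > 0.95, MAF ≥ 0.05,
windowed LD pruning 50/5/0.5), a centered genomic relationship matrix and
10 stratification PCs are built, the variance ratio λ is REML-fitted once
under the null on the GRM spectrum, and every marker is tested by GLS with
a Wald statistic on F(1, n−c−1). Hits (p < 1e-4) are annotated against a
local gene table within ±500 kb.

## Worked example

Fit the repeatability model on synthetic records generated at the
reference component magnitudes:

```python
from recurve import SimConfig, fit_repeatability, simulate_rep_dataset

cfg = SimConfig(seed=7, n_founders=80, n_generations=5,
                cows_per_generation=200, n_sires_per_generation=8)
ped, table, truth = simulate_rep_dataset(cfg)
res = fit_repeatability(table, ped)
print(res.components, res.meta["h2"])
```

prints (one replicate, ~860 cows):

```
animal     118.18   (truth 91.82)
pe          86.60   (truth 105.55)
hys         35.67   (truth 27.38)
residual    80.54   (truth 79.52)
h2 = 0.37  repeatability = 0.64
```

The four variance components land near their generating values (additive
and permanent-environment estimates are anti-correlated at this scale, so
single replicates scatter in opposite directions — the recovery tests
average replicates). The trajectory model (`fit_rrm(table, ped, r=2)`)
prints a per-calving table whose genetic variance falls from ~117 to ~40
while h² rises with parity, and its `solutions["egv"]` panel feeds the PCA
index (`examples/05_pca_index_cohort.py` shows PC1 loadings uniformly
≈ 0.33 — the size vector — with PC1+PC2 carrying ~99% of the EGV
covariance). `examples/06_gwas_scan.py` plants a causal SNP explaining 15%
of the pseudo-phenotype variance in 250 × 5,000 genotypes and the scan
recovers it at p ≈ 1.5e-9 with λ_GC ≈ 0.94.

Each capability has a narrative script under `examples/`; a thin CLI runs
the whole chain (`recurve simulate|quantgen|gwas|all --config run.yaml`)
and writes the report tables (descriptives, variance components, model
comparison, trajectory parameters, eigen analysis, index, scan, hits,
gene windows) as tab-separated text stamped with the config hash and seed.

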