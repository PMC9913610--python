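# Methods

`recurve` implements a quantitative-genetic analysis of reproductive
efficiency (Re) in beef cattle along the calving trajectory, together with
the downstream selection index and a genome-wide association scan. This
note documents the models, the estimation machinery, the synthetic-data
generator, and the numerical and design choices a maintainer should know
about.

## The trait

Re expresses, as a percentage, how close a cow's realized calving history
is to an optimum of a first calving at 24 months followed by one calf per
year. The default (time-ratio) form at the n-th calving is

    Re_n = 100 * (24 + (n - 1) * 12) / age_n        (months, capped at 100)

A count-ratio variant (100 × realized / optimal parity count at the cow's
age) is available behind the `formula="count"` switch; the verbal
definition of the trait admits both readings, so both are
implemented and neither is asserted as the original. The time-ratio form is
the default because it is continuous in age and reproduces the reference
descriptive range (minimum ≈ 33 for a first calving at 72 months). Only
structural record filters are applied (calving number cap, incomplete rows,
non-monotone calving dates); no outlier rules beyond these are applied.

## Mixed models

Two animal models are fitted by REML through Henderson's mixed-model
equations (MME):

**Repeatability (Rep).** y = μ + Cn class + Fc class + animal + permanent
environment + HYS + e, with Var(animal) = σ²ₐA, scalar permanent
environment and HYS variances, and one residual class. A is the pedigree
numerator relationship matrix; its sparse inverse is assembled directly
from parent triplets and Mendelian-sampling variances, with inbreeding
coefficients from the Meuwissen–Luo algorithm. h² = σ²ₐ/σ²ₜₒₜ and
repeatability = (σ²ₐ+σ²ₚ)/σ²ₜₒₜ.

**Random regression (RA, order r ∈ {1,2}).** The animal effect is a
polynomial in the standardized calving number, u_m(x) = Σₖ φₖ(x) a_{mk},
with normalized Legendre basis φₖ(x) = √((2k+1)/2) Pₖ(x) on
x = −1 + 2(Cn−1)/8. Coefficients follow N(0, Ka ⊗ A). Fixed effects are
order-r Legendre regressions on Cn and on the inbreeding-class midpoint
(the constant of the Fc regression is dropped — it duplicates the Cn
intercept). Permanent environment and HYS are scalar; the residual has 6
variance classes by min(Cn, 6). Parameter counts are 11 (r=1) and 14 (r=2),
against 4 for Rep.

Normalization of the basis affects the numerical values in Ka but none of
the derived quantities (Φ Ka Φ′, h², genetic correlations, EGVs). From a
fit, per-calving genetic variance is the quadratic form φᵢ Ka φᵢ′, point
heritability divides it by the total at that calving, genetic correlations
are the normalized off-diagonal quadratic forms, and per-calving EGVs are
Φ aₘ′ for each animal's estimated coefficient vector. Evaluation is
restricted to the nine integer calving classes; no extrapolation.

## REML algorithm

The engine maximizes the restricted likelihood with EM-REML steps for the
first iterations (monotone and unconditionally stable), then switches to
damped average-information (AI) updates:

* the REML score is computed analytically from MME traces (verified
  against numerical gradients to machine precision);
* the AI matrix uses the standard working vectors f_i = V_i P y, which
  require only solves against the current MME factorization;
* the Newton step is damped Levenberg–Marquardt style (ρ ∈ {0, 0.01, 0.1,
  1, 10}); a proposal that leaves the parameter space is "bent" back by
  clipping Ka eigenvalues at 1e-4 of the mean diagonal and flooring scalar
  variances at 1e-8 of the phenotypic variance; a proposal that decreases
  the restricted logL is rejected in favour of the (over-relaxed) EM step.
* when the AI step is rejected, the EM direction is extrapolated (step
  doubling) and kept if it improves the likelihood — this recovers most of
  the Newton gain along likelihood ridges where plain EM creeps.

Ka is updated as a full symmetric matrix; EM steps keep it positive
definite by construction and every accepted update passes a Cholesky
check. (An explicit Cholesky parameterization of Ka was considered and
rejected: the EM/AI updates with PD-guarded steps give the same guarantee
with simpler gradient bookkeeping.)

Convergence is declared when the relative logL change is below 1e-8 *and*
the largest relative parameter change is below 1e-6, or — secondary rule —
after three consecutive iterations whose likelihood gain is negligible
(100× the logL tolerance). The secondary rule exists because fits whose Ka
is pinned at the PD boundary keep drifting in a likelihood-flat direction
and would otherwise exhaust `max_iter` (200) without changing the fit.
Starting values split the phenotypic variance 40% animal / 30% permanent
environment / 10% HYS / 20% residual; the optimum was verified to be
independent of the start on test data.

Fixed-effect design matrices are rank-reduced by pivoted QR, so redundant
class columns (empty classes, collinear dummies) are dropped rather than
crashing the factorization. Model comparison uses AIC = −2logL + 2k and
BIC = −2logL + k ln n with n = number of records and k = number of
variance parameters.

### Identifiability at small scale

The additive intercept variance and the permanent-environment variance are
both cow-level; they are separated only by the covariance between
relatives. At a few hundred cows with a shallow pedigree their REML
estimates are strongly anti-correlated, and a mild systematic transfer
appears (genetic surface up, permanent environment down; verified to
disappear when the generator omits the permanent-environment effect, and
to shrink to nothing at ~700 cows with a five-generation pedigree). The
recovery tests therefore run at 5 replicates × ~690 cows for the RA2 model
and 6 replicates × ~480 cows for Rep — the largest sizes that keep the
suite inside a single-CPU run — and accept each component when its
replicate mean is within 2 Monte-Carlo SE of the generating value or
within 10% of it.

## Composite index (PCA)

Per-calving EGVs from the RA fit are standardized column-wise (sample SD),
the 9×9 correlation matrix is eigen-decomposed, and animals are scored on
the first two components: Ipc1 (the near-uniform positive "size" vector)
and Ipc2 (the sign-switching "shape" vector). IpcT = Ipc1 + Ipc2 is the
composite pseudo-phenotype. Eigenvector signs are fixed by making the
largest-magnitude loading positive, which renders the decomposition (and
IpcT) independent of the eigen-solver's internal conventions. Two
components are summed by default (they carry >99% of the panel variance
when the trajectories come from an order-2 fit, which has rank 3);
the count is configurable. The genotyping cohort unions the top animals of
the upper IpcT quartile (default 212) with the most negative animals
(default 40).

## GWAS

Genotypes are PLINK-1 bed/bim/fam (SNP-major, read and written natively).
QC removes markers with call rate ≤ 0.95 (strict, per the stated rule) or
MAF < 0.05 (markers exactly at 0.05 are kept), then greedy windowed LD
pruning (window 50, step 5, r² > 0.5 removes the later marker of a pair;
chromosomes pruned independently). The GRM is K = Zc Zc′/m on
column-centered, per-marker mean-imputed dosages. Stratification
covariates are the top 10 sample principal components of the pruned
markers, alongside an intercept.

The association model is the standard univariate LMM with a single
variance ratio λ: the null model is fitted once by REML on the spectral
decomposition of K (grid search over log₁₀λ ∈ [−5, 5] refined by bounded
Brent), flagging boundary or likelihood-flat cases; every marker is then
tested by GLS with a Wald statistic referred to F(1, n − c − 1), c being
the number of covariate columns. With λ → 0 the scan reduces exactly to
OLS (tested against statsmodels). Monomorphic markers after imputation are
reported as missing. Significance thresholds default to 1e-4 (suggestive,
the hit rule) and 1e-5 (genome-wide), and candidate genes are looked up in
a local gene table over closed ±500 kb windows around each hit.

## Synthetic data generator

The generator mirrors the generative side of the fitted models and is the
package's validation instrument; its defaults are the study conditions.

* **Pedigree:** founders plus overlapping generations with random mating;
  a small sire pool per generation (default 6) reuses sires and builds
  inbreeding (later-generation mean F > 0).
* **Breeding values:** founders ~ N(0, Ka); offspring = parent average +
  Mendelian deviation with covariance (0.5 − 0.25(F_s + F_d))·Ka, giving
  exactly A ⊗ Ka in distribution (checked by Monte-Carlo against the
  tabular A).
* **Records:** Re = μ + quadratic Cn profile + linear-in-F inbreeding
  effect + φ(Cn)·aₘ + pe + HYS + class-wise residual. Cows accumulate 1–9
  calvings with geometric retention 0.8 per extra calving, mimicking the
  thinning of records at high parity. Calving dates can be emitted by
  inverting the time-ratio Re definition, so the phenotype pipeline
  reproduces the generated values end-to-end (up to the cap).
* **Magnitudes:** the repeatability variant uses the reference component
  set (91.82 / 105.55 / 27.38 / 79.52). The trajectory variant uses a
  Ka whose implied genetic variance falls from ~117 at the first calving
  to ~35–41 later, with high positive correlations along the trajectory
  (obtained once by least-squares projection of that target surface onto
  the order-2 covariance-function space and frozen); permanent environment
  30, HYS 15 and residual classes (345, 110, 54, 33, 22, 13) make the
  per-calving totals fall from ~507 to ~95. The reference repeatability
  and trajectory component sets are not mutually consistent (the
  repeatability-scale permanent-environment variance would drive later
  trajectory residuals negative), so each generator variant uses its own
  internally consistent set.
* **Genotypes:** allele frequencies ~ U(0.05, 0.5), Hardy–Weinberg
  sampling, optional two-subpopulation Balding–Nichols structure
  (`fst`), configurable missingness, planted causal markers whose
  standardized score is mixed into the pseudo-phenotype at `causal_h2`.

What the generator does **not** emulate: linkage disequilibrium from a
coalescent (markers are independent), selection-driven mating, culling
tied to performance, genotype-pedigree linkage (the GWAS cohort's K comes
from the markers, not from A), and seasonal calving-date structure beyond
the HYS code. Passing tests therefore demonstrate correctness of the
estimation machinery under the assumed models, not robustness to the ways
real herd data violate them.

One seed fixes pedigree, phenotypes, genotypes and the truth ledger
bit-exactly.

## Problem sizes in the test suite

Chosen as a single-CPU budget, stated here as package policy: pedigree
oracles up to 500 animals; Rep recovery 6 × ~480 cows; RA2 recovery
5 × ~690 cows (~3,000 records each); null GWAS calibration 20 seeds of
252 × 5,000 markers; planted-signal power 9 seeds at n = 250 with a 15%
variance SNP; model-selection ordering 10 replicates of ~220 cows
requiring the AIC order RA2 < RA1 < Rep in ≥ 9/10.

## Known limitations

* No standard errors of h² by Taylor expansion; resample or refit for
  uncertainty.
* HYS is always random (both models); genetic groups and single-step
  (H-matrix) blending are out of scope.
* The LMM scan fixes λ at the null estimate rather than re-optimizing per
  marker; with n ≪ m this is the usual approximation and costs little
  power.
* The number of inbreeding classes defaults to 15 (2% intervals); the
  random-regression fixed regression spans 16 classes by default —
  both counts are configurable because the source material uses both.
* Dense MME are used (dimension ≈ 3·animals + cows + HYS groups), which is
  comfortable to ~1,500 cows on one CPU but not sized for national
  evaluations.
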