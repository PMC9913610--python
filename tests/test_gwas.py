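import numpy as np
import pandas as pd
import pytest

from recurve import gwas
from recurve.gwas import (NullModel, candidate_genes, grm_centered,
                          lambda_gc, ld_prune, lmm_null, mean_impute,
                          qc_filter, significant_hits, stratification_pcs,
                          wald_scan)
from recurve.plinkio import GenotypeMatrix
from recurve.simulate import SimConfig, simulate_genotypes


def _geno_from(dosages, chrom=None, pos=None):
    n, m = dosages.shape
    bim = pd.DataFrame({"chrom": chrom if chrom is not None else ["1"] * m,
                        "snp": [f"s{j}" for j in range(m)], "cm": 0.0,
                        "pos": pos if pos is not None else np.arange(1, m + 1) * 1000,
                        "a1": "A", "a2": "B"})
    fam = pd.DataFrame({"fid": "f", "iid": [f"i{k}" for k in range(n)],
                        "father": "0", "mother": "0", "sex": 2, "phenotype": -9})
    return GenotypeMatrix(np.asarray(dosages, dtype=float), bim, fam)


class TestQc:
    def test_low_callrate_removed(self):
        dos = np.ones((10, 2)) * 1.0
        dos[:1, 0] = np.nan          # 90% call rate -> fails > 0.95
        dos[:, 1] = [0, 1, 2, 0, 1, 2, 0, 1, 2, 0]
        out, rep = qc_filter(_geno_from(dos))
        assert rep.n_fail_callrate == 1
        assert list(out.bim["snp"]) == ["s1"]

    def test_maf_boundary_inclusive(self):
        n = 50
        dos = np.zeros((n, 2))
        dos[:5, 0] = 1.0             # MAF exactly 0.05 -> kept
        dos[:4, 1] = 1.0             # MAF 0.04 -> removed
        out, rep = qc_filter(_geno_from(dos))
        assert list(out.bim["snp"]) == ["s0"]
        assert rep.n_fail_maf == 1

    def test_counts_match_brute_force(self, rng):
        dos = rng.integers(0, 3, size=(40, 30)).astype(float)
        dos[rng.random(dos.shape) < 0.1] = np.nan
        geno = _geno_from(dos)
        out, rep = qc_filter(geno, 0.95, 0.05)
        keep = []
        for j in range(30):
            col = dos[:, j]
            cr = np.mean(~np.isnan(col))
            p = np.nanmean(col) / 2
            maf = min(p, 1 - p)
            keep.append(cr > 0.95 and maf >= 0.05)
        assert out.n_markers == sum(keep)

    def test_all_removed_is_error(self):
        dos = np.zeros((20, 3))
        with pytest.raises(ValueError):
            qc_filter(_geno_from(dos))


class TestLdPrune:
    def test_duplicate_marker_one_survives(self, rng):
        x = rng.integers(0, 3, 50).astype(float)
        out, rep = ld_prune(_geno_from(np.column_stack([x, x])))
        assert out.n_markers == 1 and rep.n_pruned_ld == 1

    def test_independent_markers_survive(self, rng):
        dos = rng.integers(0, 3, size=(200, 20)).astype(float)
        out, _ = ld_prune(_geno_from(dos))
        assert out.n_markers == 20

    def test_postcondition_no_pair_above_threshold(self, rng):
        # build blocks of correlated markers
        base = rng.integers(0, 3, size=(120, 10)).astype(float)
        cols = []
        for j in range(10):
            for _ in range(10):
                noisy = base[:, j].copy()
                flip = rng.random(120) < 0.05
                noisy[flip] = rng.integers(0, 3, flip.sum())
                cols.append(noisy)
        geno = _geno_from(np.column_stack(cols))
        out, _ = ld_prune(geno, window=50, step=5, r2_max=0.5)
        X = out.dosages - out.dosages.mean(axis=0)
        X /= X.std(axis=0)
        r2 = (X.T @ X / len(X)) ** 2
        for start in range(0, out.n_markers, 5):
            w = r2[start:start + 50, start:start + 50]
            off = w - np.diag(np.diag(w))
            assert off.max() <= 0.5 + 1e-9

    def test_chromosomes_pruned_independently(self, rng):
        x = rng.integers(0, 3, 80).astype(float)
        geno = _geno_from(np.column_stack([x, x]), chrom=["1", "2"])
        out, _ = ld_prune(geno)
        assert out.n_markers == 2


class TestGrm:
    def test_two_identical_samples_single_marker(self):
        dos = np.array([[2.0], [2.0]])
        # centered dosages are zero -> K = 0; identical rows give equal entries
        K = grm_centered(_geno_from(dos))
        assert K[0, 0] == pytest.approx(K[0, 1])

    def test_hand_computed_product(self):
        dos = np.array([[0.0, 1.0, 2.0, 0.0],
                        [1.0, 1.0, 0.0, 2.0],
                        [2.0, 1.0, 1.0, 1.0]])
        Zc = dos - dos.mean(axis=0)
        expected = Zc @ Zc.T / 4
        np.testing.assert_allclose(grm_centered(_geno_from(dos)), expected, atol=1e-12)

    def test_psd(self, rng):
        dos = rng.integers(0, 3, size=(30, 100)).astype(float)
        K = grm_centered(_geno_from(dos))
        assert np.linalg.eigvalsh(K).min() >= -1e-10

    def test_sample_order_invariance(self, rng):
        dos = rng.integers(0, 3, size=(15, 40)).astype(float)
        K = grm_centered(_geno_from(dos))
        perm = rng.permutation(15)
        K2 = grm_centered(_geno_from(dos[perm]))
        np.testing.assert_allclose(K2, K[np.ix_(perm, perm)], atol=1e-12)


class TestStratificationPcs:
    def test_two_subpopulations_separated_by_pc1(self):
        cfg = SimConfig(seed=9, n_samples=120, n_markers=800, n_causal=0,
                        fst=0.2, missing_rate=0.0)
        geno, _, truth = simulate_genotypes(cfg)
        W = stratification_pcs(geno, 5)
        subpop = np.array(truth.variance_components["subpop"])
        r = np.corrcoef(W[:, 1], subpop)[0, 1]
        assert abs(r) > 0.9

    def test_zero_pcs_intercept_only(self, rng):
        dos = rng.integers(0, 3, size=(20, 30)).astype(float)
        W = stratification_pcs(_geno_from(dos), 0)
        np.testing.assert_array_equal(W, np.ones((20, 1)))

    def test_pcs_orthogonal(self, rng):
        dos = rng.integers(0, 3, size=(40, 200)).astype(float)
        W = stratification_pcs(_geno_from(dos), 6)
        P = W[:, 1:]
        off = P.T @ P - np.diag(np.diag(P.T @ P))
        assert np.abs(off).max() < 1e-8

    def test_too_many_pcs_rejected(self, rng):
        dos = rng.integers(0, 3, size=(10, 30)).astype(float)
        with pytest.raises(ValueError):
            stratification_pcs(_geno_from(dos), 10)


def _null_with_lambda(y, W, K, lam):
    d, U = np.linalg.eigh(K)
    d = np.maximum(d, 0)
    return NullModel(lam=lam, tau_inv=1.0, eigvals=d, rot_y=U.T @ y,
                     rot_W=U.T @ W, U=U)


class TestLmm:
    def test_pure_noise_lambda_at_lower_boundary(self, rng):
        lams = []
        for seed in range(5):
            r = np.random.default_rng(seed)
            dos = r.integers(0, 3, size=(100, 300)).astype(float)
            K = grm_centered(dos)
            y = r.standard_normal(100)
            null = lmm_null(y, np.ones((100, 1)), K)
            lams.append(null.lam)
        assert np.median(lams) < 1e-2

    def test_heritable_phenotype_large_lambda(self, rng):
        dos = rng.integers(0, 3, size=(150, 500)).astype(float)
        K = grm_centered(dos)
        L = np.linalg.cholesky(K + 1e-6 * np.eye(150))
        y = L @ rng.standard_normal(150)          # pure genetic signal
        null = lmm_null(y, np.ones((150, 1)), K)
        assert null.lam > 10.0

    def test_identity_k_flagged_boundary(self, rng):
        y = rng.standard_normal(80)
        null = lmm_null(y, np.ones((80, 1)), np.eye(80))
        assert null.boundary

    def test_zero_lambda_scan_equals_ols(self, rng):
        """With the relationship matrix switched off the mixed-model scan
        must reproduce ordinary least squares exactly."""
        import statsmodels.api as sm
        n, m = 60, 8
        dos = rng.integers(0, 3, size=(n, m)).astype(float)
        geno = _geno_from(dos)
        W = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = rng.standard_normal(n) + 0.3 * dos[:, 2]
        K = grm_centered(geno)
        res = wald_scan(geno, y, W, K, _null_with_lambda(y, W, K, 0.0))
        for j in range(m):
            ols = sm.OLS(y, np.column_stack([W, dos[:, j]])).fit()
            assert res["beta"].iloc[j] == pytest.approx(ols.params[-1], abs=1e-8)
            assert res["se"].iloc[j] == pytest.approx(ols.bse[-1], abs=1e-8)
            assert res["p_wald"].iloc[j] == pytest.approx(ols.pvalues[-1], abs=1e-8)

    def test_monomorphic_marker_flagged_missing(self, rng):
        dos = rng.integers(0, 3, size=(50, 3)).astype(float)
        dos[:, 1] = 1.0
        geno = _geno_from(dos)
        y = rng.standard_normal(50)
        K = grm_centered(geno)
        res = wald_scan(geno, y, np.ones((50, 1)), K)
        assert np.isnan(res["p_wald"].iloc[1])
        assert np.isfinite(res["p_wald"].iloc[0])

    def test_mean_imputation(self):
        dos = np.array([[0.0, np.nan], [2.0, 1.0], [np.nan, 1.0]])
        X = mean_impute(dos)
        assert X[2, 0] == pytest.approx(1.0)
        assert X[0, 1] == pytest.approx(1.0)

    def test_type_one_error_calibrated(self):
        """Null-simulation rejection rate at alpha=1e-3 within binomial CI."""
        ps = []
        for seed in range(4):
            cfg = SimConfig(seed=seed + 50, n_samples=200, n_markers=2500,
                            n_causal=0, causal_h2=0.0, missing_rate=0.0)
            geno, y, _ = simulate_genotypes(cfg)
            K = grm_centered(geno)
            W = stratification_pcs(geno, 10)
            res = wald_scan(geno, y.to_numpy(), W, K)
            ps.append(res["p_wald"].dropna().to_numpy())
        ps = np.concatenate(ps)
        alpha = 1e-3
        hits = (ps < alpha).sum()
        ci = 3 * np.sqrt(len(ps) * alpha * (1 - alpha))
        assert abs(hits - len(ps) * alpha) <= ci


class TestHitsAndGenes:
    def test_mean_abs_beta_of_reported_hits(self):
        """Internal consistency of the hit summary on printed effect sizes."""
        res = pd.DataFrame({
            "chr": ["4", "4", "4", "4", "28"],
            "rs": [f"m{i}" for i in range(5)],
            "ps": [93739544, 97052195, 97052759, 97128968, 10126454],
            "beta": [-5.414, -4.382, -4.290, -5.936, -4.530],
            "se": [1.334, 0.964, 0.979, 1.229, 1.086],
            "p_wald": [7.199054e-5, 9.616885e-6, 1.926352e-5, 2.755483e-6,
                       4.607665e-5],
        })
        hits = significant_hits(res)
        assert len(hits) == 5
        assert round(hits.attrs["mean_abs_beta"], 2) == 4.91
        assert hits["genomewide"].sum() == 2      # p < 1e-5

    def test_empty_hits(self):
        res = pd.DataFrame({"chr": ["1"], "rs": ["a"], "ps": [1],
                            "beta": [0.1], "se": [0.1], "p_wald": [0.5]})
        hits = significant_hits(res)
        assert hits.empty and np.isnan(hits.attrs["mean_abs_beta"])

    def test_threshold_one_returns_all(self, rng):
        res = pd.DataFrame({"chr": "1", "rs": [f"m{i}" for i in range(9)],
                            "ps": range(9), "beta": 0.1, "se": 0.1,
                            "p_wald": rng.random(9)})
        assert len(significant_hits(res, suggestive=1.0000001)) == 9

    def test_gene_window_lookup(self):
        hits = pd.DataFrame({"chr": ["4"], "rs": ["AX-124382279"],
                             "ps": [93739544], "beta": [-5.414],
                             "se": [1.334], "p_wald": [7.2e-5]})
        genes = pd.DataFrame({
            "gene": ["NRF1", "SSMEM1", "CPA5", "FARAWAY"],
            "chromosome": ["4", "4", "4", "4"],
            "start": [93539544, 93939544, 94139544, 99999999],
            "end": [93639544, 94039544, 94239544, 100000999],
        })
        out = candidate_genes(hits, genes, flank=500_000)
        assert sorted(out["gene"]) == ["CPA5", "NRF1", "SSMEM1"]

    def test_boundary_gene_included(self):
        hits = pd.DataFrame({"chr": ["1"], "rs": ["m"], "ps": [1_000_000],
                             "beta": [1.0], "se": [0.1], "p_wald": [1e-6]})
        genes = pd.DataFrame({"gene": ["edge"], "chromosome": ["1"],
                              "start": [1_500_000], "end": [1_600_000]})
        assert len(candidate_genes(hits, genes, flank=500_000)) == 1
        genes2 = genes.assign(start=1_500_001, end=1_600_000)
        assert candidate_genes(hits, genes2, flank=500_000).empty

    def test_empty_gene_table(self):
        hits = pd.DataFrame({"chr": ["1"], "rs": ["m"], "ps": [100],
                             "beta": [1.0], "se": [0.1], "p_wald": [1e-6]})
        genes = pd.DataFrame(columns=["gene", "chromosome", "start", "end"])
        assert candidate_genes(hits, genes).empty

    def test_lambda_gc_of_uniform_p_near_one(self, rng):
        assert lambda_gc(rng.random(20000)) == pytest.approx(1.0, abs=0.05)
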