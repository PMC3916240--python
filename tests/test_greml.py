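"""X-aware GRM construction, relatedness pruning, and REML."""

import numpy as np
import pytest
from scipy import stats

from xwas.greml import (
    GRM,
    MALE_GRM_SCALE,
    lrt_zero_variance,
    make_grm,
    prune_related,
    reml_fit,
)
from xwas.simulate import ArchitectureSpec, XGenotypes, genetic_values, \
    inverse_normal_transform, simulate_genotypes


def _toy_geno(fem, mal):
    fem = np.asarray(fem, dtype=float)
    mal = np.asarray(mal, dtype=float)
    m = fem.shape[1]
    return XGenotypes(
        snp_ids=np.array([f"s{i}" for i in range(m)]),
        positions=np.arange(m) + 1,
        effect_allele=np.full(m, "G"), other_allele=np.full(m, "A"),
        female_dosages=fem, male_dosages=mal,
        eaf_female=fem.mean(axis=0) / 2 if len(fem) else np.zeros(m),
        eaf_male=mal.mean(axis=0) if len(mal) else np.zeros(m),
        info_female=np.ones(m),
    )


class TestMakeGrm:
    def test_direct_summation_oracle(self):
        # 3 samples x 4 SNPs, expanded by hand with explicit loops
        fem = [[0, 1, 2, 1], [2, 0, 1, 1]]
        mal = [[1, 0, 1, 0]]
        geno = _toy_geno(fem, mal)
        for model in ("FDC", "NDC", "EV"):
            grm = make_grm(geno, dc_model=model, maf_min=0.0)
            p = (np.sum(fem, axis=0) + np.sum(mal, axis=0)) / 5.0  # 2*2F + 1M
            w = np.zeros((3, 4))
            for j in range(4):
                for i in range(2):
                    w[i, j] = (fem[i][j] - 2 * p[j]) / np.sqrt(2 * p[j] * (1 - p[j]))
                w[2, j] = MALE_GRM_SCALE[model] * (mal[0][j] - p[j]) \
                    / np.sqrt(p[j] * (1 - p[j]))
            expected = np.zeros((3, 3))
            for a in range(3):
                for b in range(3):
                    expected[a, b] = sum(w[a, j] * w[b, j] for j in range(4)) / 4
            np.testing.assert_allclose(grm.matrix, expected, atol=1e-12)

    def test_duplicate_samples_ev(self):
        fem = [[0, 1, 2, 1], [0, 1, 2, 1], [2, 1, 0, 2]]
        geno = _toy_geno(fem, np.empty((0, 4)))
        grm = make_grm(geno, dc_model="EV", maf_min=0.0)
        assert grm.matrix[0, 1] == pytest.approx(grm.matrix[0, 0])

    def test_fdc_ndc_male_block_ratio_is_four(self):
        geno = simulate_genotypes(50, 50, np.linspace(0.1, 0.5, 40), seed=41)
        fdc = make_grm(geno, "FDC").matrix
        ndc = make_grm(geno, "NDC").matrix
        mm = np.s_[50:, 50:]
        np.testing.assert_allclose(fdc[mm], 4.0 * ndc[mm], rtol=1e-10)

    def test_diagonal_means_by_model(self):
        geno = simulate_genotypes(400, 400, np.linspace(0.1, 0.5, 300), seed=43)
        for model in ("FDC", "NDC", "EV"):
            grm = make_grm(geno, model)
            d = np.diag(grm.matrix)
            assert d[:400].mean() == pytest.approx(1.0, abs=0.05)
            assert d[400:].mean() == pytest.approx(MALE_GRM_SCALE[model] ** 2,
                                                   abs=0.05)

    def test_sample_permutation_equivariance(self):
        geno = simulate_genotypes(20, 0, np.linspace(0.2, 0.5, 15), seed=47)
        grm = make_grm(geno, "EV", maf_min=0.0)
        perm = np.random.default_rng(0).permutation(20)
        permuted_geno = _toy_geno(geno.female_dosages[perm], np.empty((0, 15)))
        grm_p = make_grm(permuted_geno, "EV", maf_min=0.0)
        np.testing.assert_allclose(grm_p.matrix, grm.matrix[np.ix_(perm, perm)],
                                   atol=1e-12)

    def test_monomorphic_snps_skipped(self):
        fem = [[0, 1, 2], [0, 1, 0], [0, 2, 1]]
        geno = _toy_geno(fem, np.empty((0, 3)))
        grm = make_grm(geno, "EV", maf_min=0.0)
        assert grm.m_snps == 2  # first SNP is monomorphic

    def test_all_monomorphic_errors(self):
        geno = _toy_geno([[0, 2], [0, 2]], np.empty((0, 2)))
        with pytest.raises(ValueError, match="polymorphic"):
            make_grm(geno, "EV", maf_min=0.0)

    def test_autosomal_matrix_input(self):
        x = np.random.default_rng(3).binomial(2, 0.4, size=(30, 20)).astype(float)
        grm = make_grm(x, maf_min=0.01)
        assert grm.dc_model == "AUTO"
        assert np.diag(grm.matrix).mean() == pytest.approx(1.0, abs=0.25)


class TestPruneRelated:
    @staticmethod
    def _grm(mat):
        n = len(mat)
        return GRM(matrix=np.asarray(mat, dtype=float),
                   sample_ids=np.array([f"S{i}" for i in range(n)]),
                   sex=np.full(n, "female"), dc_model="EV", m_snps=10)

    def test_unrelated_all_kept(self):
        grm = self._grm(np.eye(4) + 0.01)
        assert len(prune_related(grm, 0.05)) == 4

    def test_single_pair_drops_exactly_one(self):
        mat = np.eye(4) * 1.0
        mat[1, 2] = mat[2, 1] = 0.3
        kept = set(prune_related(self._grm(mat), 0.05))
        assert len(kept) == 3
        assert kept >= {"S0", "S3"}

    def test_tie_breaks_toward_larger_index(self):
        mat = np.eye(3)
        mat[0, 1] = mat[1, 0] = 0.3
        kept = set(prune_related(self._grm(mat), 0.05))
        assert kept == {"S0", "S2"}  # S1 (larger index of the tied pair) dropped

    def test_random_grm_output_is_pairwise_clean(self, rng):
        a = rng.normal(scale=0.05, size=(50, 50))
        mat = (a + a.T) / 2 + np.eye(50)
        grm = self._grm(mat)
        kept = prune_related(grm, 0.05)
        idx = [int(s[1:]) for s in kept]
        for ii, a_ in enumerate(idx):  # exhaustive pair check
            for b_ in idx[ii + 1:]:
                assert abs(mat[a_, b_]) <= 0.05
        assert len(kept) > 0


def _contrast_loglik(y, V):
    """Independent restricted-likelihood oracle via error contrasts."""
    n = len(y)
    # orthonormal basis of the space orthogonal to the intercept
    q, _ = np.linalg.qr(np.column_stack([np.ones(n), np.eye(n)[:, :-1]]))
    K = q[:, 1:].T
    return stats.multivariate_normal.logpdf(K @ y, mean=np.zeros(n - 1),
                                            cov=K @ V @ K.T)


class TestRemlFit:
    def test_two_eigenvalue_toy_matches_grid_oracle(self, rng):
        n = 300
        # GRM with two eigenvalue blocks: strong structure, easy grid search
        q, _ = np.linalg.qr(rng.normal(size=(n, n)))
        lam = np.concatenate([np.full(n // 2, 2.5), np.full(n - n // 2, 0.2)])
        A = (q * lam) @ q.T
        L = np.linalg.cholesky(A + 1e-9 * np.eye(n))
        y = L @ rng.normal(size=n) * np.sqrt(0.5) + rng.normal(size=n) * np.sqrt(0.5)
        fit = reml_fit(y, [A], tol=1e-10)
        assert fit.converged
        # grid over both variances; oracle is the contrast-based loglik
        grid = np.linspace(0.05, 1.5, 40)
        best, argbest = -np.inf, None
        for s_g in grid:
            for s_e in grid:
                ll = _contrast_loglik(y, s_g * A + s_e * np.eye(n))
                if ll > best:
                    best, argbest = ll, (s_g, s_e)
        step = grid[1] - grid[0]
        assert fit.sigma2[0] == pytest.approx(argbest[0], abs=step)
        assert fit.sigma2_e == pytest.approx(argbest[1], abs=step)
        # and the fitted point cannot be worse than the grid optimum
        ll_fit = _contrast_loglik(y, fit.sigma2[0] * A
                                  + fit.sigma2_e * np.eye(n))
        assert ll_fit >= best - 1e-6

    def test_identity_grm_flagged_unidentifiable(self, rng):
        y = rng.normal(size=120)
        fit = reml_fit(y, [np.eye(120)], max_iter=30)
        assert not fit.converged
        assert "aliased" in fit.message or "convergence" in fit.message

    def test_null_trait_gives_near_zero_h2(self):
        geno = simulate_genotypes(300, 300, np.linspace(0.1, 0.5, 400), seed=53)
        grm = make_grm(geno, "EV")
        y = inverse_normal_transform(
            np.random.default_rng(53).normal(size=600))
        fit = reml_fit(y, [grm])
        assert fit.h2[0] < 0.08

    def test_parameter_recovery_small(self):
        # EV architecture with h2 = 0.4 at modest size; 2-SE recovery band
        rng = np.random.default_rng(59)
        mafs = rng.uniform(0.1, 0.5, 300)
        geno = simulate_genotypes(400, 400, mafs, seed=59)
        h2 = 0.4
        b = rng.normal(size=300)
        arch = ArchitectureSpec(causal_indices=np.arange(300),
                                per_copy_effects=b, dc_model="EV",
                                residual_variance=1.0, seed=59)
        g_f, g_m = genetic_values(geno, arch)
        g = np.concatenate([g_f, g_m])
        g = g / g.std() * np.sqrt(h2)
        y = g + rng.normal(scale=np.sqrt(1 - h2), size=800)
        fit = reml_fit(y, [make_grm(geno, "EV")])
        assert fit.converged
        assert abs(fit.h2[0] - h2) < 2 * max(fit.h2_se[0], 0.05) + 0.05

    def test_mismatched_sizes_error(self):
        with pytest.raises(ValueError):
            reml_fit(np.zeros(10), [np.eye(11)])


class TestLrt:
    def test_boundary_mixture_at_origin(self):
        assert lrt_zero_variance(10.0, 10.0) == pytest.approx(0.5)

    def test_chi2_tail_oracle(self):
        assert lrt_zero_variance(11.353, 10.0) == pytest.approx(
            0.5 * stats.chi2.sf(2.706, 1), rel=1e-6)
        assert lrt_zero_variance(11.353, 10.0) == pytest.approx(0.05, abs=2e-3)

    def test_monotone_in_lr(self):
        ps = [lrt_zero_variance(10 + lr / 2, 10.0) for lr in (0.0, 1.0, 4.0, 9.0)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_negative_lr_beyond_tolerance_errors(self):
        with pytest.raises(ValueError):
            lrt_zero_variance(9.0, 10.0)
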