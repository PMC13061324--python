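import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cnaware import (
    DesignSpec,
    GLMConfig,
    SimConfig,
    build_offsets,
    estimate_dispersions,
    estimate_size_factors,
    fit_glm,
    nb_logpmf,
    run_dge,
    shrink_lfc,
    simulate_dataset,
    wald_test,
)
from cnaware.glm import GeneModelFit, _irls, _maximize_dispersion


class TestSizeFactors:
    def test_doubled_column_hand_value(self):
        col1 = np.array([10.0, 20.0, 35.0, 7.0])
        counts = np.column_stack([col1, 2 * col1])
        s = estimate_size_factors(counts)
        assert np.allclose(s, [1 / np.sqrt(2), np.sqrt(2)])

    def test_identical_columns_give_unity(self):
        counts = np.tile([[4.0], [9.0], [100.0]], (1, 5))
        assert np.allclose(estimate_size_factors(counts), 1.0)

    def test_invariance_to_global_scaling(self):
        # the DESeq2 reference is the per-gene geometric mean across samples,
        # so a global rescaling of all counts cancels in every ratio
        rng = np.random.default_rng(0)
        counts = rng.poisson(50, size=(30, 4)) + 1
        assert np.allclose(
            estimate_size_factors(3 * counts), estimate_size_factors(counts)
        )

    def test_per_sample_depth_change_scales_that_sample(self):
        rng = np.random.default_rng(1)
        counts = (rng.poisson(80, size=(200, 4)) + 1).astype(float)
        scaled = counts.copy()
        scaled[:, 2] *= 3.0
        s0 = estimate_size_factors(counts)
        s1 = estimate_size_factors(scaled)
        # sample 2 absorbs (most of) the 3x depth; ratios of others shift by
        # the common geometric-mean factor 3^(1/4)
        assert s1[2] / s0[2] == pytest.approx(3 ** (3 / 4), rel=1e-12)
        assert np.allclose(s1[[0, 1, 3]] / s0[[0, 1, 3]], 3 ** (-1 / 4))

    def test_no_reference_gene_errors_with_fallback_hint(self):
        counts = np.array([[0, 5], [5, 0]])
        with pytest.raises(ValueError, match="pseudo_reference"):
            estimate_size_factors(counts)
        assert estimate_size_factors(counts, pseudo_reference=True).shape == (2,)


class TestOffsets:
    @pytest.mark.parametrize("cn,expected", [(2.0, 1.0), (4.0, 2.0), (1.0, 0.5)])
    def test_dosage_factor(self, cn, expected):
        off = build_offsets(np.ones(2), np.full((1, 2), cn), mode="aware")
        assert np.allclose(np.exp(off), expected)

    def test_naive_mode_ignores_cn(self):
        s = np.array([0.5, 2.0])
        off = build_offsets(s, np.full((3, 2), 7.0), mode="naive")
        assert np.allclose(np.exp(off), s)

    def test_cn_floor_prevents_infinite_offsets(self):
        off = build_offsets(np.ones(1), np.zeros((1, 1)), mode="aware", cn_floor=0.1)
        assert np.isfinite(off).all()
        assert np.allclose(np.exp(off), 0.05)


def test_nb_logpmf_matches_scipy_oracle():
    """Implemented NB log-likelihood agrees with scipy's nbinom to 1e-10."""
    rng = np.random.default_rng(42)
    for _ in range(200):
        y = rng.integers(0, 500)
        mu = rng.uniform(0.1, 300.0)
        alpha = rng.uniform(1e-3, 5.0)
        r = 1.0 / alpha
        expected = stats.nbinom.logpmf(y, r, r / (r + mu))
        assert abs(nb_logpmf(y, mu, alpha) - expected) < 1e-10


class TestIRLS:
    def test_intercept_only_recovers_mean(self):
        y = np.array([[4.0, 6.0, 5.0, 5.0]])
        X = np.ones((4, 1))
        beta, mu, conv = _irls(y, X, np.zeros_like(y), np.array([0.1]), GLMConfig())
        assert conv.all()
        assert np.exp(beta[0, 0]) == pytest.approx(5.0, abs=1e-5)

    def test_offset_absorption_shifts_condition_coef_by_ln2(self):
        rng = np.random.default_rng(1)
        y = rng.poisson([50] * 4 + [150] * 4, size=(3, 8)).astype(float)
        X = np.column_stack([np.ones(8), [0] * 4 + [1] * 4])
        off0 = np.zeros_like(y)
        off2 = np.tile(np.log([1.0] * 4 + [2.0] * 4), (3, 1))
        cfg = GLMConfig()
        b0, _, _ = _irls(y, X, off0, np.array([0.05] * 3), cfg)
        b2, _, _ = _irls(y, X, off2, np.array([0.05] * 3), cfg)
        assert np.allclose(b0[:, 1] - b2[:, 1], np.log(2.0), atol=1e-6)

    def test_all_zero_gene_excluded_from_run(self, small_design):
        counts = pd.DataFrame(
            [[0] * 6, [50, 60, 55, 100, 120, 110]],
            index=["gz", "g1"],
            columns=small_design.sample_ids,
        )
        out = run_dge(counts, None, small_design, mode="naive")
        assert out.loc["gz", "flag"] == "allzero"
        assert np.isnan(out.loc["gz", "pvalue"])
        assert np.isfinite(out.loc["g1", "pvalue"])


class TestDispersion:
    def test_parameter_recovery_from_nb_draws(self):
        """MAP dispersions recover a true value of 0.1 (500 genes, n=40)."""
        rng = np.random.default_rng(11)
        G, n = 500, 40
        mu = rng.lognormal(5, 1, G)
        r = 1 / 0.1
        y = rng.negative_binomial(
            r, r / (r + np.repeat(mu[:, None], n, axis=1))
        ).astype(float)
        X = np.column_stack([np.ones(n), [0] * (n // 2) + [1] * (n - n // 2)])
        disp = estimate_dispersions(y, X, np.zeros_like(y))
        assert 0.05 < disp.alpha_map.mean() < 0.2

    def test_poisson_data_hits_dispersion_floor(self):
        rng = np.random.default_rng(2)
        y = rng.poisson(200, size=(40, 30)).astype(float)
        X = np.column_stack([np.ones(30), [0] * 15 + [1] * 15])
        disp = estimate_dispersions(y, X, np.zeros_like(y))
        cfg = GLMConfig()
        assert (disp.alpha_genewise >= cfg.min_disp).all()
        assert np.median(disp.alpha_genewise) < 1e-3

    def test_constant_counts_equal_to_mean_drive_mle_to_floor(self):
        # zero residual variance: likelihood increases as dispersion -> 0
        y = np.full((1, 10), 20.0)
        mu = np.full((1, 10), 20.0)
        alpha = _maximize_dispersion(y, mu, GLMConfig())
        assert alpha[0] == pytest.approx(GLMConfig().min_disp, rel=1e-3)


class TestShrinkage:
    def _fit(self, ds, cfg=None):
        cfg = cfg or GLMConfig()
        y = ds.counts.to_numpy(float)
        X = ds.design.matrix()
        s = estimate_size_factors(y)
        off = build_offsets(s, ds.cn, "aware", cn_floor=cfg.cn_floor)
        disp = estimate_dispersions(y, X, off, cfg)
        fit = fit_glm(y, X, off, disp.alpha_map, cfg)
        return shrink_lfc(fit, y, X, off, cfg), ds

    def test_shrinkage_vanishes_with_information(self, mixed_dataset):
        fit, ds = self._fit(mixed_dataset)
        strong = (
            (ds.truth["class"] == "DIG").to_numpy()
            & (ds.truth["baseline_mean"] > 200).to_numpy()
        )
        gap = np.abs(fit.lfc[strong] - fit.lfc_mle[strong])
        assert np.median(gap) < 0.1

    def test_prior_pulls_noisy_low_n_estimates_toward_zero(self):
        cfg = SimConfig(
            n_genes=300,
            n_per_condition=3,
            class_proportions={"DSG": 0, "DIG": 0, "DCG": 0, "nonDEG": 1.0},
            seed=8,
        )
        ds = simulate_dataset(cfg, rng=np.random.default_rng(5))
        fit, _ = self._fit(ds)
        noisy = np.abs(fit.lfc_mle) > 0.2
        assert (np.abs(fit.lfc[noisy]) <= np.abs(fit.lfc_mle[noisy]) + 1e-8).mean() > 0.95

    def test_zero_mle_stays_zero(self):
        # symmetric data put the condition MLE at the prior mode (zero), where
        # both the likelihood and prior gradients vanish
        cfg = GLMConfig()
        y_sym = np.array([[10.0, 20.0, 20.0, 10.0]])
        X_sym = np.column_stack([np.ones(4), [0, 0, 1, 1]])
        mle = fit_glm(y_sym, X_sym, np.zeros((1, 4)), np.array([0.05]), cfg)
        assert abs(mle.beta[0, 1]) < 1e-6
        shr = shrink_lfc(mle, y_sym, X_sym, np.zeros((1, 4)), cfg)
        assert abs(shr.beta_map[0, 1]) < 1e-6


class TestWald:
    def _fit_from(self, beta, se):
        G, F = beta.shape
        cov = np.zeros((G, F, F))
        for g in range(G):
            cov[g] = np.diag(se[g] ** 2)
        return GeneModelFit(
            beta=beta, se=se, cov=cov, mu=np.ones((G, 2)),
            alpha=np.ones(G), converged=np.ones(G, bool),
        )

    def test_null_statistic_gives_p_one(self):
        fit = self._fit_from(np.array([[1.0, 0.0]]), np.array([[0.1, 0.5]]))
        z, p = wald_test(fit, [0, 1])
        assert z[0] == 0 and p[0] == 1.0

    def test_normal_quantile(self):
        fit = self._fit_from(
            np.array([[0.0, 1.959964]]), np.array([[1.0, 1.0]])
        )
        _, p = wald_test(fit, [0, 1])
        assert p[0] == pytest.approx(0.05, abs=1e-6)

    def test_contrast_formula(self):
        fit = self._fit_from(np.array([[3.2, 0.7]]), np.array([[0.5, 0.35]]))
        z, p = wald_test(fit, [0, 1])
        assert z[0] == pytest.approx(2.0)
        assert p[0] == pytest.approx(0.0455, abs=2e-4)

    def test_zero_se_flagged_missing(self):
        fit = self._fit_from(np.array([[1.0, 1.0]]), np.array([[0.1, 0.0]]))
        _, p = wald_test(fit, [0, 1])
        assert np.isnan(p[0])


class TestRunDge:
    def test_deterministic(self, mixed_dataset):
        ds = mixed_dataset
        a = run_dge(ds.counts, ds.cn, ds.design, mode="aware")
        b = run_dge(ds.counts, ds.cn, ds.design, mode="aware")
        pd.testing.assert_frame_equal(a, b)

    def test_mode_equivalence_with_diploid_cn(self, mixed_dataset):
        """CN == 2 everywhere makes aware and naive runs identical (1e-10)."""
        ds = mixed_dataset
        cn = ds.cn.copy()
        cn.loc[:, :] = 2.0
        aware = run_dge(ds.counts, cn, ds.design, mode="aware")
        naive = run_dge(ds.counts, None, ds.design, mode="naive")
        for col in ("lfc", "lfc_mle", "lfc_se", "stat", "pvalue", "dispersion"):
            assert np.nanmax(np.abs(aware[col] - naive[col])) < 1e-10

    def test_offset_shift_identity(self, mixed_dataset):
        """Doubling one gene's tumor CN shifts its aware MLE lfc by exactly -1."""
        ds = mixed_dataset
        gene = ds.counts.index[5]
        cn2 = ds.cn.copy()
        tumor = ds.design.tumor_samples
        cn2.loc[gene, tumor] *= 2.0
        cfg = GLMConfig(shrink=False)
        r1 = run_dge(ds.counts, ds.cn, ds.design, mode="aware", cfg=cfg)
        r2 = run_dge(ds.counts, cn2, ds.design, mode="aware", cfg=cfg)
        shift = r2.loc[gene, "lfc_mle"] - r1.loc[gene, "lfc_mle"]
        assert shift == pytest.approx(-1.0, abs=1e-6)

    def test_dsg_gene_naive_vs_aware_lfc(self):
        """Pure dosage gene (tumor CN 4): naive lfc ~ 1, aware lfc ~ 0."""
        rng = np.random.default_rng(17)
        n = 60
        mu0 = 400.0
        y = np.column_stack(
            [rng.poisson(mu0, n), rng.poisson(2 * mu0, n)]
        )  # tumor doubled by dosage
        # 50-gene background so size factors / trend are estimable
        bg = rng.poisson(150, size=(50, 2 * n)).astype(int)
        all_counts = np.vstack([np.concatenate([y[:, 0], y[:, 1]])[None, :], bg])
        ids = ["dsg"] + [f"bg{i}" for i in range(50)]
        samples = [f"n{i}" for i in range(n)] + [f"t{i}" for i in range(n)]
        counts = pd.DataFrame(all_counts, index=ids, columns=samples)
        cn = pd.DataFrame(2.0, index=ids, columns=samples)
        cn.loc["dsg", [f"t{i}" for i in range(n)]] = 4.0
        design = DesignSpec(
            pd.DataFrame({"condition": [0] * n + [1] * n}, index=samples)
        )
        naive = run_dge(counts, None, design, mode="naive")
        aware = run_dge(counts, cn, design, mode="aware")
        assert naive.loc["dsg", "lfc"] == pytest.approx(1.0, abs=0.15)
        assert abs(aware.loc["dsg", "lfc"]) < 0.15
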