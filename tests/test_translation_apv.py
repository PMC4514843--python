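import numpy as np
import pandas as pd
import pytest
from scipy import stats

from polyapv import (
    AnalysisSettings,
    GeneClass,
    GeneClassSpec,
    NoiseSpec,
    bh_adjust,
    fit_gene_apv,
    generate_experiment,
    run_translation_analysis,
    slope_filter,
)
from polyapv.io_model import ValidationError
from polyapv.translation_apv import GeneApvFit

from conftest import make_matrix


def brute_force_ancova(P, C, conditions):
    """Normal-equation solve of P = alpha_cond + beta*C on the explicit
    design matrix; independent of the package's pooled-sums code path."""
    P = np.asarray(P, float)
    C = np.asarray(C, float)
    labels = list(dict.fromkeys(conditions))
    K = len(labels)
    n = len(P)
    X = np.zeros((n, K + 1))
    for j, lab in enumerate(labels):
        X[:, j] = [c == lab for c in conditions]
    X[:, K] = C
    coef, _, _, _ = np.linalg.lstsq(X, P, rcond=None)
    resid = P - X @ coef
    rss = float(resid @ resid)
    m = n - (K + 1)
    # reduced model: single intercept + slope
    Xr = np.column_stack([np.ones(n), C])
    coef_r, _, _, _ = np.linalg.lstsq(Xr, P, rcond=None)
    resid_r = P - Xr @ coef_r
    ss_effect = float(resid_r @ resid_r) - rss
    sigma_sq = rss / m
    cov = sigma_sq * np.linalg.inv(X.T @ X)
    slope_se = float(np.sqrt(cov[K, K]))
    means_p = {lab: P[[c == lab for c in conditions]].mean() for lab in labels}
    means_c = {lab: C[[c == lab for c in conditions]].mean() for lab in labels}
    return {
        "slope": float(coef[K]),
        "slope_se": slope_se,
        "rss": rss,
        "df_resid": m,
        "ss_effect": ss_effect,
        "delta_p": means_p[labels[-1]] - means_p[labels[0]],
        "delta_c": means_c[labels[-1]] - means_c[labels[0]],
    }


class TestFitGeneApv:
    def test_noiseless_slope_only(self):
        C = np.array([1.0, 2.0, 3.0, 1.5, 2.5, 3.5])
        P = 2.0 + 1.0 * C
        conditions = ["a", "a", "a", "b", "b", "b"]
        fit = fit_gene_apv(P, C, conditions)
        assert fit.slope == pytest.approx(1.0, abs=1e-12)
        assert fit.ss_effect == pytest.approx(0.0, abs=1e-12)
        assert fit.delta_pt == pytest.approx(0.0, abs=1e-12)

    def test_planted_intercept_shift(self):
        C = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        delta = 0.8
        P = C + delta * np.array([0, 0, 0, 1, 1, 1])
        fit = fit_gene_apv(P, C, ["a", "a", "a", "b", "b", "b"])
        adj_diff = fit.adjusted_means["b"] - fit.adjusted_means["a"]
        assert adj_diff == pytest.approx(delta, abs=1e-12)
        assert fit.delta_pt == pytest.approx(delta, abs=1e-12)

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(21)
        conditions = ["a"] * 4 + ["b"] * 4
        for _ in range(25):
            C = rng.normal(7, 1, 8)
            P = 0.5 + 1.2 * C + rng.normal(0, 0.5, 8)
            P[4:] -= 0.9
            fit = fit_gene_apv(P, C, conditions)
            want = brute_force_ancova(P, C, conditions)
            assert fit.slope == pytest.approx(want["slope"], abs=1e-8)
            assert fit.slope_se == pytest.approx(want["slope_se"], abs=1e-8)
            assert fit.rss == pytest.approx(want["rss"], abs=1e-8)
            assert fit.df_resid == want["df_resid"]
            assert fit.ss_effect == pytest.approx(want["ss_effect"], abs=1e-8)
            assert fit.delta_p == pytest.approx(want["delta_p"], abs=1e-10)
            assert fit.delta_c == pytest.approx(want["delta_c"], abs=1e-10)

    def test_three_conditions_oracle(self):
        rng = np.random.default_rng(5)
        conditions = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        C = rng.normal(6, 1, 9)
        P = 1.0 + 0.8 * C + rng.normal(0, 0.3, 9)
        fit = fit_gene_apv(P, C, conditions)
        want = brute_force_ancova(P, C, conditions)
        assert fit.slope == pytest.approx(want["slope"], abs=1e-8)
        assert fit.rss == pytest.approx(want["rss"], abs=1e-8)
        assert fit.ss_effect == pytest.approx(want["ss_effect"], abs=1e-8)

    def test_rank_deficient_constant_c(self):
        C = np.full(8, 5.0)
        P = np.arange(8.0)
        fit = fit_gene_apv(P, C, ["a"] * 4 + ["b"] * 4)
        assert fit.rank_deficient
        assert np.isnan(fit.slope)

    def test_shift_equivariance(self):
        rng = np.random.default_rng(3)
        conditions = ["a"] * 4 + ["b"] * 4
        C = rng.normal(0, 1, 8)
        P = 0.3 + 0.9 * C + rng.normal(0, 0.2, 8)
        f0 = fit_gene_apv(P, C, conditions)
        f1 = fit_gene_apv(P, C + 100.0, conditions)
        assert f1.slope == pytest.approx(f0.slope, abs=1e-9)
        assert f1.ss_effect == pytest.approx(f0.ss_effect, abs=1e-8)
        assert f1.rss == pytest.approx(f0.rss, abs=1e-8)
        assert f1.delta_pt == pytest.approx(f0.delta_pt, abs=1e-9)


class TestSlopeFilter:
    def _fit(self, slope, slope_se, m=5):
        return GeneApvFit(
            slope=slope, slope_se=slope_se, adjusted_means={},
            rss=1.0, df_resid=m, ss_effect=0.0,
            delta_p=0.0, delta_c=0.0, delta_pt=0.0,
        )

    def test_inside_bounds_not_flagged(self, settings):
        assert slope_filter(self._fit(0.5, 10.0), settings) is False

    def test_far_above_with_tiny_se_flagged(self, settings):
        assert slope_filter(self._fit(3.0, 1e-6), settings) is True

    def test_slightly_above_with_large_se_not_flagged(self, settings):
        # p = P(T > (2.1-2)/1.0) ~ 0.46 >> slopeP
        assert slope_filter(self._fit(2.1, 1.0), settings) is False

    def test_below_min_slope_t_arithmetic(self, settings):
        # closed-form one-sided t oracle at the lower boundary
        slope, se, m = -2.5, 0.4, 5
        p = stats.t.cdf((slope - settings.minSlope) / se, m)
        assert p < settings.slopeP
        assert slope_filter(self._fit(slope, se, m), settings) is True
        # and a boundary case that misses the threshold
        slope2, se2 = -1.8, 1.0
        p2 = stats.t.cdf((slope2 - settings.minSlope) / se2, m)
        assert p2 >= settings.slopeP
        assert slope_filter(self._fit(slope2, se2, m), settings) is False

    def test_zero_se_outside_bounds_flagged(self, settings):
        assert slope_filter(self._fit(2.5, 0.0), settings) is True
        assert slope_filter(self._fit(-1.5, 0.0), settings) is True


class TestBhAdjust:
    def test_textbook_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03], rtol=1e-12
        )

    def test_all_ones(self):
        np.testing.assert_array_equal(bh_adjust([1.0, 1.0, 1.0]), [1, 1, 1])

    def test_empty(self):
        assert bh_adjust([]).size == 0

    def test_against_reference_implementation(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(8)
        p = rng.uniform(size=1000)
        ours = bh_adjust(p)
        ref = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(ours, ref, rtol=1e-12)

    def test_monotone_in_rank(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(size=500)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_invalid_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])


def _null_matrix(n_genes, seed, n_rep=4):
    matrix, _ = generate_experiment(
        [GeneClassSpec(GeneClass.NULL, n_genes)], NoiseSpec(),
        ["IFN", "IFN+Torin1"], n_rep, seed=seed,
    )
    return matrix


class TestRunTranslationAnalysis:
    def test_recovery_of_planted_repression(self):
        classes = [
            GeneClassSpec(GeneClass.TOP_REPRESSED, 60, delta_translation=-1.5),
            GeneClassSpec(GeneClass.NULL, 1440),
        ]
        matrix, truth = generate_experiment(
            classes, NoiseSpec(), ["IFN", "IFN+Torin1"], 4, seed=13
        )
        result = run_translation_analysis(matrix, ("IFN", "IFN+Torin1"))
        called = set(result.significant_by_direction("repressed"))
        planted = set(truth.genes_with_label(GeneClass.TOP_REPRESSED))
        sens = len(called & planted) / len(planted)
        fdr = len(called - planted) / max(len(called), 1)
        assert sens >= 0.7
        assert fdr <= 0.2

    def test_null_dataset_nearly_no_calls(self):
        result = run_translation_analysis(
            _null_matrix(2000, seed=17), ("IFN", "IFN+Torin1")
        )
        assert result.table["significant"].sum() <= 2

    def test_identical_conditions_zero_significant(self):
        rng = np.random.default_rng(31)
        base_c = rng.normal(7, 1, (200, 4))
        base_p = base_c + 0.5
        eps = 1e-6
        C = np.concatenate([base_c, base_c + rng.normal(0, eps, base_c.shape)],
                           axis=1)
        P = np.concatenate([base_p, base_p + rng.normal(0, eps, base_p.shape)],
                           axis=1)
        matrix = make_matrix(C, P, ["a"] * 4 + ["b"] * 4)
        result = run_translation_analysis(matrix, ("a", "b"))
        assert result.table["significant"].sum() == 0

    def test_contrast_swap_negates_effects(self, small_experiment):
        matrix, _ = small_experiment
        fwd = run_translation_analysis(matrix, ("IFN", "IFN+Torin1"))
        rev = run_translation_analysis(matrix, ("IFN+Torin1", "IFN"))
        f = fwd.table.set_index("gene_id").sort_index()
        r = rev.table.set_index("gene_id").sort_index()
        np.testing.assert_allclose(f["delta_p"], -r["delta_p"], atol=1e-10)
        np.testing.assert_allclose(f["delta_c"], -r["delta_c"], atol=1e-10)
        np.testing.assert_allclose(f["delta_pt"], -r["delta_pt"], atol=1e-10)
        np.testing.assert_allclose(f["p_value"], r["p_value"], rtol=1e-9)

    def test_classical_mode_equals_oracle(self):
        """moderation off -> per-gene classical ANCOVA F and p."""
        matrix = _null_matrix(100, seed=23)
        result = run_translation_analysis(
            matrix, ("IFN", "IFN+Torin1"), moderation=False
        )
        table = result.table.set_index("gene_id")
        C, c_design = matrix.submatrix("cytosolic", ["IFN", "IFN+Torin1"])
        P, _ = matrix.submatrix("polysomal", ["IFN", "IFN+Torin1"])
        conditions = list(c_design["condition"])
        for i, gene in enumerate(matrix.gene_ids):
            want = brute_force_ancova(P[i], C[i], conditions)
            f_want = (want["ss_effect"] / 1) / (want["rss"] / want["df_resid"])
            p_want = stats.f.sf(f_want, 1, want["df_resid"])
            assert table.loc[gene, "f_stat"] == pytest.approx(f_want, rel=1e-8)
            assert table.loc[gene, "p_value"] == pytest.approx(p_want, rel=1e-8)

    def test_weak_effect_trends_negative_but_few_calls(self):
        """Weak inhibitor arm: few significant genes, negative dPT trend."""
        classes = [
            GeneClassSpec(GeneClass.TOP_REPRESSED, 100,
                          delta_translation=-0.4),
            GeneClassSpec(GeneClass.NULL, 1900),
        ]
        matrix, truth = generate_experiment(
            classes, NoiseSpec(), ["IFN", "IFN+rapamycin"], 4, seed=29
        )
        result = run_translation_analysis(matrix, ("IFN", "IFN+rapamycin"))
        planted = set(truth.genes_with_label(GeneClass.TOP_REPRESSED))
        table = result.table
        n_sig = int(table["significant"].sum())
        assert n_sig <= 10  # |dPT| = 0.4 sits below selDeltaPT = log2(1.5)
        trend = table.loc[table["gene_id"].isin(planted), "delta_pt"].mean()
        assert trend < -0.2

    def test_missing_condition_error(self, small_experiment):
        matrix, _ = small_experiment
        with pytest.raises(ValidationError, match="Torin2"):
            run_translation_analysis(matrix, ("IFN", "Torin2"))

    def test_too_few_genes_error(self):
        with pytest.raises(ValidationError, match="50"):
            run_translation_analysis(_null_matrix(20, seed=1),
                                     ("IFN", "IFN+Torin1"))

    def test_output_sorted_by_padj(self, small_experiment):
        matrix, _ = small_experiment
        table = run_translation_analysis(matrix, ("IFN", "IFN+Torin1")).table
        padj = table["padj"].to_numpy()
        assert (np.diff(padj[~np.isnan(padj)]) >= -1e-15).all()

    def test_significant_implies_flags(self, small_experiment):
        matrix, _ = small_experiment
        settings = AnalysisSettings()
        table = run_translation_analysis(
            matrix, ("IFN", "IFN+Torin1"), settings
        ).table
        sig = table[table["significant"]]
        assert (sig["padj"] <= settings.maxRvmPAdj).all()
        assert sig["deltaPT_pass"].all()
        assert (~sig["slope_flag"]).all()
        assert (sig["direction"].isin(["repressed", "enhanced"])).all()
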