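import numpy as np
import pandas as pd
import pytest

from panstrat import (
    GeneSet,
    attenuation,
    fit_instability_model,
    focal_proliferation_correlation,
    g2m_score,
    run_model_grid,
    simulate_multi_cohort,
    transform_covariates,
)
from panstrat.errors import SingularDesignError, ValidationError
from panstrat.proliferation_model import (
    PAN_CANCER,
    RegressionResult,
    Term,
    attenuation_summary,
    results_to_frame,
)
from panstrat.synthetic_data import SimulationParams, preset

from conftest import make_cohort


def _result(beta, outcome="fga", stratum=PAN_CANCER, model="unadjusted"):
    term = Term("focal", beta, 0.1, beta - 0.2, beta + 0.2, 0.01)
    return RegressionResult(outcome, stratum, model, [term], 100)


class TestG2MScore:
    def test_hand_z_score(self):
        # genes already on log2 scale after the inverse transform below
        expr = {
            "A": {"s1": 2.0**1 - 1, "s2": 2.0**3 - 1},
            "B": {"s1": 2.0**2 - 1, "s2": 2.0**6 - 1},
        }
        cohort = make_cohort(expr)
        score = g2m_score(cohort, GeneSet("SET", frozenset("AB")), exclude=frozenset())
        # per-gene z with n-1 denominator: (-1/sqrt(2), +1/sqrt(2))
        expected = 1.0 / np.sqrt(2.0)
        assert score.scores["s1"] == pytest.approx(-expected)
        assert score.scores["s2"] == pytest.approx(expected)
        assert score.n_genes_used == 2

    def test_affine_invariance_on_log_scale(self, small_sim_cohort):
        gene_set = GeneSet("SET", frozenset(["G2M_000", "G2M_001", "G2M_002"]))
        base = g2m_score(small_sim_cohort, gene_set, pseudocount=0.0)
        scaled = small_sim_cohort.expression.copy()
        # x -> x^a * 2^b is affine on the log2 scale (a > 0)
        scaled.loc["G2M_001"] = scaled.loc["G2M_001"] ** 1.7 * 2.0**3
        cohort2 = make_cohort(
            {g: scaled.loc[g].to_dict() for g in scaled.index}
        )
        again = g2m_score(cohort2, gene_set, pseudocount=0.0)
        assert np.allclose(
            base.scores.to_numpy(), again.scores.reindex(base.scores.index).to_numpy()
        )

    def test_mki67_excluded_by_default(self, small_sim_cohort):
        gene_set = GeneSet("SET", frozenset(["G2M_000", "MKI67"]))
        score = g2m_score(small_sim_cohort, gene_set)
        assert score.n_genes_used == 1
        assert "MKI67" in score.excluded_genes

    def test_all_excluded_raises(self, small_sim_cohort):
        gene_set = GeneSet("SET", frozenset(["G2M_000"]))
        with pytest.raises(ValidationError):
            g2m_score(small_sim_cohort, gene_set, exclude=frozenset(["G2M_000"]))

    def test_zero_variance_gene_dropped(self):
        expr = {
            "A": {"s1": 1.0, "s2": 4.0, "s3": 2.0},
            "FLAT": {"s1": 3.0, "s2": 3.0, "s3": 3.0},
        }
        cohort = make_cohort(expr)
        with pytest.warns(UserWarning, match="FLAT"):
            score = g2m_score(cohort, GeneSet("S", frozenset(["A", "FLAT"])),
                              exclude=frozenset())
        assert score.n_genes_used == 1


class TestTransformCovariates:
    def test_log1p_zero(self):
        cohort = make_cohort(
            {"FOCAL": {"s1": 0.0, "s2": 3.0}},
            metrics={"mutation_count": [0, 7]},
        )
        table = transform_covariates(cohort, "FOCAL")
        assert table.loc["s1", "log1p_mutation_count"] == 0.0
        assert table.loc["s1", "focal_log2"] == 0.0  # log2(0 + 1)
        assert table.loc["s2", "focal_log2"] == pytest.approx(2.0)

    def test_elementwise_closed_form(self, small_sim_cohort):
        table = transform_covariates(small_sim_cohort, "FOCAL")
        focal = small_sim_cohort.expression.loc["FOCAL"].to_numpy()
        assert np.allclose(
            table["focal_log2"].to_numpy(), np.log2(focal + 1.0), atol=1e-12
        )
        mc = small_sim_cohort.metrics["mutation_count"].to_numpy(float)
        assert np.allclose(
            table["log1p_mutation_count"].to_numpy(), np.log(1.0 + mc), atol=1e-12
        )


class TestFitInstabilityModel:
    def test_exact_fit(self):
        focal = pd.Series([1.0, 2, 3, 4, 5])
        outcome = 2.0 * focal
        res = fit_instability_model(outcome, focal)
        assert res.term("focal").beta == pytest.approx(2.0, abs=1e-10)
        assert np.allclose(res.residuals, 0.0, atol=1e-10)

    def test_collinear_covariate_raises(self):
        focal = pd.Series(np.arange(10.0))
        with pytest.raises(SingularDesignError):
            fit_instability_model(focal * 1.5, focal, covariate=focal)

    def test_insufficient_n(self):
        focal = pd.Series([1.0, 2.0])
        with pytest.raises(ValidationError):
            fit_instability_model(focal, focal * 2)

    def test_normal_equations_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            n = 100
            x = rng.normal(size=n)
            z = rng.normal(size=n)
            y = 0.5 * x - 0.3 * z + rng.normal(size=n)
            res = fit_instability_model(
                pd.Series(y), pd.Series(x), pd.Series(z), covariate_name="z"
            )
            X = np.column_stack([np.ones(n), x, z])
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            resid = y - X @ beta
            sigma2 = resid @ resid / (n - 3)
            se = np.sqrt(np.diag(sigma2 * np.linalg.inv(X.T @ X)))
            assert res.term("focal").beta == pytest.approx(beta[1], abs=1e-8)
            assert res.term("z").beta == pytest.approx(beta[2], abs=1e-8)
            assert res.term("focal").se == pytest.approx(se[1], abs=1e-8)

    def test_ci_uses_t_quantile(self):
        from scipy import stats

        rng = np.random.default_rng(14)
        x = pd.Series(rng.normal(size=30))
        y = 0.4 * x + rng.normal(size=30) * 0.5
        res = fit_instability_model(y, x)
        t = res.term("focal")
        half = stats.t.ppf(0.975, df=30 - 2) * t.se
        assert t.ci_low == pytest.approx(t.beta - half, abs=1e-10)
        assert t.ci_high == pytest.approx(t.beta + half, abs=1e-10)


class TestAttenuation:
    def test_table_style_arithmetic(self):
        # unadjusted 0.05, adjusted 0.0037 -> 1 - 0.0037/0.05 = 0.926
        assert attenuation(_result(0.05), _result(0.0037, model="g2m_adjusted")) == (
            pytest.approx(0.926)
        )

    def test_no_attenuation(self):
        assert attenuation(_result(0.4), _result(0.4, model="g2m_adjusted")) == 0.0

    def test_full_attenuation(self):
        assert attenuation(_result(0.4), _result(0.0, model="g2m_adjusted")) == 1.0

    def test_zero_unadjusted_flagged_nan(self):
        assert np.isnan(attenuation(_result(0.0), _result(0.1)))

    def test_stratum_mismatch_raises(self):
        with pytest.raises(ValidationError):
            attenuation(_result(0.1), _result(0.1, stratum="OTHER"))


class TestModelGrid:
    def test_grid_size_single_cohort(self):
        params = SimulationParams(
            n_cohorts=1, n_samples_per_cohort=80, n_genes=40,
            n_planted_coexpressed=4, n_g2m_genes=8, seed=3,
        )
        cohorts = simulate_multi_cohort(params)
        results = run_model_grid(cohorts, "FOCAL", params.g2m_gene_set())
        # 2 outcomes x 3 models, for the cohort and the pan-cancer pool
        assert len(results) == 12
        strata = {r.stratum for r in results}
        assert strata == {PAN_CANCER, "SIM_00"}

    def test_mediation_attenuation_large_n(self):
        params = preset("mediation", n_cohorts=1, n_samples_per_cohort=5000,
                        n_genes=40, n_planted_coexpressed=4, n_g2m_genes=8, seed=5)
        cohorts = simulate_multi_cohort(params)
        results = run_model_grid(cohorts, "FOCAL", params.g2m_gene_set())
        summary = attenuation_summary(results)
        row = summary[
            (summary.stratum == PAN_CANCER)
            & (summary.outcome == "fga")
            & (summary.model == "g2m_adjusted")
        ].iloc[0]
        assert row["attenuation"] > 0.75

    def test_direct_effect_survives_adjustment(self):
        params = preset("direct-effect", n_cohorts=1, n_samples_per_cohort=5000,
                        n_genes=40, n_planted_coexpressed=4, n_g2m_genes=8, seed=5)
        cohorts = simulate_multi_cohort(params)
        results = run_model_grid(cohorts, "FOCAL", params.g2m_gene_set())
        adj = next(
            r for r in results
            if r.stratum == PAN_CANCER and r.outcome == "fga"
            and r.model == "g2m_adjusted"
        )
        assert adj.term("focal").p_value < 0.05

    def test_g2m_attenuates_more_than_mki67(self):
        params = preset("mediation", n_cohorts=2, n_samples_per_cohort=2000,
                        n_genes=40, n_planted_coexpressed=4, n_g2m_genes=8, seed=9)
        cohorts = simulate_multi_cohort(params)
        summary = attenuation_summary(
            run_model_grid(cohorts, "FOCAL", params.g2m_gene_set())
        )
        pan = summary[(summary.stratum == PAN_CANCER) & (summary.outcome == "fga")]
        g2m = pan[pan.model == "g2m_adjusted"]["attenuation"].iloc[0]
        mki = pan[pan.model == "mki67_adjusted"]["attenuation"].iloc[0]
        assert g2m > mki

    def test_results_frame_columns(self):
        frame = results_to_frame([_result(0.2)])
        assert list(frame.columns)[:5] == ["stratum", "outcome", "model", "term", "beta"]


class TestFocalProliferationCorrelation:
    def test_score_equal_focal_gives_one(self, small_sim_cohort):
        focal_log2 = np.log2(small_sim_cohort.expression.loc["FOCAL"] + 1.0)
        scores = {small_sim_cohort.cohort_id: focal_log2}
        rho, p = focal_proliferation_correlation([small_sim_cohort], "FOCAL", scores)
        assert rho == pytest.approx(1.0)

    def test_reversed_score_negates(self, small_sim_cohort):
        focal_log2 = np.log2(small_sim_cohort.expression.loc["FOCAL"] + 1.0)
        rho_pos, _ = focal_proliferation_correlation(
            [small_sim_cohort], "FOCAL", {small_sim_cohort.cohort_id: focal_log2}
        )
        rho_neg, _ = focal_proliferation_correlation(
            [small_sim_cohort], "FOCAL", {small_sim_cohort.cohort_id: -focal_log2}
        )
        assert rho_neg == pytest.approx(-rho_pos)

    def test_calibrated_target_under_mediation(self):
        # focal and score share the latent factor P; the Pearson correlation
        # is fl * corr(score, P) and the Spearman target follows from the
        # Gaussian-copula conversion (calibration documented in the module)
        from panstrat.synthetic_data import spearman_target

        params = preset("mediation", n_cohorts=1, n_samples_per_cohort=5000,
                        n_genes=60, n_planted_coexpressed=4, n_g2m_genes=20, seed=17)
        [cohort] = simulate_multi_cohort(params)
        score = g2m_score(cohort, params.g2m_gene_set())
        rho, p = focal_proliferation_correlation(
            [cohort], "FOCAL", {cohort.cohort_id: score.scores}
        )
        gl, k = params.g2m_loading, params.n_g2m_genes
        score_vs_p = gl / np.sqrt(gl**2 + (1 - gl**2) / k)
        target = spearman_target(params.focal_loading * score_vs_p)
        assert rho == pytest.approx(target, abs=0.05)
        assert p < 1e-4
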