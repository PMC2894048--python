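"""Design building, OLS diagnostics, subset selection and the predictive equation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gagfib.data_model import entries_to_frame
from gagfib.exceptions import DomainError, NoModelError, SingularDesignError
from gagfib.multivariate import (
    PREDICTIVE_SPEC,
    ModelSpec,
    PredictiveModel,
    build_design,
    ols_fit,
    optimal_molar_ratio,
    predict_G,
    select_model,
)
from gagfib.synthetic_data import (
    GeneratorConfig,
    generate_entries,
    noise_for_target_r2,
    recovery_universe,
)


def normal_equations_oracle(X: np.ndarray, y: np.ndarray):
    """Textbook OLS by explicit matrix algebra, independent of statsmodels."""
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    n, k = X.shape
    sigma2 = resid @ resid / (n - k)
    se = np.sqrt(np.diag(sigma2 * np.linalg.inv(XtX)))
    tss = np.sum((y - y.mean()) ** 2)
    r2 = 1 - resid @ resid / tss
    r2_adj = 1 - (1 - r2) * (n - 1) / (n - k)
    f = (r2 / (k - 1)) / ((1 - r2) / (n - k))
    model_p = stats.f.sf(f, k - 1, n - k)
    return beta, se, r2, r2_adj, model_p


class TestBuildDesign:
    def test_predictive_design_is_n_by_5_with_intercept(self, demo_entries):
        X, y = build_design(demo_entries, PREDICTIVE_SPEC)
        assert X.shape == (39, 5)
        assert list(X.columns) == [
            "const",
            "sulfates_per_disaccharide",
            "solute_molarity",
            "protein_gag_molar_ratio",
            "protein_gag_molar_ratio^2",
        ]
        assert (X["const"] == 1.0).all()
        assert np.allclose(
            X["protein_gag_molar_ratio^2"], X["protein_gag_molar_ratio"] ** 2
        )

    def test_empty_spec_gives_intercept_only(self, demo_entries):
        X, y = build_design(demo_entries, ModelSpec())
        assert list(X.columns) == ["const"]
        assert len(y) == 39

    def test_duplicated_column_rejected_by_rank_check(self, demo_entries):
        spec = ModelSpec(predictors=["sulfates_per_disaccharide", "charges_per_disaccharide"])
        frame = entries_to_frame(demo_entries).copy()
        frame["charges_per_disaccharide"] = frame["sulfates_per_disaccharide"]
        with pytest.raises(SingularDesignError):
            build_design(frame, spec)

    def test_quadratic_without_linear_term_rejected(self):
        with pytest.raises(DomainError, match="linear term"):
            ModelSpec(quadratics=["solute_molarity"]).validate()

    def test_interaction_must_involve_a_dummy(self):
        with pytest.raises(DomainError, match="dummy"):
            ModelSpec(
                predictors=["solute_molarity", "protein_gag_molar_ratio"],
                interactions=[("solute_molarity", "protein_gag_molar_ratio")],
            ).validate()

    def test_missing_predictor_values_drop_entries(self, demo_entries):
        frame = entries_to_frame(demo_entries).copy()
        frame.loc[frame.index[:4], "protein_gag_molar_ratio"] = np.nan
        X, y = build_design(frame, PREDICTIVE_SPEC)
        assert len(X) == 35


class TestOlsFit:
    def test_matches_normal_equations_oracle_to_1e10(self):
        rng = np.random.default_rng(8)
        for trial in range(5):
            X = np.column_stack([np.ones(20), rng.normal(size=(20, 2))])
            y = rng.normal(size=20)
            frame = pd.DataFrame(X, columns=["const", "x1", "x2"])
            fit = ols_fit(frame, y)
            beta, se, r2, r2_adj, model_p = normal_equations_oracle(X, y)
            np.testing.assert_allclose(fit.params.to_numpy(), beta, atol=1e-10)
            np.testing.assert_allclose(fit.bse.to_numpy(), se, atol=1e-10)
            assert fit.r2 == pytest.approx(r2, abs=1e-10)
            assert fit.r2_adj == pytest.approx(r2_adj, abs=1e-10)
            assert fit.model_p == pytest.approx(model_p, abs=1e-10)

    def test_exact_linear_response_gives_r2_one_and_zero_residuals(self):
        rng = np.random.default_rng(3)
        X = np.column_stack([np.ones(15), rng.normal(size=15)])
        y = 2.0 + 3.0 * X[:, 1]
        fit = ols_fit(pd.DataFrame(X, columns=["const", "x"]), y)
        assert fit.r2 == pytest.approx(1.0)
        np.testing.assert_allclose(fit.residuals, 0.0, atol=1e-10)

    def test_rank_deficiency_is_singular(self):
        X = pd.DataFrame({"const": np.ones(10), "a": np.arange(10.0), "b": np.arange(10.0)})
        with pytest.raises(SingularDesignError):
            ols_fit(X, np.arange(10.0))

    def test_vif_detects_between_variable_collinearity(self, noisy_entries):
        spec = ModelSpec(
            predictors=["sulfates_per_disaccharide", "charges_per_disaccharide"]
        )
        X, y = build_design(noisy_entries, spec)
        fit = ols_fit(X, y, spec=spec)
        assert (fit.vif_between_variables > 5).all()

    def test_structural_square_collinearity_not_penalized(self, noisy_entries):
        X, y = build_design(noisy_entries, PREDICTIVE_SPEC)
        fit = ols_fit(X, y, spec=PREDICTIVE_SPEC)
        # raw VIF of the ratio terms is large, between-variable VIF is not
        assert fit.vif["protein_gag_molar_ratio"] > 5
        assert fit.vif_between_variables["protein_gag_molar_ratio"] < 5

    def test_adjusted_r2_not_increased_by_pure_noise_column_on_average(self):
        # E[delta adj R2] = 0 exactly for an irrelevant regressor (the
        # adjustment compensates the fit improvement in expectation), while
        # E[delta R2] > 0; assert the adj-R2 mean is not significantly
        # positive and strictly below the raw-R2 mean
        rng = np.random.default_rng(21)
        deltas_adj, deltas_raw = [], []
        for _ in range(100):
            n = 40
            x = rng.normal(size=n)
            y = 1.0 + 0.8 * x + rng.normal(size=n)
            base = pd.DataFrame({"const": np.ones(n), "x": x})
            fit0 = ols_fit(base, y)
            noisy = base.assign(junk=rng.normal(size=n))
            fit1 = ols_fit(noisy, y)
            deltas_adj.append(fit1.r2_adj - fit0.r2_adj)
            deltas_raw.append(fit1.r2 - fit0.r2)
        sem = np.std(deltas_adj, ddof=1) / np.sqrt(len(deltas_adj))
        assert np.mean(deltas_adj) <= 2 * sem
        assert np.mean(deltas_adj) < np.mean(deltas_raw)


class TestSelectModel:
    def test_recovers_generating_specification_on_calibrated_data(self):
        cfg = GeneratorConfig(n_entries=200, seed=0)
        cfg.noise_sd = noise_for_target_r2(cfg, 0.74)
        entries = generate_entries(cfg)
        fit, spec = select_model(entries, recovery_universe(), method="best_subset")
        assert sorted(fit.params.index) == [
            "const",
            "protein_gag_molar_ratio",
            "protein_gag_molar_ratio^2",
            "solute_molarity",
            "sulfates_per_disaccharide",
        ]

    def test_stepwise_and_best_subset_agree_on_calibrated_data(self):
        cfg = GeneratorConfig(n_entries=200, seed=1)
        cfg.noise_sd = noise_for_target_r2(cfg, 0.74)
        entries = generate_entries(cfg)
        fit_bs, _ = select_model(entries, recovery_universe(), method="best_subset")
        fit_sw, _ = select_model(entries, recovery_universe(), method="stepwise")
        assert sorted(fit_bs.params.index) == sorted(fit_sw.params.index)

    def test_collinear_sulfation_measures_never_coselected(self):
        universe = ModelSpec(
            predictors=[
                "sulfates_per_disaccharide",
                "charges_per_disaccharide",
                "solute_molarity",
                "protein_gag_molar_ratio",
            ],
            quadratics=["protein_gag_molar_ratio"],
        )
        for seed in range(10):
            cfg = GeneratorConfig(n_entries=200, seed=seed)
            cfg.noise_sd = noise_for_target_r2(cfg, 0.74)
            fit, _ = select_model(generate_entries(cfg), universe, method="best_subset")
            chosen = set(fit.params.index)
            assert not {
                "sulfates_per_disaccharide", "charges_per_disaccharide"
            } <= chosen

    def test_pure_noise_response_yields_no_model(self):
        rng = np.random.default_rng(5)
        cfg = GeneratorConfig(n_entries=39, seed=5, noise_sd=0.0)
        frame = entries_to_frame(generate_entries(cfg)).copy()
        frame["G"] = rng.normal(size=len(frame))  # sever the covariate link
        with pytest.raises(NoModelError):
            select_model(frame, recovery_universe(), method="best_subset")


class TestPredictiveEquation:
    def test_hand_evaluated_prediction(self, published_model):
        # 2.0 + 0.30*2 - 0.016*100 + 0.11*10 - 0.0020*100 = 1.9
        assert predict_G(published_model, 2.0, 100.0, 10.0) == pytest.approx(1.9)

    def test_prediction_vanishes_at_molarity_125_without_sulfates(self, published_model):
        # 2.0 - 0.016*125 = 0 in the limit of vanishing molar ratio
        assert predict_G(published_model, 0.0, 125.0, 1e-9) == pytest.approx(0.0, abs=1e-6)

    def test_zero_coefficients_predict_zero(self):
        zero = PredictiveModel(0.0, 0.0, 0.0, 0.0, 0.0)
        assert predict_G(zero, 3.0, 250.0, 50.0) == 0.0

    def test_linearity_in_coefficients_superposition(self, published_model):
        m = published_model
        parts = [
            PredictiveModel(m.y0, 0, 0, 0, 0),
            PredictiveModel(0, m.a, 0, 0, 0),
            PredictiveModel(0, 0, m.b, 0, 0),
            PredictiveModel(0, 0, 0, m.c, 0),
            PredictiveModel(0, 0, 0, 0, m.c_prime),
        ]
        args = (1.5, 180.0, 22.0)
        total = sum(predict_G(p, *args) for p in parts)
        assert predict_G(m, *args) == pytest.approx(total, abs=1e-12)

    def test_domain_errors(self, published_model):
        with pytest.raises(DomainError):
            predict_G(published_model, -1.0, 10.0, 1.0)
        with pytest.raises(DomainError):
            predict_G(published_model, 1.0, 10.0, 0.0)

    def test_json_round_trip(self, tmp_path, published_model):
        path = tmp_path / "model.json"
        published_model.to_json(path, provenance={"origin": "test"})
        loaded = PredictiveModel.from_json(path)
        np.testing.assert_allclose(
            loaded.coefficients(), published_model.coefficients()
        )
        assert loaded.se_a == published_model.se_a


class TestOptimalRatio:
    def test_published_vertex_at_27_5(self, published_model):
        vertex, g_at = optimal_molar_ratio(published_model)
        assert vertex == pytest.approx(27.5)

    def test_vertex_agrees_with_grid_search(self, published_model):
        grid = np.arange(0.1, 100.0 + 1e-9, 0.01)
        g = predict_G(
            published_model, np.zeros_like(grid), np.zeros_like(grid), grid
        )
        vertex, _ = optimal_molar_ratio(published_model)
        assert abs(grid[np.argmax(g)] - vertex) <= 0.01 + 1e-9

    def test_zero_linear_term_puts_vertex_at_zero(self):
        m = PredictiveModel(1.0, 0.1, -0.01, 0.0, -0.002)
        vertex, _ = optimal_molar_ratio(m)
        assert vertex == 0.0

    def test_convex_ratio_dependence_has_no_interior_maximum(self):
        m = PredictiveModel(1.0, 0.1, -0.01, 0.1, 0.001)
        with pytest.raises(DomainError):
            optimal_molar_ratio(m)
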