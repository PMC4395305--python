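"""Design construction, OLS, stepwise AIC selection, cohort deconstruction."""

import numpy as np
import pandas as pd
import pytest

from neteff.modeling import (
    build_design,
    cohort_equations,
    design_columns,
    fit_model,
    ols_fit,
    stepwise_select,
)
from neteff.synthetic import CohortSpec, generate_subject_cohort

CONT_CANDIDATES = ["e_local_task", "e_global_task", "mean_rt", "age_group"]


@pytest.fixture(scope="module")
def noisy_cohort() -> pd.DataFrame:
    return generate_subject_cohort(CohortSpec(25, 25, noise_sd=0.5, seed=7))


class TestBuildDesign:
    def test_candidate_column_count(self, noisy_cohort):
        """3 continuous + age: 4 mains + C(4,2)=6 products + 3 squares = 13."""
        X, kinds = build_design(noisy_cohort, CONT_CANDIDATES)
        assert X.shape[1] == 13
        assert sum(k == "main" for k in kinds.values()) == 4
        assert sum(k == "interaction" for k in kinds.values()) == 6
        assert sum(k == "quadratic" for k in kinds.values()) == 3

    def test_binary_square_dropped(self, noisy_cohort):
        X, _ = build_design(noisy_cohort, CONT_CANDIDATES)
        assert "age_group^2" not in X.columns
        assert "mean_rt^2" in X.columns

    def test_identical_covariates_give_identical_rows(self, noisy_cohort):
        doubled = pd.concat([noisy_cohort.iloc[[0]], noisy_cohort], ignore_index=True)
        X, _ = build_design(doubled, CONT_CANDIDATES)
        assert np.allclose(X.iloc[0], X.iloc[1])

    def test_constant_column_rejected_by_name(self, noisy_cohort):
        bad = noisy_cohort.copy()
        bad["mean_rt"] = 700.0
        with pytest.raises(ValueError, match="mean_rt"):
            build_design(bad, CONT_CANDIDATES)

    def test_grid_cohort_full_candidate_design_is_full_rank(self, noise_free_cohort):
        X, _ = build_design(noise_free_cohort)  # all five default candidates
        Xc = np.column_stack([np.ones(len(X)), X.to_numpy()])
        assert np.linalg.matrix_rank(Xc) == Xc.shape[1]


class TestOlsFit:
    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.standard_normal((8, 2)), columns=["a", "b"])
        y = rng.standard_normal(8)
        fit = ols_fit(y, X)
        Xc = np.column_stack([np.ones(8), X.to_numpy()])
        beta = np.linalg.solve(Xc.T @ Xc, Xc.T @ y)
        assert np.allclose(fit.coefficients.to_numpy(), beta, atol=1e-10)

    def test_exact_linear_outcome(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.standard_normal((20, 2)), columns=["a", "b"])
        y = 1.5 + 2.0 * X["a"] - 3.0 * X["b"]
        fit = ols_fit(y, X)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.rss < 1e-20
        assert fit.coefficients["a"] == pytest.approx(2.0)

    def test_orthogonal_column_gets_zero_coefficient(self):
        n = 100
        t = np.arange(n)
        a = np.sin(2 * np.pi * t / 20)
        b = np.cos(2 * np.pi * t / 20)
        X = pd.DataFrame({"a": a, "b": b})
        fit = ols_fit(5.0 * a, X)
        assert fit.coefficients["b"] == pytest.approx(0.0, abs=1e-10)

    def test_singular_design_names_collinear_terms(self):
        rng = np.random.default_rng(2)
        col = rng.standard_normal(15)
        X = pd.DataFrame({"a": col, "b": 2 * col})
        with pytest.raises(ValueError, match="collinear"):
            ols_fit(rng.standard_normal(15), X)

    def test_adjusted_r2_below_r2_and_statistics_finite(self, noisy_cohort):
        fit = fit_model(noisy_cohort, ["e_local_task", "e_global_task", "age_group"])
        assert fit.adj_r2 <= fit.r2
        assert np.isfinite(fit.aic)
        assert fit.cohens_f2 == pytest.approx(fit.r2 / (1 - fit.r2))
        assert (fit.conf_int["low"] <= fit.coefficients).all()
        assert (fit.coefficients <= fit.conf_int["high"]).all()

    def test_aicc_penalizes_more_than_aic(self, noisy_cohort):
        plain = fit_model(noisy_cohort, ["e_local_task", "age_group"], aicc=False)
        small = fit_model(noisy_cohort, ["e_local_task", "age_group"], aicc=True)
        k = 2 + 2
        expected = 2 * k * (k + 1) / (len(noisy_cohort) - k - 1)
        assert small.aic - plain.aic == pytest.approx(expected)


class TestStepwise:
    def test_single_relevant_candidate_retained(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"x": rng.uniform(0, 1, 60)})
        df["dprime"] = 5.0 * df["x"] + rng.normal(0, 1e-4, 60)
        fit = stepwise_select(df, candidates=["x"], interactions=False, quadratics=False)
        assert fit.terms == ["x"]
        assert fit.coefficients["x"] == pytest.approx(5.0, abs=1e-2)

    def test_never_worse_than_full_or_empty_model(self, noisy_cohort):
        fit = stepwise_select(noisy_cohort, CONT_CANDIDATES)
        X, _ = build_design(noisy_cohort, CONT_CANDIDATES)
        full = ols_fit(noisy_cohort["dprime"], X)
        y = noisy_cohort["dprime"].to_numpy()
        n = len(y)
        tss = float(np.sum((y - y.mean()) ** 2))
        empty_aic = n * np.log(tss / n) + 2 * 2
        assert fit.aic <= full.aic + 1e-9
        assert fit.aic <= empty_aic + 1e-9

    def test_irrelevant_noise_column_changes_aic_at_most_one_penalty(self, noisy_cohort):
        rng = np.random.default_rng(4)
        base = stepwise_select(noisy_cohort, CONT_CANDIDATES)
        augmented = noisy_cohort.copy()
        augmented["junk"] = rng.standard_normal(len(augmented))
        more = stepwise_select(augmented, CONT_CANDIDATES + ["junk"])
        assert more.aic <= base.aic + 2.0 + 1e-9

    def test_deterministic_given_input(self, noisy_cohort):
        a = stepwise_select(noisy_cohort, CONT_CANDIDATES)
        b = stepwise_select(noisy_cohort, CONT_CANDIDATES)
        assert a.terms == b.terms
        assert np.allclose(a.coefficients, b.coefficients)

    def test_hierarchy_flag_keeps_parents_of_survivors(self, noisy_cohort):
        fit = stepwise_select(noisy_cohort, CONT_CANDIDATES, hierarchy=True)
        terms = set(fit.terms)
        for t in terms:
            if ":" in t:
                assert set(t.split(":")) <= terms
            elif t.endswith("^2"):
                assert t[:-2] in terms


class TestCohortEquations:
    def test_algebraic_deconstruction(self):
        # y = 1 + 2x + 3G + 4xG exactly
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"x": rng.uniform(0, 1, 40), "age_group": np.repeat([0, 1], 20)})
        df["dprime"] = 1.0 + 2.0 * df.x + 3.0 * df.age_group + 4.0 * df.x * df.age_group
        fit = fit_model(df, ["x", "age_group", "x:age_group"])
        eqs = cohort_equations(fit)
        assert eqs[0]["intercept"] == pytest.approx(1.0)
        assert eqs[0]["x"] == pytest.approx(2.0)
        assert eqs[1]["intercept"] == pytest.approx(4.0)  # 1 + 3
        assert eqs[1]["x"] == pytest.approx(6.0)  # 2 + 4

    def test_no_interactions_shares_all_slopes(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame({"x": rng.uniform(0, 1, 30), "age_group": np.repeat([0, 1], 15)})
        df["dprime"] = 2.0 - 1.0 * df.x + 0.5 * df.age_group + rng.normal(0, 0.1, 30)
        eqs = cohort_equations(fit_model(df, ["x", "age_group"]))
        assert eqs[0]["x"] == eqs[1]["x"]

    def test_requires_group_term(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame({"x": rng.uniform(0, 1, 20)})
        df["dprime"] = df.x
        fit = fit_model(df, ["x"])
        with pytest.raises(ValueError):
            cohort_equations(fit)


class TestDesignColumns:
    def test_term_grammar(self, noisy_cohort):
        X = design_columns(noisy_cohort, ["mean_rt", "mean_rt^2", "e_local_task:age_group"])
        assert np.allclose(X["mean_rt^2"], noisy_cohort["mean_rt"] ** 2)
        assert np.allclose(
            X["e_local_task:age_group"],
            noisy_cohort["e_local_task"] * noisy_cohort["age_group"],
        )
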