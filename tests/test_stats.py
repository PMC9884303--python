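"""Statistical battery: formulas, oracles, model contracts."""

import numpy as np
import pandas as pd
import pytest

from epifat.cohort import generate_cohort, inject_missingness
from epifat.errors import CollinearityError, ParameterError, UndefinedStatisticError
from epifat.stats import (
    PairwiseFit,
    fit_staged_models,
    homa_ir,
    kendall_tau_b_exhaustive,
    kendall_trend,
    model_fits_to_frame,
    pairwise_regressions,
    qualify_confounders,
    summarize_groups,
)


class TestHomaIR:
    def test_constant_cancellation(self):
        assert homa_ir(22.5, 1.0) == 1.0

    def test_direct_evaluation(self):
        assert homa_ir(10.0, 5.0) == pytest.approx(10.0 * 5.0 / 22.5)
        assert homa_ir(10.0, 5.0) == pytest.approx(2.2222222222, abs=1e-9)

    def test_zero_insulin(self):
        assert homa_ir(0.0, 5.0) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ParameterError):
            homa_ir(-1.0, 5.0)

    def test_vectorised(self):
        out = homa_ir([22.5, 45.0], [1.0, 1.0])
        assert np.allclose(out, [1.0, 2.0])


class TestSummaries:
    def _tiny_table(self):
        return pd.DataFrame(
            {
                "glucose_group": ["NGT"] * 3 + ["T2D"] * 3,
                "eatv_ml": [90.0, 100.0, 120.0, 130.0, 150.0, 160.0],
            }
        )

    def test_hand_computed_medians_and_iqr(self):
        s = summarize_groups(self._tiny_table(), continuous=("eatv_ml",), categorical=())
        row = s.continuous.loc[("eatv_ml", "NGT")]
        assert row["median"] == 100.0
        assert row["iqr"] == pytest.approx(15.0)  # q75=110, q25=95
        t2d = s.continuous.loc[("eatv_ml", "T2D")]
        assert t2d["diff_vs_ref"] == 50.0
        assert np.isnan(row["diff_vs_ref"])

    def test_identical_groups_no_difference(self):
        tab = pd.DataFrame(
            {
                "glucose_group": ["NGT"] * 20 + ["IGT"] * 20,
                "eatv_ml": list(range(20)) * 2,
            }
        )
        s = summarize_groups(tab, continuous=("eatv_ml",), categorical=())
        row = s.continuous.loc[("eatv_ml", "IGT")]
        assert row["diff_vs_ref"] == 0.0
        assert row["p_vs_ref"] > 0.9

    def test_categorical_chi2_across_groups(self):
        rng = np.random.default_rng(0)
        tab = pd.DataFrame(
            {
                "glucose_group": ["NGT"] * 200 + ["T2D"] * 200,
                "smoking": np.r_[rng.random(200) < 0.1, rng.random(200) < 0.5].astype(int),
            }
        )
        s = summarize_groups(tab, continuous=(), categorical=("smoking",))
        assert s.categorical_p["smoking"] < 0.001
        assert s.categorical.loc[("smoking", 1, "T2D")]["rate"] == pytest.approx(0.5, abs=0.1)

    def test_missing_reference_rejected(self):
        tab = pd.DataFrame({"glucose_group": ["IGT"] * 3, "eatv_ml": [1.0, 2.0, 3.0]})
        with pytest.raises(ParameterError):
            summarize_groups(tab, continuous=("eatv_ml",), categorical=())


class TestKendall:
    def test_perfect_trend(self):
        # tie-free pairs: every concordance counts, so tau-b is exactly 1
        tab = pd.DataFrame(
            {"glucose_group_ord": [0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0],
             "v": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0]}
        )
        res = kendall_trend(tab, "v", n_boot=50, seed=0)
        assert res.tau == pytest.approx(1.0)

    def test_matches_exhaustive_oracle_with_ties(self):
        rng = np.random.default_rng(42)
        x = rng.integers(0, 4, size=60).astype(float)
        y = np.round(rng.normal(size=60), 1)  # induces ties in y too
        tab = pd.DataFrame({"glucose_group_ord": x, "v": y})
        res = kendall_trend(tab, "v", n_boot=50, seed=0)
        assert res.tau == pytest.approx(kendall_tau_b_exhaustive(x, y), abs=1e-12)

    def test_constant_variable_undefined(self):
        tab = pd.DataFrame({"glucose_group_ord": [0, 1, 2, 3], "v": [5.0] * 4})
        with pytest.raises(UndefinedStatisticError):
            kendall_trend(tab, "v")

    def test_single_level_undefined(self):
        tab = pd.DataFrame({"glucose_group_ord": [1, 1, 1], "v": [1.0, 2.0, 3.0]})
        with pytest.raises(UndefinedStatisticError):
            kendall_trend(tab, "v")

    def test_bootstrap_ci_deterministic_and_brackets_tau(self, cohort_table):
        r1 = kendall_trend(cohort_table, "eatv_ml", n_boot=200, seed=3)
        r2 = kendall_trend(cohort_table, "eatv_ml", n_boot=200, seed=3)
        assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)
        assert r1.ci_low < r1.tau < r1.ci_high


class TestQualifyConfounders:
    def test_known_partial_effects_recovered(self):
        """Age has a built-in effect on EATV beyond VAT; season has none."""
        rng = np.random.default_rng(7)
        n = 800
        vat = rng.lognormal(np.log(140), 0.4, n)
        age = rng.uniform(50, 64, n)
        eatv = 20 + 0.5 * vat + 1.5 * (age - 57) + rng.normal(0, 15, n)
        tab = pd.DataFrame(
            {
                "glucose_group": "NGT",
                "eatv_ml": eatv,
                "vat_cm2": vat,
                "age": age,
                "season": rng.choice(["Winter", "Spring", "Summer", "Fall"], size=n),
            }
        )
        got = qualify_confounders(tab, candidates=("age", "season"))
        assert got == ["age"]

    def test_no_candidates(self, cohort_table):
        assert qualify_confounders(cohort_table, candidates=()) == []

    def test_empty_reference_group_rejected(self):
        tab = pd.DataFrame({"glucose_group": ["T2D"], "eatv_ml": [1.0], "vat_cm2": [1.0]})
        with pytest.raises(ParameterError):
            qualify_confounders(tab, candidates=("age",))

    def test_calibrated_generator_recovers_published_set(self):
        table = generate_cohort(seed=29)
        got = qualify_confounders(table)
        assert {"age", "sex", "smoking", "physical_activity"} <= set(got)
        assert "season" not in got


class TestStagedModels:
    def test_noiseless_slope_exact(self):
        tab = pd.DataFrame({"x": np.arange(10.0)})
        tab["y"] = 2.0 + 3.0 * tab["x"]
        fits = fit_staged_models(tab, outcome="y", exposure="x", confounders=[], models=(1,))
        assert fits[0].params.loc["x", "coef"] == pytest.approx(3.0, abs=1e-12)
        assert fits[0].params.loc["Intercept", "coef"] == pytest.approx(2.0, abs=1e-10)

    def test_matches_normal_equations(self):
        """5-row fixture: coefficients equal the closed-form OLS solution."""
        rng = np.random.default_rng(1)
        x1, x2 = rng.normal(size=5), rng.normal(size=5)
        y = 1.0 + 2.0 * x1 - 0.5 * x2 + rng.normal(size=5)
        tab = pd.DataFrame({"y": y, "x1": x1, "bmi": x2})
        fits = fit_staged_models(tab, outcome="y", exposure="x1", confounders=[], models=(2,))
        X = np.column_stack([np.ones(5), x1, x2])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        got = fits[0].params["coef"].to_numpy()
        assert np.allclose(got, beta, rtol=1e-11, atol=1e-11)

    def test_collinearity_names_columns(self):
        tab = pd.DataFrame({"y": np.arange(6.0), "x": np.arange(6.0)})
        tab["bmi"] = 2.0 * tab["x"]  # exact collinearity
        with pytest.raises(CollinearityError) as err:
            fit_staged_models(tab, outcome="y", exposure="x", confounders=[], models=(2,))
        assert any("bmi" in c or "x" in c for c in err.value.columns)

    def test_model6_requires_attenuation_outcome(self, cohort_table):
        with pytest.raises(ParameterError):
            fit_staged_models(cohort_table, outcome="eatv_ml", confounders=[], models=(6,))

    def test_nesting_never_increases_rss(self, cohort_table):
        """Adding a covariate cannot worsen the least-squares fit."""
        fits = fit_staged_models(
            cohort_table, outcome="eatv_ml", exposure="groups",
            confounders=["age", "sex"], models=(1, 5),
        )
        r2 = {f.model_id: f.r_squared for f in fits}
        assert r2[5] >= r2[1]

    def test_complete_case_accounting(self, cohort_table):
        masked = inject_missingness(cohort_table, counts={"homa_ir": 28, "vat_cm2": 4}, seed=8)
        fits = fit_staged_models(
            masked, outcome="eatv_ml", exposure="homa_ir", confounders=[], models=(1, 4)
        )
        assert fits[0].n == len(masked.dropna(subset=["eatv_ml", "homa_ir"]))
        assert fits[1].n == len(masked.dropna(subset=["eatv_ml", "homa_ir", "vat_cm2"]))

    def test_group_exposure_reference_coding(self, cohort_table):
        fits = fit_staged_models(cohort_table, outcome="eatv_ml", confounders=[], models=(1,))
        terms = fits[0].exposure_terms
        assert len(terms) == 4  # four non-NGT indicators
        assert all("NGT" not in t.split("[")[-1] for t in terms)

    def test_type_i_error_control(self):
        """Null data: the Model-1 group F-test rejects at ~5 %."""
        rng = np.random.default_rng(123)
        rejections = 0
        n_rep, n = 500, 160
        for _ in range(n_rep):
            tab = pd.DataFrame(
                {
                    "glucose_group": rng.choice(["NGT", "IGT", "IFG", "CGI", "T2D"], size=n),
                    "eatv_ml": rng.normal(100, 20, size=n),
                }
            )
            fit = fit_staged_models(tab, outcome="eatv_ml", confounders=[], models=(1,))[0]
            rejections += fit.f_p < 0.05
        rate = rejections / n_rep
        assert 0.03 <= rate <= 0.07


class TestPairwise:
    def test_zero_noise_linear_fixture(self):
        x = np.linspace(50, 250, 40)
        tab = pd.DataFrame(
            {"eatv_ml": x, "eata_hu": -60 - 0.082 * x, "vat_hu": -70 - 0.129 * x}
        )
        fits = pairwise_regressions(tab)
        assert fits["eata_on_eatv"].slope == pytest.approx(-0.082, abs=1e-12)
        assert fits["eata_on_eatv"].r == pytest.approx(-1.0)
        assert abs(fits["eata_on_vat_hu"].r) == pytest.approx(1.0)

    def test_sign_pattern_on_calibrated_cohort(self, cohort_table):
        fits = pairwise_regressions(cohort_table)
        assert fits["eata_on_eatv"].slope < 0
        assert fits["vat_hu_on_eatv"].slope < 0
        assert fits["eata_on_vat_hu"].slope > 0
        assert isinstance(fits["eata_on_eatv"], PairwiseFit)

    def test_ci_contains_point_estimate(self, cohort_table):
        for f in pairwise_regressions(cohort_table).values():
            assert f.ci_low <= f.slope <= f.ci_high


def test_model_frame_export(cohort_table):
    fits = fit_staged_models(cohort_table, outcome="eatv_ml", confounders=["age"], models=(1, 4))
    frame = model_fits_to_frame(fits)
    assert {"outcome", "model", "term", "coef", "ci_low", "ci_high", "p"} <= set(frame.columns)
    assert frame["is_exposure_term"].sum() == 8  # 4 indicators x 2 models
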