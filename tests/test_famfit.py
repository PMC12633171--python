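"""Association and direct-effect estimation, ratio inference, multiple
testing, and meta-analysis."""

import numpy as np
import pandas as pd
import pytest

from pgifam import scoring, sim
from pgifam.data import AssocResult, WeightSet
from pgifam.famfit import (
    bh_fdr,
    diff_test,
    fit_causal_effect,
    fit_population_association,
    ivw_meta,
    ratio_with_delta_se,
    residualize_phenotype,
)


def _assoc(est, se, scale="raw", n=100, model="linear"):
    return AssocResult(estimate=est, se=se, n=n, model=model, scale=scale)


class TestResidualize:
    def test_orthogonal_phenotype_unchanged(self):
        rng = np.random.default_rng(300)
        sex = np.repeat([0, 1], 100)
        y = rng.normal(size=200)
        y = y - np.polyval(np.polyfit(sex, y, 1), sex)  # orthogonalize
        phen = pd.DataFrame(
            {"individual_id": [f"i{k}" for k in range(200)], "y": y, "sex": sex}
        )
        out = residualize_phenotype(phen, ["sex"])
        merged = phen.merge(out, on="individual_id", suffixes=("", "_r"))
        np.testing.assert_allclose(merged["y"], merged["y_r"], atol=1e-10)

    def test_constant_phenotype_gives_zero_residuals(self):
        phen = pd.DataFrame(
            {"individual_id": ["a", "b", "c"], "y": 5.0, "sex": [0, 1, 0]}
        )
        out = residualize_phenotype(phen, ["sex"])
        np.testing.assert_allclose(out["y"], 0.0, atol=1e-10)

    def test_two_wave_mean_matches_hand_computation(self):
        phen = pd.DataFrame(
            {
                "individual_id": ["a", "b", "a", "b"],
                "y": [1.0, 3.0, 2.0, 6.0],
                "sex": [0.0, 1.0, 0.0, 1.0],
                "wave": [1, 1, 2, 2],
            }
        )
        out = residualize_phenotype(phen, ["sex"], wave_col="wave").set_index(
            "individual_id"
        )
        # per wave the sex regression fits exactly (2 points) -> residuals 0
        assert out.loc["a", "y"] == pytest.approx(0.0, abs=1e-10)
        assert out.loc["b", "y"] == pytest.approx(0.0, abs=1e-10)

    def test_missing_covariate_rejected(self):
        phen = pd.DataFrame(
            {"individual_id": ["a"], "y": [1.0], "sex": [np.nan]}
        )
        with pytest.raises(ValueError, match="missing"):
            residualize_phenotype(phen, ["sex"])


class TestPopulationAssociation:
    def test_recovers_generator_slope_without_confounding(self, small_panel):
        cohort, phen = sim.make_population(small_panel, 8_000, 0.5, seed=310)
        kids = cohort.subset(cohort.rows("proband"))
        pgi = scoring.compute_pgi(kids, WeightSet.from_panel(small_panel, "gamma"))
        res = fit_population_association(phen, pgi)
        # slope of y on the standardized causal factor = sd(x gamma) * 1
        truth = np.sqrt(
            np.sum(small_panel.genotype_variance() * small_panel.gamma**2)
        )
        assert abs(res.estimate - truth) < 3 * res.se

    def test_related_sample_refused(self, sib_data, true_mu_weights):
        cohort, phen = sib_data
        pgi = scoring.compute_pgi(cohort, true_mu_weights)
        with pytest.raises(ValueError, match="relatives"):
            fit_population_association(phen, pgi)
        assert fit_population_association(phen, pgi, allow_related=True).se > 0

    def test_logistic_reports_log_odds_and_or(self, small_panel):
        cohort, phen = sim.make_population(
            small_panel, 4_000, 0.4, seed=311, binary=True, prevalence=0.3
        )
        kids = cohort.subset(cohort.rows("proband"))
        pgi = scoring.compute_pgi(kids, WeightSet.from_panel(small_panel, "gamma"))
        res = fit_population_association(phen, pgi, binary=True)
        assert res.scale == "log_odds"
        assert res.odds_ratio == pytest.approx(np.exp(res.estimate))


class TestCausalEffect:
    def test_delta_below_psi_under_parental_effects(
        self, trio_data, true_mu_weights, confounded_panel
    ):
        cohort, phen = trio_data
        pgi = scoring.compute_pgi(cohort, true_mu_weights)
        psi = fit_population_association(phen, pgi)
        delta = fit_causal_effect(phen, pgi)
        assert delta.estimate < psi.estimate
        assert set(delta.parental_coefs) == {"alpha_p", "alpha_m"}

    def test_delta_equals_psi_without_confounding(self, small_panel):
        cohort, phen = sim.make_trio_cohort(small_panel, 1_500, 0.4, seed=312)
        pgi = scoring.compute_pgi(cohort, WeightSet.from_panel(small_panel, "gamma"))
        psi = fit_population_association(phen, pgi)
        delta = fit_causal_effect(phen, pgi)
        z = (psi.estimate - delta.estimate) / np.sqrt(psi.se**2 + delta.se**2)
        assert abs(z) < 3

    def test_combined_parental_column_used_when_separate_absent(
        self, sib_data, true_mu_weights
    ):
        from pgifam.imputation import impute_parental_pgi

        cohort, phen = sib_data
        pgi = impute_parental_pgi(cohort.children_only(), true_mu_weights)
        res = fit_causal_effect(phen, pgi)
        assert list(res.parental_coefs) == ["alpha"]
        assert res.model == "linear_mixed"

    def test_no_parental_columns_rejected(self, trio_data, true_mu_weights):
        cohort, phen = trio_data
        pgi = scoring.compute_pgi(cohort, true_mu_weights)
        bare = pgi[["individual_id", "family_id", "pgi_proband"]]
        with pytest.raises(ValueError, match="parental"):
            fit_causal_effect(phen, bare)

    def test_mixed_model_matches_ols_when_family_variance_vanishes(
        self, small_panel
    ):
        """With no shared family component the random-intercept fit and OLS
        coincide."""
        import statsmodels.api as sm

        rng = np.random.default_rng(313)
        cohort, phen = sim.make_trio_cohort(
            small_panel, 400, 0.4, seed=314, n_children=2
        )
        # replace y by iid noise + direct effect only: no family variance
        pgi = scoring.compute_pgi(cohort, WeightSet.from_panel(small_panel, "gamma"))
        df = phen.merge(pgi.drop(columns="family_id"), on="individual_id")
        z = (df["pgi_proband"] - df["pgi_proband"].mean()) / df["pgi_proband"].std()
        df["y"] = 0.5 * z + rng.normal(size=len(df))
        res = fit_causal_effect(df[["individual_id", "family_id", "y"]], pgi)
        X = sm.add_constant(
            pd.DataFrame(
                {
                    "pgi": (df["pgi_proband"] - df["pgi_proband"].mean())
                    / df["pgi_proband"].std(ddof=0),
                    "fa": (df["pgi_father"] - df["pgi_father"].mean())
                    / df["pgi_father"].std(ddof=0),
                    "mo": (df["pgi_mother"] - df["pgi_mother"].mean())
                    / df["pgi_mother"].std(ddof=0),
                }
            )
        )
        ols = sm.OLS(df["y"].to_numpy(), X).fit()
        assert res.estimate == pytest.approx(float(ols.params["pgi"]), abs=5e-3)


class TestRatioAndTests:
    def test_ratio_reduces_when_psi_exact(self):
        out = ratio_with_delta_se(_assoc(0.8, 0.08), _assoc(0.8, 1e-9))
        assert out.ratio == pytest.approx(1.0)
        assert out.se == pytest.approx(0.08 / 0.8, rel=1e-6)

    def test_ratio_hand_arithmetic(self):
        out = ratio_with_delta_se(_assoc(0.5, 0.1), _assoc(1.0, 0.1))
        assert out.ratio == pytest.approx(0.5)
        assert out.se == pytest.approx(np.sqrt(0.01 + 0.25 * 0.01), abs=1e-6)
        assert out.se == pytest.approx(0.1118, abs=5e-4)

    def test_weak_psi_warns(self):
        with pytest.warns(UserWarning, match="weakly identified"):
            ratio_with_delta_se(_assoc(0.1, 0.1), _assoc(0.2, 0.1))

    def test_zero_psi_rejected(self):
        with pytest.raises(ZeroDivisionError):
            ratio_with_delta_se(_assoc(0.5, 0.1), _assoc(0.0, 0.1))

    def test_diff_test_trivials(self):
        z, p = diff_test(_assoc(0.5, 0.1), _assoc(0.5, 0.1))
        assert z == 0 and p == pytest.approx(1.0)
        se = np.sqrt(0.1**2 + 0.1**2)
        z, p = diff_test(_assoc(0.5, 0.1), _assoc(0.5 + 1.96 * se, 0.1))
        assert p == pytest.approx(0.05, abs=1e-3)

    def test_delta_se_matches_monte_carlo(self):
        """Analytic ratio SE vs the sampling SD of simulated ratios."""
        rng = np.random.default_rng(320)
        delta, psi, sd, sp = 0.4, 0.8, 0.05, 0.04
        draws = rng.normal(delta, sd, 50_000) / rng.normal(psi, sp, 50_000)
        analytic = ratio_with_delta_se(_assoc(delta, sd), _assoc(psi, sp)).se
        assert analytic == pytest.approx(draws.std(), rel=0.05)


class TestMultipleTestingAndMeta:
    def test_bh_all_ones_no_rejections(self):
        assert not bh_fdr([1.0, 1.0, 1.0]).any()

    def test_bh_step_up_example(self):
        flags = bh_fdr([0.01, 0.02, 0.03, 0.5], q=0.05)
        assert list(flags) == [True, True, True, False]

    def test_bh_single_p(self):
        assert bh_fdr([0.04], q=0.05)[0]

    def test_bh_empty_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([])

    def test_ivw_single_passthrough(self):
        one = _assoc(1.3, 0.2)
        out = ivw_meta([one])
        assert out.estimate == pytest.approx(1.3)
        assert out.se == pytest.approx(0.2)

    def test_ivw_equal_se_symmetry(self):
        out = ivw_meta([_assoc(1.0, 1.0), _assoc(3.0, 1.0)])
        assert out.estimate == pytest.approx(2.0)
        assert out.se == pytest.approx(1 / np.sqrt(2))

    def test_ivw_hand_computed_weights(self):
        ests = [_assoc(1.0, 0.5), _assoc(2.0, 1.0), _assoc(0.5, 0.25)]
        w = np.array([4.0, 1.0, 16.0])
        expect = np.sum(w * np.array([1.0, 2.0, 0.5])) / w.sum()
        out = ivw_meta(ests)
        assert out.estimate == pytest.approx(expect)
        assert out.se == pytest.approx(1 / np.sqrt(w.sum()))

    def test_ivw_mixed_scales_rejected(self):
        with pytest.raises(ValueError, match="scales"):
            ivw_meta([_assoc(1.0, 0.5), _assoc(1.0, 0.5, scale="log_odds")])


def test_null_diff_test_type_one_error(small_panel):
    """Under theta=0 the psi-delta test rejects at close to nominal rate."""
    rejections = []
    for rep in range(120):
        cohort, phen = sim.make_trio_cohort(small_panel, 200, 0.4, seed=400 + rep)
        pgi = scoring.compute_pgi(cohort, WeightSet.from_panel(small_panel, "gamma"))
        half = len(phen) // 2
        psi = fit_population_association(phen.iloc[:half], pgi)
        delta = fit_causal_effect(phen.iloc[half:], pgi)
        _, p = diff_test(delta, psi)
        rejections.append(p < 0.05)
    rate = np.mean(rejections)
    assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 120)
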