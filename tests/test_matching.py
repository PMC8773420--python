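"""Propensity model, greedy matching, standardized differences, balance."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, strategies as st

from thrombomark import (
    ClinicalCohort,
    ValidationError,
    balance_report,
    fit_propensity,
    match_nearest_neighbor,
    standardized_difference,
    standardized_difference_continuous,
)
from thrombomark.matching import MatchResult, PropensityModel, SeparationError
from thrombomark.synthetic import CohortSpec, simulate_cohort


def cohort_from_arrays(x: np.ndarray, y: np.ndarray, extra=None) -> ClinicalCohort:
    n = len(x)
    table = pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(n)],
            "age": 60,
            "vte": y.astype(bool),
            "lauren": "diffuse",
            "thromboprophylaxis": False,
            "x": x,
        }
    )
    if extra is not None:
        for name, vals in extra.items():
            table[name] = vals
    return ClinicalCohort(table)


def model_from_propensities(ps: np.ndarray, vte: np.ndarray) -> PropensityModel:
    ids = [f"P{i}" for i in range(len(ps))]
    return PropensityModel(
        covariates=("x",),
        coefficients=pd.Series([0.0], index=["x"]),
        intercept=0.0,
        propensity=pd.Series(ps, index=ids),
        vte=pd.Series(vte.astype(bool).tolist(), index=ids),
    )


class TestFitPropensity:
    def test_saturated_binary_model_gives_group_case_fractions(self):
        """One binary covariate: fitted propensity = case fraction within x group."""
        x = np.array([1] * 20 + [0] * 20)
        y = np.array([1] * 15 + [0] * 5 + [1] * 5 + [0] * 15)
        model = fit_propensity(cohort_from_arrays(x, y), ["x"])
        assert np.allclose(model.propensity[x == 1], 0.75, atol=1e-6)
        assert np.allclose(model.propensity[x == 0], 0.25, atol=1e-6)

    def test_constant_covariate_rejected(self):
        y = np.array([1] * 10 + [0] * 30)
        cohort = cohort_from_arrays(np.zeros(40), y)
        with pytest.raises(ValidationError, match="zero variance"):
            fit_propensity(cohort, ["x"])

    def test_single_binary_covariate_closed_form(self):
        """2x2 counts (20,10 / 10,20) -> coefficient log 4 (closed-form MLE)."""
        x = np.array([1] * 20 + [0] * 10 + [1] * 10 + [0] * 20)
        y = np.array([1] * 30 + [0] * 30)
        model = fit_propensity(cohort_from_arrays(x, y), ["x"])
        assert model.coefficients["x"] == pytest.approx(np.log(4), abs=1e-5)

    def test_recovers_generating_log_odds(self):
        """Coefficient on a confounded covariate within 2 SE of the truth."""
        gamma = 0.6
        spec = CohortSpec(
            n_patients=5000,
            vte_rate=0.3,
            confounding_strength={"cisplatin": gamma},
            seed=13,
        )
        cohort = simulate_cohort(spec).exclude_thromboprophylaxis()
        covs = list(cohort.covariates)
        model = fit_propensity(cohort, covs)
        # independent SE from a direct statsmodels refit
        X = sm.add_constant(cohort.table[covs].astype(float))
        ref = sm.Logit(cohort.table["vte"].astype(int), X).fit(disp=0)
        assert abs(model.coefficients["cisplatin"] - gamma) < 2 * ref.bse["cisplatin"]

    def test_perfect_separation_names_covariate(self):
        x = np.array([1] * 5 + [0] * 5)
        y = np.array([1] * 5 + [0] * 5)
        with pytest.raises(SeparationError, match="x"):
            fit_propensity(cohort_from_arrays(x, y), ["x"])

    def test_missing_covariate_rejected(self):
        cohort = cohort_from_arrays(np.zeros(10), np.array([1] * 5 + [0] * 5))
        with pytest.raises(ValidationError):
            fit_propensity(cohort, ["nope"])

    def test_prophylaxis_users_must_be_excluded_first(self):
        cohort = cohort_from_arrays(np.zeros(10), np.array([1] * 5 + [0] * 5))
        cohort.table.loc[0, "thromboprophylaxis"] = True
        with pytest.raises(ValidationError, match="thromboprophylaxis"):
            fit_propensity(cohort, ["x"])


class TestMatchNearestNeighbor:
    def test_identical_propensities_all_matched_distance_zero(self):
        vte = np.array([1] * 5 + [0] * 8)
        model = model_from_propensities(np.full(13, 0.4), vte)
        result = match_nearest_neighbor(model)
        assert len(result.pairs) == 5
        assert result.unmatched_cases == []

    def test_case_beyond_caliper_unmatched(self):
        ps = np.array([0.95, 0.30, 0.31, 0.32, 0.33])
        vte = np.array([1, 0, 0, 0, 0])
        result = match_nearest_neighbor(model_from_propensities(ps, vte))
        assert result.pairs == []
        assert result.unmatched_cases == ["P0"]

    def test_matches_brute_force_greedy_oracle(self):
        """5 cases / 8 controls: pairs equal an independently coded greedy pass."""
        case_ps = np.array([0.62, 0.55, 0.81, 0.47, 0.59])
        ctrl_ps = np.array([0.50, 0.63, 0.58, 0.44, 0.77, 0.61, 0.49, 0.56])
        ps = np.concatenate([case_ps, ctrl_ps])
        vte = np.array([1] * 5 + [0] * 8)
        result = match_nearest_neighbor(model_from_propensities(ps, vte))

        logit = np.log(ps / (1 - ps))
        sd = np.std(logit, ddof=1)
        expected = []
        used = set()
        for ci in sorted(range(5), key=lambda i: -logit[i]):
            best, best_d = None, np.inf
            for j in range(8):
                if j in used:
                    continue
                d = abs(logit[5 + j] - logit[ci])
                if d < best_d:
                    best, best_d = j, d
            if best is not None and best_d <= 0.2 * sd:
                used.add(best)
                expected.append((f"P{ci}", f"P{5 + best}"))
        assert sorted(result.pairs) == sorted(expected)

    @given(
        st.lists(st.floats(min_value=0.05, max_value=0.95), min_size=6, max_size=40),
        st.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_no_control_reused_and_caliper_respected(self, ps_list, seed):
        ps = np.array(ps_list)
        rng = np.random.default_rng(seed)
        vte = rng.random(len(ps)) < 0.4
        if vte.sum() == 0 or vte.sum() == len(ps):
            return
        result = match_nearest_neighbor(model_from_propensities(ps, vte))
        controls = result.matched_control_ids
        assert len(controls) == len(set(controls))
        assert len(result.pairs) + len(result.unmatched_cases) == int(vte.sum())
        logit = dict(zip([f"P{i}" for i in range(len(ps))], np.log(ps / (1 - ps))))
        width = 0.2 * np.std(np.log(ps / (1 - ps)), ddof=1)
        if width > 0:
            for case, ctrl in result.pairs:
                assert abs(logit[case] - logit[ctrl]) <= width + 1e-12


class TestStandardizedDifference:
    @pytest.mark.parametrize(
        "p_case,p_ctrl,expected,digits",
        [
            (0.229, 0.204, -6.07, 2),  # trastuzumab, after matching
            (0.750, 0.694, -12.5, 1),  # male sex, after matching
            (0.417, 0.347, -14.4, 1),  # >2 metastatic sites, after matching
            (0.692, 0.711, 4.15, 2),  # male sex, before matching
        ],
    )
    def test_reproduces_published_cells(self, p_case, p_ctrl, expected, digits):
        assert round(standardized_difference(p_case, p_ctrl), digits) == expected

    @given(st.floats(min_value=0.01, max_value=0.99))
    def test_equal_groups_give_zero(self, p):
        assert standardized_difference(p, p) == 0.0

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            standardized_difference(0.0, 0.0)
        with pytest.raises(ValidationError):
            standardized_difference(1.0, 1.0)

    def test_continuous_form(self):
        # means 10 vs 12, SDs 2 and 2 -> 100*2/2 = 100
        assert standardized_difference_continuous(10, 12, 2, 2) == pytest.approx(100.0)


class TestBalanceReport:
    def test_matching_reduces_imbalance_on_confounded_cohorts(self):
        wins = 0
        for seed in range(10):
            cohort = simulate_cohort(
                CohortSpec(n_patients=1500, seed=seed)
            ).exclude_thromboprophylaxis()
            model = fit_propensity(cohort, list(cohort.covariates) + ["age"])
            match = match_nearest_neighbor(model)
            bal = balance_report(cohort, match)
            wins += bal["d_star_after"].abs().mean() < bal["d_star_before"].abs().mean()
        assert wins >= 9

    def test_unconfounded_cohort_balanced_before_and_after(self):
        cohort = simulate_cohort(
            CohortSpec(n_patients=4000, confounding_strength={}, seed=21)
        ).exclude_thromboprophylaxis()
        model = fit_propensity(cohort, list(cohort.covariates) + ["age"])
        match = match_nearest_neighbor(model)
        bal = balance_report(cohort, match)
        assert bal["d_star_before"].abs().mean() < 10

    def test_report_contains_all_covariates_and_age(self):
        cohort = simulate_cohort(CohortSpec(n_patients=300, seed=5)).exclude_thromboprophylaxis()
        model = fit_propensity(cohort, list(cohort.covariates))
        match = match_nearest_neighbor(model)
        bal = balance_report(cohort, match)
        assert set(bal["covariate"]) == set(cohort.covariates) | {"age"}
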