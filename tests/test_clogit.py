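"""Conditional logistic regression: recursion vs enumeration, Newton fit vs oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from thrombomark import ValidationError, clogit_fit, conditional_loglik, per_gene_clogit
from thrombomark.synthetic import CohortSpec, ExpressionSpec, simulate_cohort, simulate_expression
from tests.conftest import tiny_matrix


def enum_loglik(beta, x, case, strata):
    """Brute-force conditional log likelihood with derivatives by subset
    enumeration (independent of the package recursion)."""
    x = np.asarray(x, float)
    case = np.asarray(case, bool)
    strata = np.asarray(strata)
    ll = grad = hess = 0.0
    for s in np.unique(strata):
        idx = np.where(strata == s)[0]
        k = int(case[idx].sum())
        if k == 0 or k == len(idx):
            continue
        sums = np.array([x[list(c)].sum() for c in itertools.combinations(idx, k)])
        w = np.exp(beta * sums)
        B = w.sum()
        mean = (w * sums).sum() / B
        var = (w * sums**2).sum() / B - mean**2
        ll += beta * x[idx][case[idx]].sum() - math.log(B)
        grad += x[idx][case[idx]].sum() - mean
        hess += -var
    return ll, grad, hess


def random_instance(rng, n_strata=3, max_m=8):
    x, case, strata = [], [], []
    for s in range(n_strata):
        m = rng.integers(2, max_m + 1)
        k = rng.integers(1, m)
        x.extend(rng.normal(0, 1, m))
        case.extend([True] * k + [False] * (m - k))
        strata.extend([s] * m)
    return np.array(x), np.array(case), np.array(strata)


class TestConditionalLoglik:
    def test_beta_zero_closed_form(self):
        """At beta=0 the log likelihood is -sum_s log C(m_s, k_s)."""
        x = np.arange(9, dtype=float)
        case = np.array([1, 0, 0, 1, 1, 0, 0, 1, 0], bool)
        strata = np.array([0] * 3 + [1] * 4 + [2] * 2)
        ll, _, _ = conditional_loglik(0.0, x, case, strata)
        expected = -(math.log(comb(3, 1)) + math.log(comb(4, 2)) + math.log(comb(2, 1)))
        assert ll == pytest.approx(expected, rel=1e-12)

    def test_matches_enumeration_on_random_instances(self):
        rng = np.random.default_rng(40)
        for _ in range(60):
            x, case, strata = random_instance(rng)
            beta = rng.uniform(-2, 2)
            got = conditional_loglik(beta, x, case, strata)
            want = enum_loglik(beta, x, case, strata)
            assert got == pytest.approx(want, rel=1e-9)

    def test_concave_in_beta(self):
        rng = np.random.default_rng(41)
        x, case, strata = random_instance(rng)
        for beta in np.linspace(-4, 4, 33):
            _, _, hess = conditional_loglik(beta, x, case, strata)
            assert hess < 0

    def test_invariant_to_within_stratum_shift(self):
        rng = np.random.default_rng(42)
        x, case, strata = random_instance(rng)
        shifted = x + np.array([10.0, -3.0, 100.0])[strata]
        a = conditional_loglik(0.7, x, case, strata)
        b = conditional_loglik(0.7, shifted, case, strata)
        assert a == pytest.approx(b, rel=1e-9)

    def test_uninformative_strata_rejected(self):
        with pytest.raises(ValidationError):
            clogit_fit([1.0, 2.0], [True, True], [0, 0])


class TestClogitFit:
    def test_matched_pairs_reduce_to_pair_difference_likelihood(self):
        """With 1:1 strata the fit maximizes sum -log(1 + exp(-beta * d_i))."""
        rng = np.random.default_rng(43)
        n = 40
        d = rng.normal(0.4, 1.0, n)
        x = np.column_stack([d, np.zeros(n)]).ravel()
        case = np.tile([True, False], n)
        strata = np.repeat(np.arange(n), 2)
        fit = clogit_fit(x, case, strata)
        assert fit.converged

        grid = np.arange(-3, 3, 1e-4)
        ll = np.array([-np.logaddexp(0, -b * d).sum() for b in grid])
        assert fit.beta == pytest.approx(grid[ll.argmax()], abs=1e-3)
        assert fit.loglik == pytest.approx(ll.max(), abs=1e-6)

    def test_grid_search_oracle_two_strata(self):
        x = np.array([1.2, 0.3, -0.5, 0.8, 2.0, -1.0, 0.1, 0.6])
        case = np.array([1, 1, 0, 0, 1, 0, 0, 0], bool)
        strata = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        fit = clogit_fit(x, case, strata)
        grid = np.arange(-5, 5, 1e-4)
        ll = np.array([enum_loglik(b, x, case, strata)[0] for b in grid])
        assert fit.converged
        assert fit.beta == pytest.approx(grid[ll.argmax()], abs=1e-3)

    def test_constant_exposure_gives_or_one(self):
        fit = clogit_fit(np.ones(8), [1, 0, 1, 0, 1, 0, 1, 0], [0] * 4 + [1] * 4)
        assert fit.odds_ratio == pytest.approx(1.0)
        assert fit.p_value == 1.0
        assert np.isnan(fit.se)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(44)
        x, case, strata = random_instance(rng, n_strata=5)
        a = clogit_fit(x, case, strata)
        b = clogit_fit(10.0 * x, case, strata)
        assert b.beta == pytest.approx(a.beta / 10.0, rel=1e-6)
        assert b.se == pytest.approx(a.se / 10.0, rel=1e-6)
        assert b.p_value == pytest.approx(a.p_value, rel=1e-6)

    def test_agrees_with_statsmodels(self):
        from statsmodels.discrete.conditional_models import ConditionalLogit

        rng = np.random.default_rng(45)
        strata = np.repeat(np.arange(20), 5)
        x = rng.normal(0, 1, 100)
        p = 1 / (1 + np.exp(-(0.8 * x)))
        case = rng.random(100) < p
        # ensure informative strata
        for s in range(20):
            idx = strata == s
            if case[idx].all() or not case[idx].any():
                case[np.where(idx)[0][0]] = not case[np.where(idx)[0][0]]
        fit = clogit_fit(x, case, strata)
        ref = ConditionalLogit(case.astype(int), x[:, None], groups=strata).fit(disp=0)
        assert fit.beta == pytest.approx(ref.params[0], abs=1e-5)
        assert fit.se == pytest.approx(ref.bse[0], rel=1e-4)

    def test_separation_reported_not_estimated(self):
        """Cases hold the largest exposures in every stratum -> monotone
        likelihood, reported as non-estimable."""
        x = np.array([5.0, 0.0, -1.0, 6.0, 1.0, 0.5] * 3)
        case = np.array([1, 0, 0, 1, 0, 0] * 3, bool)
        strata = np.repeat(np.arange(6), 3)
        fit = clogit_fit(x, case, strata)
        assert not fit.converged
        assert np.isnan(fit.odds_ratio)
        assert np.isnan(fit.p_value)


@pytest.fixture(scope="module")
def planted():
    cohort = simulate_cohort(CohortSpec(n_patients=600, vte_rate=0.5, seed=50))
    spec = ExpressionSpec(
        n_genes=30,
        baseline_sd=0.5,
        planted_genes=[("UP_GENE", 2.0, "both"), ("DN_GENE", -2.0, "both")],
        seed=51,
    )
    return cohort, simulate_expression(cohort, spec)


class TestPerGeneClogit:
    def test_directional_recovery(self, planted):
        cohort, mat = planted
        res = per_gene_clogit(mat, ["UP_GENE", "DN_GENE", "G00005"], cohort).set_index(
            "gene_symbol"
        )
        assert res.loc["UP_GENE", "odds_ratio"] > 1
        assert res.loc["UP_GENE", "p_value"] < 1e-6
        assert res.loc["DN_GENE", "odds_ratio"] < 1
        assert res.loc["DN_GENE", "p_value"] < 1e-6
        assert res.loc["G00005", "p_value"] > 1e-6
        assert res["converged"].all()
        # CI orientation
        assert (res["ci_low"] < res["odds_ratio"]).all()
        assert (res["odds_ratio"] < res["ci_high"]).all()

    def test_pair_strata_series_mode(self, planted):
        cohort, mat = planted
        ids = list(cohort.table["patient_id"])[:100]
        pair_ids = pd.Series(np.repeat(np.arange(50), 2), index=ids)
        sub = cohort.subset(ids)
        res = per_gene_clogit(mat.subset_samples(ids), ["UP_GENE"], sub, strata=pair_ids)
        assert len(res) == 1
        assert res["odds_ratio"].iloc[0] > 1

    def test_missing_gene_rejected(self, planted):
        cohort, mat = planted
        with pytest.raises(ValidationError, match="NOPE"):
            per_gene_clogit(mat, ["NOPE"], cohort)

    def test_empty_gene_list(self, planted):
        cohort, mat = planted
        res = per_gene_clogit(mat, [], cohort)
        assert len(res) == 0
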