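"""Grouped Poisson linear-RR likelihood, MLE and profile intervals."""

import numpy as np
import pytest

from regcal import (
    FitParams,
    GroupedDataset,
    fit_mle,
    log_likelihood,
    lss_cohort,
    profile_ci,
)
from regcal.likelihood import INVALID_LOGLIK, PoissonLQObjective, _profile_max


def _expected_data(lam=0.06, alpha=0.25, beta=2.0, scale=1.0):
    """Grouped data whose case vector equals the model expectation exactly."""
    c = lss_cohort()
    d = c.central_dose_array()
    n = c.person_count_array() * scale
    y = n * lam * (1 + alpha * d + beta * d * d)
    return GroupedDataset(group_dose=d, cases=y, offset=n)


class TestLogLikelihood:
    def test_direct_value_single_group(self):
        data = GroupedDataset(group_dose=[1.0], cases=[2.0], offset=[1.0])
        ll = log_likelihood(FitParams(lam=2.0, alpha=0.0, beta=0.0), data)
        assert ll == pytest.approx(2 * np.log(2) - 2)

    def test_negative_relative_risk_is_invalid(self):
        data = GroupedDataset(group_dose=[2.0], cases=[1.0], offset=[1.0])
        ll = log_likelihood(FitParams(lam=1.0, alpha=-1.0, beta=0.0), data)
        assert ll == INVALID_LOGLIK

    def test_offset_rate_rescaling_invariance(self):
        d = _expected_data()
        scaled = GroupedDataset(group_dose=d.group_dose, cases=d.cases,
                                offset=10.0 * d.offset)
        p = FitParams(lam=0.03, alpha=0.1, beta=1.0)
        p_scaled = FitParams(lam=0.003, alpha=0.1, beta=1.0)
        assert log_likelihood(p, d) == pytest.approx(
            log_likelihood(p_scaled, scaled), abs=1e-9)

    def test_truth_beats_null_on_expected_data(self):
        data = _expected_data()
        at_truth = log_likelihood(FitParams(0.06, 0.25, 2.0), data)
        lam_null = data.cases.sum() / data.offset.sum()
        at_null = log_likelihood(FitParams(lam_null, 0.0, 0.0), data)
        assert at_truth > at_null


class TestExactFitRecovery:
    @pytest.mark.parametrize("lam,alpha,beta", [
        (0.06, 0.25, 2.0),
        (0.1, 0.1, 0.0),
        (0.02, 1.0, 0.5),
    ])
    def test_recovers_generating_parameters(self, lam, alpha, beta):
        data = _expected_data(lam, alpha, beta)
        res = fit_mle(data, compute_ci=False)
        assert res.converged
        assert res.alpha == pytest.approx(alpha, abs=2e-5)
        assert res.beta == pytest.approx(beta, abs=2e-5)
        assert res.lam == pytest.approx(lam, rel=1e-4)

    def test_rescaled_offsets_leave_coefficients_unchanged(self):
        # same case vector, offsets scaled by c: lam_hat scales by 1/c and
        # the ERR coefficients are untouched
        base = _expected_data()
        scaled = GroupedDataset(base.group_dose, base.cases, 7.0 * base.offset)
        res1 = fit_mle(base, compute_ci=False)
        res2 = fit_mle(scaled, compute_ci=False)
        assert res1.alpha == pytest.approx(res2.alpha, abs=1e-5)
        assert res1.beta == pytest.approx(res2.beta, abs=1e-5)
        assert res1.lam == pytest.approx(7 * res2.lam, rel=1e-4)


class TestProfileCI:
    def test_deviance_residual_at_bounds(self, cohort, rng):
        # endpoints must satisfy 2*(llmax - pll(theta)) = chi2_95 to <1e-4
        d = cohort.central_dose_array()
        n = cohort.person_count_array()
        mu = n * 0.06 * (1 + 0.25 * d + 2 * d * d)
        data = GroupedDataset(group_dose=d, cases=rng.poisson(mu), offset=n)
        res = fit_mle(data)
        obj = PoissonLQObjective(data)
        for which, (lo, hi) in [("alpha", res.ci_alpha), ("beta", res.ci_beta)]:
            for bound in (lo, hi):
                assert np.isfinite(bound)
                pll, _ = _profile_max(obj, which, bound,
                                      center=getattr(res, which))
                dev = 2 * (res.loglik - pll)
                assert dev == pytest.approx(3.841458820694124, abs=1e-4)
            theta = getattr(res, which)
            assert lo < theta < hi

    def test_matches_wald_on_near_quadratic_surface(self):
        # with huge counts the log-likelihood is locally quadratic and the
        # profile interval collapses onto the Wald interval
        data = _expected_data(scale=2000.0)
        res = fit_mle(data)
        obj = PoissonLQObjective(data)
        for which, ci in [("alpha", res.ci_alpha), ("beta", res.ci_beta)]:
            theta = getattr(res, which)
            h = 1e-4 * max(abs(theta), 1.0)
            f = lambda t: _profile_max(obj, which, t, center=theta)[0]
            curv = (f(theta + h) - 2 * f(theta) + f(theta - h)) / h ** 2
            se = np.sqrt(-1 / curv)
            assert ci[0] == pytest.approx(theta - 1.959964 * se, rel=2e-2)
            assert ci[1] == pytest.approx(theta + 1.959964 * se, rel=2e-2)

    def test_public_interval_brackets_estimate(self):
        data = _expected_data()
        data = GroupedDataset(data.group_dose, np.round(data.cases), data.offset)
        lo, hi = profile_ci(data, "beta")
        assert lo < 2.1 and hi > 1.9

    def test_consistency_large_n(self, cohort, rng):
        # noise-free doses, N=1e5 cases: estimates approach the truth
        gids = cohort.individual_group_index()
        doses = cohort.central_dose_array()[gids]
        rr = 1 + 0.25 * doses + 2 * doses ** 2
        p = rr / rr.sum()
        cases = rng.multinomial(100_000, p)
        grouped = np.bincount(gids, weights=cases.astype(float))
        data = GroupedDataset(cohort.central_dose_array(), grouped,
                              cohort.person_count_array())
        res = fit_mle(data, compute_ci=False)
        assert res.alpha == pytest.approx(0.25, abs=0.05)
        assert res.beta == pytest.approx(2.0, abs=0.15)


def test_zero_cases_flagged_nonconverged():
    c = lss_cohort()
    data = GroupedDataset(c.central_dose_array(), np.zeros(5),
                          c.person_count_array())
    res = fit_mle(data)
    assert not res.converged
    assert res.params is None
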