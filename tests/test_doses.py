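"""Dose-error model: exactness, moments, correlations and degeneracies."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from regcal import (
    CohortDefinition,
    ErrorScenario,
    analytic_interindividual_correlation,
    calibration_summary,
    empirical_interindividual_correlation,
    group_means,
    sample_calibration_group_means,
    sample_surrogate_realization,
    sample_true_realization,
    simulate_dose_ensemble,
)


def _scen(bs=0.0, bu=0.0, cs=0.0, cu=0.0):
    return ErrorScenario(gsd_berkson_shared=bs, gsd_berkson_unshared=bu,
                         gsd_classical_shared=cs, gsd_classical_unshared=cu)


class TestZeroGsdExactness:
    def test_true_doses_equal_central(self, cohort, rng):
        real = sample_true_realization(cohort, _scen(cs=0.5, cu=0.5), rng)
        central = cohort.central_dose_array()[cohort.individual_group_index()]
        assert np.array_equal(real.doses, central)
        assert real.shared_draw == 0.0

    def test_surrogate_doses_equal_central(self, cohort, rng):
        real = sample_surrogate_realization(cohort, _scen(bs=0.5, bu=0.2), rng)
        central = cohort.central_dose_array()[cohort.individual_group_index()]
        assert np.array_equal(real.doses, central)

    def test_calibration_matrix_degenerates(self, cohort, rng):
        gm = sample_calibration_group_means(cohort, _scen(cs=0.5), 50, rng)
        assert np.array_equal(gm, np.tile(cohort.central_dose_array(), (50, 1)))

    def test_summary_mean_central_cov_zero(self, cohort, rng):
        ens = simulate_dose_ensemble(cohort, _scen(cu=0.2), 20, rng, rng,
                                     include_surrogate=False)
        summ = calibration_summary(ens, cohort)
        assert np.array_equal(summ.mean_group_dose, cohort.central_dose_array())
        assert np.all(summ.cov_group_dose == 0.0)


class TestMomentsAndSpread:
    def test_mean_preservation_true_dose(self, rng):
        # bias factor exp(-(s^2+u^2)/2) cancels the lognormal mean exactly
        cohort = CohortDefinition((1, 2), (1.0, 2.0), (500, 5))
        gm = sample_calibration_group_means(cohort, _scen(bs=0.5, bu=0.5), 4000, rng)
        # group-mean variance dominated by the shared factor: var ~ e^.25-1
        se = np.sqrt((np.exp(0.25) - 1) / 4000)
        assert abs(gm[:, 0].mean() - 1.0) < 4 * se

    def test_mean_preservation_surrogate(self, rng):
        cohort = CohortDefinition((1, 2), (1.0, 2.0), (2000, 5))
        means = [sample_surrogate_realization(cohort, _scen(cs=0.2, cu=0.5), rng)
                 .doses[:2000].mean() for _ in range(2000)]
        se = np.sqrt((np.exp(0.04) - 1) / 2000)
        assert abs(np.mean(means) - 1.0) < 4 * se

    def test_within_realization_spread_is_unshared_only(self, rng):
        # within one realization the shared deviate is constant, so the
        # empirical GSD of a group's doses estimates exp(sigma_unshared)
        cohort = CohortDefinition((1, 2), (1.0, 2.0), (20000, 5))
        real = sample_true_realization(cohort, _scen(bs=0.7, bu=0.5), rng)
        log_doses = np.log(real.doses[:20000])
        assert np.exp(log_doses.std()) == pytest.approx(np.exp(0.5), rel=0.02)

    def test_true_and_surrogate_independent(self, cohort, rng):
        scen = _scen(bs=0.3, bu=0.3, cs=0.3, cu=0.3)
        n = 3000
        t = np.empty(n)
        s = np.empty(n)
        for k in range(n):
            t[k] = sample_true_realization(cohort, scen, rng).doses[-1]
            s[k] = sample_surrogate_realization(cohort, scen, rng).doses[-1]
        assert abs(np.corrcoef(t, s)[0, 1]) < 4 / np.sqrt(n)


class TestInterindividualCorrelation:
    # closed form rho = (e^{s^2}-1)/(e^{s^2+u^2}-1)
    @pytest.mark.parametrize("shared,unshared,expected", [
        (0.2, 0.2, 0.4900),
        (0.5, 0.2, 0.8442),
        (0.5, 0.5, 0.4378),
        (0.2, 0.5, 0.1213),
    ])
    def test_analytic_values(self, shared, unshared, expected):
        rho = analytic_interindividual_correlation(_scen(bs=shared, bu=unshared))
        assert rho == pytest.approx(expected, abs=5e-4)

    def test_undefined_without_berkson_error(self):
        assert np.isnan(analytic_interindividual_correlation(_scen(cs=0.5)))

    @pytest.mark.parametrize("shared,unshared", [(0.2, 0.2), (0.5, 0.2), (0.5, 0.5)])
    def test_empirical_matches_analytic(self, shared, unshared, rng):
        scen = _scen(bs=shared, bu=unshared)
        emp = empirical_interindividual_correlation(scen, rng, n_draws=200_000)
        assert emp == pytest.approx(analytic_interindividual_correlation(scen),
                                    abs=0.02)


class TestGroupMeans:
    def test_arithmetic_mean(self):
        assert group_means(np.array([1.0, 3.0, 5.0]), np.array([0, 0, 1]),
                           2).tolist() == [2.0, 5.0]

    def test_zero_gsd_equals_central(self, cohort, rng):
        real = sample_true_realization(cohort, _scen(), rng)
        gm = group_means(real, cohort.individual_group_index(), cohort.n_groups)
        assert np.allclose(gm, cohort.central_dose_array())

    def test_empty_group_raises(self):
        with pytest.raises(ValueError, match="empty"):
            group_means(np.array([1.0, 2.0]), np.array([0, 0]), 2)


class TestCalibrationSummary:
    def test_shared_only_group_means_perfectly_correlated(self, cohort, rng):
        ens = simulate_dose_ensemble(cohort, _scen(bs=0.5), 400, rng, rng,
                                     include_surrogate=False)
        summ = calibration_summary(ens, cohort)
        corr = np.corrcoef(summ.realization_group_means, rowvar=False)
        assert np.min(corr) > 1 - 1e-9

    def test_mixed_error_group_mean_correlations_high(self, cohort, rng):
        # averaging shrinks unshared errors, so shared errors dominate the
        # between-group correlations of the group means
        ens = simulate_dose_ensemble(cohort, _scen(bs=0.5, bu=0.2), 500, rng, rng,
                                     include_surrogate=False)
        summ = calibration_summary(ens, cohort)
        corr = np.corrcoef(summ.realization_group_means, rowvar=False)
        assert np.min(corr) > 0.95

    def test_covariance_psd_and_symmetric(self, cohort, rng):
        ens = simulate_dose_ensemble(cohort, _scen(bs=0.2, bu=0.5), 200, rng, rng,
                                     include_surrogate=False)
        cov = calibration_summary(ens, cohort).cov_group_dose
        assert np.allclose(cov, cov.T)
        assert np.min(np.linalg.eigvalsh(cov)) > -1e-12

    def test_batch_matches_per_realization_reference(self, rng):
        # the vectorized float32 batch path must be distribution-identical to
        # looping the per-individual float64 sampler
        cohort = CohortDefinition((1, 2), (0.5, 2.0), (200, 20))
        scen = _scen(bs=0.3, bu=0.4)
        n = 4000
        batch = sample_calibration_group_means(cohort, scen, n, rng)
        gids = cohort.individual_group_index()
        loop = np.stack([
            group_means(sample_true_realization(cohort, scen, rng), gids, 2)
            for _ in range(n)])
        for g in range(2):
            se = loop[:, g].std() * np.sqrt(2.0 / n)
            assert abs(batch[:, g].mean() - loop[:, g].mean()) < 4 * se
        assert np.allclose(batch.std(axis=0), loop.std(axis=0), rtol=0.15)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(bs=st.floats(0, 1.5), bu=st.floats(0, 1.5), seed=st.integers(0, 2**31 - 1))
def test_doses_strictly_positive(bs, bu, seed):
    cohort = CohortDefinition((1, 2), (0.01, 2.0), (30, 10))
    real = sample_true_realization(cohort, _scen(bs=bs, bu=bu),
                                   np.random.default_rng(seed))
    assert np.all(real.doses > 0)
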