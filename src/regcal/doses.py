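"""Composite multiplicative Berkson-classical dose-error simulation.

True and surrogate doses are generated around each group's central estimate
``D_cent`` by independent lognormal multipliers,

    D_true = D_cent * exp(-(s_B^2 + u_B^2)/2) * exp(s_B*eps + u_B*delta_i)
    D_surr = D_cent * exp(-(s_C^2 + u_C^2)/2) * exp(s_C*mu  + u_C*kappa_i)

where ``eps``/``mu`` are shared standard-normal deviates (one per
realization) and ``delta_i``/``kappa_i`` are unshared per-individual
deviates; all four streams are mutually independent.  The leading bias
factors make the theoretical mean of every individual's dose coincide with
the group central estimate.  Setting the Berkson pair to zero leaves a pure
classical-error model and vice versa.

The calibration summaries consumed by the correction methods are the
within-group means of the true-dose realizations: their Monte Carlo mean
(regression calibration), their covariance across realizations (extended
regression calibration) and the full matrix of realization group means
(Monte Carlo maximum likelihood).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import CohortDefinition, ErrorScenario

__all__ = [
    "DoseRealization",
    "DoseEnsemble",
    "CalibrationSummary",
    "sample_true_realization",
    "sample_surrogate_realization",
    "sample_calibration_group_means",
    "simulate_dose_ensemble",
    "group_means",
    "calibration_summary",
    "analytic_interindividual_correlation",
    "empirical_interindividual_correlation",
]


@dataclass
class DoseRealization:
    """One realization of per-individual doses (Gy).

    ``shared_draw`` is the realized shared standard-normal deviate; ``kind``
    is ``"true"`` or ``"surrogate"``.
    """

    doses: np.ndarray
    shared_draw: float
    kind: str


@dataclass
class DoseEnsemble:
    """One simulation's dose data: the "actual" true realization that
    generates cases, a single surrogate realization, and ``n_calibration``
    fresh true-dose realizations summarised as group means.

    ``calibration_group_means`` has shape ``(n_calibration, K)``; the full
    per-individual calibration realizations are retained only when
    explicitly requested (``calibration_realizations``), since the group
    means are sufficient for every correction method.
    """

    true_realization: DoseRealization
    surrogate_realization: DoseRealization | None
    calibration_group_means: np.ndarray | None
    group_ids: np.ndarray
    calibration_realizations: list[DoseRealization] | None = None

    @property
    def n_calibration(self) -> int:
        if self.calibration_group_means is None:
            return 0
        return int(self.calibration_group_means.shape[0])


@dataclass
class CalibrationSummary:
    """Monte Carlo summaries of the calibration true-dose group means.

    ``mean_group_dose``: K-vector of MC means (Gy); ``cov_group_dose``:
    K x K sample covariance (divisor n-1, Gy^2); ``realization_group_means``:
    the underlying (n, K) matrix, retained for MCML.
    """

    mean_group_dose: np.ndarray
    cov_group_dose: np.ndarray
    realization_group_means: np.ndarray


def _sample_realization(cohort: CohortDefinition, sigma_shared: float,
                        sigma_unshared: float, rng: np.random.Generator,
                        kind: str) -> DoseRealization:
    central = cohort.central_dose_array()[cohort.individual_group_index()]
    if sigma_shared == 0.0 and sigma_unshared == 0.0:
        # exp(0*Z) == 1 exactly; skip the draws entirely
        return DoseRealization(doses=central.copy(), shared_draw=0.0, kind=kind)
    shared = float(rng.standard_normal())
    unshared = rng.standard_normal(central.size)
    bias = np.exp(-0.5 * (sigma_shared ** 2 + sigma_unshared ** 2))
    doses = central * bias * np.exp(sigma_shared * shared + sigma_unshared * unshared)
    return DoseRealization(doses=doses, shared_draw=shared, kind=kind)


def sample_true_realization(cohort: CohortDefinition, scenario: ErrorScenario,
                            rng: np.random.Generator) -> DoseRealization:
    """Draw one true-dose realization (Berkson error components)."""
    s, u = scenario.berkson_pair
    return _sample_realization(cohort, s, u, rng, "true")


def sample_surrogate_realization(cohort: CohortDefinition, scenario: ErrorScenario,
                                 rng: np.random.Generator) -> DoseRealization:
    """Draw one surrogate-dose realization (classical error components)."""
    s, u = scenario.classical_pair
    return _sample_realization(cohort, s, u, rng, "surrogate")


def group_means(realization, group_ids: np.ndarray,
                n_groups: int | None = None) -> np.ndarray:
    """Arithmetic mean dose within each group.

    ``realization`` may be a :class:`DoseRealization` or a plain dose array.
    Raises if any group is empty.
    """
    doses = realization.doses if isinstance(realization, DoseRealization) else np.asarray(realization, float)
    group_ids = np.asarray(group_ids)
    k = int(n_groups) if n_groups is not None else int(group_ids.max()) + 1
    counts = np.bincount(group_ids, minlength=k)
    if np.any(counts == 0):
        empty = np.nonzero(counts == 0)[0]
        raise ValueError(f"empty dose group(s): {empty.tolist()}")
    sums = np.bincount(group_ids, weights=doses, minlength=k)
    return sums / counts


_CHUNK_ELEMENTS = 64_000_000  # cap transient memory of the batch sampler


def sample_calibration_group_means(cohort: CohortDefinition, scenario: ErrorScenario,
                                   n: int, rng: np.random.Generator) -> np.ndarray:
    """Vectorized batch of ``n`` true-dose realizations, reduced to group means.

    Returns an ``(n, K)`` array.  Distributionally identical to calling
    :func:`sample_true_realization` ``n`` times and taking group means; the
    unshared deviates are drawn in float32 for throughput (the group
    averaging makes the precision loss negligible against Monte Carlo noise).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    s, u = scenario.berkson_pair
    central = cohort.central_dose_array()
    if s == 0.0 and u == 0.0:
        return np.tile(central, (n, 1))
    starts = cohort.group_start_offsets()
    counts = cohort.person_count_array()
    m_ind = cohort.total_persons
    bias = np.exp(-0.5 * (s ** 2 + u ** 2))
    out = np.empty((n, cohort.n_groups))
    chunk = max(1, int(_CHUNK_ELEMENTS // max(m_ind, 1)))
    done = 0
    while done < n:
        rows = min(chunk, n - done)
        shared = rng.standard_normal(rows)
        if u > 0.0:
            unshared = rng.standard_normal((rows, m_ind), dtype=np.float32)
            np.multiply(unshared, np.float32(u), out=unshared)
            np.exp(unshared, out=unshared)
            gm_unshared = np.add.reduceat(unshared, starts, axis=1, dtype=np.float64) / counts
        else:
            gm_unshared = np.ones((rows, cohort.n_groups))
        out[done:done + rows] = (central * bias) * np.exp(s * shared)[:, None] * gm_unshared
        done += rows
    return out


def simulate_dose_ensemble(cohort: CohortDefinition, scenario: ErrorScenario,
                           n_calibration: int,
                           rng_true: np.random.Generator,
                           rng_calibration: np.random.Generator | None = None,
                           rng_classical: np.random.Generator | None = None,
                           include_surrogate: bool = True,
                           keep_realizations: bool = False,
                           actual_in_calibration: bool = False) -> DoseEnsemble:
    """Assemble a full :class:`DoseEnsemble` from independent RNG streams.

    The Berkson streams (``rng_true``, ``rng_calibration``) and the
    classical stream (``rng_classical``) must be independent so that
    calibration-based fits are unaffected by the classical error settings.

    By default the calibration bank consists of fresh unconditional draws,
    independent of the "actual" realization that generates the cases.  With
    ``actual_in_calibration=True`` the actual realization's group means form
    the first bank row (topped up with fresh draws), making the bank the
    full set of dose samples of which the case-generating realization is
    one; at the default bank size the two designs are statistically
    indistinguishable.
    """
    gids = cohort.individual_group_index()
    true = sample_true_realization(cohort, scenario, rng_true)
    surrogate = None
    if include_surrogate:
        if rng_classical is None:
            raise ValueError("rng_classical required when include_surrogate=True")
        surrogate = sample_surrogate_realization(cohort, scenario, rng_classical)
    cal_gm = None
    realizations = None
    if n_calibration > 0:
        if rng_calibration is None:
            raise ValueError("rng_calibration required when n_calibration > 0")
        n_fresh = n_calibration - 1 if actual_in_calibration else n_calibration
        if keep_realizations:
            realizations = [sample_true_realization(cohort, scenario, rng_calibration)
                            for _ in range(n_fresh)]
            fresh_gm = [group_means(r, gids, cohort.n_groups) for r in realizations]
            if actual_in_calibration:
                realizations = [true, *realizations]
                fresh_gm = [group_means(true, gids, cohort.n_groups), *fresh_gm]
            cal_gm = np.stack(fresh_gm)
        else:
            parts = []
            if actual_in_calibration:
                if scenario.has_berkson:
                    actual_gm = group_means(true, gids, cohort.n_groups)
                else:
                    # actual doses are exactly the central estimates; avoid
                    # floating-point drift from averaging identical values
                    actual_gm = cohort.central_dose_array()
                parts.append(actual_gm[None, :])
            if n_fresh > 0:
                parts.append(sample_calibration_group_means(
                    cohort, scenario, n_fresh, rng_calibration))
            cal_gm = np.concatenate(parts, axis=0)
    return DoseEnsemble(true_realization=true, surrogate_realization=surrogate,
                        calibration_group_means=cal_gm, group_ids=np.asarray(gids),
                        calibration_realizations=realizations)


def calibration_summary(ensemble: DoseEnsemble,
                        cohort: CohortDefinition) -> CalibrationSummary:
    """Mean and sample covariance (divisor n-1) of the calibration group means."""
    gm = ensemble.calibration_group_means
    if gm is None:
        if not ensemble.calibration_realizations:
            raise ValueError("ensemble carries no calibration realizations")
        gm = np.stack([group_means(r, ensemble.group_ids, cohort.n_groups)
                       for r in ensemble.calibration_realizations])
    n = gm.shape[0]
    mean = gm.mean(axis=0)
    if n >= 2 and np.any(gm != gm[0]):
        cov = np.cov(gm, rowvar=False, ddof=1)
        cov = 0.5 * (cov + cov.T)
    else:
        # all realizations identical (e.g. zero Berkson error): exactly zero
        cov = np.zeros((cohort.n_groups, cohort.n_groups))
        mean = gm[0].copy()
    return CalibrationSummary(mean_group_dose=mean, cov_group_dose=np.atleast_2d(cov),
                              realization_group_means=gm)


def analytic_interindividual_correlation(scenario: ErrorScenario) -> float:
    """Closed-form Pearson correlation between two individuals' true doses.

    With shared/unshared Berkson GSDs (s, u) the lognormal moments give

        rho = (exp(s^2) - 1) / (exp(s^2 + u^2) - 1).

    Undefined (NaN) when both Berkson GSDs are zero.
    """
    s, u = scenario.berkson_pair
    if s == 0.0 and u == 0.0:
        return float("nan")
    return float(np.expm1(s ** 2) / np.expm1(s ** 2 + u ** 2))


def empirical_interindividual_correlation(scenario: ErrorScenario,
                                          rng: np.random.Generator,
                                          n_draws: int = 100_000) -> float:
    """Sample Pearson correlation between two individuals' true doses.

    Draws ``n_draws`` independent realizations of the shared and unshared
    Berkson deviates for a pair of individuals in the same dose group (the
    correlation does not depend on the central dose).
    """
    s, u = scenario.berkson_pair
    if s == 0.0 and u == 0.0:
        return float("nan")
    shared = rng.standard_normal(n_draws)
    unshared = rng.standard_normal((n_draws, 2))
    doses = np.exp(s * shared[:, None] + u * unshared)
    return float(np.corrcoef(doses[:, 0], doses[:, 1])[0, 1])
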