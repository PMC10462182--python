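"""The four estimation strategies for dose-error correction.

Given one dose ensemble and one case vector, each strategy produces a
:class:`~regcal.likelihood.FitResult` for the grouped linear-quadratic
Poisson relative-risk model; they differ only in the dose covariate and, for
extended regression calibration and MCML, in the likelihood itself:

``unadjusted``
    group means of a single surrogate-dose realization;
``regcal``
    regression calibration — the Monte Carlo mean over the calibration
    realizations of the true-dose group means;
``ext_regcal``
    extended regression calibration — the same mean doses, with a
    second-order likelihood adjustment driven by the Monte Carlo covariance
    of the group-mean doses (designed for shared-error settings);
``mcml``
    Monte Carlo maximum likelihood — maximizes the log of the average over
    calibration realizations of the likelihood evaluated at each
    realization's group-mean doses.

When the Berkson GSDs are zero every calibration realization equals the
central doses, the covariance vanishes, and all three calibration-based
strategies coincide exactly with the fit on central doses.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from scipy import optimize
from scipy.special import logsumexp

from .cohort import CohortDefinition, METHOD_NAMES
from .doses import CalibrationSummary, DoseEnsemble, calibration_summary, group_means
from .likelihood import (
    INVALID_LOGLIK,
    FitResult,
    PoissonLQObjective,
    fit_objective,
)
from .outcomes import GroupedDataset, collapse

__all__ = [
    "METHOD_NAMES",
    "AdjustedPoissonLQObjective",
    "MCMLObjective",
    "fit_unadjusted",
    "fit_regression_calibration",
    "fit_extended_regression_calibration",
    "fit_mcml",
]


class AdjustedPoissonLQObjective(PoissonLQObjective):
    """Covariance-adjusted likelihood for extended regression calibration.

    Regression calibration evaluates the relative risk at the mean
    calibration dose, RR(D̄_g); with curvature this misses the second
    moment of the dose distribution.  The adjusted likelihood instead uses
    the *expected* relative risk under the Monte Carlo distribution of the
    group-mean dose,

        E[RR(D_g)] = 1 + alpha*D̄_g + beta*(D̄_g^2 + Var(D̄_g)),

    which is exact (not a truncated expansion) because the model is
    quadratic in dose: the covariance of the calibration group means is the
    entire second-order correction.  The Poisson mean becomes
    mu_g = n_g lam E[RR(D_g)], the marginal mean of the counts over the
    dose uncertainty.  A zero covariance reproduces the plain
    regression-calibration fit exactly, and the correction grows with the
    shared error magnitude, which dominates Var(D̄_g) after within-group
    averaging.
    """

    def __init__(self, data: GroupedDataset, dose_cov: np.ndarray):
        super().__init__(data)
        cov = 0.5 * (np.asarray(dose_cov, dtype=float) +
                     np.asarray(dose_cov, dtype=float).T)
        eigval, eigvec = np.linalg.eigh(cov)
        if np.any(eigval < -1.0e-10 * max(eigval.max(initial=0.0), 1.0)):
            warnings.warn("dose covariance not PSD; clipping negative eigenvalues",
                          RuntimeWarning, stacklevel=2)
        cov = (eigvec * np.clip(eigval, 0.0, None)) @ eigvec.T
        self.dose_cov = cov
        self.var_diag = np.diag(cov).copy()
        # quadratic-term covariate: second moment of the group-mean dose
        self.d2_adj = self.d2 + self.var_diag

    def expected_relative_risk(self, alpha: float, beta: float) -> np.ndarray:
        return 1.0 + alpha * self.d + beta * self.d2_adj

    def loglik(self, lam: float, alpha: float, beta: float) -> float:
        if lam <= 0:
            return INVALID_LOGLIK
        err = self.expected_relative_risk(alpha, beta)
        if np.any(err <= 0):
            return INVALID_LOGLIK
        mu = self.n * (lam * err)
        return float(self.y @ np.log(mu) - mu.sum())

    def profiled(self, alpha: float, beta: float) -> tuple[float, float]:
        err = self.expected_relative_risk(alpha, beta)
        if np.any(err <= 0) or self.N <= 0:
            return INVALID_LOGLIK, float("nan")
        denom = float(self.n @ err)
        if denom <= 0:
            return INVALID_LOGLIK, float("nan")
        lam = self.N / denom
        ll = self._ylogn + float(self.y @ np.log(lam * err)) - self.N
        return ll, lam

    def alpha_floor(self, beta: float) -> float:
        return float(np.max(-(1.0 + beta * self.d2_adj) / self.d))

    def beta_floor(self, alpha: float) -> float:
        return float(np.max(-(1.0 + alpha * self.d) / self.d2_adj))


class MCMLObjective:
    """Monte Carlo maximum-likelihood objective over calibration realizations.

    The likelihood is the average over the n realization-wise likelihoods,
    each evaluated at that realization's group-mean dose vector, computed
    stably on the log scale:

        l_MCML(theta) = log( (1/n) sum_k exp(l(theta; D_k)) ).

    Realizations in which any group's relative risk is non-positive
    contribute likelihood zero; the point is infeasible only if every
    realization drops out.  The baseline rate cannot be profiled in closed
    form and is maximized numerically (safeguarded Newton on log lam with a
    bracketed-Brent fallback).
    """

    def __init__(self, cases: np.ndarray, offsets: np.ndarray,
                 dose_matrix: np.ndarray):
        self.y = np.asarray(cases, dtype=float)
        self.n = np.asarray(offsets, dtype=float)
        self.D = np.asarray(dose_matrix, dtype=float)
        if self.D.ndim != 2 or self.D.shape[1] != self.y.size:
            raise ValueError("dose_matrix must have shape (n_realizations, K)")
        self.D2 = self.D ** 2
        # realization-mean doses; used only to seed the optimizer
        self.d = self.D.mean(axis=0)
        self.d2 = self.d ** 2
        self.N = float(self.y.sum())
        self.n_realizations = self.D.shape[0]
        self._log_nreal = math.log(self.n_realizations)
        self._ylogn = float(self.y @ np.log(self.n))
        self._lam_warm: float | None = None

    # -- feasibility: at least one realization must stay positive ----------

    def relative_risk(self, alpha: float, beta: float) -> np.ndarray:
        return 1.0 + alpha * self.D + beta * self.D2

    def alpha_floor(self, beta: float) -> float:
        floors = np.max(-(1.0 + beta * self.D2) / self.D, axis=1)
        return float(np.min(floors))

    def beta_floor(self, alpha: float) -> float:
        floors = np.max(-(1.0 + alpha * self.D) / self.D2, axis=1)
        return float(np.min(floors))

    # -- likelihood --------------------------------------------------------

    def loglik(self, lam: float, alpha: float, beta: float) -> float:
        if lam <= 0:
            return INVALID_LOGLIK
        cs = self._realization_terms(alpha, beta)
        if cs is None:
            return INVALID_LOGLIK
        c, s = cs
        return self._ylogn + self._f(lam, c, s)

    def profiled(self, alpha: float, beta: float) -> tuple[float, float]:
        if self.N <= 0:
            return INVALID_LOGLIK, float("nan")
        cs = self._realization_terms(alpha, beta)
        if cs is None:
            return INVALID_LOGLIK, float("nan")
        c, s = cs
        lam, fmax = self._maximize_lam(c, s)
        if not np.isfinite(fmax):
            return INVALID_LOGLIK, float("nan")
        self._lam_warm = lam
        return self._ylogn + fmax, lam

    def profiled_loglik(self, alpha: float, beta: float) -> float:
        return self.profiled(alpha, beta)[0]

    def _realization_terms(self, alpha: float, beta: float):
        """Per-valid-realization (c_k, S_k) with
        c_k = sum_g y_g log RR_gk and S_k = sum_g n_g RR_gk."""
        rr = self.relative_risk(alpha, beta)
        valid = (rr > 0).all(axis=1)
        if not valid.any():
            return None
        rr = rr[valid]
        return np.log(rr) @ self.y, rr @ self.n

    def _f(self, lam: float, c: np.ndarray, s: np.ndarray) -> float:
        if lam <= 0:
            return -1.0e300
        return (self.N * math.log(lam)
                + float(logsumexp(c - lam * s)) - self._log_nreal)

    def _maximize_lam(self, c: np.ndarray, s: np.ndarray) -> tuple[float, float]:
        """Maximize f(lam) = N log lam + LSE(c - lam S) - log n over lam > 0."""
        lam = self._lam_warm if self._lam_warm and self._lam_warm > 0 \
            else self.N / float(np.mean(s))
        t = math.log(lam)
        converged = False
        for _ in range(60):
            e_s, var_s = self._weighted_s_moments(c, s, math.exp(t))
            g = self.N - math.exp(t) * e_s               # df/dt
            if abs(g) < 1.0e-9 * max(self.N, 1.0):
                converged = True
                break
            h = -math.exp(t) * e_s + math.exp(2 * t) * var_s  # d2f/dt2
            if h >= -1.0e-12 * max(abs(g), 1.0):
                break  # not locally concave; fall back to bracketing
            step = max(-1.0, min(1.0, -g / h))  # damp large jumps
            t += step
        if converged:
            lam = math.exp(t)
            return lam, self._f(lam, c, s)
        return self._bracket_brent_lam(c, s)

    def _weighted_s_moments(self, c, s, lam):
        z = c - lam * s
        z = z - z.max()
        w = np.exp(z)
        w /= w.sum()
        e_s = float(w @ s)
        var_s = float(w @ (s - e_s) ** 2)
        return e_s, var_s

    def _bracket_brent_lam(self, c, s) -> tuple[float, float]:
        f = lambda lam: self._f(lam, c, s)
        x0 = self.N / float(np.mean(s))
        xa, xb, xc = _bracket_maximum(f, x0)
        res = optimize.minimize_scalar(lambda lam: -f(lam), bracket=(xa, xb, xc),
                                       method="brent", options={"xtol": 1.0e-10})
        return float(res.x), -float(res.fun)


def _bracket_maximum(f, x0: float, factor: float = 2.5, max_steps: int = 120):
    """Multiplicative bracket (a < b < c, f(b) >= f(a), f(c)) of a 1-D max."""
    fa = f(x0)
    x_hi, f_hi = x0 * factor, f(x0 * factor)
    if f_hi > fa:
        prev, cur = x0, x0 * factor
        f_prev, f_cur = fa, f_hi
        for _ in range(max_steps):
            nxt = cur * factor
            f_nxt = f(nxt)
            if f_nxt < f_cur:
                return prev, cur, nxt
            prev, cur, f_prev, f_cur = cur, nxt, f_cur, f_nxt
        return prev, cur, cur * factor
    x_lo, f_lo = x0 / factor, f(x0 / factor)
    if f_lo > fa:
        prev, cur = x0, x0 / factor
        f_prev, f_cur = fa, f_lo
        for _ in range(max_steps):
            nxt = cur / factor
            f_nxt = f(nxt)
            if f_nxt < f_cur:
                return nxt, cur, prev
            prev, cur, f_prev, f_cur = cur, nxt, f_cur, f_nxt
        return cur / factor, cur, prev
    return x0 / factor, x0, x0 * factor


# ---------------------------------------------------------------------------
# The four public strategies
# ---------------------------------------------------------------------------

def _collapse_with(ensemble: DoseEnsemble, case_counts: np.ndarray,
                   cohort: CohortDefinition, dose: np.ndarray) -> GroupedDataset:
    return collapse(case_counts, ensemble.group_ids, dose, cohort)


def fit_unadjusted(ensemble: DoseEnsemble, case_counts: np.ndarray,
                   cohort: CohortDefinition, level: float = 0.95) -> FitResult:
    """Fit on group means of the single surrogate-dose realization."""
    if ensemble.surrogate_realization is None:
        raise ValueError("ensemble carries no surrogate realization")
    dose = group_means(ensemble.surrogate_realization, ensemble.group_ids,
                       cohort.n_groups)
    data = _collapse_with(ensemble, case_counts, cohort, dose)
    return fit_objective(PoissonLQObjective(data), level=level, method="unadjusted")


def fit_regression_calibration(ensemble: DoseEnsemble, case_counts: np.ndarray,
                               cohort: CohortDefinition, level: float = 0.95,
                               summary: CalibrationSummary | None = None) -> FitResult:
    """Fit on the Monte Carlo mean of the calibration true-dose group means."""
    if summary is None:
        summary = calibration_summary(ensemble, cohort)
    data = _collapse_with(ensemble, case_counts, cohort, summary.mean_group_dose)
    return fit_objective(PoissonLQObjective(data), level=level, method="regcal")


def fit_extended_regression_calibration(
        ensemble: DoseEnsemble, case_counts: np.ndarray,
        cohort: CohortDefinition, level: float = 0.95,
        summary: CalibrationSummary | None = None) -> FitResult:
    """Covariance-adjusted (second-order) fit at the calibration mean doses."""
    if summary is None:
        if ensemble.n_calibration < 2:
            raise ValueError("extended regression calibration needs >= 2 "
                             "calibration realizations for a covariance estimate")
        summary = calibration_summary(ensemble, cohort)
    data = _collapse_with(ensemble, case_counts, cohort, summary.mean_group_dose)
    obj = AdjustedPoissonLQObjective(data, summary.cov_group_dose)
    return fit_objective(obj, level=level, method="ext_regcal")


def fit_mcml(ensemble: DoseEnsemble, case_counts: np.ndarray,
             cohort: CohortDefinition, level: float = 0.95,
             summary: CalibrationSummary | None = None) -> FitResult:
    """Monte Carlo maximum likelihood over the calibration group-mean doses."""
    if summary is None:
        summary = calibration_summary(ensemble, cohort)
    if summary.realization_group_means.shape[0] < 1:
        raise ValueError("MCML needs at least one calibration realization")
    data = _collapse_with(ensemble, case_counts, cohort, summary.mean_group_dose)
    obj = MCMLObjective(data.cases, data.offset, summary.realization_group_means)
    # The averaged likelihood can carry spurious distant modes in which one
    # extreme calibration realization reproduces the case vector almost
    # exactly; start from the regression-calibration estimate to target the
    # scientifically relevant mode.
    rc = fit_objective(PoissonLQObjective(data), compute_ci=False)
    starts = [(rc.alpha, rc.beta)] if rc.converged else None
    return fit_objective(obj, level=level, starts=starts, method="mcml")
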