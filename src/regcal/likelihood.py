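"""Grouped Poisson linear-quadratic relative-risk likelihood and inference.

The model for group g with dose covariate d_g, person count n_g and case
count y_g is

    y_g ~ Poisson(mu_g),   mu_g = n_g * lam * (1 + alpha*d_g + beta*d_g^2),

with lam the baseline rate per person.  The log-likelihood drops the
y_g-only constant (log y_g!), which shifts every likelihood by the same
amount and leaves estimates, deviances and profile intervals unchanged.

The feasible region requires every relative risk to stay positive; outside
it the likelihood is assigned a large negative sentinel that optimizers
treat as minus infinity.  lam is profiled out in closed form
(lam_hat = sum y_g / sum n_g RR_g), reducing maximization to two
dimensions.  Confidence intervals are profile-likelihood intervals: the
parameter values at which twice the profile deviance reaches the
chi-squared(1) quantile, located by bracketed root finding on each side of
the estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .outcomes import GroupedDataset

__all__ = [
    "INVALID_LOGLIK",
    "FitParams",
    "FitResult",
    "PoissonLQObjective",
    "log_likelihood",
    "fit_mle",
    "fit_objective",
    "profile_ci",
]

#: Sentinel log-likelihood for parameter points outside the feasible region.
INVALID_LOGLIK = -1.0e30

#: Search cap for nuisance-parameter maximization (per Gy or per Gy^2).
_NUISANCE_CAP = 1.0e4

#: Base limit beyond which a profile-CI bound is declared unbounded.
PROFILE_SEARCH_LIMIT = 50.0

_FLOOR_MARGIN = 1.0e-9


@dataclass(frozen=True)
class FitParams:
    """Baseline rate per person and ERR coefficients (per Gy, per Gy^2)."""

    lam: float
    alpha: float
    beta: float


@dataclass
class FitResult:
    """Point estimates, maximized log-likelihood and 95% profile CIs.

    CI bounds may be ``-inf``/``+inf`` when the profile deviance never
    reaches the cutoff inside the search limits, or NaN when an inner
    profile maximization failed.  Non-converged fits are excluded from
    coverage and bias tallies by the study runner.
    """

    params: FitParams | None
    loglik: float
    ci_alpha: tuple[float, float]
    ci_beta: tuple[float, float]
    converged: bool
    method: str = ""

    @property
    def alpha(self) -> float:
        return self.params.alpha if self.params else float("nan")

    @property
    def beta(self) -> float:
        return self.params.beta if self.params else float("nan")

    @property
    def lam(self) -> float:
        return self.params.lam if self.params else float("nan")

    def ci(self, which: str) -> tuple[float, float]:
        return self.ci_alpha if which == "alpha" else self.ci_beta


class PoissonLQObjective:
    """Plain grouped likelihood at a fixed dose vector, lam profiled out."""

    def __init__(self, data: GroupedDataset):
        self.y = np.asarray(data.cases, dtype=float)
        self.n = np.asarray(data.offset, dtype=float)
        self.d = np.asarray(data.group_dose, dtype=float)
        self.d2 = self.d ** 2
        self.N = float(self.y.sum())
        self._ylogn = float(self.y @ np.log(self.n))

    # -- likelihood -------------------------------------------------------

    def relative_risk(self, alpha: float, beta: float) -> np.ndarray:
        return 1.0 + alpha * self.d + beta * self.d2

    def loglik(self, lam: float, alpha: float, beta: float) -> float:
        """Full three-parameter log-likelihood (constants in y dropped)."""
        if lam <= 0:
            return INVALID_LOGLIK
        rr = self.relative_risk(alpha, beta)
        if np.any(rr <= 0):
            return INVALID_LOGLIK
        mu = self.n * (lam * rr)
        return float(self.y @ np.log(mu) - mu.sum())

    def profiled(self, alpha: float, beta: float) -> tuple[float, float]:
        """(max-over-lam log-likelihood, lam_hat) at fixed (alpha, beta)."""
        rr = self.relative_risk(alpha, beta)
        if np.any(rr <= 0) or self.N <= 0:
            return INVALID_LOGLIK, float("nan")
        denom = float(self.n @ rr)
        if denom <= 0:
            return INVALID_LOGLIK, float("nan")
        lam = self.N / denom
        ll = self._ylogn + float(self.y @ np.log(lam * rr)) - self.N
        return ll, lam

    def profiled_loglik(self, alpha: float, beta: float) -> float:
        return self.profiled(alpha, beta)[0]

    # -- feasibility ------------------------------------------------------

    def alpha_floor(self, beta: float) -> float:
        """Infimum of alpha keeping all relative risks positive (doses > 0)."""
        return float(np.max(-(1.0 + beta * self.d2) / self.d))

    def beta_floor(self, alpha: float) -> float:
        return float(np.max(-(1.0 + alpha * self.d) / self.d2))


def log_likelihood(params: FitParams, data: GroupedDataset) -> float:
    """Log-likelihood of ``params``; ``INVALID_LOGLIK`` outside feasibility."""
    return PoissonLQObjective(data).loglik(params.lam, params.alpha, params.beta)


# ---------------------------------------------------------------------------
# Maximization machinery (shared by all correction methods)
# ---------------------------------------------------------------------------

def _profile_max(obj, fixed: str, value: float, center: float = 0.0,
                 window: float = 10.0, xatol: float = 1.0e-7) -> tuple[float, float]:
    """Maximize the lam-profiled log-likelihood over the parameter that is
    not ``fixed``.  Returns ``(loglik, argmax)``; sentinel when infeasible.

    The search is a bounded Brent pass on an expanding window around
    ``center``: if the optimum lands on a window edge the window is grown
    and the search repeated.  Keeping the search local (rather than
    scanning the whole feasible range) matters for the averaged MCML
    likelihood, which can carry spurious distant modes where a single
    extreme calibration realization fits the case vector almost exactly.
    """
    if fixed == "alpha":
        floor = obj.beta_floor(value)
        fun = lambda b: -obj.profiled_loglik(value, b)
    else:
        floor = obj.alpha_floor(value)
        fun = lambda a: -obj.profiled_loglik(a, value)
    lo_feas = max(floor + _FLOOR_MARGIN, -_NUISANCE_CAP)
    hi_feas = _NUISANCE_CAP
    if not lo_feas < hi_feas:
        return INVALID_LOGLIK, float("nan")
    center = min(max(center, lo_feas), hi_feas)
    w = window
    best_ll, best_x = INVALID_LOGLIK, float("nan")
    for _ in range(8):
        lo = max(lo_feas, center - w)
        hi = min(hi_feas, center + w)
        res = optimize.minimize_scalar(fun, bounds=(lo, hi), method="bounded",
                                       options={"xatol": xatol})
        best_ll, best_x = -float(res.fun), float(res.x)
        edge = 0.02 * (hi - lo)
        at_lo = best_x - lo < edge and lo > lo_feas
        at_hi = hi - best_x < edge and hi < hi_feas
        if not (at_lo or at_hi):
            break
        center, w = best_x, w * 4.0
    return best_ll, best_x


def _moment_start(obj) -> tuple[float, float]:
    """Weighted least-squares start for (alpha, beta), shrunk into feasibility."""
    lam0 = obj.N / obj.n.sum()
    z = obj.y / (obj.n * lam0) - 1.0
    x = np.column_stack([obj.d, obj.d2])
    w = np.sqrt(obj.n)
    coef, *_ = np.linalg.lstsq(x * w[:, None], z * w, rcond=None)
    a, b = (float(coef[0]), float(coef[1]))
    for _ in range(100):
        if np.all(obj.relative_risk(a, b) > 1.0e-8):
            break
        a *= 0.7
        b *= 0.7
    else:
        a = b = 0.0
    return a, b


def _maximize(obj, starts=None) -> tuple[float, float, float, float, bool]:
    """Maximize the profiled log-likelihood.  Returns
    ``(loglik, alpha, beta, lam, success)``.
    """
    if starts is None:
        starts = [(0.0, 0.0), _moment_start(obj)]
    best_x, best_f, success = None, np.inf, False
    for x0 in starts:
        if obj.profiled_loglik(*x0) <= INVALID_LOGLIK / 2:
            continue
        res = optimize.minimize(
            lambda x: -obj.profiled_loglik(x[0], x[1]), x0,
            method="Nelder-Mead",
            options={"xatol": 1.0e-6, "fatol": 1.0e-9, "maxiter": 800})
        if res.fun < best_f:
            best_x, best_f, success = res.x, res.fun, bool(res.success)
    if best_x is None or best_f >= -INVALID_LOGLIK / 2:
        return INVALID_LOGLIK, float("nan"), float("nan"), float("nan"), False
    a, b = float(best_x[0]), float(best_x[1])
    # coordinate polish with the same 1-D optimizer the profiler uses, so the
    # maximized likelihood is consistent with the profile curves
    for _ in range(2):
        ll, a_new = _profile_max(obj, "beta", b, center=a, window=1.0)
        if ll > INVALID_LOGLIK / 2:
            a = a_new
        ll, b_new = _profile_max(obj, "alpha", a, center=b, window=1.0)
        if ll > INVALID_LOGLIK / 2:
            b = b_new
    ll, lam = obj.profiled(a, b)
    return ll, a, b, lam, success


def _ci_side(dev, theta_hat: float, direction: int, cutoff: float,
             limit: float) -> float:
    """Locate one profile-CI bound by bracket expansion plus Brent root find."""
    # initial step from the local curvature of the deviance
    h = max(1.0e-3, 1.0e-3 * abs(theta_hat))
    d_h = dev(theta_hat + direction * h)
    curv = d_h / h ** 2 if d_h > 0 else 0.0
    step = math.sqrt(cutoff / curv) if curv > 0 else max(0.5, 0.5 * abs(theta_hat))
    step = min(max(step, 1.0e-3), limit)

    d0 = dev(theta_hat)
    if d0 > cutoff:
        # profile value at the estimate inconsistent with the maximized
        # likelihood (inner maximization failure): flag the bound unreliable
        return float("nan")

    x_in, d_in = theta_hat, d0
    for _ in range(80):
        x_out = x_in + direction * step
        clipped = False
        if direction > 0 and x_out >= limit:
            x_out, clipped = limit, True
        elif direction < 0 and x_out <= -limit:
            x_out, clipped = -limit, True
        d_out = dev(x_out)
        if d_out > cutoff:
            if d_in >= cutoff:  # pathological; give up on this side
                return float("nan")
            lo, hi = sorted((x_in, x_out))
            return float(optimize.brentq(lambda t: dev(t) - cutoff, lo, hi,
                                         xtol=1.0e-8, maxiter=200))
        if clipped:
            return direction * float("inf")
        x_in, d_in = x_out, d_out
        step *= 2.0
    return direction * float("inf")


def _profile_ci_param(obj, which: str, theta_hat: float, nuisance_hat: float,
                      llmax: float, level: float) -> tuple[float, float]:
    cutoff = float(stats.chi2.ppf(level, 1))
    limit = max(PROFILE_SEARCH_LIMIT, 3.0 * abs(theta_hat))
    holder = {"center": nuisance_hat}
    memo: dict[float, float] = {}

    def dev(theta: float) -> float:
        # memoized so that root finding sees one consistent value per point
        # despite the warm-started (stateful) nuisance search
        if theta in memo:
            return memo[theta]
        ll, x = _profile_max(obj, which, theta, center=holder["center"])
        if ll <= INVALID_LOGLIK / 2:
            out = 1.0e6
        else:
            holder["center"] = x  # profile continuation for the next call
            out = max(0.0, 2.0 * (llmax - ll))
        memo[theta] = out
        return out

    lo = _ci_side(dev, theta_hat, -1, cutoff, limit)
    holder["center"] = nuisance_hat
    hi = _ci_side(dev, theta_hat, +1, cutoff, limit)
    return (lo, hi)


def fit_objective(obj, level: float = 0.95, compute_ci: bool = True,
                  starts=None, method: str = "") -> FitResult:
    """Maximize an objective exposing the ``PoissonLQObjective`` protocol and
    attach profile-likelihood confidence intervals.

    ``starts`` overrides the default (null + moment-based) start list; the
    MCML strategy passes the regression-calibration estimate to target the
    mode the averaged likelihood shares with it.
    """
    nan_ci = (float("nan"), float("nan"))
    if obj.N <= 0:
        # zero total cases: declared non-converged rather than guessed at
        return FitResult(None, INVALID_LOGLIK, nan_ci, nan_ci, False, method)
    ll, a, b, lam, success = _maximize(obj, starts)
    if not np.isfinite(ll) or ll <= INVALID_LOGLIK / 2:
        return FitResult(None, INVALID_LOGLIK, nan_ci, nan_ci, False, method)
    params = FitParams(lam=lam, alpha=a, beta=b)
    ci_a = ci_b = nan_ci
    if compute_ci:
        ci_a = _profile_ci_param(obj, "alpha", a, b, ll, level)
        ci_b = _profile_ci_param(obj, "beta", b, a, ll, level)
    return FitResult(params, ll, ci_a, ci_b, success, method)


def fit_mle(data: GroupedDataset, start: FitParams | None = None,
            level: float = 0.95, compute_ci: bool = True) -> FitResult:
    """Maximum-likelihood fit of the grouped linear-quadratic model."""
    if np.unique(data.group_dose).size < 2:
        raise ValueError("fit requires at least 2 distinct group doses")
    starts = None
    if start is not None:
        starts = [(0.0, 0.0), (start.alpha, start.beta)]
    return fit_objective(PoissonLQObjective(data), level=level,
                         compute_ci=compute_ci, starts=starts)


def profile_ci(data: GroupedDataset, which: str,
               level: float = 0.95) -> tuple[float, float]:
    """Profile-likelihood interval for ``which`` in {"alpha", "beta"}."""
    if which not in ("alpha", "beta"):
        raise ValueError("which must be 'alpha' or 'beta'")
    obj = PoissonLQObjective(data)
    ll, a, b, _, success = _maximize(obj)
    if not success or ll <= INVALID_LOGLIK / 2:
        raise RuntimeError("maximum-likelihood fit did not converge")
    theta, nuis = (a, b) if which == "alpha" else (b, a)
    return _profile_ci_param(obj, which, theta, nuis, ll, level)
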