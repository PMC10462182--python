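"""Orchestration of dose+cancer ensembles, coverage and bias tallies.

For each scenario, m independent ensembles are simulated; each ensemble
draws one "actual" true-dose realization (which generates the cases), one
surrogate realization, and n calibration realizations, then fits every
requested correction method on the same case vector.  Coverage is the
percentage of converged fits whose 95% profile-likelihood interval contains
the generating coefficient; bias is summarised by plain arithmetic means of
the point estimates.

Random streams are pre-assigned per ensemble with ``numpy`` seed sequences:
the true-dose, calibration and case streams depend only on the master seed,
the Berkson GSDs and the ensemble index, while the surrogate stream depends
on the master seed, the classical GSDs and the ensemble index.  Fits that
ignore the surrogate dose are therefore bit-identical across scenarios that
differ only in their classical error settings.
"""

from __future__ import annotations

import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import METHOD_NAMES, CohortDefinition, ErrorScenario, StudyDesign
from .doses import (
    analytic_interindividual_correlation,
    calibration_summary,
    empirical_interindividual_correlation,
    simulate_dose_ensemble,
)
from .likelihood import FitResult
from .methods import (
    fit_extended_regression_calibration,
    fit_mcml,
    fit_regression_calibration,
    fit_unadjusted,
)
from .outcomes import case_probabilities, sample_cases

__all__ = [
    "MethodSummary",
    "ScenarioReport",
    "run_ensemble",
    "run_scenario",
    "run_scenario_grid",
    "coverage",
    "full_scenario_grid",
]

_DOMAIN_BERKSON = 1
_DOMAIN_CLASSICAL = 2
_DOMAIN_CORRELATION = 3
_STREAM_TRUE, _STREAM_CALIBRATION, _STREAM_CASES = 0, 1, 2

_CALIBRATION_METHODS = frozenset({"regcal", "ext_regcal", "mcml"})


def _gsd_key(gsd: float) -> int:
    return int(round(gsd * 1_000_000))


def _stream(master_seed: int, domain: int, pair: tuple[float, float],
            ensemble_index: int, stream_id: int) -> np.random.Generator:
    entropy = [int(master_seed), domain, _gsd_key(pair[0]), _gsd_key(pair[1]),
               int(ensemble_index), stream_id]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def run_ensemble(cohort: CohortDefinition, scenario: ErrorScenario,
                 design: StudyDesign, ensemble_index: int,
                 methods: tuple[str, ...] | None = None,
                 master_seed: int | None = None) -> dict[str, FitResult]:
    """Simulate one dose+cancer ensemble and fit every requested method.

    All methods consume the identical case vector; they differ only in the
    dose covariate / likelihood.  Per-method failures are recorded in the
    returned :class:`FitResult` rather than aborting the ensemble.
    """
    methods = tuple(methods if methods is not None else design.methods)
    unknown = set(methods) - set(METHOD_NAMES)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    seed = design.seed if master_seed is None else master_seed

    rng_true = _stream(seed, _DOMAIN_BERKSON, scenario.berkson_pair,
                       ensemble_index, _STREAM_TRUE)
    rng_cal = _stream(seed, _DOMAIN_BERKSON, scenario.berkson_pair,
                      ensemble_index, _STREAM_CALIBRATION)
    rng_case = _stream(seed, _DOMAIN_BERKSON, scenario.berkson_pair,
                       ensemble_index, _STREAM_CASES)
    rng_surr = _stream(seed, _DOMAIN_CLASSICAL, scenario.classical_pair,
                       ensemble_index, _STREAM_TRUE)

    need_cal = bool(_CALIBRATION_METHODS & set(methods))
    ensemble = simulate_dose_ensemble(
        cohort, scenario,
        n_calibration=design.n_calibration_samples if need_cal else 0,
        rng_true=rng_true, rng_calibration=rng_cal if need_cal else None,
        rng_classical=rng_surr, include_surrogate="unadjusted" in methods)

    probs, _ = case_probabilities(ensemble.true_realization.doses,
                                  design.true_alpha, design.true_beta)
    cases = sample_cases(probs, design.n_cases, rng_case)

    summary = calibration_summary(ensemble, cohort) if need_cal else None
    dispatch = {
        "unadjusted": lambda: fit_unadjusted(ensemble, cases, cohort),
        "regcal": lambda: fit_regression_calibration(
            ensemble, cases, cohort, summary=summary),
        "ext_regcal": lambda: fit_extended_regression_calibration(
            ensemble, cases, cohort, summary=summary),
        "mcml": lambda: fit_mcml(ensemble, cases, cohort, summary=summary),
    }
    return {m: dispatch[m]() for m in methods}


def coverage(results: list[FitResult], true_value: float,
             param: str = "beta") -> float:
    """Percent of converged fits whose profile CI contains ``true_value``.

    Fits that did not converge, or whose relevant CI has a NaN bound, are
    excluded.  Returns NaN when nothing usable remains.
    """
    used = covered = 0
    for r in results:
        if not r.converged:
            continue
        lo, hi = r.ci(param)
        if np.isnan(lo) or np.isnan(hi):
            continue
        used += 1
        covered += int(lo <= true_value <= hi)
    return float("nan") if used == 0 else 100.0 * covered / used


@dataclass
class MethodSummary:
    """Coverage (%) and mean coefficients for one method in one scenario."""

    method: str
    n_used: int
    n_nonconverged: int
    coverage_alpha: float
    coverage_beta: float
    mean_alpha: float
    mean_beta: float


@dataclass
class ScenarioReport:
    """Tallies for one error scenario across m ensembles."""

    scenario: ErrorScenario
    interind_corr: float
    interind_corr_analytic: float
    methods: dict[str, MethodSummary]
    fits: dict[str, list[FitResult]] | None = None


def _summarize(method: str, fits: list[FitResult],
               design: StudyDesign) -> MethodSummary:
    conv = [r for r in fits if r.converged]
    alphas = np.array([r.alpha for r in conv])
    betas = np.array([r.beta for r in conv])
    return MethodSummary(
        method=method,
        n_used=len(conv),
        n_nonconverged=len(fits) - len(conv),
        coverage_alpha=coverage(fits, design.true_alpha, "alpha"),
        coverage_beta=coverage(fits, design.true_beta, "beta"),
        mean_alpha=float(alphas.mean()) if conv else float("nan"),
        mean_beta=float(betas.mean()) if conv else float("nan"),
    )


def run_scenario(cohort: CohortDefinition, scenario: ErrorScenario,
                 design: StudyDesign, methods: tuple[str, ...] | None = None,
                 master_seed: int | None = None, keep_fits: bool = True,
                 corr_draws: int = 100_000) -> ScenarioReport:
    """Run m ensembles for one scenario and tally coverage and means."""
    methods = tuple(methods if methods is not None else design.methods)
    seed = design.seed if master_seed is None else master_seed
    fits: dict[str, list[FitResult]] = {m: [] for m in methods}
    for j in range(design.n_ensembles):
        results = run_ensemble(cohort, scenario, design, j, methods=methods,
                               master_seed=seed)
        for m in methods:
            fits[m].append(results[m])
    if scenario.has_berkson:
        rng = _stream(seed, _DOMAIN_CORRELATION, scenario.berkson_pair, 0, 0)
        emp = empirical_interindividual_correlation(scenario, rng, corr_draws)
    else:
        emp = float("nan")
    return ScenarioReport(
        scenario=scenario,
        interind_corr=emp,
        interind_corr_analytic=analytic_interindividual_correlation(scenario),
        methods={m: _summarize(m, fits[m], design) for m in methods},
        fits=fits if keep_fits else None,
    )


def full_scenario_grid() -> list[ErrorScenario]:
    """The full 20-row factorial grid of shared/unshared Berkson and
    classical GSDs used in the accompanying simulation study: four
    zero-Berkson rows followed by four Berkson blocks, each crossed with the
    four classical settings (0.2/0.5 shared x unshared)."""
    pairs = [(0.2, 0.2), (0.2, 0.5), (0.5, 0.2), (0.5, 0.5)]  # (unshared, shared)
    grid: list[ErrorScenario] = []
    for b_unshared, b_shared in [(0.0, 0.0), *pairs]:
        for c_unshared, c_shared in pairs:
            grid.append(ErrorScenario(
                gsd_berkson_shared=b_shared, gsd_berkson_unshared=b_unshared,
                gsd_classical_shared=c_shared, gsd_classical_unshared=c_unshared))
    return grid


def _scenario_columns(scenario: ErrorScenario) -> dict:
    return {
        "gsd_berkson_unshared": scenario.gsd_berkson_unshared,
        "gsd_berkson_shared": scenario.gsd_berkson_shared,
        "gsd_classical_unshared": scenario.gsd_classical_unshared,
        "gsd_classical_shared": scenario.gsd_classical_shared,
    }


def reports_to_frames(reports: list[ScenarioReport]
                      ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Coverage, mean-coefficient and per-ensemble fit tables."""
    cov_rows, mean_rows, fit_rows = [], [], []
    for report in reports:
        base = _scenario_columns(report.scenario)
        cov_row = dict(base, interind_corr=report.interind_corr,
                       interind_corr_analytic=report.interind_corr_analytic)
        mean_row = dict(base)
        for m, s in report.methods.items():
            cov_row[f"{m}_coverage_alpha"] = s.coverage_alpha
            cov_row[f"{m}_coverage_beta"] = s.coverage_beta
            mean_row[f"{m}_mean_alpha"] = s.mean_alpha
            mean_row[f"{m}_mean_beta"] = s.mean_beta
            mean_row[f"{m}_n_nonconverged"] = s.n_nonconverged
        cov_rows.append(cov_row)
        mean_rows.append(mean_row)
        if report.fits:
            for m, results in report.fits.items():
                for j, r in enumerate(results):
                    fit_rows.append(dict(
                        base, method=m, ensemble=j,
                        alpha=r.alpha, alpha_lo=r.ci_alpha[0], alpha_hi=r.ci_alpha[1],
                        beta=r.beta, beta_lo=r.ci_beta[0], beta_hi=r.ci_beta[1],
                        loglik=r.loglik, converged=r.converged))
    return pd.DataFrame(cov_rows), pd.DataFrame(mean_rows), pd.DataFrame(fit_rows)


def run_scenario_grid(scenarios: list[ErrorScenario], cohort: CohortDefinition,
                      design: StudyDesign, out_dir=None,
                      methods: tuple[str, ...] | None = None,
                      progress: bool = False) -> list[ScenarioReport]:
    """Run every scenario; optionally write coverage/means/fits CSVs and a
    run log to ``out_dir``."""
    reports = []
    for i, scenario in enumerate(scenarios):
        if progress:
            print(f"[regcal] scenario {i + 1}/{len(scenarios)}: {scenario}",
                  flush=True)
        reports.append(run_scenario(cohort, scenario, design, methods=methods))
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cov_df, mean_df, fit_df = reports_to_frames(reports)
        cov_df.to_csv(out / "coverage.csv", index=False)
        mean_df.to_csv(out / "means.csv", index=False)
        fit_df.to_csv(out / "fits.csv", index=False)
        (out / "run_log.txt").write_text(
            f"regcal {__version__}\n"
            f"python {platform.python_version()} numpy {np.__version__}\n"
            f"seed = {design.seed}\n"
            f"design = {design}\n"
            f"scenarios = {len(scenarios)}\n")
    return reports
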