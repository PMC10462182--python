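"""Case generation under the linear-quadratic relative-risk model.

A fixed total of N cases is allocated across individuals by a single
multinomial draw with probabilities proportional to the relative risk at
true dose, RR(d) = 1 + alpha*d + beta*d^2, normalized to sum to one.  The
per-individual counts are then collapsed to the dose groups (summing cases)
for grouped Poisson fitting, with the group person counts as offsets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortDefinition

__all__ = ["GroupedDataset", "case_probabilities", "sample_cases", "collapse"]


@dataclass
class GroupedDataset:
    """Per-group data for Poisson linear relative-risk fitting.

    ``group_dose``: the dose covariate used by a given method (Gy);
    ``cases``: case counts; ``offset``: person counts.
    """

    group_dose: np.ndarray
    cases: np.ndarray
    offset: np.ndarray

    def __post_init__(self) -> None:
        self.group_dose = np.asarray(self.group_dose, dtype=float)
        self.cases = np.asarray(self.cases, dtype=float)
        self.offset = np.asarray(self.offset, dtype=float)
        if not (self.group_dose.shape == self.cases.shape == self.offset.shape):
            raise ValueError("group_dose, cases and offset must have equal shape")
        if np.any(self.cases < 0):
            raise ValueError("case counts must be non-negative")
        if np.any(self.offset <= 0):
            raise ValueError("person-count offsets must be positive")

    @property
    def n_cases(self) -> float:
        return float(self.cases.sum())

    def to_csv(self, path) -> None:
        pd.DataFrame({
            "group": np.arange(1, self.group_dose.size + 1),
            "dose_gy": self.group_dose,
            "cases": self.cases,
            "persons": self.offset,
        }).to_csv(path, index=False)


def case_probabilities(true_doses: np.ndarray, alpha: float,
                       beta: float) -> tuple[np.ndarray, float]:
    """Per-individual case probabilities under the linear-quadratic model.

    Returns ``(probabilities, lam)`` where ``lam`` is the normalizing
    constant making ``lam * RR(d_i)`` sum to one.  Raises if any relative
    risk is non-positive.
    """
    d = np.asarray(true_doses, dtype=float)
    rr = 1.0 + alpha * d + beta * d * d
    if np.any(rr <= 0):
        bad = d[np.argmin(rr)]
        raise ValueError(
            f"non-positive relative risk at dose {bad:.6g} Gy "
            f"(alpha={alpha}, beta={beta})")
    total = rr.sum()
    lam = 1.0 / total
    probs = rr / total
    probs /= probs.sum()  # exact renormalization against rounding
    return probs, float(lam)


def sample_cases(probabilities: np.ndarray, n_cases: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Multinomial allocation of ``n_cases`` cases over individuals."""
    return rng.multinomial(int(n_cases), np.asarray(probabilities, dtype=float))


def collapse(case_counts: np.ndarray, group_ids: np.ndarray,
             dose_covariate: np.ndarray,
             cohort: CohortDefinition) -> GroupedDataset:
    """Sum per-individual case counts into groups and attach a dose covariate."""
    k = cohort.n_groups
    cases = np.bincount(np.asarray(group_ids),
                        weights=np.asarray(case_counts, dtype=float), minlength=k)
    dose = np.asarray(dose_covariate, dtype=float)
    if dose.shape != (k,):
        raise ValueError(f"dose covariate must have shape ({k},), got {dose.shape}")
    return GroupedDataset(group_dose=dose, cases=cases,
                          offset=cohort.person_count_array())
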