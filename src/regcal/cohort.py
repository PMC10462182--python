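"""Cohort structure, dose-error scenarios and study configuration.

The synthetic cohort mimics the grouped structure of the Japanese atomic
bomb survivor Life Span Study (LSS): a handful of dose groups, each with a
central dose estimate in Gy and a person count that serves as the Poisson
offset in the grouped relative-risk fits.  Study configuration is read from
flat key-value "steering" files (one ``key = value`` per line, ``#``
comments), echoing the steering-file style of classic Fortran dose-fitting
programs while remaining trivially parseable.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CohortDefinition",
    "ErrorScenario",
    "StudyDesign",
    "SteeringError",
    "METHOD_NAMES",
    "lss_cohort",
    "load_cohort_csv",
    "write_cohort_csv",
    "load_steering",
    "write_steering",
]

#: Stable identifiers for the four correction strategies.
METHOD_NAMES = ("unadjusted", "regcal", "ext_regcal", "mcml")


class SteeringError(ValueError):
    """Raised for malformed or invalid steering-file content."""


@dataclass(frozen=True)
class CohortDefinition:
    """Dose groups with central dose estimates (Gy) and person counts.

    Groups must be in strictly increasing central-dose order; at least two
    groups are required for a dose-response fit to be identifiable.
    """

    group_ids: tuple[int, ...]
    central_doses: tuple[float, ...]
    n_persons: tuple[int, ...]

    def __post_init__(self) -> None:
        k = len(self.central_doses)
        if not (len(self.group_ids) == len(self.n_persons) == k):
            raise ValueError("group_ids, central_doses and n_persons must have equal length")
        if k < 2:
            raise ValueError("a dose-response fit needs at least 2 dose groups")
        doses = np.asarray(self.central_doses, dtype=float)
        if np.any(doses <= 0):
            raise ValueError("all central doses must be positive")
        if np.any(np.diff(doses) <= 0):
            raise ValueError("central doses must be strictly increasing across groups")
        if any(int(n) < 1 for n in self.n_persons):
            raise ValueError("every group must contain at least 1 person")

    @classmethod
    def from_rows(cls, rows) -> "CohortDefinition":
        """Build from an iterable of ``(group_id, central_dose_gy, n_persons)``."""
        gids, doses, counts = zip(*rows)
        return cls(tuple(int(g) for g in gids),
                   tuple(float(d) for d in doses),
                   tuple(int(n) for n in counts))

    @property
    def n_groups(self) -> int:
        return len(self.central_doses)

    @property
    def total_persons(self) -> int:
        return int(sum(self.n_persons))

    def central_dose_array(self) -> np.ndarray:
        return np.asarray(self.central_doses, dtype=float)

    def person_count_array(self) -> np.ndarray:
        return np.asarray(self.n_persons, dtype=float)

    def individual_group_index(self) -> np.ndarray:
        """0-based group index per individual, individuals ordered by group."""
        return _individual_group_index(self.n_persons)

    def group_start_offsets(self) -> np.ndarray:
        """Start index of each group's block in the per-individual ordering."""
        counts = np.asarray(self.n_persons, dtype=np.intp)
        return np.concatenate(([0], np.cumsum(counts)[:-1]))


@functools.lru_cache(maxsize=128)
def _individual_group_index(n_persons: tuple[int, ...]) -> np.ndarray:
    idx = np.repeat(np.arange(len(n_persons), dtype=np.intp),
                    np.asarray(n_persons, dtype=np.intp))
    idx.setflags(write=False)
    return idx


@dataclass(frozen=True)
class ErrorScenario:
    """Lognormal geometric standard deviations of the four error components.

    Each GSD is the sigma of the underlying normal on the log scale
    (0.2 ≡ "20%").  Berkson components perturb true dose around the group
    central estimate; classical components perturb the surrogate (observed)
    dose.  "Shared" multipliers are common to the whole cohort within one
    realization, "unshared" ones are drawn independently per individual.
    """

    gsd_berkson_shared: float = 0.0
    gsd_berkson_unshared: float = 0.0
    gsd_classical_shared: float = 0.0
    gsd_classical_unshared: float = 0.0

    def __post_init__(self) -> None:
        for name in ("gsd_berkson_shared", "gsd_berkson_unshared",
                     "gsd_classical_shared", "gsd_classical_unshared"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")

    @property
    def berkson_pair(self) -> tuple[float, float]:
        """(shared, unshared) Berkson GSDs."""
        return (self.gsd_berkson_shared, self.gsd_berkson_unshared)

    @property
    def classical_pair(self) -> tuple[float, float]:
        return (self.gsd_classical_shared, self.gsd_classical_unshared)

    @property
    def has_berkson(self) -> bool:
        return self.gsd_berkson_shared > 0 or self.gsd_berkson_unshared > 0

    @property
    def has_classical(self) -> bool:
        return self.gsd_classical_shared > 0 or self.gsd_classical_unshared > 0

    @property
    def is_error_free(self) -> bool:
        return not (self.has_berkson or self.has_classical)


@dataclass(frozen=True)
class StudyDesign:
    """Outcome-model and simulation-design parameters.

    Defaults reproduce the reference simulation study: N=250 cases per
    ensemble, m=500 dose+cancer ensembles, n=1000 calibration dose samples,
    true excess relative risk coefficients alpha=0.25/Gy, beta=2/Gy^2.
    """

    n_cases: int = 250
    n_ensembles: int = 500
    n_calibration_samples: int = 1000
    true_alpha: float = 0.25
    true_beta: float = 2.0
    seed: int = 1
    methods: tuple[str, ...] = METHOD_NAMES

    def __post_init__(self) -> None:
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")
        if self.n_ensembles < 1:
            raise ValueError("n_ensembles must be >= 1")
        if self.n_calibration_samples < 1:
            raise ValueError("n_calibration_samples must be >= 1")
        if self.seed < 0:
            raise ValueError("seed must be a non-negative integer")
        unknown = set(self.methods) - set(METHOD_NAMES)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}; valid: {METHOD_NAMES}")


def lss_cohort() -> CohortDefinition:
    """The built-in LSS-like 5-group cohort used throughout the study.

    Central doses (Gy): 0.01, 0.1, 0.5, 1.5, 2 with scaled person counts
    2591, 334, 438, 102, 6 (3471 persons in total).
    """
    return CohortDefinition(
        group_ids=(1, 2, 3, 4, 5),
        central_doses=(0.01, 0.1, 0.5, 1.5, 2.0),
        n_persons=(2591, 334, 438, 102, 6),
    )


# ---------------------------------------------------------------------------
# Steering files
# ---------------------------------------------------------------------------

_SCENARIO_KEYS = ("gsd_berkson_shared", "gsd_berkson_unshared",
                  "gsd_classical_shared", "gsd_classical_unshared")
_DESIGN_FLOAT_KEYS = ("true_alpha", "true_beta")
_DESIGN_INT_KEYS = ("n_cases", "n_ensembles", "n_calibration_samples", "seed")
_ALL_KEYS = _SCENARIO_KEYS + _DESIGN_FLOAT_KEYS + _DESIGN_INT_KEYS + ("methods", "cohort_csv")


def _parse_lines(text: str, source: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise SteeringError(f"{source}:{lineno}: expected 'key = value', got {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        if key not in _ALL_KEYS:
            raise SteeringError(f"{source}:{lineno}: unknown key {key!r}")
        if key in out:
            raise SteeringError(f"{source}:{lineno}: duplicate key {key!r}")
        out[key] = value
    return out


def load_steering(path) -> tuple[CohortDefinition, ErrorScenario, StudyDesign]:
    """Read a flat key-value steering file.

    Unspecified keys fall back to the study defaults (error-free scenario,
    :func:`lss_cohort`, default :class:`StudyDesign`).  A ``cohort_csv`` key
    may point to a cohort override CSV (header ``group,central_dose_gy,
    n_persons``), resolved relative to the steering file.
    """
    path = Path(path)
    entries = _parse_lines(path.read_text(), str(path))

    def _number(key: str, caster):
        try:
            return caster(entries[key])
        except ValueError as exc:
            raise SteeringError(f"{path}: key {key!r}: {exc}") from exc

    scen_kwargs = {k: _number(k, float) for k in _SCENARIO_KEYS if k in entries}
    design_kwargs: dict = {k: _number(k, float) for k in _DESIGN_FLOAT_KEYS if k in entries}
    design_kwargs.update({k: _number(k, int) for k in _DESIGN_INT_KEYS if k in entries})
    if "methods" in entries:
        design_kwargs["methods"] = tuple(
            m.strip() for m in entries["methods"].split(",") if m.strip())

    try:
        scenario = ErrorScenario(**scen_kwargs)
        design = StudyDesign(**design_kwargs)
    except ValueError as exc:
        raise SteeringError(f"{path}: {exc}") from exc

    if "cohort_csv" in entries:
        csv_path = Path(entries["cohort_csv"])
        if not csv_path.is_absolute():
            csv_path = path.parent / csv_path
        cohort = load_cohort_csv(csv_path)
    else:
        cohort = lss_cohort()
    return cohort, scenario, design


def write_steering(path, scenario: ErrorScenario, design: StudyDesign,
                   cohort: CohortDefinition | None = None) -> None:
    """Write a steering file that :func:`load_steering` round-trips exactly.

    A non-default cohort is written as a sibling CSV referenced through the
    ``cohort_csv`` key.
    """
    path = Path(path)
    lines = ["# regcal steering file"]
    for key in _SCENARIO_KEYS:
        lines.append(f"{key} = {getattr(scenario, key)!r}")
    for key in _DESIGN_INT_KEYS:
        lines.append(f"{key} = {getattr(design, key)}")
    for key in _DESIGN_FLOAT_KEYS:
        lines.append(f"{key} = {getattr(design, key)!r}")
    lines.append(f"methods = {','.join(design.methods)}")
    if cohort is not None and cohort != lss_cohort():
        csv_path = path.with_suffix(path.suffix + ".cohort.csv")
        write_cohort_csv(csv_path, cohort)
        lines.append(f"cohort_csv = {csv_path.name}")
    path.write_text("\n".join(lines) + "\n")


def load_cohort_csv(path) -> CohortDefinition:
    """Read a cohort from CSV with header ``group,central_dose_gy,n_persons``."""
    df = pd.read_csv(path)
    required = {"group", "central_dose_gy", "n_persons"}
    missing = required - set(df.columns)
    if missing:
        raise SteeringError(f"{path}: cohort CSV missing columns {sorted(missing)}")
    df = df.sort_values("group")
    return CohortDefinition.from_rows(
        df[["group", "central_dose_gy", "n_persons"]].itertuples(index=False))


def write_cohort_csv(path, cohort: CohortDefinition) -> None:
    pd.DataFrame({
        "group": cohort.group_ids,
        "central_dose_gy": cohort.central_doses,
        "n_persons": cohort.n_persons,
    }).to_csv(path, index=False)
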