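"""Virtual patient roster and cohort generation.

The reference roster mirrors the 33 virtual subjects (11 adults, 11
adolescents, 11 children; the eleventh of each cohort is the simulator's
built-in "average" subject) through the only patient quantity the analysis
depends on: the personal safe CC-error limit ``dCHO_max``.  Individual
ICR/ISF pairs of the proprietary simulator population are not published, so
each patient is assigned the cohort-mean ICR and the ISF that reproduces the
published ``dCHO_max`` exactly through the limit formula
(``isf = icr * 30 / dCHO_max`` under the standard 70/100/180 band).

``generate_cohort`` draws arbitrary-size synthetic cohorts from the published
cohort-level ICR/ISF summary statistics (independent truncated normals),
for property tests and power exploration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dosing import STANDARD_THRESHOLDS, GlucoseThresholds, TherapyParams, compute_delta_cho_max

__all__ = [
    "VirtualPatient",
    "CohortStats",
    "COHORT_STATS",
    "COHORT_BASAL_RATES",
    "load_reference_roster",
    "summarize_roster",
    "generate_cohort",
    "roster_to_csv",
    "roster_from_csv",
]

#: Published per-patient safe limits (grams), rows 1-10 plus the "Avg." subject.
_REFERENCE_DELTA_CHO_MAX: dict[str, list[float]] = {
    "adult": [13.11, 16.02, 12.42, 11.11, 8.41, 10.42, 12.78, 7.12, 11.09, 10.46, 11.03],
    "adolescent": [9.90, 7.72, 12.76, 6.42, 5.50, 10.06, 16.55, 7.04, 7.95, 8.52, 8.63],
    "child": [5.48, 8.03, 9.58, 5.37, 6.87, 7.40, 5.55, 5.70, 5.89, 10.06, 6.41],
}


@dataclass(frozen=True)
class CohortStats:
    """Cohort-level ICR/ISF summary statistics (mean +/- SD)."""

    cohort: str
    icr_mean: float
    icr_sd: float
    isf_mean: float
    isf_sd: float

    def __post_init__(self) -> None:
        if min(self.icr_mean, self.icr_sd, self.isf_mean, self.isf_sd) <= 0.0:
            raise ValueError("cohort statistics must be strictly positive")


#: Published cohort ICR (g/U) and ISF (mg/dL/U) summaries.
COHORT_STATS: dict[str, CohortStats] = {
    "adult": CohortStats("adult", 15.9, 4.5, 42.2, 8.0),
    "adolescent": CohortStats("adolescent", 17.6, 7.0, 57.1, 13.8),
    "child": CohortStats("child", 26.5, 5.3, 117.8, 27.7),
}

#: Default basal infusion (U/h) per cohort; the trial re-derives each
#: patient's steady-state basal during calibration, these seed that search.
COHORT_BASAL_RATES: dict[str, float] = {"adult": 1.2, "adolescent": 1.1, "child": 0.6}


@dataclass(frozen=True)
class VirtualPatient:
    """One virtual subject: identity, therapy parameters, safe limit and
    (once calibrated) the metabolic parameters of the glucose simulator."""

    id: str
    cohort: str
    therapy: TherapyParams
    delta_cho_max: float
    basal_rate: float
    model_params: object | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.cohort not in COHORT_STATS:
            raise ValueError(f"unknown cohort {self.cohort!r}")
        implied = compute_delta_cho_max(self.therapy, STANDARD_THRESHOLDS)
        if abs(implied - self.delta_cho_max) > 0.01:
            raise ValueError(
                f"{self.id}: delta_cho_max {self.delta_cho_max} inconsistent with "
                f"therapy (implies {implied:.4f})"
            )

    def with_model_params(self, params: object) -> "VirtualPatient":
        return replace(self, model_params=params)


def _subject_id(cohort: str, index: int) -> str:
    label = {"adult": "Adult", "adolescent": "Adolescent", "child": "Child"}[cohort]
    return f"{label}#{'Avg' if index == 10 else index + 1}"


def load_reference_roster(
    thresholds: GlucoseThresholds = STANDARD_THRESHOLDS,
) -> list[VirtualPatient]:
    """The fixed 33-subject reference roster.

    Each patient's ICR is the cohort mean and the ISF is back-derived so the
    limit formula round-trips the published ``dCHO_max`` exactly.
    """
    margin = min(thresholds.g_high - thresholds.g_target, thresholds.g_target - thresholds.g_low)
    roster = []
    for cohort, limits in _REFERENCE_DELTA_CHO_MAX.items():
        icr = COHORT_STATS[cohort].icr_mean
        for i, dmax in enumerate(limits):
            therapy = TherapyParams(icr=icr, isf=icr * margin / dmax)
            roster.append(
                VirtualPatient(
                    id=_subject_id(cohort, i),
                    cohort=cohort,
                    therapy=therapy,
                    delta_cho_max=dmax,
                    basal_rate=COHORT_BASAL_RATES[cohort],
                )
            )
    return roster


def summarize_roster(roster: Sequence[VirtualPatient]) -> dict[str, float]:
    """Sample statistics (mean, sd with n-1, max, min) of ``delta_cho_max``."""
    if len(roster) == 0:
        raise ValueError("roster is empty")
    values = np.array([p.delta_cho_max for p in roster])
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    return {
        "n": len(values),
        "mean": float(values.mean()),
        "sd": sd,
        "max": float(values.max()),
        "min": float(values.min()),
    }


def generate_cohort(
    stats: CohortStats,
    n: int,
    seed: int | np.random.Generator,
    thresholds: GlucoseThresholds = STANDARD_THRESHOLDS,
) -> list[VirtualPatient]:
    """Draw ``n`` synthetic patients from cohort-level ICR/ISF statistics.

    ICR and ISF are drawn independently (no published correlation) from
    normal laws rejection-truncated to mean +/- 3 SD and to strictly positive
    values, then the safe limit follows from the limit formula.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def draw(mean: float, sd: float, size: int) -> np.ndarray:
        out = np.empty(size)
        filled = 0
        while filled < size:
            cand = rng.normal(mean, sd, size=size - filled)
            ok = cand[(np.abs(cand - mean) <= 3.0 * sd) & (cand > 0.0)]
            out[filled : filled + len(ok)] = ok
            filled += len(ok)
        return out

    icrs = draw(stats.icr_mean, stats.icr_sd, n)
    isfs = draw(stats.isf_mean, stats.isf_sd, n)
    patients = []
    for i in range(n):
        therapy = TherapyParams(icr=float(icrs[i]), isf=float(isfs[i]))
        patients.append(
            VirtualPatient(
                id=f"{stats.cohort.capitalize()}.syn#{i + 1}",
                cohort=stats.cohort,
                therapy=therapy,
                delta_cho_max=compute_delta_cho_max(therapy, thresholds),
                basal_rate=COHORT_BASAL_RATES[stats.cohort],
            )
        )
    return patients


_CSV_COLUMNS = ["id", "cohort", "icr_g_per_U", "isf_mgdl_per_U", "delta_cho_max_g", "basal_U_per_h"]


def roster_to_csv(roster: Iterable[VirtualPatient], path_or_buf) -> None:
    df = pd.DataFrame(
        [
            {
                "id": p.id,
                "cohort": p.cohort,
                "icr_g_per_U": p.therapy.icr,
                "isf_mgdl_per_U": p.therapy.isf,
                "delta_cho_max_g": p.delta_cho_max,
                "basal_U_per_h": p.basal_rate,
            }
            for p in roster
        ],
        columns=_CSV_COLUMNS,
    )
    df.to_csv(path_or_buf, index=False)


def roster_from_csv(path_or_buf) -> list[VirtualPatient]:
    df = pd.read_csv(path_or_buf)
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"roster CSV missing columns: {sorted(missing)}")
    return [
        VirtualPatient(
            id=row.id,
            cohort=row.cohort,
            therapy=TherapyParams(icr=row.icr_g_per_U, isf=row.isf_mgdl_per_U),
            delta_cho_max=row.delta_cho_max_g,
            basal_rate=row.basal_U_per_h,
        )
        for row in df.itertuples()
    ]
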