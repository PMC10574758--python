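"""Paired nonparametric bootstrap inference and subject filtering.

Each error experiment is compared with the error-free control on a
per-subject paired basis: the unit of resampling is the subject-level
difference ``d_i = metric_i(experiment) - metric_i(control)``.  The interval
is the percentile interval of the resampled mean and the two-sided p-value
doubles the smaller tail probability of the resampled mean around zero.

Subjects whose control TIR falls below 90% are excluded before inference (to
keep glucose-regulation problems unrelated to carb counting out of the
comparison), and two analysis strata are formed: subjects always in range
(TIR = 100%) and subjects at least 90% in range.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "PairedSample",
    "BootResult",
    "exclude_subjects",
    "shapiro_wilk_gate",
    "bootstrap_paired_diff",
]


@dataclass(frozen=True)
class PairedSample:
    """Per-subject metric values under an experiment and under the control,
    aligned by subject id."""

    subject_ids: tuple[str, ...]
    values_experiment: np.ndarray
    values_control: np.ndarray

    def __post_init__(self) -> None:
        ve = np.asarray(self.values_experiment, float)
        vc = np.asarray(self.values_control, float)
        if not (len(self.subject_ids) == len(ve) == len(vc)):
            raise ValueError("subject ids and value arrays must have equal length")
        object.__setattr__(self, "values_experiment", ve)
        object.__setattr__(self, "values_control", vc)

    @property
    def differences(self) -> np.ndarray:
        return self.values_experiment - self.values_control


@dataclass(frozen=True)
class BootResult:
    """Bootstrap estimate of a mean paired difference (percentage points)."""

    mean_diff: float
    ci_low: float
    ci_high: float
    p_value: float
    n_resamples: int
    seed: int

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.mean_diff + 1e-12 and self.mean_diff <= self.ci_high + 1e-12):
            raise ValueError("point estimate must lie inside its percentile interval")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value out of [0, 1]")


def exclude_subjects(
    control_records: Mapping[str, float], min_tir: float = 90.0
) -> dict[str, list[str]]:
    """Apply the control-scenario exclusion rule and form analysis strata.

    ``control_records`` maps subject id -> control (error-free) TIR %.
    Returns ``retained`` (TIR >= min_tir), plus the strata ``tir_100``
    (always in range) and ``tir_90`` (the retained set itself).
    """
    retained = [sid for sid, tir in control_records.items() if tir >= min_tir]
    always = [sid for sid, tir in control_records.items() if tir >= 100.0 - 1e-9]
    return {"retained": retained, "tir_100": always, "tir_90": retained}


def shapiro_wilk_gate(sample: Sequence[float], alpha: float = 0.05) -> dict[str, float | bool]:
    """Shapiro-Wilk normality diagnostic (the pipeline proceeds with the
    bootstrap regardless of the verdict)."""
    x = np.asarray(sample, float)
    if len(x) < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 observations")
    if np.ptp(x) == 0.0:
        raise ValueError("degenerate (constant) sample")
    statistic, p_value = stats.shapiro(x)
    return {"statistic": float(statistic), "p_value": float(p_value), "normal": bool(p_value > alpha)}


def bootstrap_paired_diff(
    sample: PairedSample,
    n_resamples: int = 10_000,
    seed: int = 0,
    level: float = 0.95,
) -> BootResult:
    """Percentile-bootstrap CI and two-sided test for a mean paired difference.

    Subjects are resampled with replacement; the p-value is
    ``2 * min(P*(mean* <= 0), P*(mean* >= 0))`` clipped to [0, 1].
    """
    d = sample.differences
    n = len(d)
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_resamples, n))
    means = d[idx].mean(axis=1)
    alpha = 1.0 - level
    ci_low, ci_high = np.quantile(means, [alpha / 2.0, 1.0 - alpha / 2.0])
    p = 2.0 * min(np.mean(means <= 0.0), np.mean(means >= 0.0))
    return BootResult(
        mean_diff=float(d.mean()),
        ci_low=float(min(ci_low, d.mean())),
        ci_high=float(max(ci_high, d.mean())),
        p_value=float(min(p, 1.0)),
        n_resamples=n_resamples,
        seed=seed,
    )
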