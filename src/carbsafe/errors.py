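"""Per-experiment carbohydrate-counting error distributions.

Each experiment E1..E9 prescribes an interval of CC errors expressed in
multiples of the patient's personal limit ``dCHO_max``; the interval is read
as the central 95% of a normal law, so

    mu    = midpoint * dCHO_max          (grams)
    sigma = half-width * dCHO_max / z    (grams),  z = Phi^-1(0.975)

E0 is the error-free control (point mass at zero).  Draws are *not*
truncated: by construction 5% of meals fall outside the printed interval.

Experiment design (interval in multiples of dCHO_max):

    E1 [-1, 1]        symmetric, at the limit
    E2 [0, 1]         underestimation within the safe interval
    E3 [-1, 0]        overestimation within the safe interval
    E4 [0.5, 1]       underestimation, upper half of the safe interval
    E5 [-1, -0.5]     overestimation, mirror of E4
    E6 [0.95, 1.05]   underestimation centered on the limit (50% outside)
    E7 [-1.05, -0.95] overestimation centered on the limit
    E8 [1, 1.5]       underestimation beyond the limit (97.5% outside)
    E9 [-1.5, -1]     overestimation beyond the limit
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = [
    "ErrorSpec",
    "EXPERIMENT_INTERVALS",
    "EXPERIMENT_IDS",
    "Z_95",
    "build_error_spec",
    "sample_errors",
    "fraction_outside_safe",
]

#: Exact 97.5% standard-normal quantile used to map 95% intervals to sigma.
Z_95: float = 1.959964

#: Interval endpoints in multiples of dCHO_max, keyed by experiment id.
EXPERIMENT_INTERVALS: dict[str, tuple[float, float]] = {
    "E0": (0.0, 0.0),
    "E1": (-1.0, 1.0),
    "E2": (0.0, 1.0),
    "E3": (-1.0, 0.0),
    "E4": (0.5, 1.0),
    "E5": (-1.0, -0.5),
    "E6": (0.95, 1.05),
    "E7": (-1.05, -0.95),
    "E8": (1.0, 1.5),
    "E9": (-1.5, -1.0),
}

EXPERIMENT_IDS: tuple[str, ...] = tuple(EXPERIMENT_INTERVALS)


@dataclass(frozen=True)
class ErrorSpec:
    """One experiment's CC-error law: N(mu, sigma^2) in grams."""

    experiment_id: str
    lower_mult: float
    upper_mult: float
    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.lower_mult > self.upper_mult:
            raise ValueError("lower_mult must be <= upper_mult")
        if self.sigma < 0.0:
            raise ValueError("sigma must be >= 0")


def build_error_spec(experiment_id: str, delta_cho_max: float) -> ErrorSpec:
    """Scale an experiment's interval by a patient's ``delta_cho_max`` (g)."""
    if experiment_id not in EXPERIMENT_INTERVALS:
        raise ValueError(
            f"unknown experiment {experiment_id!r}; expected one of {sorted(EXPERIMENT_INTERVALS)}"
        )
    if delta_cho_max <= 0.0:
        raise ValueError(f"delta_cho_max must be > 0, got {delta_cho_max}")
    lo, hi = EXPERIMENT_INTERVALS[experiment_id]
    mu = 0.5 * (lo + hi) * delta_cho_max
    sigma = 0.5 * (hi - lo) * delta_cho_max / Z_95
    return ErrorSpec(experiment_id, lo, hi, mu, sigma)


def sample_errors(
    spec: ErrorSpec, n: int, seed: int | np.random.Generator | np.random.SeedSequence
) -> np.ndarray:
    """``n`` independent CC errors (grams) from the spec's normal law.

    Untruncated on purpose; the control spec (sigma = 0) returns exact
    constants.  Reproducible given the seed (or an already-split Generator).
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if spec.sigma == 0.0:
        return np.full(n, spec.mu)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.normal(spec.mu, spec.sigma, size=n)


def fraction_outside_safe(spec: ErrorSpec, delta_cho_max: float) -> float:
    """Probability that a drawn CC error falls outside [-dCHO_max, dCHO_max].

    Closed form ``1 - [Phi((d - mu)/sigma) - Phi((-d - mu)/sigma)]``.  For the
    degenerate control (sigma = 0) the point mass is either inside or outside.
    By design this is 0.05 for E1, exactly 0.5 for E6/E7 (the mean sits on the
    interval edge) and Phi(z) = 0.975 for E8/E9.
    """
    if delta_cho_max <= 0.0:
        raise ValueError(f"delta_cho_max must be > 0, got {delta_cho_max}")
    if spec.sigma == 0.0:
        return 0.0 if abs(spec.mu) <= delta_cho_max else 1.0
    inside = norm.cdf((delta_cho_max - spec.mu) / spec.sigma) - norm.cdf(
        (-delta_cho_max - spec.mu) / spec.sigma
    )
    return float(1.0 - inside)
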