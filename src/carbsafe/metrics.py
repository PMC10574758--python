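"""Range-occupancy outcome metrics for CGM traces.

TIR/TAR/TBR partition every sample exactly once: time-in-range is the closed
interval [70, 180] mg/dL, above-range is strictly > 180 and below-range
strictly < 70, so ``tir + tar + tbr == 100`` by construction.  Percentages
are sample counts over total samples -- valid because the CGM grid is
uniform.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable

import numpy as np

from .simulator import GlucoseTrace

__all__ = ["OutcomeRecord", "compute_metrics", "count_meals"]

METRIC_NAMES = ("tir", "tar", "tbr", "pct_below_50", "pct_above_300")


@dataclass(frozen=True)
class OutcomeRecord:
    """Per-trace glycemic outcome percentages."""

    tir: float  # % of time in [70, 180] mg/dL
    tar: float  # % of time > 180 mg/dL
    tbr: float  # % of time < 70 mg/dL
    pct_below_50: float  # % of time < 50 mg/dL
    pct_above_300: float  # % of time > 300 mg/dL

    def __post_init__(self) -> None:
        vals = asdict(self)
        for name, v in vals.items():
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} out of [0, 100]: {v}")
        if abs(self.tir + self.tar + self.tbr - 100.0) > 1e-9:
            raise ValueError("tir + tar + tbr must equal 100")
        if self.pct_below_50 > self.tbr + 1e-12 or self.pct_above_300 > self.tar + 1e-12:
            raise ValueError("extreme-range percentages exceed their parent class")

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def compute_metrics(
    trace: GlucoseTrace, g_low: float = 70.0, g_high: float = 180.0
) -> OutcomeRecord:
    """Occupancy percentages of a trace; range boundaries are inclusive."""
    g = trace.g
    n = len(g)
    if n == 0:
        raise ValueError("empty trace")
    pct = lambda mask: 100.0 * np.count_nonzero(mask) / n
    return OutcomeRecord(
        tir=pct((g >= g_low) & (g <= g_high)),
        tar=pct(g > g_high),
        tbr=pct(g < g_low),
        pct_below_50=pct(g < 50.0),
        pct_above_300=pct(g > 300.0),
    )


def count_meals(schedule: Iterable, days: int) -> int:
    """Total meals over the horizon: meals per day times days."""
    per_day = len(list(schedule))
    if days < 0:
        raise ValueError("days must be >= 0")
    return per_day * days
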