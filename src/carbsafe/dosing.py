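"""Bolus-calculator arithmetic and the personalized safe carb-counting error limit.

The three closed-form quantities that everything else in the package is built
on:

* the standard prandial bolus
  ``B = CHO/ICR + (G - G_T)/ISF - IOB`` (clamped at 0 U),
* the personalized maximum admissible carbohydrate-counting (CC) error
  ``dCHO_max = (ICR/ISF) * min(G_H - G_T, G_T - G_L)``,
* the error-corrupted carbohydrate estimate ``CHO = CHO_true - dCHO``
  (clamped at 0 g).

``dCHO_max`` is the largest absolute error (grams) a patient can make when
counting carbohydrates such that the resulting bolus error still keeps the
2-3 h postprandial glucose inside the 70-180 mg/dL target band.  It is a pure
function of the patient's therapy parameters: a patient covering many grams
per unit of insulin (large ICR) with low insulin sensitivity (small ISF) can
afford larger counting mistakes.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "GlucoseThresholds",
    "TherapyParams",
    "BolusInputs",
    "STANDARD_THRESHOLDS",
    "compute_delta_cho_max",
    "compute_bolus",
    "estimate_cho",
]


@dataclass(frozen=True)
class GlucoseThresholds:
    """Glycemic band: hypoglycemia threshold, target, hyperglycemia threshold.

    All in mg/dL; must satisfy ``0 < g_low < g_target < g_high``.
    """

    g_low: float = 70.0
    g_target: float = 100.0
    g_high: float = 180.0

    def __post_init__(self) -> None:
        if not (0.0 < self.g_low < self.g_target < self.g_high):
            raise ValueError(
                f"thresholds must satisfy 0 < g_low < g_target < g_high, "
                f"got ({self.g_low}, {self.g_target}, {self.g_high})"
            )


#: ADA/EASD consensus band: 70 / 100 / 180 mg/dL.
STANDARD_THRESHOLDS = GlucoseThresholds(70.0, 100.0, 180.0)


@dataclass(frozen=True)
class TherapyParams:
    """A patient's insulin-therapy parameters.

    icr
        Insulin-to-carbohydrate ratio, g of carbohydrate covered by 1 U (g/U).
    isf
        Insulin sensitivity factor, glucose drop produced by 1 U (mg/dL/U).
    """

    icr: float
    isf: float

    def __post_init__(self) -> None:
        if not (self.icr > 0.0 and self.isf > 0.0):
            raise ValueError(f"icr and isf must be positive, got ({self.icr}, {self.isf})")


@dataclass(frozen=True)
class BolusInputs:
    """Inputs to one prandial bolus: estimated carbs (g), preprandial glucose
    (mg/dL) and insulin still on board from earlier boluses (U)."""

    cho_estimated: float
    g_preprandial: float
    iob: float = 0.0

    def __post_init__(self) -> None:
        if self.cho_estimated < 0.0:
            raise ValueError(f"cho_estimated must be >= 0, got {self.cho_estimated}")
        if self.g_preprandial <= 0.0:
            raise ValueError(f"g_preprandial must be > 0, got {self.g_preprandial}")
        if self.iob < 0.0:
            raise ValueError(f"iob must be >= 0, got {self.iob}")


def compute_delta_cho_max(
    therapy: TherapyParams, thresholds: GlucoseThresholds = STANDARD_THRESHOLDS
) -> float:
    """Personalized maximum admissible CC error, in grams.

    ``(ICR/ISF) * min(G_H - G_T, G_T - G_L)``: the bolus error produced by
    miscounting ``dCHO_max`` grams shifts the settled postprandial glucose by
    exactly the distance from target to the nearer band edge.  With the
    standard 70/100/180 band the hypoglycemia side binds and the result is
    ``30 * ICR/ISF``.
    """
    margin = min(thresholds.g_high - thresholds.g_target, thresholds.g_target - thresholds.g_low)
    return therapy.icr / therapy.isf * margin


def compute_bolus(
    inputs: BolusInputs,
    therapy: TherapyParams,
    thresholds: GlucoseThresholds = STANDARD_THRESHOLDS,
) -> float:
    """Prandial bolus in U: meal term + correction term - insulin on board.

    The raw value is clamped at 0 U; insulin cannot be removed, so a low
    preprandial glucose on a small meal simply yields no bolus.
    """
    raw = (
        inputs.cho_estimated / therapy.icr
        + (inputs.g_preprandial - thresholds.g_target) / therapy.isf
        - inputs.iob
    )
    return max(0.0, raw)


def estimate_cho(cho_true: float, delta_cho: float) -> float:
    """Carbohydrate estimate entered in the bolus calculator, in grams.

    ``max(0, cho_true - delta_cho)``: a positive error is an underestimation
    (the patient counts fewer grams than eaten, under-dosing insulin), a
    negative error an overestimation.  Clamped at zero grams: no patient
    enters a negative meal.
    """
    if cho_true < 0.0:
        raise ValueError(f"cho_true must be >= 0, got {cho_true}")
    return max(0.0, cho_true - delta_cho)
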