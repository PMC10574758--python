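"""Orchestration of the 90-day in-silico trial.

``CarbCountingTrial`` wires the whole study together: calibrate each virtual
patient, build the five-meal daily schedule, sample one carb-counting error
per meal from the experiment's distribution, dose every meal with the bolus
calculator (preprandial glucose read from the simulation at mealtime, IOB
zero), integrate the 90-day glucose trace, reduce it to range-occupancy
outcomes, and compare every error experiment against the error-free control
with the paired bootstrap.

The trial clock starts at the first meal (08:00 of day 1); the fifth meal of
each day falls at 00:00 of the following calendar day, so every trial day
carries exactly five meals and the default 90-day horizon carries 450.

Randomness: a single master seed is split into one independent sub-stream
per (experiment, patient) for the error draws and one per comparison for the
bootstrap, so any slice of the study can be re-run in isolation and the full
run is byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .bootstrap import PairedSample, bootstrap_paired_diff, exclude_subjects
from .cohort import VirtualPatient
from .dosing import (
    STANDARD_THRESHOLDS,
    BolusInputs,
    GlucoseThresholds,
    compute_bolus,
    estimate_cho,
)
from .errors import EXPERIMENT_IDS, build_error_spec, sample_errors
from .metrics import METRIC_NAMES, OutcomeRecord, compute_metrics
from .simulator import (
    CGM_DT,
    GlucoseTrace,
    MetabolicParams,
    TEMPLATE_PARAMS,
    _rk4_segment,
    calibrate_patient,
    equilibrium_state,
)

__all__ = [
    "MEAL_PLAN",
    "MEAL_CLOCKS",
    "TrialConfig",
    "MealSlot",
    "MealEvent",
    "build_schedule",
    "run_experiment",
    "run_trial",
    "analyze_outcomes",
    "CarbCountingTrial",
    "TrialResults",
]

#: Daily meal grams per cohort (five meals/day).
MEAL_PLAN: dict[str, tuple[float, ...]] = {
    "adult": (30.0, 45.0, 30.0, 45.0, 15.0),
    "adolescent": (30.0, 45.0, 45.0, 45.0, 30.0),
    "child": (30.0, 30.0, 30.0, 30.0, 15.0),
}

#: Clock times of the five daily meals; offsets are minutes after the first.
MEAL_CLOCKS: tuple[str, ...] = ("08:00", "12:00", "16:00", "20:00", "00:00")
_MEAL_OFFSETS: tuple[int, ...] = (0, 240, 480, 720, 960)

MINUTES_PER_DAY = 1440

#: Calibration anchors each patient's largest scheduled meal to peak this many
#: mg/dL below the hyperglycemia threshold under exact dosing: the virtual
#: subjects are well-controlled but ride the edge of the target band, so
#: counting errors at the personal limit actually reach the band boundaries.
CONTROL_PEAK_MARGIN = 0.5


@dataclass(frozen=True)
class TrialConfig:
    """Study configuration; the control experiment E0 is always required."""

    days: int = 90
    experiments: tuple[str, ...] = EXPERIMENT_IDS
    thresholds: GlucoseThresholds = STANDARD_THRESHOLDS
    master_seed: int = 0
    n_resamples: int = 10_000
    min_tir_retained: float = 90.0

    def __post_init__(self) -> None:
        if self.days < 1:
            raise ValueError("days must be >= 1")
        unknown = set(self.experiments) - set(EXPERIMENT_IDS)
        if unknown:
            raise ValueError(f"unknown experiments: {sorted(unknown)}")
        if "E0" not in self.experiments:
            raise ValueError("E0 (the control) must be part of every trial")

    def to_dict(self) -> dict:
        return {
            "days": self.days,
            "experiments": list(self.experiments),
            "thresholds": [
                self.thresholds.g_low,
                self.thresholds.g_target,
                self.thresholds.g_high,
            ],
            "master_seed": self.master_seed,
            "n_resamples": self.n_resamples,
            "min_tir_retained": self.min_tir_retained,
        }


@dataclass(frozen=True)
class MealSlot:
    """One scheduled meal: trial day (1-based), wall clock, minutes since
    trial start, true carbohydrate content."""

    day: int
    clock: str
    t_min: float
    cho_true: float


@dataclass(frozen=True)
class MealEvent(MealSlot):
    """A dosed meal: the sampled counting error, the resulting estimate, the
    preprandial glucose read at mealtime and the administered bolus."""

    delta_cho: float = 0.0
    cho_estimated: float = 0.0
    g_preprandial: float = 0.0
    bolus: float = 0.0

    def __post_init__(self) -> None:
        if abs(self.cho_estimated - max(0.0, self.cho_true - self.delta_cho)) > 1e-9:
            raise ValueError("cho_estimated inconsistent with cho_true - delta_cho")


def build_schedule(cohort_type: str, days: int) -> list[MealSlot]:
    """The per-cohort daily meal plan repeated over ``days`` trial days."""
    if cohort_type not in MEAL_PLAN:
        raise ValueError(f"unknown cohort {cohort_type!r}")
    if days < 1:
        raise ValueError("days must be >= 1")
    grams = MEAL_PLAN[cohort_type]
    return [
        MealSlot(
            day=d + 1,
            clock=MEAL_CLOCKS[i],
            t_min=float(d * MINUTES_PER_DAY + _MEAL_OFFSETS[i]),
            cho_true=grams[i],
        )
        for d in range(days)
        for i in range(len(grams))
    ]


def _error_stream(master_seed: int, experiment_id: str, patient_id: str) -> np.random.Generator:
    """Independent error sub-stream for one (experiment, patient) cell."""
    exp_idx = EXPERIMENT_IDS.index(experiment_id)
    pat_key = int(hashlib.sha256(patient_id.encode()).hexdigest()[:8], 16)
    ss = np.random.SeedSequence(master_seed, spawn_key=(0, exp_idx, pat_key))
    return np.random.default_rng(ss)


def _comparison_seed(master_seed: int, experiment_id: str, metric: str, stratum: str) -> int:
    ss = np.random.SeedSequence(
        master_seed,
        spawn_key=(
            1,
            EXPERIMENT_IDS.index(experiment_id),
            METRIC_NAMES.index(metric),
            0 if stratum == "tir_100" else 1,
        ),
    )
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _run_protocol(
    patient: VirtualPatient,
    schedule: Sequence[MealSlot],
    errors: np.ndarray,
    thresholds: GlucoseThresholds,
    horizon: int,
) -> tuple[GlucoseTrace, list[MealEvent]]:
    """Closed-loop basal-bolus protocol: every meal is dosed from the
    simulated preprandial glucose, then the trace continues."""
    params: MetabolicParams = patient.model_params
    if params is None:
        raise ValueError(f"{patient.id}: patient is not calibrated")
    basal = params.basal_equilibrium_rate
    y = equilibrium_state(params, basal, thresholds.g_target)
    out = np.empty(horizon)
    events: list[MealEvent] = []
    cursor = 0
    u = basal / 60.0
    for slot, delta in zip(schedule, errors):
        t_meal = int(round(slot.t_min))
        if t_meal > cursor:
            _rk4_segment(
                y, t_meal - cursor, 1.0, params.p1, params.si, params.p2, params.g_b,
                params.v_g, params.tau_i, params.tau_m, params.i_clear, params.i_basal,
                u, out, cursor,
            )
            cursor = t_meal
        g_pre = float(y[0])
        est = estimate_cho(slot.cho_true, float(delta))
        bolus = compute_bolus(BolusInputs(est, g_pre, 0.0), patient.therapy, thresholds)
        y[5] += 1000.0 * params.bioavail * slot.cho_true
        y[3] += bolus
        events.append(
            MealEvent(
                day=slot.day, clock=slot.clock, t_min=slot.t_min, cho_true=slot.cho_true,
                delta_cho=float(delta), cho_estimated=est, g_preprandial=g_pre, bolus=bolus,
            )
        )
    if horizon > cursor:
        _rk4_segment(
            y, horizon - cursor, 1.0, params.p1, params.si, params.p2, params.g_b,
            params.v_g, params.tau_i, params.tau_m, params.i_clear, params.i_basal,
            u, out, cursor,
        )
    if not np.all(np.isfinite(out)) or np.any(out <= 0.0):
        raise RuntimeError(
            f"{patient.id}: integration produced non-physical glucose "
            f"(min={np.nanmin(out):.2f} mg/dL)"
        )
    step = int(CGM_DT)
    trace = GlucoseTrace(t=np.arange(0.0, horizon, CGM_DT), g=out[::step].copy())
    return trace, events


def run_experiment(
    patient: VirtualPatient,
    experiment_id: str,
    config: TrialConfig = TrialConfig(),
    return_trace: bool = False,
):
    """Run one (patient, experiment) cell of the study.

    Samples one error per meal from the experiment's distribution (exact
    zeros for the control), doses and simulates the full horizon, and returns
    the outcome record (optionally with the trace and the meal log).
    """
    schedule = build_schedule(patient.cohort, config.days)
    spec = build_error_spec(experiment_id, patient.delta_cho_max)
    rng = _error_stream(config.master_seed, experiment_id, patient.id)
    errors = sample_errors(spec, len(schedule), rng)
    horizon = config.days * MINUTES_PER_DAY
    try:
        trace, events = _run_protocol(patient, schedule, errors, config.thresholds, horizon)
    except RuntimeError as exc:
        raise RuntimeError(f"experiment {experiment_id}: {exc}") from exc
    record = compute_metrics(trace, config.thresholds.g_low, config.thresholds.g_high)
    if return_trace:
        return record, trace, events
    return record, None, events


def analyze_outcomes(outcomes: pd.DataFrame, config: TrialConfig) -> pd.DataFrame:
    """Exclusion, stratification and paired bootstrap comparisons vs E0.

    ``outcomes`` is tidy: one row per (patient, experiment) with the five
    metric columns.  Returns one row per (experiment, stratum, metric).
    """
    control = outcomes[outcomes.experiment == "E0"].set_index("patient_id")
    strata = exclude_subjects(control["tir"].to_dict(), config.min_tir_retained)
    rows = []
    for stratum in ("tir_100", "tir_90"):
        ids = sorted(strata[stratum])
        if len(ids) < 2:
            continue
        for experiment in config.experiments:
            if experiment == "E0":
                continue
            exp = outcomes[outcomes.experiment == experiment].set_index("patient_id")
            for metric in METRIC_NAMES:
                sample = PairedSample(
                    subject_ids=tuple(ids),
                    values_experiment=exp.loc[ids, metric].to_numpy(),
                    values_control=control.loc[ids, metric].to_numpy(),
                )
                seed = _comparison_seed(config.master_seed, experiment, metric, stratum)
                res = bootstrap_paired_diff(sample, config.n_resamples, seed)
                rows.append(
                    {
                        "experiment": experiment,
                        "stratum": stratum,
                        "metric": metric,
                        "mean_diff": res.mean_diff,
                        "ci_low": res.ci_low,
                        "ci_high": res.ci_high,
                        "p_value": res.p_value,
                        "n_subjects": len(ids),
                        "n_resamples": res.n_resamples,
                        "seed": res.seed,
                    }
                )
    return pd.DataFrame(rows)


class TrialResults:
    """Container for a finished study: per-cell outcomes, meal logs,
    bootstrap comparisons and a reproducibility manifest."""

    def __init__(
        self,
        outcomes: pd.DataFrame,
        comparisons: pd.DataFrame,
        meal_log: pd.DataFrame,
        strata: dict[str, list[str]],
        config: TrialConfig,
        patients: list[VirtualPatient],
    ) -> None:
        self.outcomes = outcomes
        self.comparisons = comparisons
        self.meal_log = meal_log
        self.strata = strata
        self.config = config
        self.patients = patients

    @property
    def manifest(self) -> dict:
        cfg = self.config.to_dict()
        return {
            "config": cfg,
            "config_sha256": hashlib.sha256(
                json.dumps(cfg, sort_keys=True).encode()
            ).hexdigest(),
            "n_patients": len(self.patients),
            "retained_subjects": sorted(self.strata["retained"]),
            "excluded_subjects": sorted(
                set(p.id for p in self.patients) - set(self.strata["retained"])
            ),
        }

    def mean_tir_shift(self, experiments: Sequence[str], stratum: str = "tir_90") -> float:
        """Mean absolute TIR difference from control over ``experiments``."""
        sel = self.comparisons[
            (self.comparisons.stratum == stratum)
            & (self.comparisons.metric == "tir")
            & (self.comparisons.experiment.isin(list(experiments)))
        ]
        return float(sel.mean_diff.abs().mean())

    def summary(self) -> str:
        lines = [
            f"Carb-counting error trial: {len(self.patients)} patients, "
            f"{self.config.days} days, experiments {', '.join(self.config.experiments)}",
            f"Retained after control TIR >= {self.config.min_tir_retained:g}%: "
            f"{len(self.strata['retained'])} subjects "
            f"(always-in-range stratum: {len(self.strata['tir_100'])})",
            "",
            "Mean difference vs E0 (tir_90 stratum), percentage points:",
            f"{'exp':>4} {'TIR':>8} {'TAR':>8} {'TBR':>8} {'%<50':>8} {'%>300':>8}",
        ]
        comp = self.comparisons[self.comparisons.stratum == "tir_90"]
        for experiment in self.config.experiments:
            if experiment == "E0":
                continue
            row = comp[comp.experiment == experiment].set_index("metric")["mean_diff"]
            if row.empty:
                continue
            lines.append(
                f"{experiment:>4} "
                + " ".join(f"{row[m]:>8.2f}" for m in METRIC_NAMES)
            )
        return "\n".join(lines)

    def save(self, out_dir: str | Path, figures: bool = True) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.outcomes.to_csv(out / "metrics.csv", index=False)
        self.comparisons.to_csv(out / "comparisons.csv", index=False)
        self.meal_log.to_csv(out / "meal_log.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=2, sort_keys=True))
        if figures and not self.comparisons.empty:
            for stratum in ("tir_100", "tir_90"):
                if (self.comparisons.stratum == stratum).any():
                    fig = self.plot_differences(stratum=stratum)
                    fig.savefig(out / f"differences_{stratum}.png", dpi=150)
                    import matplotlib.pyplot as plt

                    plt.close(fig)

    def plot_differences(self, stratum: str = "tir_90"):
        """Bar plots of TIR and TAR/TBR mean differences vs E0 with CI
        whiskers, one panel per quantity."""
        import matplotlib.pyplot as plt

        comp = self.comparisons[self.comparisons.stratum == stratum]
        experiments = [e for e in self.config.experiments if e != "E0"]
        fig, (ax_tir, ax_ranges) = plt.subplots(1, 2, figsize=(11, 4))
        x = np.arange(len(experiments))

        def series(metric):
            s = comp[comp.metric == metric].set_index("experiment")
            return (
                s.reindex(experiments)["mean_diff"].to_numpy(),
                s.reindex(experiments)["ci_low"].to_numpy(),
                s.reindex(experiments)["ci_high"].to_numpy(),
            )

        m, lo, hi = series("tir")
        ax_tir.bar(x, m, color="tab:gray")
        ax_tir.errorbar(x, m, yerr=[m - lo, hi - m], fmt="none", ecolor="k", capsize=3)
        ax_tir.set_xticks(x, experiments)
        ax_tir.set_ylabel("TIR difference vs E0 (pp)")
        ax_tir.axhline(0, color="k", lw=0.5)

        width = 0.4
        for off, metric, color in ((-width / 2, "tar", "tab:blue"), (width / 2, "tbr", "gold")):
            m, lo, hi = series(metric)
            ax_ranges.bar(x + off, m, width, label=metric.upper(), color=color)
            ax_ranges.errorbar(
                x + off, m, yerr=[m - lo, hi - m], fmt="none", ecolor="k", capsize=2
            )
        ax_ranges.set_xticks(x, experiments)
        ax_ranges.set_ylabel("difference vs E0 (pp)")
        ax_ranges.axhline(0, color="k", lw=0.5)
        ax_ranges.legend()
        fig.suptitle(f"Glycemic differences vs error-free control ({stratum})")
        fig.tight_layout()
        return fig


class CarbCountingTrial:
    """The full in-silico study over a patient roster.

    Parameters
    ----------
    patients
        Virtual patients; uncalibrated patients are calibrated on ``run()``.
    config
        Study configuration (horizon, experiments, seeds, inference).
    template
        Metabolic template shared by all patients before calibration.
    """

    def __init__(
        self,
        patients: Sequence[VirtualPatient],
        config: TrialConfig = TrialConfig(),
        template: MetabolicParams = TEMPLATE_PARAMS,
    ) -> None:
        if len(patients) == 0:
            raise ValueError("empty roster")
        self.patients = list(patients)
        self.config = config
        self.template = template

    def calibrate(self) -> list[VirtualPatient]:
        """Calibrate every patient that does not yet carry model parameters."""
        calibrated = []
        for p in self.patients:
            if p.model_params is None:
                params = calibrate_patient(
                    p.therapy,
                    self.template,
                    self.config.thresholds,
                    basal_rate=p.basal_rate,
                    reference_meal=max(MEAL_PLAN[p.cohort]),
                    peak_target=self.config.thresholds.g_high - CONTROL_PEAK_MARGIN,
                )
                p = p.with_model_params(params)
            calibrated.append(p)
        self.patients = calibrated
        return calibrated

    def run(self) -> TrialResults:
        self.calibrate()
        outcome_rows = []
        log_rows = []
        for patient in self.patients:
            for experiment in self.config.experiments:
                record, _, events = run_experiment(patient, experiment, self.config)
                outcome_rows.append(
                    {
                        "patient_id": patient.id,
                        "cohort": patient.cohort,
                        "experiment": experiment,
                        **record.as_dict(),
                    }
                )
                for ev in events:
                    log_rows.append(
                        {
                            "patient_id": patient.id,
                            "experiment": experiment,
                            "day": ev.day,
                            "clock": ev.clock,
                            "t_min": ev.t_min,
                            "cho_true": ev.cho_true,
                            "delta_cho": ev.delta_cho,
                            "cho_estimated": ev.cho_estimated,
                            "g_preprandial": ev.g_preprandial,
                            "bolus": ev.bolus,
                        }
                    )
        outcomes = pd.DataFrame(outcome_rows)
        comparisons = analyze_outcomes(outcomes, self.config)
        control = outcomes[outcomes.experiment == "E0"].set_index("patient_id")
        strata = exclude_subjects(control["tir"].to_dict(), self.config.min_tir_retained)
        return TrialResults(
            outcomes=outcomes,
            comparisons=comparisons,
            meal_log=pd.DataFrame(log_rows),
            strata=strata,
            config=self.config,
            patients=self.patients,
        )


def run_trial(
    patients: Sequence[VirtualPatient],
    config: TrialConfig = TrialConfig(),
    template: MetabolicParams = TEMPLATE_PARAMS,
) -> TrialResults:
    """Functional entry point equivalent to ``CarbCountingTrial(...).run()``."""
    return CarbCountingTrial(patients, config, template).run()
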