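"""Per-day, per-condition reference truth and percent deviations.

Blood samples cannot be prepared at exactly the same hematocrit and glucose
level on different days, so the "true value" for a condition is defined per
day: the arithmetic mean of that day's reference-analyzer (YSI) replicates,
nominally five.  Every valid meter reading is then expressed as a signed
percent deviation from its own day's truth:

    percent_deviation = 100 * (meter - truth) / truth

A drift check guards the glycolysis assumption: ex vivo red cells keep
consuming glucose, so if the reference value slides across the five
replicates of a run, the day-mean truth would be biased.  The check reports
the per-group replicate slope and flags groups whose first-to-last change
exceeds a configurable percentage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .measurements_io import ConditionKey, MeasurementRecord


@dataclass
class ReferenceTruth:
    """Mean of one day's reference replicates for one condition."""

    day_id: str
    condition: ConditionKey
    mean_reference: float
    n_replicates: int
    replicate_values: list[float]
    mean_measured_hct: float


@dataclass
class DeviationPoint:
    """One meter reading expressed relative to its day/condition truth."""

    device_model: str
    day_id: str
    condition: ConditionKey
    meter_value: float  # mg/dL
    true_value: float  # mg/dL
    percent_deviation: float  # signed


@dataclass
class DriftReport:
    """Reference drift across the replicates of one (day, condition) group."""

    day_id: str
    condition: ConditionKey
    slope_per_replicate: float  # mg/dL per replicate step
    first_to_last_pct: float
    flagged: bool


def build_truth(records: Iterable[MeasurementRecord]) -> list[ReferenceTruth]:
    """Average reference replicates into one truth per (day, condition).

    The reference value travels on every device's record for the same
    replicate, so values are first deduplicated by replicate index (averaged,
    in case of entry jitter) and then averaged across replicates.  User-error
    rows are ignored.  A group with no reference values at all is an error.
    """
    groups: dict[tuple[str, ConditionKey], dict[int, list[float]]] = {}
    hcts: dict[tuple[str, ConditionKey], list[float]] = {}
    for rec in records:
        if rec.user_error:
            continue
        key = (rec.day_id, rec.condition)
        groups.setdefault(key, {})
        hcts.setdefault(key, []).append(rec.measured_hct)
        if rec.reference_value is not None:
            groups[key].setdefault(rec.replicate_index, []).append(rec.reference_value)

    truths = []
    for (day, cond), by_rep in sorted(groups.items()):
        if not by_rep:
            raise ValueError(
                f"no reference values for day {day!r}, condition {cond.label()}"
            )
        reps = [float(np.mean(by_rep[i])) for i in sorted(by_rep)]
        truths.append(
            ReferenceTruth(
                day_id=day,
                condition=cond,
                mean_reference=float(np.mean(reps)),
                n_replicates=len(reps),
                replicate_values=reps,
                mean_measured_hct=float(np.mean(hcts[(day, cond)])),
            )
        )
    return truths


def truth_lookup(truths: Iterable[ReferenceTruth]) -> dict[tuple[str, ConditionKey], ReferenceTruth]:
    return {(t.day_id, t.condition): t for t in truths}


def compute_deviations(
    records: Iterable[MeasurementRecord], truths: Iterable[ReferenceTruth]
) -> list[DeviationPoint]:
    """Percent deviation of each valid meter reading from its day truth.

    Device-error and user-error records contribute nothing.  A valid reading
    whose (day, condition) has no truth is a hard error: it means the truth
    table and the record set are out of sync.
    """
    lut = truth_lookup(truths)
    points = []
    for rec in records:
        if not rec.is_valid_reading:
            continue
        key = (rec.day_id, rec.condition)
        if key not in lut:
            raise ValueError(
                f"no reference truth for day {rec.day_id!r}, "
                f"condition {rec.condition.label()}"
            )
        truth = lut[key].mean_reference
        meter = rec.reading_mgdl()
        points.append(
            DeviationPoint(
                device_model=rec.device_model,
                day_id=rec.day_id,
                condition=rec.condition,
                meter_value=meter,
                true_value=truth,
                percent_deviation=100.0 * (meter - truth) / truth,
            )
        )
    return points


def truth_drift_check(
    truths: Iterable[ReferenceTruth], threshold_pct: float = 5.0
) -> list[DriftReport]:
    """Flag (day, condition) groups whose reference drifts across replicates.

    ``slope_per_replicate`` is the least-squares slope of reference value on
    replicate index; ``first_to_last_pct`` compares the last replicate to the
    first.  Report-only: nothing is dropped.
    """
    reports = []
    for t in truths:
        vals = np.asarray(t.replicate_values, dtype=float)
        if len(vals) >= 2:
            slope = float(np.polyfit(np.arange(len(vals)), vals, 1)[0])
            change = 100.0 * (vals[-1] - vals[0]) / vals[0]
        else:
            slope, change = 0.0, 0.0
        reports.append(
            DriftReport(
                day_id=t.day_id,
                condition=t.condition,
                slope_per_replicate=slope,
                first_to_last_pct=float(change),
                flagged=bool(abs(change) > threshold_pct),
            )
        )
    return reports
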