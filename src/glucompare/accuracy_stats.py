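"""Headline accuracy statistics per (device, condition) cell.

For the pooled percent deviations of one device model at one condition
(all units, strip lots and days combined):

* mean percent bias  — mean of the signed percent deviations,
* MARD               — mean absolute relative difference, the mean of the
                       absolute percent deviations,
* SD                 — sample standard deviation (n-1) of the signed
                       percent deviations,
* 95% limits of agreement — the reading interval expected to contain 95% of
  the device's values at the condition's nominal glucose, built
  multiplicatively from bias and SD:

      LoA = nominal * (1 + (bias -/+ z*SD) / 100),   z = 1.96 by default.

Empty cells yield ``None`` (never a silent zero); SD needs n >= 2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .measurements_io import ConditionKey
from .reference_truth import DeviationPoint

#: normal 95% quantile used for limits of agreement
DEFAULT_LOA_Z = 1.96


@dataclass
class AccuracySummary:
    """Accuracy/precision summary of one device model at one condition."""

    device_model: str
    condition: ConditionKey
    n: int
    mean_percent_bias: float | None
    mard: float | None
    sd_percent: float | None
    loa_low: float | None  # mg/dL at the condition's nominal glucose
    loa_high: float | None
    # pooled raw means, used for error-grid condition averages
    mean_meter_mgdl: float | None = None
    mean_reference_mgdl: float | None = None
    sd_meter_mgdl: float | None = None


def _devs(points: Sequence[DeviationPoint]) -> np.ndarray:
    return np.asarray([p.percent_deviation for p in points], dtype=float)


def mean_percent_bias(points: Sequence[DeviationPoint]) -> float | None:
    """Mean signed percent deviation; ``None`` on empty input."""
    if not points:
        return None
    return float(np.mean(_devs(points)))


def mard(points: Sequence[DeviationPoint]) -> float | None:
    """Mean absolute relative difference; ``None`` on empty input."""
    if not points:
        return None
    return float(np.mean(np.abs(_devs(points))))


def sd_percent(points: Sequence[DeviationPoint]) -> float | None:
    """Sample (n-1) standard deviation of signed percent deviation."""
    if len(points) < 2:
        return None
    return float(np.std(_devs(points), ddof=1))


def limits_of_agreement(
    bias_pct: float,
    sd_pct: float,
    nominal_glucose: float,
    z: float = DEFAULT_LOA_Z,
) -> tuple[float, float]:
    """95% limits of agreement in mg/dL at a nominal glucose level."""
    if nominal_glucose <= 0:
        raise ValueError(f"nominal glucose must be positive, got {nominal_glucose}")
    low = nominal_glucose * (1.0 + (bias_pct - z * sd_pct) / 100.0)
    high = nominal_glucose * (1.0 + (bias_pct + z * sd_pct) / 100.0)
    return float(low), float(high)


def summary_loa(
    summary: AccuracySummary, nominal_glucose: float, z: float = DEFAULT_LOA_Z
) -> tuple[float, float]:
    """Limits of agreement for an existing summary at a nominal glucose."""
    if summary.sd_percent is None:
        raise ValueError("limits of agreement need a non-null SD (n >= 2)")
    return limits_of_agreement(
        summary.mean_percent_bias, summary.sd_percent, nominal_glucose, z
    )


def group_points(
    points: Iterable[DeviationPoint],
) -> dict[tuple[str, ConditionKey], list[DeviationPoint]]:
    """Pool deviation points by (device model, condition) across days."""
    cells: dict[tuple[str, ConditionKey], list[DeviationPoint]] = {}
    for p in points:
        cells.setdefault((p.device_model, p.condition), []).append(p)
    return cells


def summarize(
    points: Iterable[DeviationPoint], z: float = DEFAULT_LOA_Z
) -> list[AccuracySummary]:
    """Per-(device, condition) accuracy summaries from pooled deviations.

    The LoA is evaluated at the condition's nominal (target) glucose.  Raw
    meter/reference means in mg/dL are carried along for error-grid
    condition averages.
    """
    summaries = []
    for (model, cond), pts in sorted(group_points(points).items()):
        bias = mean_percent_bias(pts)
        sd = sd_percent(pts)
        loa_low = loa_high = None
        if sd is not None:
            loa_low, loa_high = limits_of_agreement(bias, sd, cond.target_glucose, z)
        meter = np.asarray([p.meter_value for p in pts], dtype=float)
        ref = np.asarray([p.true_value for p in pts], dtype=float)
        summaries.append(
            AccuracySummary(
                device_model=model,
                condition=cond,
                n=len(pts),
                mean_percent_bias=bias,
                mard=mard(pts),
                sd_percent=sd,
                loa_low=loa_low,
                loa_high=loa_high,
                mean_meter_mgdl=float(meter.mean()),
                mean_reference_mgdl=float(ref.mean()),
                sd_meter_mgdl=float(meter.std(ddof=1)) if len(pts) >= 2 else None,
            )
        )
    return summaries
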