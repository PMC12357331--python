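"""Accuracy-band compliance against three published standards.

Three percentage limits on deviation from the reference are used:

* +/- 8%  — UNICEF/NEST360 glucometer Target Product Profile minimal
            accuracy requirement, also the proposed CLIA acceptance limit;
* +/- 15% — ISO 15197:2015 limit for glucose >= 100 mg/dL;
* +/- 20% — the older ISO 15197:2003 recommendation.

The percentage limits are applied at every glucose level, including below
100 mg/dL where ISO 15197:2015 formally switches to an absolute mg/dL limb;
using percentages throughout keeps devices comparable across conditions
(the absolute limb is left as a config extension point, not implemented).

A (device, condition) cell is banded by its *mean* percent bias:
``green`` within +/-8, ``orange`` between 8 and 15, ``red`` beyond 15;
boundary values belong to the inner (safer) band.  Individual points are
additionally scored as within-band fractions at each threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .accuracy_stats import AccuracySummary, group_points
from .measurements_io import ConditionKey
from .reference_truth import DeviationPoint

GREEN, ORANGE, RED = "green", "orange", "red"

#: (TPP/CLIA, ISO 15197:2015, ISO 15197:2003) percent limits
DEFAULT_THRESHOLDS = (8.0, 15.0, 20.0)


@dataclass
class BandClassification:
    """Band and within-threshold point fractions for one (device, condition)."""

    device_model: str
    condition: ConditionKey
    band: str | None
    frac_within_8: float | None
    frac_within_15: float | None
    frac_within_20: float | None


def classify_band(
    mean_percent_bias: float | None,
    green_limit: float = 8.0,
    orange_limit: float = 15.0,
) -> str | None:
    """Band a mean percent bias: green <= 8 < orange <= 15 < red.

    Symmetric in sign; boundary values fall in the inner band ("within").
    """
    if mean_percent_bias is None:
        return None
    b = abs(mean_percent_bias)
    if b <= green_limit:
        return GREEN
    if b <= orange_limit:
        return ORANGE
    return RED


def within_band_fractions(
    points: Sequence[DeviationPoint],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> tuple[float | None, ...]:
    """Fraction of points with |percent deviation| <= t, per threshold t."""
    if not points:
        return tuple(None for _ in thresholds)
    devs = np.abs([p.percent_deviation for p in points])
    return tuple(float(np.mean(devs <= t)) for t in thresholds)


def band_table(
    points: Iterable[DeviationPoint],
    summaries: Iterable[AccuracySummary],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> list[BandClassification]:
    """Band every summarized (device, condition) cell and score its points."""
    cells = group_points(points)
    out = []
    for s in summaries:
        pts = cells.get((s.device_model, s.condition), [])
        f8, f15, f20 = within_band_fractions(pts, thresholds)
        out.append(
            BandClassification(
                device_model=s.device_model,
                condition=s.condition,
                band=classify_band(s.mean_percent_bias),
                frac_within_8=f8,
                frac_within_15=f15,
                frac_within_20=f20,
            )
        )
    return out
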