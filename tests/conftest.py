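import numpy as np
import pytest

from glucompare.error_grid import load_zone_polygons
from glucompare.measurements_io import ConditionKey, MeasurementRecord
from glucompare.reference_truth import DeviationPoint

COND = ConditionKey(40, 40)


@pytest.fixture(scope="session")
def grid():
    return load_zone_polygons()


def make_record(
    model="MeterX",
    day="day01",
    cond=COND,
    rep=1,
    reading=42.0,
    unit="mg/dL",
    reference=40.0,
    error=None,
    user_error=False,
    hct=40.0,
):
    return MeasurementRecord(
        device_model=model,
        device_unit_id=f"{model}-U1",
        strip_lot="lotA",
        day_id=day,
        condition=cond,
        measured_hct=hct,
        replicate_index=rep,
        reading_value=reading,
        reading_unit=unit,
        reference_value=reference,
        error_code=error,
        user_error=user_error,
    )


def make_points(deviations, model="MeterX", cond=COND, truth=100.0):
    """Deviation points with the given percent deviations around a truth."""
    return [
        DeviationPoint(
            device_model=model,
            day_id="day01",
            condition=cond,
            meter_value=truth * (1 + d / 100.0),
            true_value=truth,
            percent_deviation=float(d),
        )
        for d in deviations
    ]
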