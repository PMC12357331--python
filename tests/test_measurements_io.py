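import json
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_record
from glucompare.measurements_io import (
    ConditionKey,
    RecordValidationError,
    UnknownUnitError,
    convert_to_mgdl,
    plasma_equivalent,
    read_measurements,
    records_to_frame,
    tally_errors,
    write_measurements,
)


@pytest.mark.parametrize(
    "mmol, mgdl",
    [(1.0, 18.0), (0.0, 0.0), (2.2, 39.6)],
)
def test_mmol_to_mgdl_conversion(mmol, mgdl):
    assert convert_to_mgdl(mmol) == pytest.approx(mgdl)


@pytest.mark.parametrize("wb, plasma", [(100.0, 111.0), (0.0, 0.0), (40.0, 44.4)])
def test_plasma_equivalent_factor(wb, plasma):
    assert plasma_equivalent(wb) == pytest.approx(plasma)


@pytest.mark.parametrize("fn", [convert_to_mgdl, plasma_equivalent])
def test_negative_concentration_rejected(fn):
    with pytest.raises(ValueError):
        fn(-1.0)


@given(st.floats(0, 50), st.floats(0, 50))
def test_conversion_is_linear(a, b):
    assert convert_to_mgdl(a + b) == pytest.approx(convert_to_mgdl(a) + convert_to_mgdl(b))


def _device_records(model, n_valid, n_errors, n_user=0):
    recs = [make_record(model=model, rep=1 + i % 5) for i in range(n_valid)]
    recs += [
        make_record(model=model, reading=None, error="E70", rep=1 + i % 5)
        for i in range(n_errors)
    ]
    recs += [
        make_record(model=model, reading=None, error="user", user_error=True)
        for _ in range(n_user)
    ]
    return recs


@pytest.mark.parametrize(
    "n_valid, n_errors, rate",
    [(106, 4, 3.6), (262, 9, 3.3), (10, 0, 0.0)],
)
def test_error_rate_denominator_includes_errors(n_valid, n_errors, rate):
    (tally,) = tally_errors(_device_records("M", n_valid, n_errors))
    assert tally.n_valid == n_valid
    assert tally.n_device_errors == n_errors
    assert tally.error_rate_pct == rate


def test_tally_ignores_order_and_user_errors():
    recs = _device_records("A", 12, 3, n_user=4) + _device_records("B", 5, 0)
    base = tally_errors(recs)
    shuffled = recs[:]
    random.Random(0).shuffle(shuffled)
    assert tally_errors(shuffled) == base
    assert [t.device_model for t in base] == ["A", "B"]
    assert base[0].n_valid == 12 and base[0].n_device_errors == 3


def test_tally_empty_device_rate_is_null():
    recs = [make_record(model="OnlyUser", reading=None, error="x", user_error=True)]
    (tally,) = tally_errors(recs)
    assert tally.n_valid == 0 and tally.n_device_errors == 0
    assert tally.error_rate_pct is None


def test_csv_round_trip_preserves_fields(tmp_path):
    recs = [
        make_record(rep=i + 1, reading=40.0 + i) for i in range(3)
    ] + [
        make_record(model="MmolMeter", reading=2.2, unit="mmol/L", rep=1),
        make_record(reading=None, error="lo", rep=4),
        make_record(reading=None, error="underfill", user_error=True, rep=5),
    ]
    path = tmp_path / "m.csv"
    write_measurements(recs, path)
    back = read_measurements(path)
    assert len(back) == len(recs)
    # mmol/L reading is preserved untouched at read time, converted on access
    mmol = [r for r in back if r.device_model == "MmolMeter"][0]
    assert mmol.reading_unit == "mmol/L"
    assert mmol.reading_value == pytest.approx(2.2)
    assert mmol.reading_mgdl() == pytest.approx(39.6)
    assert records_to_frame(back).equals(records_to_frame(recs))


def test_row_with_reading_and_error_code_rejected(tmp_path):
    recs = [make_record(rep=1), make_record(rep=2)]
    path = tmp_path / "m.csv"
    write_measurements(recs, path)
    txt = path.read_text().splitlines()
    bad = txt[1].replace(",,False", ",E70,False")  # add error code to a reading row
    path.write_text("\n".join([txt[0], bad, txt[2]]) + "\n")
    log_path = tmp_path / "log.json"
    back = read_measurements(path, log_path=log_path)
    assert len(back) == 1
    log = json.loads(log_path.read_text())
    assert log["n_rejected"] == 1
    assert log["rejects"][0]["line"] == 2
    assert "exactly one" in log["rejects"][0]["reason"]


def test_missing_column_is_fatal(tmp_path):
    path = tmp_path / "m.csv"
    write_measurements([make_record()], path)
    txt = path.read_text().replace("reference", "ysi")
    path.write_text(txt)
    with pytest.raises(ValueError, match="missing required column"):
        read_measurements(path)
    # but a column map can recover it
    back = read_measurements(path, schema_config={"reference": "ysi"})
    assert len(back) == 1


def test_unknown_unit_is_fatal(tmp_path):
    path = tmp_path / "m.csv"
    write_measurements([make_record()], path)
    path.write_text(path.read_text().replace("mg/dL", "g/L"))
    with pytest.raises(UnknownUnitError):
        read_measurements(path)


def test_record_invariants_enforced_at_construction():
    with pytest.raises(RecordValidationError):
        make_record(reading=40.0, error="E70")
    with pytest.raises(RecordValidationError):
        make_record(reading=None, error=None)
    with pytest.raises(RecordValidationError):
        make_record(rep=0)


def test_condition_key_labels():
    c = ConditionKey(18, 40)
    assert "18" in c.label() and "40" in c.label()
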