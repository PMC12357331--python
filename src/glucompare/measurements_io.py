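"""Measurement records: data model, CSV I/O, validation and error triage.

A glucometer evaluation study produces long-format records: one row per
(device unit, strip lot, day, condition, replicate).  Each row carries either
a numeric meter reading or a device error code — never both — alongside the
reference-analyzer (YSI) value measured on the same blood sample.

Two kinds of failed measurement are distinguished:

* **user error** — an operator mistake (under-filled strip, strip not fully
  inserted).  Such rows are retained in the file with ``user_error=True`` so
  drop decisions stay auditable, but they are invisible to every downstream
  statistic, including error counting.
* **device error** — an instrument-reported fault (faulty strip, "lo" below
  the display floor).  These are counted in per-device error tallies.

All statistics downstream run in mg/dL; meters that report in mmol/L keep
their native unit in the record and are converted on access
(mg/dL = mmol/L x 18).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

MGDL_PER_MMOL = 18.0
#: whole-blood -> equivalent plasma glucose factor used by many strip meters.
PLASMA_CORRECTION_FACTOR = 1.11

MGDL = "mg/dL"
MMOL = "mmol/L"
VALID_UNITS = (MGDL, MMOL)

#: canonical CSV column order
CANONICAL_COLUMNS = [
    "device_model",
    "device_unit_id",
    "strip_lot",
    "day_id",
    "target_hct",
    "target_glucose",
    "measured_hct",
    "replicate",
    "reading",
    "reading_unit",
    "reference",
    "error_code",
    "user_error",
]


@dataclass(frozen=True, order=True)
class ConditionKey:
    """One stratum of the study design: nominal hematocrit x nominal glucose.

    Grouping is by *target* levels; the realized hematocrit and glucose of a
    given day's sample are carried as metadata on the records and absorbed by
    the per-day reference truth.
    """

    target_hct: int
    target_glucose: int

    def label(self) -> str:
        return f"Hct {self.target_hct}% / {self.target_glucose} mg/dL"


#: the six strata of the default design: {18, 40, 55}% Hct x {40, 150} mg/dL
DEFAULT_CONDITIONS: tuple[ConditionKey, ...] = tuple(
    ConditionKey(h, g) for g in (40, 150) for h in (18, 40, 55)
)


class RecordValidationError(ValueError):
    """A row violates the measurement-record invariants."""


class UnknownUnitError(ValueError):
    """A reading-unit string is neither mg/dL nor mmol/L (fatal on read)."""


@dataclass
class MeasurementRecord:
    """One meter reading (or error) paired with its condition and reference."""

    device_model: str
    device_unit_id: str
    strip_lot: str
    day_id: str
    condition: ConditionKey
    measured_hct: float
    replicate_index: int
    reading_value: float | None
    reading_unit: str
    reference_value: float | None
    error_code: str | None
    user_error: bool = False

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.reading_unit not in VALID_UNITS:
            raise RecordValidationError(
                f"unknown reading unit {self.reading_unit!r}; expected one of {VALID_UNITS}"
            )
        has_reading = self.reading_value is not None
        has_error = self.error_code is not None and str(self.error_code).strip() != ""
        if has_reading == has_error:
            raise RecordValidationError(
                "record must carry exactly one of a reading or an error code "
                f"(got reading={self.reading_value!r}, error_code={self.error_code!r})"
            )
        if self.replicate_index < 1:
            raise RecordValidationError("replicate_index must be >= 1")
        if not 0.0 <= self.measured_hct <= 100.0:
            raise RecordValidationError(
                f"measured hematocrit {self.measured_hct!r} outside 0-100%"
            )

    # -- derived views ----------------------------------------------------

    @property
    def is_device_error(self) -> bool:
        """Instrument-reported error on a non-user-error row."""
        return self.error_code is not None and not self.user_error

    @property
    def is_valid_reading(self) -> bool:
        """Numeric reading usable for statistics."""
        return self.reading_value is not None and not self.user_error

    def reading_mgdl(self) -> float | None:
        """Reading on the mg/dL scale regardless of the native unit."""
        if self.reading_value is None:
            return None
        if self.reading_unit == MMOL:
            return convert_to_mgdl(self.reading_value)
        return float(self.reading_value)


@dataclass
class ErrorTally:
    """Per-device count of valid samples vs instrument errors.

    ``error_rate_pct`` is ``100 * errors / (valid + errors)`` rounded to one
    decimal, or ``None`` when the device contributed no records at all.
    """

    device_model: str
    n_valid: int
    n_device_errors: int
    error_rate_pct: float | None


# -- unit conversions ------------------------------------------------------


def convert_to_mgdl(value_mmol: float) -> float:
    """Convert a glucose concentration from mmol/L to mg/dL (x 18)."""
    if value_mmol < 0:
        raise ValueError(f"glucose concentration must be non-negative, got {value_mmol}")
    return float(value_mmol) * MGDL_PER_MMOL

def plasma_equivalent(whole_blood_glucose_mgdl: float) -> float:
    """Whole-blood glucose -> equivalent plasma glucose (x 1.11).

    Provided as a reference utility only: the analysis pipeline never applies
    it, because both meters and the reference analyzer already report
    plasma-equivalent values.  The factor assumes a normal adult hematocrit,
    which is one mechanism behind hematocrit interference at the extremes.
    """
    if whole_blood_glucose_mgdl < 0:
        raise ValueError(
            f"glucose concentration must be non-negative, got {whole_blood_glucose_mgdl}"
        )
    return float(whole_blood_glucose_mgdl) * PLASMA_CORRECTION_FACTOR


# -- error accounting ------------------------------------------------------


def tally_errors(records: Iterable[MeasurementRecord]) -> list[ErrorTally]:
    """Count valid samples and device errors per device model.

    User-error rows are excluded from both numerator and denominator: they
    represent operator mistakes that were repeated or dropped, not
    instrument faults.
    """
    valid: dict[str, int] = {}
    errors: dict[str, int] = {}
    for rec in records:
        valid.setdefault(rec.device_model, 0)
        errors.setdefault(rec.device_model, 0)
        if rec.user_error:
            continue
        if rec.reading_value is not None:
            valid[rec.device_model] += 1
        elif rec.error_code is not None:
            errors[rec.device_model] += 1
    tallies = []
    for model in sorted(valid):
        n_v, n_e = valid[model], errors[model]
        denom = n_v + n_e
        rate = round(100.0 * n_e / denom, 1) if denom else None
        tallies.append(ErrorTally(model, n_v, n_e, rate))
    return tallies


# -- CSV I/O ---------------------------------------------------------------


def load_schema_config(path: str | Path) -> dict:
    """Load a YAML/JSON column-map config ({canonical name: file column})."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, Mapping):
        raise ValueError(f"schema config {path} must be a mapping")
    return dict(cfg)


_TRUE = {"true", "1", "yes", "y", "t"}
_FALSE = {"false", "0", "no", "n", "f", ""}


def _parse_bool(raw: str, line: int) -> bool:
    s = str(raw).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise RecordValidationError(f"line {line}: cannot parse boolean {raw!r}")


def _opt_float(raw) -> float | None:
    s = str(raw).strip()
    if s == "" or s.lower() in ("nan", "none", "na"):
        return None
    return float(s)


def read_measurements(
    path: str | Path,
    schema_config: Mapping[str, str] | str | Path | None = None,
    log_path: str | Path | None = None,
) -> list[MeasurementRecord]:
    """Read and validate a long-format measurement CSV.

    Parameters
    ----------
    path
        CSV file with the canonical columns (or columns remappable through
        ``schema_config``).
    schema_config
        Optional mapping ``{canonical column: file column}`` or path to a
        YAML/JSON file holding one.  Unlisted columns keep canonical names.
    log_path
        Where to write the JSON parse log (row counts plus per-row rejects
        with line numbers).  Defaults to no log file.

    Rows violating record invariants are rejected (collected in the parse
    log) rather than aborting the read; a missing required column or an
    unknown reading unit is fatal.
    """
    path = Path(path)
    if schema_config is not None and not isinstance(schema_config, Mapping):
        schema_config = load_schema_config(schema_config)
    colmap = {c: c for c in CANONICAL_COLUMNS}
    if schema_config:
        colmap.update({k: v for k, v in schema_config.items() if k in colmap})

    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [v for v in colmap.values() if v not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")

    records: list[MeasurementRecord] = []
    rejects: list[dict] = []
    for i in range(len(df)):
        line = i + 2  # header is line 1
        raw = {c: df.iloc[i][colmap[c]] for c in CANONICAL_COLUMNS}
        unit = str(raw["reading_unit"]).strip()
        if unit not in VALID_UNITS:
            raise UnknownUnitError(f"{path} line {line}: unknown reading unit {unit!r}")
        try:
            rec = MeasurementRecord(
                device_model=str(raw["device_model"]).strip(),
                device_unit_id=str(raw["device_unit_id"]).strip(),
                strip_lot=str(raw["strip_lot"]).strip(),
                day_id=str(raw["day_id"]).strip(),
                condition=ConditionKey(
                    int(float(raw["target_hct"])), int(float(raw["target_glucose"]))
                ),
                measured_hct=float(raw["measured_hct"]),
                replicate_index=int(float(raw["replicate"])),
                reading_value=_opt_float(raw["reading"]),
                reading_unit=unit,
                reference_value=_opt_float(raw["reference"]),
                error_code=(str(raw["error_code"]).strip() or None),
                user_error=_parse_bool(raw["user_error"], line),
            )
        except (RecordValidationError, ValueError) as exc:
            rejects.append({"line": line, "reason": str(exc)})
            continue
        records.append(rec)

    log = {
        "input": str(path),
        "n_rows": int(len(df)),
        "n_records": len(records),
        "n_rejected": len(rejects),
        "rejects": rejects,
    }
    if log_path is not None:
        Path(log_path).write_text(json.dumps(log, indent=2))
    return records


def records_to_frame(records: Sequence[MeasurementRecord]) -> pd.DataFrame:
    """Records -> canonical-column DataFrame (native units preserved)."""
    rows = []
    for r in records:
        rows.append(
            {
                "device_model": r.device_model,
                "device_unit_id": r.device_unit_id,
                "strip_lot": r.strip_lot,
                "day_id": r.day_id,
                "target_hct": r.condition.target_hct,
                "target_glucose": r.condition.target_glucose,
                "measured_hct": r.measured_hct,
                "replicate": r.replicate_index,
                "reading": r.reading_value,
                "reading_unit": r.reading_unit,
                "reference": r.reference_value,
                "error_code": r.error_code if r.error_code is not None else "",
                "user_error": r.user_error,
            }
        )
    return pd.DataFrame(rows, columns=CANONICAL_COLUMNS)


def write_measurements(records: Sequence[MeasurementRecord], path: str | Path) -> None:
    """Write records as a canonical CSV (round-trips through read)."""
    records_to_frame(records).to_csv(path, index=False)
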