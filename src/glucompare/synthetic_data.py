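"""Study simulator with known ground truth.

Emulates the laboratory design of a stratified glucometer evaluation:
blood panels prepared at target hematocrits {18, 40, 55}% and target
glucose levels {40, 150} mg/dL, measured on multiple days with five
replicates per day per condition on a reference analyzer and on each
candidate meter.

Device behaviour is parameterized per model:

* ``base_bias_pct`` — proportional bias at 40% hematocrit;
* ``hct_coeff_pct_per_hct`` — additional percent bias per hematocrit point
  away from 40% (linear hematocrit interference);
* ``sigma_low_pct`` / ``sigma_high_pct`` — relative noise SD at 40 and
  150 mg/dL, interpolated linearly in glucose between the anchors (strip
  meters are typically less precise at low glucose);
* ``error_rate`` — per-measurement probability of an instrument error code;
* ``display_floor`` — readings below it become "lo" error records;
* ``reads_mmol`` — emit readings in mmol/L (value / 18).

The expected reading for a replicate at true glucose G and hematocrit H is

    G * (1 + [base_bias + hct_coeff * (H - 40)] / 100)

with Gaussian relative noise around it.  All randomness flows from one
seeded generator in a documented draw order (panel jitter, then reference
replicates, then devices in the order given), so a dataset is reproducible
bit-for-bit from the seed recorded in its truth manifest.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .measurements_io import (
    DEFAULT_CONDITIONS,
    MGDL,
    MMOL,
    MGDL_PER_MMOL,
    ConditionKey,
    MeasurementRecord,
)

COST_TIERS = ("meets_TPP", "exceeds_2_3x", "exceeds_20x", "unknown")


@dataclass
class DeviceProfile:
    """Simulator ground truth for one device model."""

    device_model: str
    base_bias_pct: float = 0.0
    hct_coeff_pct_per_hct: float = 0.0
    sigma_low_pct: float = 0.0
    sigma_high_pct: float = 0.0
    error_rate: float = 0.0
    reads_mmol: bool = False
    display_floor: float | None = None
    cost_tier: str = "unknown"

    def __post_init__(self) -> None:
        if self.sigma_low_pct < 0 or self.sigma_high_pct < 0:
            raise ValueError("noise SDs must be non-negative")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must be a probability")
        if self.cost_tier not in COST_TIERS:
            raise ValueError(f"cost_tier must be one of {COST_TIERS}")

    def sigma_pct(self, glucose_mgdl: float) -> float:
        """Relative noise SD (%) at a glucose level, linear between anchors."""
        g = float(np.clip(glucose_mgdl, 40.0, 150.0))
        w = (g - 40.0) / 110.0
        return (1.0 - w) * self.sigma_low_pct + w * self.sigma_high_pct

    def expected_bias_pct(self, hct: float) -> float:
        """Expected percent bias at a hematocrit level."""
        return self.base_bias_pct + self.hct_coeff_pct_per_hct * (hct - 40.0)


@dataclass
class StudyDesign:
    """Shape and noise of the simulated study.

    Defaults mirror the laboratory design being emulated: the six
    hematocrit x glucose strata, five replicates per day per condition, a
    six-day campaign, ~1% relative scatter on reference replicates, and
    day-to-day jitter of the realized levels (SD 2 hematocrit points,
    5 mg/dL glucose) because samples cannot be re-prepared identically.
    """

    conditions: tuple[ConditionKey, ...] = DEFAULT_CONDITIONS
    days: int = 6
    replicates_per_day: int = 5
    reference_sigma_pct: float = 1.0
    hct_jitter_sd: float = 2.0
    glucose_jitter_sd: float = 5.0
    units_per_device: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates_per_day < 1:
            raise ValueError("replicates_per_day must be >= 1")
        for v in (self.reference_sigma_pct, self.hct_jitter_sd, self.glucose_jitter_sd):
            if v < 0:
                raise ValueError("noise/jitter SDs must be >= 0")


@dataclass
class PanelSample:
    """Realized (glucose, hematocrit) of one day's sample for one condition."""

    day_id: str
    condition: ConditionKey
    true_glucose: float
    true_hct: float


def simulate_panel(design: StudyDesign, rng: np.random.Generator | None = None) -> list[PanelSample]:
    """Realized panel levels: targets plus Gaussian day-to-day jitter.

    Realized values are truncated to physiologic bounds (glucose >= 10
    mg/dL, hematocrit 5-70%).  Deterministic given the design seed.
    """
    rng = np.random.default_rng(design.seed) if rng is None else rng
    panel = []
    for d in range(design.days):
        day_id = f"day{d + 1:02d}"
        for cond in sorted(design.conditions):
            g = cond.target_glucose + rng.normal(0.0, design.glucose_jitter_sd)
            h = cond.target_hct + rng.normal(0.0, design.hct_jitter_sd)
            panel.append(
                PanelSample(
                    day_id=day_id,
                    condition=cond,
                    true_glucose=float(max(g, 10.0)),
                    true_hct=float(np.clip(h, 5.0, 70.0)),
                )
            )
    return panel


def simulate_reference(
    panel: Sequence[PanelSample],
    design: StudyDesign,
    rng: np.random.Generator,
) -> dict[tuple[str, ConditionKey], np.ndarray]:
    """Reference-analyzer replicates: Gaussian around the realized glucose."""
    out = {}
    for s in panel:
        sd = s.true_glucose * design.reference_sigma_pct / 100.0
        out[(s.day_id, s.condition)] = rng.normal(
            s.true_glucose, sd, size=design.replicates_per_day
        )
    return out


def simulate_device(
    panel: Sequence[PanelSample],
    profile: DeviceProfile,
    design: StudyDesign,
    rng: np.random.Generator,
    reference: Mapping[tuple[str, ConditionKey], np.ndarray],
) -> list[MeasurementRecord]:
    """Meter records for one device across the whole panel.

    Draw order per replicate: error-code Bernoulli first, then the reading.
    Readings at or below the display floor (or non-positive) become "lo"
    error records; mmol/L models emit value / 18 with the mmol/L unit.
    """
    records = []
    floor = profile.display_floor
    for s in panel:
        refs = reference[(s.day_id, s.condition)]
        sigma = profile.sigma_pct(s.true_glucose)
        expected = s.true_glucose * (1.0 + profile.expected_bias_pct(s.true_hct) / 100.0)
        for unit in range(design.units_per_device):
            unit_id = f"{profile.device_model}-U{unit + 1}"
            lot = f"lot{unit + 1}"
            for rep in range(design.replicates_per_day):
                reading: float | None
                error: str | None = None
                if profile.error_rate > 0 and rng.uniform() < profile.error_rate:
                    reading = None
                    error = "ERR"
                else:
                    # noise scales with the true level, so sigma_*_pct is
                    # exactly the SD of the percent deviation from truth
                    reading = float(rng.normal(expected, s.true_glucose * sigma / 100.0))
                    if reading <= 0 or (floor is not None and reading < floor):
                        reading, error = None, "lo"
                    elif profile.reads_mmol:
                        reading = reading / MGDL_PER_MMOL
                records.append(
                    MeasurementRecord(
                        device_model=profile.device_model,
                        device_unit_id=unit_id,
                        strip_lot=lot,
                        day_id=s.day_id,
                        condition=s.condition,
                        measured_hct=s.true_hct,
                        replicate_index=rep + 1,
                        reading_value=reading,
                        reading_unit=MMOL if profile.reads_mmol else MGDL,
                        reference_value=float(refs[rep]),
                        error_code=error,
                        user_error=False,
                    )
                )
    return records


def simulate_study(
    design: StudyDesign,
    profiles: Sequence[DeviceProfile],
) -> tuple[list[MeasurementRecord], dict]:
    """Full study: panel, reference replicates, every device, plus manifest.

    Returns the flat record list and a truth manifest holding the design,
    every profile, and the seed — enough to regenerate the dataset
    bit-identically and to score parameter recovery.
    """
    rng = np.random.default_rng(design.seed)
    panel = simulate_panel(design, rng)
    reference = simulate_reference(panel, design, rng)
    records: list[MeasurementRecord] = []
    for profile in profiles:
        records.extend(simulate_device(panel, profile, design, rng, reference))
    manifest = {
        "seed": design.seed,
        "design": _design_dict(design),
        "profiles": [dataclasses.asdict(p) for p in profiles],
    }
    return records, manifest


# -- manifest and profile I/O ----------------------------------------------


def _design_dict(design: StudyDesign) -> dict:
    d = dataclasses.asdict(design)
    d["conditions"] = [
        {"target_hct": c.target_hct, "target_glucose": c.target_glucose}
        for c in design.conditions
    ]
    return d


def design_from_dict(d: Mapping) -> StudyDesign:
    kw = dict(d)
    if "conditions" in kw:
        kw["conditions"] = tuple(
            ConditionKey(int(c["target_hct"]), int(c["target_glucose"]))
            for c in kw["conditions"]
        )
    return StudyDesign(**kw)


def write_truth_manifest(
    profiles: Sequence[DeviceProfile], design: StudyDesign, path: str | Path
) -> None:
    """Write the ground-truth manifest (profiles + design + seed) as JSON."""
    manifest = {
        "seed": design.seed,
        "design": _design_dict(design),
        "profiles": [dataclasses.asdict(p) for p in profiles],
    }
    Path(path).write_text(json.dumps(manifest, indent=2))


def load_truth_manifest(path: str | Path) -> tuple[list[DeviceProfile], StudyDesign]:
    """Load a truth manifest; a manifest without a seed is rejected."""
    raw = json.loads(Path(path).read_text())
    if "seed" not in raw or raw["seed"] is None:
        raise ValueError(f"truth manifest {path} has no seed; dataset not reproducible")
    design = design_from_dict(raw["design"])
    if design.seed != raw["seed"]:
        raise ValueError(f"truth manifest {path}: seed disagrees with design seed")
    profiles = [DeviceProfile(**p) for p in raw["profiles"]]
    return profiles, design


def load_device_profiles(path: str | Path | None = None) -> list[DeviceProfile]:
    """Load device profiles from YAML; default: the packaged demo presets.

    The shipped presets are *synthetic illustrations* qualitatively shaped
    like commercial meter behaviour (signs of bias, hematocrit sensitivity,
    low-glucose imprecision, error rates); they are not measured device
    parameters and must not be quoted as such.
    """
    if path is None:
        text = resources.files("glucompare.data").joinpath("device_profiles.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    entries = raw["profiles"] if isinstance(raw, Mapping) else raw
    return [DeviceProfile(**e) for e in entries]
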