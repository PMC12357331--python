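"""End-to-end analysis orchestration: records in, ranked results out."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .accuracy_stats import AccuracySummary, summarize
from .compliance_bands import BandClassification, band_table
from .error_grid import ZonePolygonSet, ZoneResult, classify_condition_averages, load_zone_polygons
from .measurements_io import ErrorTally, MeasurementRecord, tally_errors
from .ranking_report import (
    DeviceRanking,
    bands_frame,
    rank_devices,
    ranking_frame,
    summaries_frame,
    zones_frame,
)
from .reference_truth import (
    DeviationPoint,
    DriftReport,
    ReferenceTruth,
    build_truth,
    compute_deviations,
    truth_drift_check,
)


@dataclass
class AnalysisResult:
    """Everything one analysis run produces, in computation order."""

    truths: list[ReferenceTruth]
    points: list[DeviationPoint]
    summaries: list[AccuracySummary]
    bands: list[BandClassification]
    zones: list[ZoneResult]
    tallies: list[ErrorTally]
    rankings: list[DeviceRanking]
    drift: list[DriftReport]

    def frames(self) -> dict[str, pd.DataFrame]:
        """Artifact tables keyed by name (ready for CSV/report rendering)."""
        dev = pd.DataFrame(
            [
                {
                    "device_model": p.device_model,
                    "day_id": p.day_id,
                    "target_hct": p.condition.target_hct,
                    "target_glucose": p.condition.target_glucose,
                    "meter_mgdl": p.meter_value,
                    "true_mgdl": p.true_value,
                    "percent_deviation": p.percent_deviation,
                }
                for p in self.points
            ]
        )
        truths = pd.DataFrame(
            [
                {
                    "day_id": t.day_id,
                    "target_hct": t.condition.target_hct,
                    "target_glucose": t.condition.target_glucose,
                    "mean_reference": t.mean_reference,
                    "n_replicates": t.n_replicates,
                    "mean_measured_hct": t.mean_measured_hct,
                }
                for t in self.truths
            ]
        )
        tallies = pd.DataFrame(
            [
                {
                    "device_model": t.device_model,
                    "n_valid": t.n_valid,
                    "n_device_errors": t.n_device_errors,
                    "error_rate_pct": t.error_rate_pct,
                }
                for t in self.tallies
            ]
        )
        return {
            "truths": truths,
            "deviations": dev,
            "summary": summaries_frame(self.summaries),
            "bands": bands_frame(self.bands),
            "zones": zones_frame(self.zones),
            "tallies": tallies,
            "ranking": ranking_frame(self.rankings),
        }


def run_analysis(
    records: Sequence[MeasurementRecord],
    grid: ZonePolygonSet | None = None,
    cost_config: Mapping[str, str] | None = None,
    drift_threshold_pct: float = 5.0,
    sd_gate: float = 10.0,
    sd_red: float = 15.0,
) -> AnalysisResult:
    """Run the full evaluation pipeline on validated records."""
    grid = grid if grid is not None else load_zone_polygons()
    truths = build_truth(records)
    points = compute_deviations(records, truths)
    summaries = summarize(points)
    bands = band_table(points, summaries)
    zones = classify_condition_averages(summaries, grid)
    tallies = tally_errors(records)
    rankings = rank_devices(
        summaries, bands, zones, cost_config, sd_gate=sd_gate, sd_red=sd_red
    )
    drift = truth_drift_check(truths, drift_threshold_pct)
    return AnalysisResult(
        truths=truths,
        points=points,
        summaries=summaries,
        bands=bands,
        zones=zones,
        tallies=tallies,
        rankings=rankings,
        drift=drift,
    )


def write_artifacts(result: AnalysisResult, out_dir: str | Path) -> dict[str, Path]:
    """Write all artifact tables as CSV plus the drift report as JSON."""
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in result.frames().items():
        p = out / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p
    drift = [
        {
            "day_id": d.day_id,
            "target_hct": d.condition.target_hct,
            "target_glucose": d.condition.target_glucose,
            "slope_per_replicate": d.slope_per_replicate,
            "first_to_last_pct": d.first_to_last_pct,
            "flagged": d.flagged,
        }
        for d in result.drift
    ]
    p = out / "drift.json"
    p.write_text(json.dumps(drift, indent=2))
    paths["drift"] = p
    return paths
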