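"""Device ranking (Groups 1-4) and report rendering.

The ranking reduces each device's stratified results to one of four groups,
best to worst, by an explicit, configurable rule.  Published device
rankings of this kind are narrative; the rule here is a deterministic
reconstruction combining accuracy banding, precision and consumable cost:

* **Group 4** — any condition red (|mean bias| > 15%), or SD > ``sd_red``
  (default 15%) at a low-glucose condition, or any condition average in
  error-grid zone C or worse: serious accuracy/precision failures.
* **Group 3** — otherwise, any orange condition (8 < |bias| <= 15%), or an
  SD above the precision gate ``sd_gate`` (default 10%): usable with
  caution.
* **Groups 1/2** — all conditions green and precise; split by consumable
  cost tier: devices whose consumables exceed the target cost land in
  Group 1 (best performance, cost-limited availability), affordable ones
  in Group 2.

The rule is monotone: improving a device's bias or SD never worsens its
group, and assignments are a pure function of the inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .accuracy_stats import AccuracySummary
from .compliance_bands import GREEN, ORANGE, RED, BandClassification
from .error_grid import ZoneResult

#: cost tiers considered "high cost" (split Group 1 from Group 2)
HIGH_COST_TIERS = ("exceeds_2_3x", "exceeds_20x")
#: glucose level (mg/dL) at or below which a condition counts as low-glucose
LOW_GLUCOSE_MGDL = 70.0


@dataclass
class DeviceRanking:
    device_model: str
    group: int
    rationale: str
    cost_tier: str


def rank_devices(
    summaries: Sequence[AccuracySummary],
    bands: Sequence[BandClassification],
    zones: Sequence[ZoneResult] | None = None,
    cost_config: Mapping[str, str] | None = None,
    sd_gate: float = 10.0,
    sd_red: float = 15.0,
) -> list[DeviceRanking]:
    """Assign each device to Group 1-4 by the documented rule.

    ``cost_config`` maps device model -> cost tier; unlisted models are
    ``unknown`` (treated as affordable).  Devices with no summaries are
    excluded.  Missing conditions do not disqualify a device; they simply
    contribute nothing, and are noted in the rationale.
    """
    cost_config = dict(cost_config or {})
    by_device: dict[str, dict] = {}
    for s in summaries:
        d = by_device.setdefault(s.device_model, {"bands": [], "sds": [], "low_sds": [], "zones": [], "n_cond": 0})
        d["n_cond"] += 1
        if s.sd_percent is not None:
            d["sds"].append(s.sd_percent)
            if s.condition.target_glucose <= LOW_GLUCOSE_MGDL:
                d["low_sds"].append(s.sd_percent)
    for b in bands:
        if b.band is not None and b.device_model in by_device:
            by_device[b.device_model]["bands"].append(b.band)
    for z in zones or []:
        if z.device_model in by_device:
            by_device[z.device_model]["zones"].append(z.zone)

    rankings = []
    for model in sorted(by_device):
        d = by_device[model]
        tier = cost_config.get(model, "unknown")
        bandset = set(d["bands"])
        reasons = []
        if d["n_cond"] < 6:
            reasons.append(f"only {d['n_cond']} condition(s) summarized")
        bad_zone = any(z in ("C", "D", "E") for z in d["zones"])
        low_imprecise = any(sd > sd_red for sd in d["low_sds"])
        if RED in bandset or low_imprecise or bad_zone:
            if RED in bandset:
                reasons.append("mean bias beyond +/-15% in at least one condition")
            if low_imprecise:
                reasons.append(f"SD > {sd_red:g}% at low glucose")
            if bad_zone:
                reasons.append("condition average in error-grid zone C or worse")
            group = 4
        elif ORANGE in bandset or any(sd > sd_gate for sd in d["sds"]):
            if ORANGE in bandset:
                reasons.append("mean bias between 8 and 15% in at least one condition")
            if any(sd > sd_gate for sd in d["sds"]):
                reasons.append(f"SD above the {sd_gate:g}% precision gate")
            group = 3
        else:
            reasons.append("all conditions within +/-8% with high precision")
            if tier in HIGH_COST_TIERS:
                reasons.append("consumable cost above target")
                group = 1
            else:
                group = 2
        rankings.append(
            DeviceRanking(
                device_model=model,
                group=group,
                rationale="; ".join(reasons),
                cost_tier=tier,
            )
        )
    return rankings


# -- report rendering ------------------------------------------------------


@dataclass
class ReportBundle:
    """Paths of the artifacts a report run produced, plus notices."""

    tables: dict[str, Path]
    figures: dict[str, Path]
    summary_md: Path | None
    notices: list[str]


def _cond_cols(df_row_cond) -> dict:
    return {
        "target_hct": df_row_cond.target_hct,
        "target_glucose": df_row_cond.target_glucose,
    }


def summaries_frame(summaries: Sequence[AccuracySummary]) -> pd.DataFrame:
    rows = [
        {
            "device_model": s.device_model,
            **_cond_cols(s.condition),
            "n": s.n,
            "mean_percent_bias": s.mean_percent_bias,
            "mard": s.mard,
            "sd_percent": s.sd_percent,
            "loa_low": s.loa_low,
            "loa_high": s.loa_high,
            "mean_meter_mgdl": s.mean_meter_mgdl,
            "mean_reference_mgdl": s.mean_reference_mgdl,
        }
        for s in summaries
    ]
    return pd.DataFrame(rows)


def bands_frame(bands: Sequence[BandClassification]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "device_model": b.device_model,
                **_cond_cols(b.condition),
                "band": b.band,
                "frac_within_8": b.frac_within_8,
                "frac_within_15": b.frac_within_15,
                "frac_within_20": b.frac_within_20,
            }
            for b in bands
        ]
    )


def zones_frame(zones: Sequence[ZoneResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "device_model": z.device_model,
                **_cond_cols(z.condition),
                "reference_mgdl": z.reference_mgdl,
                "meter_mgdl": z.meter_mgdl,
                "meter_sd_mgdl": z.meter_sd_mgdl,
                "zone": z.zone,
            }
            for z in zones
        ]
    )


def ranking_frame(rankings: Sequence[DeviceRanking]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "device_model": r.device_model,
                "group": r.group,
                "cost_tier": r.cost_tier,
                "rationale": r.rationale,
            }
            for r in rankings
        ]
    ).sort_values(["group", "device_model"], kind="stable").reset_index(drop=True)


BAND_COLORS = {GREEN: "tab:green", ORANGE: "tab:orange", RED: "tab:red", None: "tab:gray"}


def render_report(out_dir: str | Path, artifacts: Mapping[str, pd.DataFrame]) -> ReportBundle:
    """Render figures and a markdown summary from analysis artifact tables.

    ``artifacts`` maps table names (``deviations``, ``summary``, ``bands``,
    ``zones``, ``ranking``, ``tallies``) to DataFrames; missing tables just
    drop the corresponding figure/section with a notice, so a partial
    analysis still renders.  Tables are re-written as CSV next to the
    figures; reruns on identical inputs are byte-identical.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables: dict[str, Path] = {}
    figures: dict[str, Path] = {}
    notices: list[str] = []

    for name in ("summary", "bands", "zones", "ranking", "tallies"):
        if name in artifacts:
            p = out / f"{name}.csv"
            artifacts[name].to_csv(p, index=False)
            tables[name] = p

    # Fig: per-condition deviation strip chart with the +/-8 / +/-15 bands
    if "deviations" in artifacts and "bands" in artifacts:
        dev = artifacts["deviations"]
        bnd = artifacts["bands"]
        models = sorted(dev["device_model"].unique())
        conds = sorted(
            dev[["target_hct", "target_glucose"]].drop_duplicates().itertuples(index=False),
            key=lambda c: (c.target_glucose, c.target_hct),
        )
        fig, axes = plt.subplots(
            1, len(models), figsize=(2.2 * len(models) + 2, 4.5), sharey=True
        )
        if len(models) == 1:
            axes = [axes]
        for ax, model in zip(axes, models):
            sub = dev[dev["device_model"] == model]
            for i, c in enumerate(conds):
                pts = sub[
                    (sub["target_hct"] == c.target_hct)
                    & (sub["target_glucose"] == c.target_glucose)
                ]
                row = bnd[
                    (bnd["device_model"] == model)
                    & (bnd["target_hct"] == c.target_hct)
                    & (bnd["target_glucose"] == c.target_glucose)
                ]
                band = row["band"].iloc[0] if len(row) else None
                ax.scatter(
                    [i] * len(pts),
                    pts["percent_deviation"],
                    s=8,
                    alpha=0.5,
                    color=BAND_COLORS.get(band, "tab:gray"),
                )
            for y in (8, -8):
                ax.axhline(y, ls="--", lw=0.8, color="0.4")
            for y in (15, -15):
                ax.axhline(y, ls=":", lw=0.8, color="0.4")
            ax.set_title(model, fontsize=8)
            ax.set_xticks(range(len(conds)))
            ax.set_xticklabels(
                [f"{c.target_hct}%\n{c.target_glucose}" for c in conds], fontsize=6
            )
        axes[0].set_ylabel("% deviation from reference average")
        fig.tight_layout()
        p = out / "fig_bands.png"
        fig.savefig(p, dpi=150)
        plt.close(fig)
        figures["bands"] = p
    else:
        notices.append("band figure skipped: deviations/bands table missing")

    # Fig: MARD by model and condition
    if "summary" in artifacts:
        summ = artifacts["summary"]
        pivot = summ.pivot_table(
            index="device_model",
            columns=["target_glucose", "target_hct"],
            values="mard",
        )
        fig, ax = plt.subplots(figsize=(1.1 * len(pivot) + 3, 4))
        pivot.plot.bar(ax=ax, width=0.8)
        ax.set_ylabel("MARD (%)")
        ax.legend(title="glucose, Hct", fontsize=6, ncol=2)
        fig.tight_layout()
        p = out / "fig_mard.png"
        fig.savefig(p, dpi=150)
        plt.close(fig)
        figures["mard"] = p
    else:
        notices.append("MARD figure skipped: summary table missing")

    # Fig: Parkes error grid with condition averages
    if "zones" in artifacts:
        from .error_grid import load_zone_polygons

        grid = load_zone_polygons()
        zdf = artifacts["zones"]
        fig, ax = plt.subplots(figsize=(6, 6))
        for key in ("AB", "BC", "CD", "DE"):
            v = grid.upper[key]
            ax.plot(v[:, 0], v[:, 1], lw=1, color="0.3")
        for key in ("AB", "BC", "CD"):
            v = grid.lower[key]
            ax.plot(v[:, 0], v[:, 1], lw=1, color="0.3")
        ax.plot([0, 550], [0, 550], lw=1, color="k")
        for model, sub in zdf.groupby("device_model"):
            ax.errorbar(
                sub["reference_mgdl"],
                sub["meter_mgdl"],
                yerr=sub["meter_sd_mgdl"],
                fmt="o",
                ms=4,
                capsize=2,
                label=model,
            )
        ax.set_xlim(0, 250)
        ax.set_ylim(0, 250)
        ax.set_xlabel("reference glucose (mg/dL)")
        ax.set_ylabel("meter glucose (mg/dL)")
        ax.legend(fontsize=6)
        fig.tight_layout()
        p = out / "fig_errorgrid.png"
        fig.savefig(p, dpi=150)
        plt.close(fig)
        figures["errorgrid"] = p
    else:
        notices.append("error-grid figure skipped: zones table missing")

    # markdown summary
    lines = ["# Glucometer evaluation report", ""]
    if "ranking" in artifacts:
        lines.append("## Device ranking (reconstructed grouping rule)")
        lines.append("")
        lines.append("```\n" + artifacts["ranking"].to_string(index=False) + "\n```")
        lines.append("")
    if "tallies" in artifacts:
        lines.append("## Device error rates")
        lines.append("")
        lines.append("```\n" + artifacts["tallies"].to_string(index=False) + "\n```")
        lines.append("")
    if "summary" in artifacts:
        lines.append("## Accuracy summaries (per device and condition)")
        lines.append("")
        rounded = artifacts["summary"].copy()
        for c in rounded.select_dtypes("float").columns:
            rounded[c] = rounded[c].round(1)
        lines.append("```\n" + rounded.to_string(index=False) + "\n```")
        lines.append("")
    for n in notices:
        lines.append(f"> notice: {n}")
    md = out / "report.md"
    md.write_text("\n".join(lines) + "\n")

    return ReportBundle(tables=tables, figures=figures, summary_md=md, notices=notices)
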