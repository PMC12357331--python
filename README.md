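# glucompare

Stratified method comparison for point-of-care (POC) blood-glucose meters.

Handheld adult glucometers are widely available and cheap, but before they
can be trusted for neonatal care they must be validated at the glucose
levels that matter for newborns (hypoglycemic ~40 mg/dL, hyperglycemic
~150 mg/dL) and across the wide hematocrit range seen in neonates
(anemic ~18% up to polycythemic ~55%), because strip-based meters are
known to be hematocrit-sensitive. `glucompare` implements the analysis
side of a laboratory evaluation of that kind: meters are measured in
replicate against a reference analyzer (e.g. a YSI 2300) on blood panels
prepared at each hematocrit × glucose stratum over multiple days, and the
package turns those paired records into the statistics, compliance bands,
error-grid zones and a device ranking that such a study reports. A
full-study simulator with known ground truth is included, so the entire
pipeline is testable without clinical data.

## What it computes

For each day *d* and condition *c*, the **true value** is the mean of that
day's reference replicates (nominally five). Each valid meter reading *y*
is expressed as a signed percent deviation from its own day's truth
*ȳ<sub>ref</sub>*:

> δ = 100 · (y − ȳ<sub>ref</sub>) / ȳ<sub>ref</sub>

Pooling deviations per (device, condition) across days, units and strip
lots gives:

- **mean percent bias** = mean(δ)
- **MARD** (mean absolute relative difference) = mean(|δ|)
- **SD** = sample standard deviation of δ (n − 1)
- **95% limits of agreement** at the condition's nominal glucose *G*:
  G · (1 + (bias ∓ 1.96·SD)/100)
- **accuracy bands**: mean bias within ±8% (UNICEF/NEST360 TPP & proposed
  CLIA limit) → *green*; within ±15% (ISO 15197:2015) → *orange*; beyond →
  *red*; plus per-point fractions within ±8/±15/±20%
- **Parkes consensus error grid** (Type 1) zones A–E for per-condition
  average points, using the published boundary vertices
- **device error rates**: instrument errors / (valid + errors), with
  user errors (operator mistakes) excluded from all statistics
- **device ranking** into Groups 1–4 by a deterministic, configurable rule
  combining worst-condition band, precision gates and consumable cost tier

Readings reported in mmol/L are converted at ingest (mg/dL = mmol/L × 18).

## Worked example

Simulate a six-day study of the 11 bundled demo device profiles (synthetic
presets, not measured parameters), analyze it, and render the report:

```sh
glucompare simulate --seed 7 --out measurements.csv
glucompare analyze --input measurements.csv --config conf.yaml --out analysis
glucompare report --from analysis
```

with `conf.yaml` supplying consumable cost tiers (procurement facts, never
computed):

```yaml
cost_tiers:
  StatStrip: exceeds_2_3x
  StatStrip Xpress 2: exceeds_2_3x
  HemoCue Glucose 201 RT: exceeds_2_3x
  Accu-Chek Instant: meets_TPP
  Accu-Chek Active: meets_TPP
```

`analysis/ranking.csv` then contains:

```
device_model,group,cost_tier,rationale
StatStrip,1,exceeds_2_3x,all conditions within +/-8% with high precision; consumable cost above target
StatStrip Xpress 2,1,exceeds_2_3x,all conditions within +/-8% with high precision; consumable cost above target
Accu-Chek Guide,2,unknown,all conditions within +/-8% with high precision
Accu-Chek GuideMe,2,unknown,all conditions within +/-8% with high precision
Accu-Chek Instant,2,meets_TPP,all conditions within +/-8% with high precision
Accu-Chek Performa,2,unknown,all conditions within +/-8% with high precision
Accu-Chek Active,3,meets_TPP,mean bias between 8 and 15% in at least one condition; SD above the 10% precision gate
GlucoNavii,3,unknown,mean bias between 8 and 15% in at least one condition; SD above the 10% precision gate
HemoCue Glucose 201 RT,4,exceeds_2_3x,mean bias beyond +/-15% in at least one condition; SD > 15% at low glucose
Nipro Premier,4,unknown,SD > 15% at low glucose
OneTouchUltra 2,4,unknown,SD > 15% at low glucose
```

Group 1 devices are accurate and precise everywhere but their consumables
cost more than the target product profile allows; Group 2 match that
performance at affordable cost; Group 3 show orange-band bias or
imprecision in some strata; Group 4 have disqualifying errors in
conditions that matter for neonates (e.g. SD above 15% at 40 mg/dL). The
first rows of `analysis/tallies.csv` for the two error-prone presets read
`HemoCue Glucose 201 RT,174,6,3.3` and `Nipro Premier,176,4,2.2` —
174 valid readings, 6 instrument errors, a 3.3% error rate, and so on.
The accompanying `summary.csv`, `bands.csv`, `zones.csv` and the three
figures (`fig_bands.png`, `fig_mard.png`, `fig_errorgrid.png`) mirror the
tables and plots such a study publishes.

The same operations are available as a library:

```python
import glucompare as gc

records = gc.read_measurements("measurements.csv")
result = gc.run_analysis(records)
result.summaries[0].mard, result.rankings[0].group
```

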