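# Methods

## Study model

The package analyzes (and simulates) a stratified method-comparison study
of point-of-care glucometers. The design has six strata — target
hematocrit {18, 40, 55}% × target glucose {40, 150} mg/dL — measured on
several days. On each day, for each stratum, one blood sample is prepared
and measured in five replicates on a reference analyzer and on every
candidate meter. Because a sample can never be re-prepared at exactly the
same levels on another day, strata are keyed by their *nominal* targets
and all per-day variation is absorbed by the per-day truth: the mean of
that day's reference replicates. Deviations are therefore always computed
within a day and only then pooled across days, units and strip lots for a
(device, condition) cell.

Two failure modes are kept strictly apart. *User errors* (operator
mistakes such as under-filled strips) are retained in the data with a
flag for auditability but are invisible to every statistic, including
error counting — in the lab they are repeated or dropped. *Device errors*
(instrument-reported faults, including "lo" readings below the display
floor) carry no numeric value and are counted: the per-device error rate
is `100 · errors / (valid + errors)`, reported to one decimal. The
denominator includes the errors themselves, which reproduces worked
examples such as 4 errors among 110 attempts → 3.6%.

All computation is in mg/dL; meters reporting mmol/L are converted at
ingest with the exact factor 18. The 1.11 whole-blood→plasma factor is
provided as a documented utility only — both meters and the reference
report plasma-equivalent values, so the pipeline never applies it.

## Statistics

Per (device, condition) cell, over pooled signed percent deviations δ:
mean percent bias = mean(δ); MARD = mean(|δ|); SD = sample standard
deviation with the n−1 denominator (the denominator is a convention
choice; n−1 is the standard unbiased-variance default). Empty cells
propagate `None`, never a silent zero; SD requires n ≥ 2.

The 95% limits of agreement express bias ± 1.96·SD multiplicatively at
the condition's nominal glucose: `G · (1 + (bias ∓ z·SD)/100)` with
z = 1.96 configurable. This is the interval expected to contain 95% of
the device's readings at that glucose if percent deviations are
approximately normal; empirical coverage is verified by simulation in the
test suite.

### Compliance bands

A cell is banded by its mean percent bias: |bias| ≤ 8 → green (the
UNICEF/NEST360 target product profile's minimal accuracy limb, also the
proposed CLIA limit), 8 < |bias| ≤ 15 → orange (ISO 15197:2015 limb for
glucose ≥ 100 mg/dL), otherwise red (beyond even the ±20% limb of the
older 2003 ISO edition, tracked via per-point fractions). Boundary values
belong to the inner band ("within ±8%"). The percentage limits are
applied at *all* glucose levels: ISO 15197:2015 formally switches to a
±15 mg/dL absolute limb below 100 mg/dL, but a single relative rule keeps
low- and high-glucose strata directly comparable; the absolute limb is a
config extension point, deliberately not implemented. No claim of formal
ISO system-accuracy certification is made — that protocol prescribes a
95%-of-points criterion over a specified glucose distribution.

### Parkes error grid

Zone classification uses the consensus (Parkes) error grid for Type 1
diabetes with the published boundary vertex coordinates (Pfützner,
Klonoff, Pardo & Parkes, *J Diabetes Sci Technol* 2013), shipped as
`data/parkes_type1.json` and overridable by config. The boundaries are
piecewise-linear; classification evaluates the nested "no worse than k"
regions S_A ⊂ S_B ⊂ S_C ⊂ S_D, each bounded above by an upper boundary
(meter as a function of reference) and on the right by a lower boundary
(reference as a function of meter); there is no E zone below the identity
line in the Type 1 grid. A point's zone is the first region containing
it, so boundary points deterministically resolve to the lower-risk zone —
the conventional inclusive-toward-safer reading, and a necessary
tie-break for a true partition. The domain is the standard 0–550 mg/dL
square; out-of-domain points are rejected, or clamped with a warning in
pipeline use (a 600 mg/dL reading carries the same clinical meaning as
550). Explicit zone polygons are built from the same boundaries with
shapely for plotting and for an independent point-in-polygon cross-check;
load-time validation checks boundary nesting, the identity line (all zone
A) and agreement of the two representations on a coverage lattice.

Grid points can be classified individually, but the headline figure
classifies per-(device, condition) *average* points — mean reference vs
mean meter value pooled across days (pooled, not per-day, means; noted
here because either reading of "condition average" is defensible), with
the ±1 SD meter interval carried for plotting.

## Device ranking

The Group 1–4 ranking is a deterministic reconstruction of the narrative
grouping such studies publish, with thresholds in config:

* Group 4 — any red condition, or SD > 15% at a low-glucose condition, or
  any condition average in error-grid zone C or worse.
* Group 3 — otherwise any orange condition, or any SD above the 10%
  precision gate.
* Groups 1/2 — all green and precise; high consumable-cost tiers
  (`exceeds_2_3x`, `exceeds_20x`) → Group 1, affordable/unknown → Group 2.

Cost tiers are configuration inputs, never computed. The rule is monotone
(improving bias or SD never worsens the group) and a pure function of its
inputs; the report labels it as a reconstruction. The low-glucose SD gate
targets trend detection in neonatal care, where precision at ~40 mg/dL is
what matters clinically.

## Simulator

`synthetic_data` emulates the study with known ground truth. Per design:
realized levels = targets + Gaussian jitter (defaults: SD 2 hematocrit
points, 5 mg/dL glucose), truncated to physiologic bounds (glucose ≥ 10
mg/dL, hematocrit 5–70%); reference replicates are Gaussian around the
realized glucose with 1% relative SD (bench-analyzer replicate scatter);
five replicates/day/condition. The default campaign is six days — within
the 4–16-day-per-device range typical of such studies and large enough
for stable per-cell estimates (n = 30 per cell per unit).

Per device, the expected reading at true glucose G and hematocrit H is
`G · (1 + [base_bias + hct_coeff·(H − 40)]/100)`: proportional bias plus
a linear hematocrit-interference term centered on the normal-adult 40%
(the simplest form consistent with observed monotone hematocrit effects;
piecewise extensions are possible but not built). Noise is Gaussian with
SD `G · σ(G)/100`, where σ(G) interpolates linearly between `sigma_low`
at 40 mg/dL and `sigma_high` at 150 mg/dL (clamped outside) — the
minimal model of the commonly observed loss of precision at low glucose.
The noise scale is anchored to the *true* level rather than the biased
expected reading, so the injected σ is exactly the SD of the percent
deviations the pipeline estimates, making parameter recovery well defined.
Instrument errors occur with a per-measurement Bernoulli probability
(drawn before the reading); readings below the display floor (or ≤ 0)
become "lo" error records; mmol/L devices emit value/18 with the mmol/L
unit. All draws come from one seeded generator in documented order
(panel, then reference, then devices in the order supplied), so the truth
manifest's seed reproduces a dataset bit-for-bit; a manifest without a
seed is rejected.

What the simulator does *not* model: hemolysis, lipemia, temperature,
strip-lot drift, glycolysis drift within a replicate run, meter display
rounding, and any non-linear (e.g. U-shaped) hematocrit response. Passing
tests therefore demonstrate that the pipeline's estimators and
classifications are correct under the stated error model — not that any
real meter behaves like a preset. The bundled 11 profiles are synthetic
demo presets shaped to qualitative descriptions of commercial meters
(labelled as such in the file) so that the demo ranking exercises all
four groups; they are not measured parameters.

## Numerical and design choices

* Truth replicates are deduplicated by replicate index (the reference
  value travels on every device's record for the same replicate) and
  averaged; a group with no reference values is a hard error.
* The glycolysis drift check flags (day, condition) groups whose
  first-to-last reference change exceeds 5% (configurable; the threshold
  is a package default, chosen because a 5% shift is the magnitude at
  which the day-mean truth would start to visibly distort percent
  deviations). Report-only.
* Repeated-after-user-error measurements: both the flagged row and any
  repeat are kept; truth building and statistics use only non-flagged
  rows.
* Statistics use vectorized numpy; equivalence with naive loop
  implementations is asserted to 1e−9 in tests.
* Error-grid boundary ties go to the safer zone everywhere (classifier
  and polygon cross-check agree by construction of the validation).
* Rounding: error rates to one decimal (reporting convention); all other
  statistics keep full precision internally, with rounding only in
  rendered reports.
* Parameter recovery is scored by regressing per-condition mean biases on
  (hematocrit − 40): the intercept recovers the base bias and the slope
  the hematocrit coefficient. Recovery of a single condition-cell mean is
  limited by sampling noise (SE = σ/√n ≈ 0.63% at σ = 10%, n = 250), so
  profile-level parameter recovery is the sharper, well-posed check.

## Limitations

The pipeline evaluates *analytical* performance only: it cannot speak to
capillary-vs-venous differences, operator behaviour, or neonatal blood
properties beyond hematocrit and glucose. The ranking rule is an explicit
reconstruction of a narrative grouping, and no error grid has been
developed specifically for neonates — zones graded for adult Type 1
diabetes may under- or over-state clinical risk in newborns.
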