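import dataclasses
import math

import numpy as np
import pytest

from glucompare.measurements_io import DEFAULT_CONDITIONS, records_to_frame, tally_errors
from glucompare.pipeline import run_analysis
from glucompare.synthetic_data import (
    DeviceProfile,
    StudyDesign,
    design_from_dict,
    load_device_profiles,
    load_truth_manifest,
    simulate_panel,
    simulate_reference,
    simulate_study,
    write_truth_manifest,
)

ZERO_NOISE = dict(reference_sigma_pct=0.0, hct_jitter_sd=0.0, glucose_jitter_sd=0.0)


def test_zero_jitter_panel_hits_targets_exactly():
    panel = simulate_panel(StudyDesign(days=2, seed=3, **ZERO_NOISE))
    assert len(panel) == 12
    for s in panel:
        assert s.true_glucose == s.condition.target_glucose
        assert s.true_hct == s.condition.target_hct


def test_panel_jitter_sds_recovered_at_scale():
    design = StudyDesign(days=100, seed=9, hct_jitter_sd=2.0, glucose_jitter_sd=5.0)
    panel = simulate_panel(design)
    for cond in DEFAULT_CONDITIONS:
        g = np.array([s.true_glucose for s in panel if s.condition == cond])
        h = np.array([s.true_hct for s in panel if s.condition == cond])
        assert np.std(g, ddof=1) == pytest.approx(5.0, rel=0.2)
        assert np.std(h, ddof=1) == pytest.approx(2.0, rel=0.2)


def test_same_seed_reproduces_dataset_bit_identically():
    profiles = load_device_profiles()[:3]
    r1, m1 = simulate_study(StudyDesign(days=2, seed=5), profiles)
    r2, m2 = simulate_study(StudyDesign(days=2, seed=5), profiles)
    assert records_to_frame(r1).equals(records_to_frame(r2))
    assert m1 == m2
    r3, _ = simulate_study(StudyDesign(days=2, seed=6), profiles)
    assert not records_to_frame(r1).equals(records_to_frame(r3))


def test_reference_replicates_and_noise():
    design = StudyDesign(days=1, seed=0, **ZERO_NOISE)
    rng = np.random.default_rng(0)
    panel = simulate_panel(design, rng)
    refs = simulate_reference(panel, design, rng)
    for (day, cond), vals in refs.items():
        assert len(vals) == 5
        assert np.all(vals == cond.target_glucose)  # sigma 0 -> exact
    noisy_design = StudyDesign(days=200, seed=1, reference_sigma_pct=1.0,
                               hct_jitter_sd=0.0, glucose_jitter_sd=0.0)
    rng = np.random.default_rng(1)
    panel = simulate_panel(noisy_design, rng)
    refs = simulate_reference(panel, noisy_design, rng)
    pooled = np.concatenate([v / k[1].target_glucose for k, v in refs.items()])
    assert np.std(pooled, ddof=1) == pytest.approx(0.01, rel=0.1)
    assert np.mean(pooled) == pytest.approx(1.0, abs=3 * 0.01 / math.sqrt(pooled.size))


def test_sigma_interpolates_linearly_in_glucose():
    p = DeviceProfile("M", sigma_low_pct=10.0, sigma_high_pct=4.0)
    assert p.sigma_pct(40) == 10.0
    assert p.sigma_pct(150) == 4.0
    assert p.sigma_pct(95) == pytest.approx(7.0)
    assert p.sigma_pct(10) == 10.0  # clamped below the low anchor
    assert p.sigma_pct(300) == 4.0


def test_constant_negative_bias_flows_through_exactly():
    profile = DeviceProfile("M", base_bias_pct=-10.0)
    design = StudyDesign(days=2, seed=4, **ZERO_NOISE)
    records, _ = simulate_study(design, [profile])
    res = run_analysis(records)
    for s in res.summaries:
        assert s.mean_percent_bias == pytest.approx(-10.0, abs=1e-12)
        assert s.mard == pytest.approx(10.0, abs=1e-12)


def test_all_zero_profiles_null_pipeline():
    profiles = [DeviceProfile("Null A"), DeviceProfile("Null B", reads_mmol=True)]
    design = StudyDesign(days=3, seed=8, **ZERO_NOISE)
    records, _ = simulate_study(design, profiles)
    res = run_analysis(records)
    assert len(res.summaries) == 12
    for s in res.summaries:
        assert s.mean_percent_bias == 0.0
        assert s.mard == 0.0
        assert s.sd_percent == 0.0
    assert {b.band for b in res.bands} == {"green"}
    assert {z.zone for z in res.zones} == {"A"}


def test_error_rate_recovered_within_binomial_error():
    rate = 0.033
    profile = DeviceProfile("M", error_rate=rate)
    design = StudyDesign(days=10, units_per_device=3, seed=12)
    records, _ = simulate_study(design, [profile])
    (tally,) = tally_errors(records)
    n = tally.n_valid + tally.n_device_errors
    assert n == 10 * 6 * 5 * 3
    se = math.sqrt(rate * (1 - rate) / n)
    assert tally.n_device_errors / n == pytest.approx(rate, abs=3 * se)


def test_display_floor_yields_lo_errors():
    profile = DeviceProfile("M", display_floor=60.0)  # above the low target
    design = StudyDesign(days=1, seed=2, **ZERO_NOISE)
    records, _ = simulate_study(design, [profile])
    low = [r for r in records if r.condition.target_glucose == 40]
    assert all(r.error_code == "lo" and r.reading_value is None for r in low)
    high = [r for r in records if r.condition.target_glucose == 150]
    assert all(r.reading_value == 150.0 for r in high)


def test_mmol_device_emits_converted_unit():
    profile = DeviceProfile("M", reads_mmol=True)
    records, _ = simulate_study(StudyDesign(days=1, seed=2, **ZERO_NOISE), [profile])
    r = records[0]
    assert r.reading_unit == "mmol/L"
    assert r.reading_mgdl() == pytest.approx(r.condition.target_glucose)
    assert r.reading_value == pytest.approx(r.condition.target_glucose / 18.0)


def test_truth_manifest_round_trip(tmp_path):
    profiles = load_device_profiles()[:2]
    design = StudyDesign(days=2, seed=17)
    path = tmp_path / "truth.json"
    write_truth_manifest(profiles, design, path)
    profiles2, design2 = load_truth_manifest(path)
    assert profiles2 == profiles
    assert design2 == design
    # and the reloaded manifest regenerates the dataset bit-identically
    r1, _ = simulate_study(design, profiles)
    r2, _ = simulate_study(design2, profiles2)
    assert records_to_frame(r1).equals(records_to_frame(r2))


def test_manifest_without_seed_rejected(tmp_path):
    import json

    path = tmp_path / "truth.json"
    write_truth_manifest(load_device_profiles()[:1], StudyDesign(seed=3), path)
    raw = json.loads(path.read_text())
    del raw["seed"]
    path.write_text(json.dumps(raw))
    with pytest.raises(ValueError, match="no seed"):
        load_truth_manifest(path)


def test_design_validation():
    with pytest.raises(ValueError):
        StudyDesign(replicates_per_day=0)
    with pytest.raises(ValueError):
        DeviceProfile("M", error_rate=1.5)
    with pytest.raises(ValueError):
        DeviceProfile("M", sigma_low_pct=-1)
    d = design_from_dict({"days": 2, "seed": 1,
                          "conditions": [{"target_hct": 40, "target_glucose": 40}]})
    assert d.days == 2 and len(d.conditions) == 1


def test_preset_profiles_load_and_cover_eleven_models():
    profiles = load_device_profiles()
    assert len(profiles) == 11
    assert len({p.device_model for p in profiles}) == 11
    assert any(p.reads_mmol for p in profiles)
    assert any(p.error_rate > 0 for p in profiles)
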