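"""Generator contracts: shapes, determinism, truth fidelity, planted effects."""

import dataclasses

import numpy as np
import pytest

from beatwise.synthetic import (
    CohortConfig,
    EffectSpec,
    LEAD_NAMES,
    N_SAMPLES,
    WaveParams,
    ef_class_of,
    make_cohort,
    simulate_record,
)


def test_zero_amplitude_waves_give_zero_signal():
    waves = {w: dataclasses.replace(p, amplitude=0.0)
             for w, p in CohortConfig().waves.items()}
    waves["R"] = dataclasses.replace(waves["R"], amplitude=1e-30)
    cfg = CohortConfig(noise_sd=0.0, baseline_wander_amp=0.0, waves=waves)
    rec = simulate_record(cfg, 60.0, False, np.random.default_rng(0))
    assert np.allclose(rec.signal, 0.0, atol=1e-20)


def test_beat_count_at_60_bpm_without_jitter(clean_config):
    cfg = dataclasses.replace(clean_config, heart_rate_mean=60.0)
    rec = simulate_record(cfg, 62.0, False, np.random.default_rng(0))
    assert len(rec.truth) == 10


def test_signal_shape_and_class_consistency(clean_config):
    rec = simulate_record(clean_config, 45.0, False, np.random.default_rng(1))
    assert rec.signal.shape == (12, N_SAMPLES)
    assert rec.ef_class == "mrEF"
    for lvef, cls in [(39.9, "rEF"), (40.0, "mrEF"), (49.9, "mrEF"),
                      (50.0, "pEF")]:
        assert ef_class_of(lvef) == cls


def test_limb_lead_closure_noise_free(clean_config):
    cfg = dataclasses.replace(clean_config, baseline_wander_amp=0.05)
    rec = simulate_record(cfg, 55.0, False, np.random.default_rng(2))
    s = rec.signal
    assert np.abs(s[2] - (s[1] - s[0])).max() < 1e-9       # III = II - I
    assert np.abs(s[3] + (s[0] + s[1]) / 2).max() < 1e-9   # aVR = -(I+II)/2
    assert np.abs(s[4] - (s[0] - s[1] / 2)).max() < 1e-9   # aVL = I - II/2
    assert np.abs(s[5] - (s[1] - s[0] / 2)).max() < 1e-9   # aVF = II - I/2


def test_truth_r_peak_is_lead_ii_argmax(clean_record):
    s = clean_record.signal[1]
    for ann in clean_record.truth:
        lo, hi = ann.r_peak - 50, ann.r_peak + 50
        assert lo + np.argmax(s[lo:hi]) == ann.r_peak


def test_t_wave_effect_scales_amplitude_exactly(clean_config):
    eff = EffectSpec("ST-T", LEAD_NAMES, amplitude_multiplier=0.5,
                     applies_to_classes=("rEF",))
    cfg = dataclasses.replace(clean_config, effects=[eff])
    rec_r = simulate_record(cfg, 30.0, False, np.random.default_rng(5))
    rec_p = simulate_record(cfg, 65.0, False, np.random.default_rng(5))
    # sample at the T-wave centre of each beat: identical seed, identical
    # beat times, so the ratio is exactly the multiplier
    t_lat = int(round(cfg.waves["T"].latency_ms / 2.0))
    for ann in rec_r.truth:
        idx = ann.r_peak + t_lat
        if idx + 1 >= N_SAMPLES:
            continue
        ratio = rec_r.signal[1, idx] / rec_p.signal[1, idx]
        assert ratio == pytest.approx(0.5, abs=1e-9)


def test_lead_restricted_effect_leaves_other_leads_untouched(clean_config):
    eff = EffectSpec("ST-T", ("I",), amplitude_multiplier=0.3,
                     applies_to_classes=("rEF",))
    cfg = dataclasses.replace(clean_config, effects=[eff])
    rec_r = simulate_record(cfg, 30.0, False, np.random.default_rng(7))
    rec_p = simulate_record(cfg, 65.0, False, np.random.default_rng(7))
    assert not np.allclose(rec_r.signal[0], rec_p.signal[0])
    for row in range(6, 12):  # precordial leads unaffected
        np.testing.assert_allclose(rec_r.signal[row], rec_p.signal[row],
                                   atol=1e-12)


def test_cohort_counts_classes_and_determinism():
    cfg = CohortConfig(n_cases={"pEF": 10, "mrEF": 5, "rEF": 5}, seed=42)
    recs = make_cohort(cfg)
    assert len(recs) == 20
    classes = [r.ef_class for r in recs]
    assert classes.count("pEF") == 10
    assert classes.count("mrEF") == 5
    assert classes.count("rEF") == 5
    recs2 = make_cohort(CohortConfig(n_cases={"pEF": 10, "mrEF": 5,
                                              "rEF": 5}, seed=42))
    for a, b in zip(recs, recs2):
        assert np.array_equal(a.signal, b.signal)
        assert a.lvef == b.lvef


def test_lvef_sampled_within_class_interval():
    cfg = CohortConfig(n_cases={"pEF": 15, "mrEF": 15, "rEF": 15}, seed=3)
    for rec in make_cohort(cfg):
        if rec.ef_class == "pEF":
            assert rec.lvef >= 50.0
        elif rec.ef_class == "mrEF":
            assert 40.0 <= rec.lvef < 50.0
        else:
            assert rec.lvef < 40.0


def test_af_records_have_zero_p_amplitude():
    cfg = CohortConfig(n_cases={"pEF": 2, "mrEF": 2, "rEF": 5},
                       af_fraction={"pEF": 0.0, "mrEF": 0.0, "rEF": 1.0},
                       seed=8)
    for rec in make_cohort(cfg):
        if rec.ef_class == "rEF":
            assert rec.af
            assert rec.truth_waves["P"].amplitude == 0.0


def test_invalid_inputs_rejected():
    with pytest.raises(ValueError):
        CohortConfig(n_cases={"bogus": 3})
    with pytest.raises(ValueError):
        CohortConfig(lead_projection=np.ones((11, 3)))
    with pytest.raises(ValueError):
        CohortConfig(heart_rate_mean=-10.0)
    with pytest.raises(ValueError):
        make_cohort(CohortConfig(n_cases={"pEF": 0, "mrEF": 0, "rEF": 0}))
    with pytest.raises(ValueError):
        EffectSpec("ST-T", (), amplitude_multiplier=0.5)
    with pytest.raises(ValueError):
        EffectSpec("U", ("I",))
    with pytest.raises(ValueError):
        WaveParams(0.1, -5.0, 0.0)
    with pytest.raises(ValueError):
        simulate_record(CohortConfig(), 0.0, False, np.random.default_rng(0))
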