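"""Delineation, strip/beat extraction, segmentation and standardisation."""

import dataclasses

import numpy as np
import pytest

from beatwise import preprocess as pp
from beatwise.synthetic import (BeatAnnotation, CohortConfig, EcgRecord,
                                LEAD_NAMES, simulate_record)


# ---------------------------------------------------------------------------
# Delineation
# ---------------------------------------------------------------------------

def test_flatline_yields_no_beats():
    rec = EcgRecord(case_id="flat", signal=np.zeros((12, 5000)), lvef=60.0,
                    ef_class="pEF")
    assert pp.delineate(rec) == []


def test_delineation_matches_truth_noise_free(clean_record):
    anns = pp.delineate(clean_record)
    truth = clean_record.truth
    det_r = [a.r_peak for a in anns]
    # every truth beat recovered within 20 ms; at most one extra detection
    # (a record-edge beat the truth list excludes as truncated)
    for tru in truth:
        assert min(abs(d - tru.r_peak) for d in det_r) <= 10
    assert len(truth) <= len(anns) <= len(truth) + 1
    for det in anns:
        assert det.qrs_onset < det.r_peak < det.st_junction < det.t_end


def test_delineation_robust_to_measurement_noise(clean_config):
    cfg = dataclasses.replace(clean_config, noise_sd=0.02,
                              baseline_wander_amp=0.05,
                              rr_jitter_sd_ms=30.0)
    matched = total = 0
    for seed in range(5):
        rec = simulate_record(cfg, 60.0, False, np.random.default_rng(seed))
        det = [a.r_peak for a in pp.delineate(rec)]
        for tru in rec.truth:
            total += 1
            if det and min(abs(d - tru.r_peak) for d in det) <= 10:
                matched += 1
    assert matched / total >= 0.95


# ---------------------------------------------------------------------------
# Strips
# ---------------------------------------------------------------------------

def test_oversample_offsets_even_spacing():
    assert pp.oversample_offsets(1) == [0]
    assert pp.oversample_offsets(4) == [0, 1167, 2333, 3500]
    offs = pp.oversample_offsets(16)
    assert len(offs) == 16
    assert offs[0] == 0 and offs[-1] == 3500
    assert all(0 <= o <= 3500 for o in offs)
    assert offs == sorted(offs)
    with pytest.raises(ValueError):
        pp.oversample_offsets(0)


@pytest.mark.parametrize("role,cls,n", [
    ("train", "pEF", 4), ("train", "mrEF", 7), ("train", "rEF", 6),
    ("dev", "pEF", 4), ("dev", "mrEF", 16), ("dev", "rEF", 11),
    ("test", "pEF", 4), ("test", "mrEF", 16), ("test", "rEF", 11),
])
def test_oversampling_factors(clean_record, role, cls, n):
    strips = pp.extract_strips(clean_record, ef_class=cls, split_role=role)
    assert len(strips) == n
    for s in strips:
        assert s.data.shape == (12, 1500)
        assert 0 <= s.start_offset <= 3500


def test_extract_strips_rejects_unknown_class(clean_record):
    with pytest.raises(ValueError):
        pp.extract_strips(clean_record, ef_class="hfpef", split_role="train")
    with pytest.raises(ValueError):
        pp.extract_strips(clean_record, split_role="external")


# ---------------------------------------------------------------------------
# Single beats
# ---------------------------------------------------------------------------

def test_single_beats_window_and_t_end_padding(clean_record):
    beats = pp.extract_single_beats(clean_record, clean_record.truth)
    assert beats, "no beats extracted"
    for b in beats:
        assert b.data.shape == (12, 375)
        ann = b.annotation
        k = ann.t_end - b.window_start
        if 0 <= k < 375:
            expected = clean_record.signal[:, ann.t_end]
            for col in range(k, 375):
                np.testing.assert_array_equal(b.data[:, col], expected)
        # window is anchored at the R peak
        assert b.window_start == ann.r_peak - 125


def test_out_of_bounds_beats_dropped(clean_record):
    early = BeatAnnotation(r_peak=100, qrs_onset=73, st_junction=128,
                           t_end=289)
    beats = pp.extract_single_beats(clean_record, [early])
    assert beats == []


# ---------------------------------------------------------------------------
# Partial segments
# ---------------------------------------------------------------------------

@pytest.fixture()
def one_beat(clean_record):
    return pp.extract_single_beats(clean_record, clean_record.truth)[1]


def test_pqrst_partial_is_identity(one_beat):
    out = pp.make_partial(one_beat, kind="PQRST")
    np.testing.assert_array_equal(out.data, one_beat.data)


def test_p_segment_constant_after_boundary(one_beat):
    out = pp.make_partial(one_beat, kind="P")
    b = one_beat.annotation.qrs_onset - 50 - one_beat.window_start
    for col in range(b, 375):
        np.testing.assert_array_equal(out.data[:, col], out.data[:, b - 1])
    np.testing.assert_array_equal(out.data[:, :b], one_beat.data[:, :b])


def test_qrs_and_qrst_agree_on_shared_span(one_beat):
    ann = one_beat.annotation
    b = ann.qrs_onset - 50 - one_beat.window_start
    j = ann.st_junction - one_beat.window_start
    qrs = pp.make_partial(one_beat, kind="QRS")
    qrst = pp.make_partial(one_beat, kind="QRST")
    np.testing.assert_array_equal(qrs.data[:, b:j], qrst.data[:, b:j])


def test_segment_span_nesting(one_beat):
    """Unmasked spans satisfy P ⊂ PQRS ⊂ PQRST and QRS ⊂ QRST ⊂ PQRST."""
    spans = {k: pp._segment_span(one_beat.annotation, one_beat.window_start, k)
             for k in pp.SEGMENT_KINDS}

    def covers(outer, inner):
        return outer[0] <= inner[0] and inner[1] <= outer[1]

    assert covers(spans["PQRS"], spans["P"])
    assert covers(spans["PQRST"], spans["PQRS"])
    assert covers(spans["QRST"], spans["QRS"])
    assert covers(spans["PQRST"], spans["QRST"])


def test_partial_rejects_bad_boundaries(one_beat):
    # valid as a beat annotation, but its P/QRS boundary (onset - 50) falls
    # before the window start, so segmentation must refuse it
    ws = one_beat.window_start
    bad = BeatAnnotation(r_peak=ws + 60, qrs_onset=ws + 30,
                         st_junction=ws + 90, t_end=ws + 200)
    with pytest.raises(ValueError):
        pp.make_partial(one_beat, annotation=bad, kind="P")


# ---------------------------------------------------------------------------
# Two-beat composition
# ---------------------------------------------------------------------------

def test_two_beat_stacking_and_wraparound(clean_record):
    beats = pp.extract_single_beats(clean_record, clean_record.truth)
    pairs = pp.compose_two_beats(beats)
    n = len(beats)
    assert len(pairs) == n
    for i, pair in enumerate(pairs):
        assert pair.data.shape == (24, 375)
        np.testing.assert_array_equal(pair.data[:12], beats[i].data)
        np.testing.assert_array_equal(pair.data[12:], beats[(i + 1) % n].data)


def test_two_beat_minimal_input():
    rng = np.random.default_rng(0)
    b0 = pp.BeatTensor(data=rng.normal(size=(12, 375)), case_id="c")
    b1 = pp.BeatTensor(data=rng.normal(size=(12, 375)), case_id="c")
    pairs = pp.compose_two_beats([b0, b1])
    np.testing.assert_array_equal(pairs[0].data, np.vstack([b0.data, b1.data]))
    np.testing.assert_array_equal(pairs[1].data, np.vstack([b1.data, b0.data]))
    assert pp.compose_two_beats([]) == []


# ---------------------------------------------------------------------------
# Lead subsetting
# ---------------------------------------------------------------------------

def test_subset_leads_canonical_order(one_beat):
    sub = pp.subset_leads(one_beat, {"aVR", "I"})
    assert sub.leads == ("I", "aVR")
    assert sub.data.shape == (2, 375)
    np.testing.assert_array_equal(sub.data[0], one_beat.data[0])
    np.testing.assert_array_equal(sub.data[1], one_beat.data[3])
    ident = pp.subset_leads(one_beat, LEAD_NAMES)
    np.testing.assert_array_equal(ident.data, one_beat.data)
    single = pp.subset_leads(one_beat, {"I"})
    assert single.data.shape == (1, 375)
    with pytest.raises(ValueError):
        pp.subset_leads(one_beat, set())
    with pytest.raises(ValueError):
        pp.subset_leads(one_beat, {"W9"})


# ---------------------------------------------------------------------------
# Standardisation
# ---------------------------------------------------------------------------

def test_standardiser_self_transform_and_shift():
    rng = np.random.default_rng(0)
    train = rng.normal(loc=0.3, scale=0.7, size=(20, 12, 375))
    std = pp.fit_standardiser(train)
    z = std.transform(train)
    assert abs(z.mean()) < 1e-6
    assert abs(z.std() - 1.0) < 1e-6
    shifted = train + 5.0
    z2 = std.transform(shifted)
    assert z2.mean() == pytest.approx(5.0 / std.scale_, abs=1e-6)


def test_standardiser_rejects_constant_training_data():
    with pytest.raises(ValueError, match="constant"):
        pp.fit_standardiser(np.ones((4, 12, 375)))
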