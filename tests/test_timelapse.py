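"""Tracking, reporter traces, onset detection and fate classification."""

import numpy as np
import pytest

from phagequant.coloc import estimate_background
from phagequant.synthetic import SceneConfig, simulate_timelapse
from phagequant.timelapse import (FluorescenceTrace, Track, classify_fate,
                                  detect_onset, fate_confusion,
                                  population_curves, trace_fluorescence,
                                  track_cells)

TRUTH_TO_CALL = {"susceptible_lyse": "expressed_lysed",
                 "resistant_outgrow": "outgrowth",
                 "uninfected": "uninfected"}


def _static_masks(n_frames=10):
    m = np.zeros((32, 32), dtype=int)
    m[4:10, 4:10] = 1
    m[20:26, 18:30] = 2
    return [m.copy() for _ in range(n_frames)]


def test_static_masks_one_full_track_per_cell():
    tracks = track_cells(_static_masks())
    assert len(tracks) == 2
    assert all(t.start == 0 and t.n_frames == 10 for t in tracks)


def test_track_ends_when_cell_disappears():
    masks = _static_masks()
    for f in range(6, 10):
        masks[f][masks[f] == 1] = 0      # simulated lysis at frame 6
    tracks = track_cells(masks)
    lysed = next(t for t in tracks if t.labels[0] == 1)
    assert lysed.end == 5


def test_tracking_invariant_to_label_permutation():
    masks = _static_masks()
    permuted = []
    perm = {0: 0, 1: 7, 2: 3}
    for f, m in enumerate(masks):
        pm = np.vectorize(perm.get)(m) if f % 2 else m
        permuted.append(pm.astype(int))
    t1 = track_cells(masks)
    t2 = track_cells(permuted)
    assert len(t1) == len(t2)
    # same footprints per frame regardless of labelling
    for a in t1:
        fp0 = masks[0] == a.label_at(0)
        b = next(t for t in t2
                 if np.array_equal(permuted[0] == t.label_at(0), fp0))
        for f in range(10):
            np.testing.assert_array_equal(masks[f] == a.label_at(f),
                                          permuted[f] == b.label_at(f))


def test_empty_sequence_raises():
    with pytest.raises(ValueError):
        track_cells([])


def test_simulated_timelapse_track_recovery():
    cfg = SceneConfig(n_cells=20, seed=8, n_frames=15, infected_dilution=0.0,
                      gaussian_read_sd=0.0, poisson_scale=0.0)
    frames = simulate_timelapse(cfg, channels=())
    masks = [f.labels() for f in frames]
    tracks = track_cells(masks)
    full = [t for t in tracks if t.start == 0 and t.n_frames == len(frames)]
    assert len(full) / cfg.n_cells >= 0.9


def test_trace_constant_expression_and_null():
    masks = _static_masks(6)
    frames = [np.zeros((32, 32)) for _ in range(6)]
    for fr in frames:
        fr[4:10, 4:10] = 50.0            # cell 1 expresses constantly
    tracks = track_cells(masks)
    traces = trace_fluorescence(frames, masks, tracks, backgrounds=[0.0] * 6)
    by_label = {t.track_id: tr for t, tr in zip(tracks, traces)}
    t1 = next(tr for t, tr in zip(tracks, traces) if t.labels[0] == 1)
    t2 = next(tr for t, tr in zip(tracks, traces) if t.labels[0] == 2)
    assert np.allclose(t1.values, 50.0)
    assert np.allclose(t2.values, 0.0)


def test_population_sd_is_sample_sd_of_traces():
    traces = [FluorescenceTrace(1, 0, np.array([1.0, 2.0])),
              FluorescenceTrace(2, 0, np.array([3.0, 6.0]))]
    curves = population_curves(traces, n_frames=2)
    assert curves.loc[curves.frame == 0, "mean"].item() == pytest.approx(2.0)
    assert curves.loc[curves.frame == 1, "sd"].item() == pytest.approx(
        np.std([2.0, 6.0], ddof=1))


def test_detect_onset_examples():
    assert detect_onset(np.zeros(10), threshold=1.0) is None
    step = np.concatenate([np.zeros(7), np.full(5, 10.0)])
    assert detect_onset(step, threshold=1.0, persistence=2) == 7
    with pytest.raises(ValueError):
        detect_onset(np.zeros(1), threshold=1.0, persistence=2)


def test_detect_onset_monotone_in_threshold(rng):
    trace = np.cumsum(rng.random(30))
    onsets = [detect_onset(trace, threshold=k) for k in (1.0, 3.0, 6.0)]
    assert all(a <= b for a, b in zip(onsets, onsets[1:]))


def test_detect_onset_in_noisy_simulation():
    cfg = SceneConfig(n_cells=12, seed=23, n_frames=18, infected_dilution=1e9,
                      resistant_fraction=0.0, image_shape=(640, 640))
    frames = simulate_timelapse(cfg, channels=("mcherry",))
    masks = [f.labels() for f in frames]
    mch = [f.channels["mcherry"] for f in frames]
    bgs = [estimate_background(m, k, 5, "mcherry")
           for m, k in zip(mch, masks)]
    tracks = track_cells(masks)
    traces = trace_fluorescence(mch, masks, tracks, bgs)
    truth = {c.cell_id: c.mcherry_onset_frame for c in frames[0].cells}
    hits = total = 0
    for tr, trc in zip(tracks, traces):
        want = truth.get(tr.labels[0])
        if want is None:
            continue
        got = detect_onset(trc, threshold=3 * bgs[0].sd)
        total += 1
        if got is not None and abs((got + tr.start) - want) <= 1:
            hits += 1
    assert total >= 8
    assert hits / total >= 0.9


def test_classify_fate_branches():
    long_track = Track(1, 0, labels=[1] * 10)
    short_track = Track(2, 0, labels=[1] * 3)
    ended_track = Track(3, 0, labels=[1] * 8)
    n = 12
    assert classify_fate(short_track, onset=None, area_start=10, area_end=30,
                         n_frames_total=n) == "censored"
    assert classify_fate(ended_track, onset=4, area_start=10, area_end=12,
                         n_frames_total=n) == "expressed_lysed"
    assert classify_fate(long_track, onset=None, area_start=10, area_end=25,
                         n_frames_total=n, infected=True) == "outgrowth"
    assert classify_fate(long_track, onset=None, area_start=10, area_end=25,
                         n_frames_total=n, infected=False) == "uninfected"
    assert classify_fate(long_track, onset=None, area_start=10, area_end=12,
                         n_frames_total=n, infected=True) == "censored"


def test_uninfected_field_has_no_lysis_calls():
    cfg = SceneConfig(n_cells=10, seed=4, n_frames=10, infected_dilution=0.0,
                      gaussian_read_sd=0.0, poisson_scale=0.0)
    frames = simulate_timelapse(cfg, channels=("mcherry",))
    masks = [f.labels() for f in frames]
    mch = [f.channels["mcherry"] for f in frames]
    tracks = track_cells(masks)
    traces = trace_fluorescence(mch, masks, tracks,
                                backgrounds=[cfg.background_level] * len(frames))
    for tr, trc in zip(tracks, traces):
        onset = detect_onset(trc, threshold=1.0)
        a0 = (masks[tr.start] == tr.labels[0]).sum()
        a1 = (masks[tr.end] == tr.labels[-1]).sum()
        fate = classify_fate(tr, onset, a0, a1, len(frames), infected=False)
        assert fate != "expressed_lysed"
        assert np.abs(trc.values).max() < 1.0   # no reporter signal at all


def test_fate_confusion_matrix_shape():
    truth = {1: "susceptible_lyse", 2: "uninfected", 3: "resistant_outgrow"}
    called = {1: "expressed_lysed", 2: "uninfected", 3: "outgrowth"}
    cm = fate_confusion(truth, called)
    assert cm.values.sum() == 3
    assert cm.loc["uninfected", "uninfected"] == 1
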