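"""Perpendicular-profile colocalization: backgrounds, splines, peaks, calls."""

import itertools

import numpy as np
import pytest
from skimage.draw import disk as _draw_disk

from phagequant.coloc import (BackgroundModel, build_splines, call_proximal,
                              detect_peaks, estimate_background, measure_green,
                              run_coloc, sample_profile)
from phagequant.segmentation import extract_outline
from phagequant.synthetic import simulate_scene


# ---------------------------------------------------------------------------
# background estimation

def test_background_constant_outside_cells(truth_mask):
    img = np.full(truth_mask.shape, 7.0)
    bg = estimate_background(img, truth_mask, dilation=5)
    assert bg.mean == 7.0 and bg.sd == 0.0


def test_background_two_pixel_closed_form():
    img = np.array([[1.0, 3.0]])
    mask = np.zeros((1, 2), dtype=int)
    bg = estimate_background(img, mask, dilation=0, min_pixels=None)
    assert bg.mean == pytest.approx(2.0)
    assert bg.sd == pytest.approx(np.sqrt(2.0))   # sample SD, ddof=1


def test_background_recovers_read_noise_sd(noiseless_config):
    cfg = noiseless_config.replace(gaussian_read_sd=4.0, poisson_scale=0.0)
    scene = simulate_scene(cfg, channels=("red",))
    mask = scene.labels()
    bg = estimate_background(scene.channels["red"], mask, dilation=8)
    assert bg.n_pixels >= 10_000
    assert bg.sd == pytest.approx(4.0, rel=0.10)


def test_background_min_pixel_guard():
    mask = np.ones((32, 32), dtype=int)
    with pytest.raises(ValueError):
        estimate_background(np.zeros((32, 32)), mask, dilation=2)


def test_background_shape_mismatch():
    with pytest.raises(ValueError):
        estimate_background(np.zeros((4, 4)), np.zeros((5, 5), dtype=int))


# ---------------------------------------------------------------------------
# spline geometry

@pytest.fixture(scope="module")
def disk_outline():
    img = np.zeros((64, 64), dtype=np.int32)
    rr, cc = _draw_disk((32, 32), 20.5)
    img[rr, cc] = 1
    return extract_outline(img, 1)


def test_spline_count_and_radial_normals_on_disk(disk_outline):
    r = 20
    spacing = 4.0
    lines = build_splines(disk_outline, spacing=spacing)
    expected = int(np.floor(2 * np.pi * r / spacing))
    assert abs(len(lines) - expected) <= 1
    centre = np.array([32.0, 32.0])
    for line in lines:
        assert np.hypot(*line.normal) == pytest.approx(1.0, abs=1e-6)
        radial = line.anchor - centre
        radial = radial / np.hypot(*radial)
        angle = np.degrees(np.arccos(np.clip(radial @ line.normal, -1, 1)))
        assert angle < 2.0


def test_spline_spacing_larger_than_circumference_gives_one_line(disk_outline):
    lines = build_splines(disk_outline, spacing=1e6)
    assert len(lines) == 1


def test_spline_inside_flags_follow_sign(disk_outline):
    line = build_splines(disk_outline, spacing=50.0)[0]
    inside = line.inside_flags
    # positions < 0 are outside the cell, deep positive positions inside
    assert not inside[line.positions < -0.75].any()
    assert inside[line.positions > 1.0].all()


# ---------------------------------------------------------------------------
# profile sampling

def test_sample_profile_constant_image(disk_outline):
    line = build_splines(disk_outline, spacing=50.0)[0]
    prof = sample_profile(np.full((64, 64), 3.5), line)
    assert np.allclose(prof[line.valid], 3.5)


def test_sample_profile_exact_on_linear_ramp(disk_outline):
    img = np.tile(np.arange(64, dtype=float), (64, 1))   # I(x, y) = x
    line = build_splines(disk_outline, spacing=50.0)[0]
    prof = sample_profile(img, line)
    xs = line.points[:, 0]
    assert np.allclose(prof[line.valid], xs[line.valid], atol=1e-9)


def test_sample_profile_locates_offgrid_punctum(disk_outline):
    sigma = 1.5
    x0, y0 = 52.3, 31.7    # near the disk's right edge, off-grid
    yy, xx = np.mgrid[0:64, 0:64]
    img = np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2 * sigma ** 2))
    lines = build_splines(disk_outline, spacing=2.0, step=0.5)
    best = max(lines, key=lambda l: np.nanmax(sample_profile(img, l)))
    prof = sample_profile(img, best)
    peak_pos = best.points[np.nanargmax(prof)]
    # dense oracle: the true projection of the punctum onto the best line
    dense = best.anchor[None, :] - np.outer(np.linspace(-3, 4, 1000), best.normal)
    d = np.hypot(dense[:, 0] - x0, dense[:, 1] - y0)
    true_proj = dense[np.argmin(d)]
    assert np.hypot(*(peak_pos - true_proj)) <= 0.5 / 2 + 0.26


def test_sample_profile_all_outside_raises(disk_outline):
    line = build_splines(disk_outline, spacing=50.0)[0]
    line.anchor = np.array([-100.0, -100.0])
    with pytest.raises(ValueError):
        sample_profile(np.zeros((64, 64)), line)


# ---------------------------------------------------------------------------
# peak detection

def _brute_force_peaks(profile):
    """Definition checker: leftmost plateau starts with strictly smaller
    non-equal neighbours on both sides, plateaus touching ends excluded."""
    prof = list(profile)
    n = len(prof)
    peaks = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and prof[j + 1] == prof[i]:
            j += 1
        left_ok = i > 0 and prof[i - 1] < prof[i]
        right_ok = j < n - 1 and prof[j + 1] < prof[i]
        if left_ok and right_ok:
            peaks.append((i, float(prof[i])))
        i = j + 1
    return peaks


@pytest.mark.parametrize("profile,expected", [
    ([0, 1, 0], [(1, 1.0)]),
    ([0, 1, 1, 0], [(1, 1.0)]),
    ([0, 1, 2, 3], []),
    ([3, 2, 1, 0], []),
    ([0, 2, 1, 2, 0], [(1, 2.0), (3, 2.0)]),
    ([1, 1, 1], []),
])
def test_detect_peaks_examples(profile, expected):
    assert detect_peaks(np.array(profile, float)) == expected


def test_detect_peaks_exhaustive_small_profiles():
    for n in range(3, 8):
        for vals in itertools.product(range(3), repeat=n):
            prof = np.array(vals, float)
            assert detect_peaks(prof) == _brute_force_peaks(prof), vals


def test_detect_peaks_random_profiles_match_oracle(rng):
    for _ in range(200):
        prof = rng.integers(0, 5, size=rng.integers(3, 30)).astype(float)
        assert detect_peaks(prof) == _brute_force_peaks(prof)


def test_detect_peaks_nan_splits_runs():
    prof = np.array([0, 5, 0, np.nan, 0, 3, 0])
    assert detect_peaks(prof) == [(1, 5.0), (5, 3.0)]


# ---------------------------------------------------------------------------
# proximal calls and green measurement

def test_call_proximal_strict_boundary():
    bg = BackgroundModel("red", mean=10.0, sd=2.0, n_pixels=1000,
                         exclusion_dilation=5)
    at_threshold = np.array([0.0, 12.0, 0.0])      # peak exactly mean + 1 sd
    above = np.array([0.0, 14.0, 0.0])             # mean + 2 sd
    assert not call_proximal(at_threshold, bg, k=1.0).proximal
    assert call_proximal(above, bg, k=1.0).proximal


def test_call_proximal_monotone_in_k(rng):
    bg = BackgroundModel("red", mean=5.0, sd=1.0, n_pixels=1000,
                         exclusion_dilation=5)
    profiles = [rng.normal(5, 1, size=15) for _ in range(100)]
    counts = []
    for k in (0.5, 1.0, 2.0, 3.0):
        counts.append(sum(call_proximal(p, bg, k=k).proximal for p in profiles))
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_measure_green_arithmetic():
    bg = BackgroundModel("green", mean=5.0, sd=1.0, n_pixels=1000,
                         exclusion_dilation=5)
    prof = np.array([100.0, 5.0, 20.0, 7.0])
    inside = np.array([False, True, True, True])
    assert measure_green(prof, inside, bg) == pytest.approx(15.0)
    flat = np.full(4, 5.0)
    assert measure_green(flat, inside, bg) == pytest.approx(0.0)
    with pytest.raises(ValueError):
        measure_green(prof, np.zeros(4, bool), bg)


def test_green_measure_higher_at_poles_than_midcell(noiseless_config):
    cfg = noiseless_config.replace(polar_green_ratio=3.0, polar_bias=1.0)
    scene = simulate_scene(cfg)
    mask = scene.labels()
    bg_green = estimate_background(scene.channels["green"], mask, 5, "green")
    wins = 0
    total = 0
    for cell in scene.cells:
        outline = extract_outline(mask, cell.cell_id)
        lines = build_splines(outline, spacing=2.0)
        pole_vals, mid_vals = [], []
        for line in lines:
            prof = sample_profile(scene.channels["green"], line)
            g = measure_green(prof, line.inside_flags & line.valid, bg_green)
            # classify the anchor by distance to the pole tips
            cap = cell.capsule
            u = cap.axis
            tips = [np.array(cap.p0) - u * cap.radius,
                    np.array(cap.p1) + u * cap.radius]
            dist = min(np.hypot(*(line.anchor - t)) for t in tips)
            (pole_vals if dist < cap.radius else
             mid_vals if dist > 3 * cap.radius else []).append(g)
        if pole_vals and mid_vals:
            total += 1
            wins += np.median(pole_vals) > np.median(mid_vals)
    assert total >= 3 and wins / total >= 0.95


# ---------------------------------------------------------------------------
# invariances and end-to-end

def test_background_shift_invariance(noiseless_scene, truth_mask):
    green = noiseless_scene.channels["green"]
    red = noiseless_scene.channels["red"]
    t1, _ = run_coloc(green, red, truth_mask)
    t2, _ = run_coloc(green + 50.0, red + 50.0, truth_mask)
    np.testing.assert_array_equal(t1.proximal.values, t2.proximal.values)
    np.testing.assert_allclose(t1.green_max_bgsub, t2.green_max_bgsub,
                               atol=1e-9)


def test_empty_phage_channel_all_nonproximal(noiseless_config):
    cfg = noiseless_config.replace(phage_rate=0.0)
    scene = simulate_scene(cfg)
    table, summary = run_coloc(scene.channels["green"], scene.channels["red"],
                               scene.labels())
    assert not table.proximal.any()
    assert summary.n_proximal == 0
    assert summary.proximal_stats["n"] == 0
    assert summary.proximal_stats["median"] is None


def test_proximal_pole_fraction_monotone_in_polar_bias(noiseless_config):
    """More polar dosing -> more proximal anchors in true pole/septum arcs."""
    fractions = []
    for bias in (0.0, 0.5, 1.0):
        cfg = noiseless_config.replace(polar_bias=bias, phage_rate=4.0,
                                       n_cells=8, seed=100)
        scene = simulate_scene(cfg)
        mask = scene.labels()
        table, _ = run_coloc(scene.channels["green"], scene.channels["red"],
                             mask)
        prox = table[table.proximal]
        hits = 0
        for _, row in prox.iterrows():
            cell = next(c for c in scene.cells if c.cell_id == row.cell_id)
            cap = cell.capsule
            u = cap.axis
            tips = [np.array(cap.p0) - u * cap.radius,
                    np.array(cap.p1) + u * cap.radius]
            anchor = np.array([row.anchor_x, row.anchor_y])
            near_pole = min(np.hypot(*(anchor - t)) for t in tips) < 1.5 * cap.radius
            near_septum = (cell.has_septum and
                           abs((anchor - cap.centroid) @ u) < 2.0)
            hits += bool(near_pole or near_septum)
        fractions.append(hits / max(len(prox), 1))
    assert fractions[0] <= fractions[1] + 0.05
    assert fractions[1] <= fractions[2] + 0.05
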