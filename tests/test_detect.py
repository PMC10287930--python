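"""Filter, threshold, peak-picking and particle-analysis behaviour."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from focigap import SceneConfig, generate_scene
from focigap.core import FieldImage
from focigap.detect import (
    _fit_gaussian,
    analyze_particles,
    detect_foci,
    discoidal_filter,
    discoidal_kernel,
    flatten,
    yen_threshold,
)

from conftest import gaussian_spot_image


# --- flatten ---------------------------------------------------------------


def test_flatten_removes_constant_background():
    img = FieldImage(np.full((64, 64), 137.0), 109.0)
    out = flatten(img)
    np.testing.assert_allclose(out.pixels, 0.0, atol=1e-9)


def test_flatten_preserves_spot_amplitude_on_gradient():
    """Fitted spot amplitude changes < 10% when a smooth ramp is removed."""
    h = w = 64
    yy, xx = np.mgrid[0:h, 0:w]
    ramp = 100.0 + 0.4 * xx + 0.2 * yy
    spot = gaussian_spot_image((h, w), centers=((32.0, 32.0),), amplitude=50.0)
    img = FieldImage(ramp + spot.pixels, 109.0)

    def fitted_amplitude(im):
        win = im.pixels[28:37, 28:37]
        _, _, a, _, _, ok = _fit_gaussian(win, 28, 28, (32, 32))
        assert ok
        return a

    before = fitted_amplitude(img)
    after = fitted_amplitude(flatten(img))
    assert abs(after - before) / before < 0.10


def test_flatten_is_idempotent():
    img = gaussian_spot_image((64, 64), amplitude=200.0, background=50.0)
    once = flatten(img)
    twice = flatten(once)
    assert np.max(np.abs(twice.pixels - once.pixels)) < 1e-6 * max(
        1.0, once.pixels.max()
    )


# --- discoidal filter ------------------------------------------------------


def test_discoidal_filter_zero_on_constant():
    img = FieldImage(np.full((32, 32), 42.0), 109.0)
    out = discoidal_filter(img, 1, 4)
    np.testing.assert_allclose(out.pixels, 0.0, atol=1e-9)


def test_discoidal_kernel_on_unit_impulse():
    """Impulse response equals the kernel itself (disk/annulus means)."""
    arr = np.zeros((21, 21))
    arr[10, 10] = 1.0
    out = discoidal_filter(FieldImage(arr, 109.0), 1, 4).pixels
    k = discoidal_kernel(1, 4)
    n_disk = 5  # pixels with Euclidean distance <= 1 of the center
    assert out[10, 10] == pytest.approx(1.0 / n_disk)
    r = (k.shape[0] - 1) // 2
    np.testing.assert_allclose(out[10 - r : 10 + r + 1, 10 - r : 10 + r + 1], k)


def test_discoidal_rejects_bad_radii():
    img = FieldImage(np.zeros((32, 32)), 109.0)
    with pytest.raises(ValueError):
        discoidal_filter(img, 4, 4)


@settings(deadline=None, max_examples=20, derandomize=True)
@given(
    a=st.floats(-3, 3, allow_nan=False),
    b=st.floats(-3, 3, allow_nan=False),
    seed=st.integers(0, 1000),
)
def test_discoidal_filter_is_linear(a, b, seed):
    rng = np.random.default_rng(seed)
    i = rng.normal(size=(24, 24))
    j = rng.normal(size=(24, 24))
    f = lambda arr: discoidal_filter(FieldImage(arr, 1.0), 1, 3).pixels
    np.testing.assert_allclose(f(a * i + b * j), a * f(i) + b * f(j), atol=1e-9)


def test_discoidal_invariant_to_constant_offset(rng):
    i = rng.normal(size=(32, 32))
    f = lambda arr: discoidal_filter(FieldImage(arr, 1.0), 1, 4).pixels
    np.testing.assert_allclose(f(i + 57.0), f(i), atol=1e-8)


# --- Yen threshold ---------------------------------------------------------


def _yen_oracle(values):
    """Direct maximization of the Yen criterion on a 256-bin histogram."""
    hist, edges = np.histogram(values.ravel(), bins=256)
    centers = (edges[:-1] + edges[1:]) / 2
    p = hist / hist.sum()
    p1 = np.cumsum(p)
    p1sq = np.cumsum(p**2)
    p2sq = np.cumsum(p[::-1] ** 2)[::-1]
    best, best_t = -np.inf, centers[0]
    for t in range(len(p) - 1):
        if p1[t] in (0.0, 1.0) or p1sq[t] == 0 or p2sq[t + 1] == 0:
            continue
        crit = np.log(p1[t] * (1 - p1[t])) * 2 - np.log(p1sq[t] * p2sq[t + 1])
        if crit > best:
            best, best_t = crit, centers[t]
    return best_t


def test_yen_separates_two_level_image(rng):
    arr = np.full((50, 50), 10.0)
    bright = rng.random((50, 50)) < 0.2
    arr[bright] = 200.0
    t, mask = yen_threshold(FieldImage(arr, 1.0))
    assert 10.0 < t < 200.0
    np.testing.assert_array_equal(mask, bright)


def test_yen_matches_direct_criterion_maximization(rng):
    for _ in range(20):
        vals = np.concatenate(
            [rng.normal(20, 3, 800), rng.normal(120, 10, rng.integers(20, 200))]
        )
        img = FieldImage(np.resize(vals, (32, 32)).clip(0), 1.0)
        t, _ = yen_threshold(img)
        assert t == pytest.approx(_yen_oracle(img.pixels), abs=1e-9)


def test_yen_recall_of_spot_centers_at_snr10(rng):
    centers = [(10.5 + 12 * i, 8.3 + 11 * j) for i in range(4) for j in range(4)]
    img = gaussian_spot_image((64, 64), centers=centers, amplitude=100.0)
    noisy = FieldImage(img.pixels + rng.normal(0, 10.0, img.pixels.shape), 109.0)
    _, mask = yen_threshold(noisy)
    hit = sum(mask[int(round(y)), int(round(x))] for x, y in centers)
    assert hit / len(centers) >= 0.95


def test_yen_constant_image_warns_and_returns_empty_mask():
    with pytest.warns(UserWarning):
        t, mask = yen_threshold(FieldImage(np.full((16, 16), 5.0), 1.0))
    assert np.isnan(t)
    assert not mask.any()


# --- detect_foci -----------------------------------------------------------


def test_blank_noise_image_yields_no_foci():
    """False-positive check: noise-only fields give 0 foci in >= 95% of seeds."""
    clean = 0
    n_seeds = 20
    for seed in range(n_seeds):
        cfg = dataclasses.replace(
            SceneConfig(),
            mode="surface",
            fov_px=(256, 256),
            foci_per_fov_mean=(0.0, 0.0),
            seed=seed,
        )
        _, img, _ = generate_scene(cfg)
        foci = detect_foci(flatten(img))
        clean += len(foci) == 0
    assert clean >= n_seeds - 1


def test_two_separated_gaussians_localized_to_five_hundredths_px():
    truth = [(20.0, 32.0), (30.0, 32.0)]  # 10 px apart
    img = gaussian_spot_image((64, 64), centers=truth, amplitude=300.0, sigma=1.2)
    foci = detect_foci(img, threshold=10.0)
    assert len(foci) == 2
    found = sorted((f.x_px, f.y_px) for f in foci)
    for (xt, yt), (xf, yf) in zip(sorted(truth), found):
        assert np.hypot(xf - xt, yf - yt) <= 0.05


def test_close_pair_merges_under_separation_rule():
    truth = [(30.0, 32.0), (32.0, 32.0)]  # 2 px apart, min separation 3
    img = gaussian_spot_image((64, 64), centers=truth, amplitude=300.0, sigma=1.2)
    foci = detect_foci(img, min_separation_px=3.0, threshold=10.0)
    assert len(foci) == 1


def test_detection_invariant_under_transposition():
    truth = [(20.0, 40.0), (45.0, 12.0), (33.0, 25.0)]
    img = gaussian_spot_image((64, 64), centers=truth, amplitude=300.0)
    foci = detect_foci(img, threshold=10.0)
    foci_t = detect_foci(FieldImage(img.pixels.T, 109.0), threshold=10.0)
    assert len(foci) == len(foci_t) == 3
    xy = sorted((round(f.x_px, 3), round(f.y_px, 3)) for f in foci)
    yx = sorted((round(f.y_px, 3), round(f.x_px, 3)) for f in foci_t)
    assert xy == yx


def test_foci_sorted_by_amplitude_descending():
    img = gaussian_spot_image(
        (64, 64), centers=((15.0, 15.0), (45.0, 45.0)), amplitude=100.0
    )
    img.pixels += gaussian_spot_image(
        (64, 64), centers=((30.0, 30.0),), amplitude=250.0
    ).pixels
    foci = detect_foci(img, threshold=10.0)
    amps = [f.amplitude for f in foci]
    assert amps == sorted(amps, reverse=True)


# --- analyze_particles -----------------------------------------------------


def _blob_mask(blobs, shape=(32, 32)):
    mask = np.zeros(shape, dtype=bool)
    for pixels in blobs:
        for r, c in pixels:
            mask[r, c] = True
    return mask


def test_small_blob_filtered_by_min_area():
    mask = _blob_mask([[(5, 5), (5, 6)]])
    assert analyze_particles(mask, np.ones(mask.shape), min_area_px2=3) == []


def test_particle_areas_counted_exactly():
    blobs = [
        [(2, 2), (2, 3), (3, 2)],
        [(10, 10), (10, 11), (11, 10), (11, 11), (12, 11)],
        [(20, c) for c in range(5)] + [(21, c) for c in range(5)],
    ]
    mask = _blob_mask(blobs)
    particles = analyze_particles(mask, np.ones(mask.shape))
    assert sorted(p.area_px2 for p in particles) == [3, 5, 10]


def test_particle_mean_intensity_measured_on_source():
    mask = _blob_mask([[(2, 2), (2, 3), (3, 2)]])
    src = np.zeros(mask.shape)
    src[2, 2], src[2, 3], src[3, 2] = 10.0, 20.0, 30.0
    (p,) = analyze_particles(mask, src)
    assert p.mean_intensity == pytest.approx(20.0)


@settings(deadline=None, max_examples=20, derandomize=True)
@given(seed=st.integers(0, 10_000), thresholds=st.tuples(st.integers(1, 5), st.integers(1, 5)))
def test_raising_min_area_never_increases_particle_count(seed, thresholds):
    rng = np.random.default_rng(seed)
    mask = rng.random((32, 32)) < 0.3
    lo, hi = min(thresholds), max(thresholds)
    src = np.ones(mask.shape)
    assert len(analyze_particles(mask, src, hi)) <= len(
        analyze_particles(mask, src, lo)
    )
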