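"""Generator contracts: determinism, planting consistency, noise statistics."""

import dataclasses

import numpy as np
import pytest
from shapely.geometry import Point, Polygon

from focigap import (
    MoleculeSimConfig,
    SceneConfig,
    generate_molecules,
    generate_scene,
    sample_truth,
)


def test_empty_scene_yields_empty_truth_and_noise_images():
    cfg = dataclasses.replace(SceneConfig(), n_cells=0, fov_px=(64, 64), seed=3)
    truth, img_a, img_b = generate_scene(cfg)
    assert truth.cell_polygons == []
    assert len(truth.foci_true["A"]) == 0
    assert len(truth.foci_true["B"]) == 0
    assert truth.coloc_pairs_true == []
    assert img_a.pixels.shape == (64, 64)


def test_negative_focus_mean_rejected():
    with pytest.raises(ValueError):
        SceneConfig(foci_per_cell_mean=(-1.0, 1.0))


def test_full_planting_duplicates_channel_a_positions():
    cfg = dataclasses.replace(
        SceneConfig(),
        fov_px=(256, 256),
        n_cells=15,
        coloc_fraction=1.0,
        coloc_jitter_nm=0.0,
        channel_offset_px=(0.0, 0.0),
        seed=5,
    )
    truth = sample_truth(cfg)
    a = truth.foci_true["A"][:, :2]
    b = truth.foci_true["B"][:, :2]
    assert len(b) > 0
    for xy in b:
        assert np.min(np.hypot(*(a - xy).T)) == 0.0
    assert len(truth.coloc_pairs_true) == len(b)


def test_planted_pair_count_matches_fraction():
    cfg = dataclasses.replace(SceneConfig(), coloc_fraction=0.5, seed=9)
    truth = sample_truth(cfg)
    n_b = len(truth.foci_true["B"])
    assert len(truth.coloc_pairs_true) == int(round(0.5 * n_b))


def test_unplanted_foci_lie_inside_cells():
    cfg = dataclasses.replace(
        SceneConfig(), fov_px=(256, 256), n_cells=15, coloc_fraction=0.0, seed=7
    )
    truth = sample_truth(cfg)
    polys = [Polygon(p).buffer(1e-9) for p in truth.cell_polygons]
    for ch in ("A", "B"):
        for x, y, _ in truth.foci_true[ch]:
            assert any(p.covers(Point(x, y)) for p in polys)


def test_scene_determinism_bitwise():
    cfg = dataclasses.replace(SceneConfig(), fov_px=(128, 128), n_cells=8, seed=1)
    t1, a1, b1 = generate_scene(cfg)
    t2, a2, b2 = generate_scene(cfg)
    assert a1.pixels.tobytes() == a2.pixels.tobytes()
    assert b1.pixels.tobytes() == b2.pixels.tobytes()
    for ch in ("A", "B"):
        np.testing.assert_array_equal(t1.foci_true[ch], t2.foci_true[ch])


def test_channel_offset_shifts_rendered_image_not_truth():
    base = dataclasses.replace(
        SceneConfig(),
        mode="surface",
        fov_px=(128, 128),
        foci_per_fov_mean=(5.0, 5.0),
        shot_noise=False,
        read_noise_sd=0.0,
        seed=21,
    )
    shifted = dataclasses.replace(base, channel_offset_px=(3.0, 0.0))
    t0, _, b0 = generate_scene(base)
    t1, _, b1 = generate_scene(shifted)
    np.testing.assert_array_equal(t0.foci_true["B"], t1.foci_true["B"])
    # rendered B image is translated by 3 px along x (up to edge columns)
    np.testing.assert_allclose(
        b1.pixels[:, 10:120].astype(float), b0.pixels[:, 7:117].astype(float), atol=1.0
    )


def test_uniform_background_has_poisson_variance():
    """With unit gain and no read noise, pixel variance matches the mean."""
    cfg = dataclasses.replace(
        SceneConfig(),
        mode="surface",
        fov_px=(256, 256),
        foci_per_fov_mean=(0.0, 0.0),
        background_level=100.0,
        em_gain=1.0,
        read_noise_sd=0.0,
        seed=2,
    )
    _, img, _ = generate_scene(cfg)
    mean = img.pixels.mean()
    var = img.pixels.var()
    assert abs(var / mean - 1.0) < 0.02


# --- molecules -------------------------------------------------------------


def test_zero_gap_rate_plants_no_gaps():
    cfg = dataclasses.replace(MoleculeSimConfig(), gap_rate_per_um=0.0, seed=4)
    _, truths = generate_molecules(cfg)
    assert all(len(g) == 0 for g in truths)


def test_total_gap_count_follows_poisson_law():
    """lambda = 0.06/um over ~10,000 um: count within 3*sqrt(mean) of mean."""
    cfg = dataclasses.replace(
        MoleculeSimConfig(), n_molecules=200, gap_rate_per_um=0.06, seed=8
    )
    profiles, truths = generate_molecules(cfg)
    total_len = sum(p.length_um for p in profiles)
    assert total_len > 5000
    expected = 0.06 * total_len
    count = sum(len(g) for g in truths)
    assert abs(count - expected) <= 3 * np.sqrt(expected)


def test_planted_gaps_disjoint_and_inside_molecule():
    cfg = dataclasses.replace(MoleculeSimConfig(), gap_rate_per_um=0.2, seed=6)
    profiles, truths = generate_molecules(cfg)
    for p, gs in zip(profiles, truths):
        gs = sorted(gs)
        for (s0, e0), (s1, e1) in zip(gs, gs[1:]):
            assert e0 <= s1
        for s, e in gs:
            assert 0 <= s < e <= p.length_um


def test_molecule_determinism():
    cfg = dataclasses.replace(MoleculeSimConfig(), n_molecules=20, seed=13)
    p1, t1 = generate_molecules(cfg)
    p2, t2 = generate_molecules(cfg)
    assert t1 == t2
    for a, b in zip(p1, p2):
        assert a.intensity.tobytes() == b.intensity.tobytes()


def test_gap_pixels_are_dark():
    cfg = dataclasses.replace(
        MoleculeSimConfig(), gap_rate_per_um=0.1, noise_sd=0.0, seed=3
    )
    profiles, truths = generate_molecules(cfg)
    for p, gs in zip(profiles, truths):
        centers = p.positions_um
        for s, e in gs:
            inside = (centers >= s) & (centers < e)
            assert np.all(p.intensity[inside] == 0.0)
        outside = np.ones(p.n_px, dtype=bool)
        for s, e in gs:
            outside &= ~((centers >= s) & (centers < e))
        assert np.all(p.intensity[outside] == cfg.ds_intensity)
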