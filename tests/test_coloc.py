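"""Colocalization classification, chance correction and shell histograms."""

import dataclasses
import math

import numpy as np
import pytest
from scipy.stats import chisquare

from focigap import SceneConfig, sample_truth
from focigap.coloc import (
    chance_colocalization,
    classify_colocalized,
    corrected_frequency,
    estimate_offset,
    full_report,
    shell_area_histogram,
)
from focigap.core import ColocConfig, ColocReport


# --- offset estimation -----------------------------------------------------


def test_offset_recovers_planted_shift(rng):
    a = rng.uniform(10, 200, size=(40, 2))
    b = a + np.array([1.5, -0.5])
    dx, dy = estimate_offset(a, b)
    assert abs(dx - 1.5) <= 0.25 and abs(dy + 0.5) <= 0.25


def test_offset_is_zero_for_identical_sets(rng):
    a = rng.uniform(0, 100, size=(25, 2))
    assert estimate_offset(a, a) == (0.0, 0.0)


def test_offset_warns_on_unrelated_sets():
    a = np.array([[0.0, 0.0], [1.0, 1.0]])
    b = a + 500.0
    with pytest.warns(UserWarning):
        assert estimate_offset(b, a, search_radius_px=5.0) == (0.0, 0.0)


# --- classification --------------------------------------------------------


def test_identical_channels_fully_colocalized(rng):
    a = rng.uniform(0, 100, size=(30, 2))
    rep = classify_colocalized(a, a, ColocConfig(), pixel_size_nm=109.0)
    assert rep.freq_A_given_B == 1.0 and rep.freq_B_given_A == 1.0
    assert all(d == 0.0 for _, _, d in rep.pairs)


def test_three_pixels_at_109nm_is_beyond_the_218nm_rule():
    a = np.array([[10.0, 10.0]])
    b = np.array([[13.0, 10.0]])  # 327 nm
    rep = classify_colocalized(a, b, ColocConfig(), pixel_size_nm=109.0)
    assert rep.freq_A_given_B == 0.0 and rep.freq_B_given_A == 0.0
    # at 2 px (218 nm) exactly the pair is classified as colocalized
    b2 = np.array([[12.0, 10.0]])
    rep2 = classify_colocalized(a, b2, ColocConfig(), pixel_size_nm=109.0)
    assert rep2.freq_A_given_B == 1.0


def test_empty_channel_reports_nan_not_zero():
    rep = classify_colocalized(
        np.zeros((0, 2)), np.array([[1.0, 1.0]]), ColocConfig(), 109.0
    )
    assert math.isnan(rep.freq_A_given_B)
    assert "empty_channel" in rep.flags


def test_channel_swap_swaps_directional_frequencies(rng):
    a = rng.uniform(0, 50, size=(15, 2))
    b = rng.uniform(0, 50, size=(22, 2))
    cfg = ColocConfig(max_dist_nm=500.0)
    r1 = classify_colocalized(a, b, cfg, 109.0)
    r2 = classify_colocalized(b, a, cfg, 109.0)
    assert r1.freq_A_given_B == r2.freq_B_given_A
    assert r1.freq_B_given_A == r2.freq_A_given_B


def test_increasing_max_dist_never_decreases_frequencies(rng):
    a = rng.uniform(0, 50, size=(20, 2))
    b = rng.uniform(0, 50, size=(20, 2))
    freqs = []
    for d in (100.0, 218.0, 400.0, 800.0):
        rep = classify_colocalized(a, b, ColocConfig(max_dist_nm=d), 109.0)
        freqs.append((rep.freq_A_given_B, rep.freq_B_given_A))
    for f0, f1 in zip(freqs, freqs[1:]):
        assert f1[0] >= f0[0] and f1[1] >= f0[1]


# --- shell histogram -------------------------------------------------------


def test_shell_histogram_empty_input():
    h = shell_area_histogram([], 218.0, 5)
    assert h.counts.tolist() == [0] * 5 and h.n_excluded == 0


def test_shell_edges_give_equal_areas():
    h = shell_area_histogram([10.0], 218.0, 8)
    areas = np.diff(h.shell_edges_nm**2) * math.pi
    np.testing.assert_allclose(areas, areas[0])


def test_shell_boundary_conventions():
    h = shell_area_histogram([0.0, 218.0, 219.0], 218.0, 4)
    assert h.counts[0] == 1  # distance 0 -> shell 1
    assert h.counts[-1] == 1  # distance r_max -> last shell
    assert h.n_excluded == 1


def test_shell_rejects_negative_distance():
    with pytest.raises(ValueError):
        shell_area_histogram([-1.0], 218.0, 4)


def test_shell_counts_uniform_under_csr(rng):
    """Pair distances of uniform points are flat across equal-area shells."""
    n = 200_000
    a = rng.uniform(0, 512, size=(n, 2))
    b = rng.uniform(0, 512, size=(n, 2))
    d = np.hypot(*(a - b).T)
    h = shell_area_histogram(d[d <= 12.0], 12.0, 6)
    assert h.counts.sum() >= 100
    _, p = chisquare(h.counts)
    assert p > 0.01


# --- chance colocalization and correction ----------------------------------


def test_chance_zero_foci_gives_zero():
    assert chance_colocalization(218.0, 0, 512 * 512, 109.0) == 0.0


def test_chance_full_coverage_limit():
    # one focus whose disc area equals the reference area -> C = 1
    area_px2 = 1000.0
    radius_nm = math.sqrt(area_px2 * 109.0**2 / math.pi)
    assert chance_colocalization(radius_nm, 1, area_px2, 109.0) == pytest.approx(1.0)


def test_chance_rejects_zero_area():
    with pytest.raises(ValueError):
        chance_colocalization(218.0, 5, 0.0, 109.0)


def _report(freq, chance):
    return ColocReport(
        pairs_ab=[],
        pairs_ba=[],
        freq_A_given_B=freq,
        freq_B_given_A=freq,
        n_A=10,
        n_B=10,
        max_dist_nm=218.0,
        chance_C=chance,
        chance_A=chance,
        chance_B=chance,
    )


def test_corrected_frequency_zero_when_freq_equals_chance():
    ca, cb = corrected_frequency(_report(0.1, 0.1))
    assert ca == 0.0 and cb == 0.0


def test_corrected_frequency_one_when_fully_colocalized():
    ca, _ = corrected_frequency(_report(1.0, 0.3))
    assert ca == 1.0


def test_corrected_frequency_undefined_when_chance_saturates():
    ca, cb = corrected_frequency(_report(0.5, 1.0))
    assert math.isnan(ca) and math.isnan(cb)


# --- CSR null and planted-fraction behaviour --------------------------------


def test_csr_raw_frequency_matches_chance_formula():
    """Surface scenes with nothing planted: raw frequency ~ formula chance."""
    cfg0 = dataclasses.replace(
        SceneConfig(),
        mode="surface",
        foci_per_fov_mean=(100.0, 100.0),
        coloc_fraction=0.0,
    )
    freqs, chances = [], []
    for k in range(60):
        truth = sample_truth(dataclasses.replace(cfg0, seed=900 + k))
        a = truth.foci_true["A"][:, :2]
        b = truth.foci_true["B"][:, :2]
        rep = full_report(
            a, b, ColocConfig(), cfg0.pixel_size_nm, fov_area_px2=512.0 * 512.0
        )
        freqs.append(rep.freq_B_given_A)
        chances.append(rep.chance_B)
    freqs = np.asarray(freqs)
    se = freqs.std(ddof=1) / math.sqrt(len(freqs))
    assert abs(freqs.mean() - np.mean(chances)) <= 3 * se


def test_full_report_applies_offset_before_classifying(rng):
    a = rng.uniform(20, 200, size=(30, 2))
    b = a + np.array([2.5, -1.0])
    cfg = ColocConfig(offset_px="estimate")
    rep = full_report(a, b, cfg, 109.0, fov_area_px2=512.0 * 512.0)
    assert rep.freq_A_given_B == 1.0
    assert abs(rep.offset_px[0] - 2.5) <= 0.25
    assert abs(rep.offset_px[1] + 1.0) <= 0.25
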