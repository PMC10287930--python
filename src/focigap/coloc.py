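"""Two-channel colocalization statistics.

Classification is per-focus and distance-based: a focus in one channel is
colocalized when its nearest neighbour in the other channel lies within a
fixed centroid distance (218 nm by default, i.e. 2 px at 109 nm/px).  The
classification is deliberately not a one-to-one bipartite matching: two A
foci may share one B partner, which keeps the frequency well defined when
channel counts differ.

The coincidental (chance) colocalization level under complete spatial
randomness is estimated with the disc-area formula

    C = A_R * n / A_FOV

where ``A_R = pi * focus_radius**2``, ``n`` is a focus count and ``A_FOV``
the reference area.  The printed convention takes n = foci of both
channels; per-direction variants with n = partner-channel count are also
computed and drive the default chance correction
``(freq - C) / (1 - C)``, which is zero in expectation under CSR.

Distance histograms use equal-area shells (edges ``r_max * sqrt(k/K)``)
so that a CSR distance distribution is flat across bins.
"""

from __future__ import annotations

import math
import warnings
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .core import ColocConfig, ColocReport, ShellHistogram, foci_coordinates

__all__ = [
    "estimate_offset",
    "classify_colocalized",
    "shell_area_histogram",
    "chance_colocalization",
    "corrected_frequency",
    "full_report",
]


def estimate_offset(
    foci_a: Sequence,
    foci_b: Sequence,
    search_radius_px: float = 8.0,
    bin_px: float = 0.25,
) -> tuple[float, float]:
    """Estimate the constant inter-channel translation B - A.

    All A-B displacement vectors shorter than ``search_radius_px`` are
    histogrammed in 2-D (``bin_px`` bins); the returned offset is the mean
    displacement inside the modal bin (ties resolved row-major), which is
    exact for an exactly shifted point set and robust to unrelated pairs.
    If no pair falls within the search radius a warning is raised and
    (0, 0) is returned.
    """
    a = foci_coordinates(foci_a)
    b = foci_coordinates(foci_b)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both focus lists must be non-empty")
    tree_a = cKDTree(a)
    pairs = tree_a.query_ball_point(b, r=search_radius_px)
    disp = [b[j] - a[i] for j, idx in enumerate(pairs) for i in idx]
    if not disp:
        warnings.warn("no A-B pair within search radius; offset set to (0, 0)", stacklevel=2)
        return (0.0, 0.0)
    d = np.asarray(disp)
    edges = np.arange(-search_radius_px, search_radius_px + bin_px, bin_px)
    hist, xe, ye = np.histogram2d(d[:, 0], d[:, 1], bins=(edges, edges))
    i, j = np.unravel_index(int(np.argmax(hist)), hist.shape)
    in_bin = (
        (d[:, 0] >= xe[i]) & (d[:, 0] < xe[i + 1])
        & (d[:, 1] >= ye[j]) & (d[:, 1] < ye[j + 1])
    )
    sel = d[in_bin]
    return (float(sel[:, 0].mean()), float(sel[:, 1].mean()))


def _direction(
    src: np.ndarray, dst: np.ndarray, max_dist_px: float, pixel_size_nm: float
) -> tuple[list[tuple[int, int, float]], float]:
    """Nearest-neighbour classification of every src focus against dst."""
    tree = cKDTree(dst)
    dist, idx = tree.query(src)
    hits = dist <= max_dist_px
    pairs = [
        (int(i), int(idx[i]), float(dist[i] * pixel_size_nm))
        for i in np.nonzero(hits)[0]
    ]
    return pairs, float(hits.mean())


def classify_colocalized(
    foci_a: Sequence,
    foci_b: Sequence,
    config: ColocConfig,
    pixel_size_nm: float,
) -> ColocReport:
    """Per-focus nearest-neighbour colocalization classification.

    Coordinates are in pixels with any inter-channel offset already applied.
    Frequencies for an empty channel are NaN and flagged, never reported
    as zero.
    """
    a = foci_coordinates(foci_a)
    b = foci_coordinates(foci_b)
    max_dist_px = config.max_dist_nm / pixel_size_nm
    flags: list[str] = []
    if len(a) == 0 or len(b) == 0:
        flags.append("empty_channel")
        return ColocReport(
            pairs_ab=[],
            pairs_ba=[],
            freq_A_given_B=float("nan"),
            freq_B_given_A=float("nan"),
            n_A=len(a),
            n_B=len(b),
            max_dist_nm=config.max_dist_nm,
            flags=tuple(flags),
        )
    pairs_ab, freq_a = _direction(a, b, max_dist_px, pixel_size_nm)
    pairs_ba, freq_b = _direction(b, a, max_dist_px, pixel_size_nm)
    return ColocReport(
        pairs_ab=pairs_ab,
        pairs_ba=pairs_ba,
        freq_A_given_B=freq_a,
        freq_B_given_A=freq_b,
        n_A=len(a),
        n_B=len(b),
        max_dist_nm=config.max_dist_nm,
    )


def shell_area_histogram(
    distances_nm: Sequence[float], r_max_nm: float, K: int
) -> ShellHistogram:
    """Bin distances into K concentric shells of equal area.

    Shell k covers ``(r_{k-1}, r_k]`` with ``r_k = r_max * sqrt(k/K)``;
    a distance of exactly zero goes to shell 1 and a distance of exactly
    ``r_max`` to shell K.  Distances beyond ``r_max`` are excluded and
    counted in ``n_excluded``; negative distances are rejected.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if r_max_nm <= 0:
        raise ValueError("r_max_nm must be positive")
    d = np.asarray(list(distances_nm), dtype=float)
    if d.size and d.min() < 0:
        raise ValueError("distances must be non-negative")
    edges = r_max_nm * np.sqrt(np.arange(K + 1) / K)
    if d.size == 0:
        return ShellHistogram(edges, np.zeros(K, dtype=int), 0)
    keep = d <= r_max_nm
    n_excluded = int((~keep).sum())
    idx = np.searchsorted(edges, d[keep], side="left")
    idx = np.clip(idx, 1, K) - 1
    counts = np.bincount(idx, minlength=K)
    return ShellHistogram(edges, counts, n_excluded)


def chance_colocalization(
    focus_radius_nm: float,
    n_total_foci: int,
    fov_area_px2: float,
    pixel_size_nm: float,
) -> float:
    """Coincidental colocalization chance C = A_R * n / A_FOV, capped at 1.

    ``A_R = pi * focus_radius**2``.  ``n_total_foci`` follows the printed
    convention (foci of both channels) when called through
    :func:`full_report`; the formula itself is agnostic and callers may pass
    a partner-channel count.  ``fov_area_px2`` is the reference area in
    square pixels — the full field of view for surface assays, or the total
    cell area when foci are confined to cells.
    """
    if fov_area_px2 <= 0:
        raise ValueError("reference area must be positive")
    if n_total_foci < 0:
        raise ValueError("focus count must be non-negative")
    a_r_nm2 = math.pi * focus_radius_nm**2
    a_fov_nm2 = fov_area_px2 * pixel_size_nm**2
    return min(1.0, a_r_nm2 * n_total_foci / a_fov_nm2)


def corrected_frequency(
    report: ColocReport, per_direction: bool = True
) -> tuple[float, float]:
    """Chance-corrected colocalization frequencies, (freq - C)/(1 - C).

    Clipped to [0, 1]; zero in expectation under CSR.  By default each
    direction uses its own chance level (partner-channel n); with
    ``per_direction=False`` the pooled printed-formula ``chance_C`` is used
    for both.  A chance level >= 1 makes the correction undefined (NaN).
    """
    if report.chance_C is None:
        raise ValueError("chance_C has not been computed for this report")
    c_a = report.chance_A if (per_direction and report.chance_A is not None) else report.chance_C
    c_b = report.chance_B if (per_direction and report.chance_B is not None) else report.chance_C

    def _corr(freq: float, c: float) -> float:
        if not np.isfinite(freq):
            return float("nan")
        if c >= 1.0:
            return float("nan")
        return float(np.clip((freq - c) / (1.0 - c), 0.0, 1.0))

    return _corr(report.freq_A_given_B, c_a), _corr(report.freq_B_given_A, c_b)


def full_report(
    foci_a: Sequence,
    foci_b: Sequence,
    config: ColocConfig,
    pixel_size_nm: float,
    fov_area_px2: float,
    reference_area_px2: float | None = None,
) -> ColocReport:
    """Offset correction + classification + chance + shells, in one call.

    ``reference_area_px2`` is the area the foci actually occupy (e.g. total
    cell area for in-cell imaging); it defaults to the field-of-view area,
    which is appropriate when foci are scattered over the whole surface.
    """
    a = foci_coordinates(foci_a)
    b = foci_coordinates(foci_b)
    if config.offset_px == "estimate":
        offset = estimate_offset(a, b) if len(a) and len(b) else (0.0, 0.0)
    else:
        offset = tuple(config.offset_px)  # type: ignore[arg-type]
    b_corr = b - np.asarray(offset) if len(b) else b
    report = classify_colocalized(a, b_corr, config, pixel_size_nm)
    report.offset_px = (float(offset[0]), float(offset[1]))

    area = reference_area_px2 if reference_area_px2 is not None else fov_area_px2
    radius = config.focus_radius_nm or config.max_dist_nm
    report.chance_C = chance_colocalization(radius, report.n_A + report.n_B, area, pixel_size_nm)
    report.chance_A = chance_colocalization(radius, report.n_B, area, pixel_size_nm)
    report.chance_B = chance_colocalization(radius, report.n_A, area, pixel_size_nm)
    report.corrected_A, report.corrected_B = corrected_frequency(report)
    dists = [p[2] for p in report.pairs]
    report.shell_histogram = shell_area_histogram(dists, config.max_dist_nm, config.n_shells)
    return report
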