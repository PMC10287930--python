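"""Synthetic two-channel cell fields and stretched-DNA molecule profiles.

Every generated object comes with full ground truth (planted focus
positions, colocalized pairs, gap intervals) so each downstream stage can be
tested against known answers.  Generation is deterministic: the same config
(including its seed) reproduces bit-identical output.

Scene model
-----------
Cells are spherocylinders (a rectangle with semicircular caps) placed
without overlap by rejection sampling.  Focus counts per cell and channel
are Poisson; positions are uniform within the cell.  A planted fraction of
channel-B foci is placed at a channel-A position plus isotropic Gaussian
localization jitter; the remaining B foci are independent.  Channel B is
rendered after adding a constant inter-channel offset to all B positions
(truth coordinates stay in the A frame, so offset correction can be tested).

Rendering sums isotropic Gaussian PSFs (total ``photons_per_focus`` photons
each) over a background confined to cell interiors ("cells" mode) or
covering the whole field ("surface" mode), applies Poisson shot noise to
the expected photon counts, multiplies by the EM gain (a pure multiplier;
EM excess noise is not modelled) and adds Gaussian read noise, then clips
at zero and quantizes to 16 bits.
"""

from __future__ import annotations

import math

import numpy as np
from shapely.geometry import LineString, Polygon
from shapely import contains_xy
from skimage.draw import polygon as draw_polygon

from .core import (
    FieldImage,
    GroundTruth,
    MoleculeProfile,
    MoleculeSimConfig,
    SceneConfig,
)

__all__ = ["generate_scene", "sample_truth", "generate_molecules", "place_cells"]

CHANNEL_A = "A"
CHANNEL_B = "B"

_MAX_PLACEMENT_TRIES = 5000


def place_cells(config: SceneConfig, rng: np.random.Generator) -> list[Polygon]:
    """Place non-overlapping spherocylindrical cells inside the field of view."""
    w_px, h_px = config.fov_px
    px_um = config.pixel_size_nm / 1000.0
    half_w_px = (config.cell_width_um / 2.0) / px_um
    cells: list[Polygon] = []
    tries = 0
    while len(cells) < config.n_cells:
        tries += 1
        if tries > _MAX_PLACEMENT_TRIES * max(1, config.n_cells):
            raise RuntimeError(
                f"could not place {config.n_cells} non-overlapping cells; "
                "reduce n_cells or cell size"
            )
        length_um = rng.uniform(*config.cell_length_um_range)
        # axis length of the rectangle part; total length = axis + width
        axis_px = max(length_um - config.cell_width_um, 0.1) / px_um
        angle = rng.uniform(0, math.pi)
        cx = rng.uniform(0, w_px - 1)
        cy = rng.uniform(0, h_px - 1)
        dx = 0.5 * axis_px * math.cos(angle)
        dy = 0.5 * axis_px * math.sin(angle)
        poly = LineString([(cx - dx, cy - dy), (cx + dx, cy + dy)]).buffer(
            half_w_px, quad_segs=8
        )
        minx, miny, maxx, maxy = poly.bounds
        if minx < 0 or miny < 0 or maxx > w_px - 1 or maxy > h_px - 1:
            continue
        if any(poly.intersects(c) for c in cells):
            continue
        cells.append(poly)
    return cells


def _uniform_in_polygon(poly: Polygon, n: int, rng: np.random.Generator) -> np.ndarray:
    """Sample n points uniformly inside a polygon by rejection in its bbox."""
    if n == 0:
        return np.zeros((0, 2))
    minx, miny, maxx, maxy = poly.bounds
    out = np.zeros((n, 2))
    got = 0
    while got < n:
        m = max(4 * (n - got), 16)
        xs = rng.uniform(minx, maxx, m)
        ys = rng.uniform(miny, maxy, m)
        ok = contains_xy(poly, xs, ys)
        take = min(int(ok.sum()), n - got)
        out[got : got + take, 0] = xs[ok][:take]
        out[got : got + take, 1] = ys[ok][:take]
        got += take
    return out


def sample_truth(config: SceneConfig, rng: np.random.Generator | None = None) -> GroundTruth:
    """Sample cell outlines and true focus positions (no rendering).

    Returns a :class:`GroundTruth` whose B-focus coordinates are in the
    channel-A frame (the inter-channel offset is applied at render time
    only).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    truth = GroundTruth()

    if config.mode == "cells":
        cells = place_cells(config, rng)
        truth.cell_polygons = [np.asarray(c.exterior.coords)[:-1] for c in cells]
        mean_a, mean_b = config.foci_per_cell_mean
        pts_a, pts_b = [], []
        for cell in cells:
            ka = rng.poisson(mean_a)
            kb = rng.poisson(mean_b)
            pts_a.append(_uniform_in_polygon(cell, ka, rng))
            pts_b.append(_uniform_in_polygon(cell, kb, rng))
        xy_a = np.vstack(pts_a) if pts_a else np.zeros((0, 2))
        xy_b = np.vstack(pts_b) if pts_b else np.zeros((0, 2))
    else:  # surface mode: uniform over the whole FOV
        w_px, h_px = config.fov_px
        mean_a, mean_b = config.foci_per_fov_mean
        na = rng.poisson(mean_a)
        nb = rng.poisson(mean_b)
        xy_a = np.column_stack([rng.uniform(0, w_px - 1, na), rng.uniform(0, h_px - 1, na)])
        xy_b = np.column_stack([rng.uniform(0, w_px - 1, nb), rng.uniform(0, h_px - 1, nb)])

    n_a, n_b = len(xy_a), len(xy_b)
    planted = np.zeros(n_b, dtype=bool)
    pairs: list[tuple[int, int]] = []
    n_plant = int(round(config.coloc_fraction * n_b))
    if n_plant > 0 and n_a > 0:
        which_b = rng.choice(n_b, size=n_plant, replace=False)
        which_a = rng.choice(n_a, size=n_plant, replace=n_plant > n_a)
        jitter_px = config.coloc_jitter_nm / config.pixel_size_nm
        jit = rng.normal(0.0, jitter_px, size=(n_plant, 2)) if jitter_px > 0 else 0.0
        xy_b[which_b] = xy_a[which_a] + jit
        w_px, h_px = config.fov_px
        xy_b[:, 0] = np.clip(xy_b[:, 0], 0, w_px - 1)
        xy_b[:, 1] = np.clip(xy_b[:, 1], 0, h_px - 1)
        planted[which_b] = True
        pairs = [(int(a), int(b)) for a, b in zip(which_a, which_b)]

    truth.foci_true[CHANNEL_A] = np.hstack([xy_a, np.zeros((n_a, 1))])
    truth.foci_true[CHANNEL_B] = np.hstack([xy_b, np.zeros((n_b, 1))])
    truth.coloc_pairs_true = pairs
    truth.planted_flag_b = planted
    return truth


def _background_mask(config: SceneConfig, truth: GroundTruth) -> np.ndarray:
    w_px, h_px = config.fov_px
    if config.mode == "surface":
        return np.ones((h_px, w_px), dtype=bool)
    mask = np.zeros((h_px, w_px), dtype=bool)
    for verts in truth.cell_polygons:
        rr, cc = draw_polygon(verts[:, 1], verts[:, 0], shape=(h_px, w_px))
        mask[rr, cc] = True
    return mask


def render_channel(
    xy: np.ndarray,
    config: SceneConfig,
    bg_mask: np.ndarray,
    rng: np.random.Generator,
    offset_px: tuple[float, float] = (0.0, 0.0),
    channel: str = "",
) -> FieldImage:
    """Render one channel from sub-pixel focus positions.

    The Gaussian PSF is sampled at pixel centers (0-based, pixel (0,0)
    center at coordinate (0.0, 0.0)) — the same convention the detector's
    sub-pixel fit uses.
    """
    w_px, h_px = config.fov_px
    sigma = config.psf_sigma_px
    amp = config.photons_per_focus / (2.0 * math.pi * sigma**2)
    expected = np.zeros((h_px, w_px))
    expected[bg_mask] += config.background_level
    r = int(math.ceil(5 * sigma))
    for x, y in np.asarray(xy, dtype=float).reshape(-1, 2):
        x = x + offset_px[0]
        y = y + offset_px[1]
        c0, c1 = int(math.floor(x)) - r, int(math.floor(x)) + r + 1
        r0, r1 = int(math.floor(y)) - r, int(math.floor(y)) + r + 1
        c0, c1 = max(c0, 0), min(c1, w_px)
        r0, r1 = max(r0, 0), min(r1, h_px)
        if c0 >= c1 or r0 >= r1:
            continue
        yy, xx = np.mgrid[r0:r1, c0:c1]
        expected[r0:r1, c0:c1] += amp * np.exp(
            -((xx - x) ** 2 + (yy - y) ** 2) / (2.0 * sigma**2)
        )
    counts = rng.poisson(expected).astype(float) if config.shot_noise else expected
    out = counts * config.em_gain
    if config.read_noise_sd > 0:
        out = out + rng.normal(0.0, config.read_noise_sd, size=out.shape)
    out = np.clip(np.rint(out), 0, 65535).astype(np.uint16)
    return FieldImage(out, config.pixel_size_nm, channel=channel)


def generate_scene(config: SceneConfig) -> tuple[GroundTruth, FieldImage, FieldImage]:
    """Generate ground truth and render both channels of one field of view."""
    rng = np.random.default_rng(config.seed)
    truth = sample_truth(config, rng)
    bg_mask = _background_mask(config, truth)
    img_a = render_channel(
        truth.foci_true[CHANNEL_A][:, :2], config, bg_mask, rng, channel=CHANNEL_A
    )
    img_b = render_channel(
        truth.foci_true[CHANNEL_B][:, :2],
        config,
        bg_mask,
        rng,
        offset_px=config.channel_offset_px,
        channel=CHANNEL_B,
    )
    return truth, img_a, img_b


# ---------------------------------------------------------------------------
# stretched-DNA molecules
# ---------------------------------------------------------------------------

def _lognormal_mu_sigma(mean: float, sd: float) -> tuple[float, float]:
    """Underlying normal parameters of a log-normal with given mean and sd."""
    s2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - 0.5 * s2
    return mu, math.sqrt(s2)


def generate_molecules(
    config: MoleculeSimConfig,
) -> tuple[list[MoleculeProfile], list[list[tuple[float, float]]]]:
    """Generate stretched-DNA molecule profiles with planted ssDNA gaps.

    Returns the profiles and, per molecule, the list of true gap intervals
    ``(start_um, end_um)`` measured from the molecule start.  Gap counts on a
    molecule of length L are Poisson(rate * L); gap lengths are log-normal;
    gaps that would overlap, exceed the molecule, or touch a molecule end
    (within one pixel; a dark end is indistinguishable from the terminus)
    are resampled.  Profiles are ``ds_intensity`` along stained dsDNA,
    ~0 inside gaps, plus Gaussian noise.
    """
    rng = np.random.default_rng(config.seed)
    mu, sig = _lognormal_mu_sigma(*config.gap_length_um_params)
    margin = config.pixel_size_um  # keep planted gaps off the molecule ends
    profiles: list[MoleculeProfile] = []
    truths: list[list[tuple[float, float]]] = []
    for i in range(config.n_molecules):
        length = 0.0
        n_px = 0
        while n_px < 2:
            length = rng.exponential(config.mean_length_um)
            n_px = int(round(length / config.pixel_size_um))
        length = n_px * config.pixel_size_um
        k = rng.poisson(config.gap_rate_per_um * length)
        gaps: list[tuple[float, float]] = []
        for _ in range(k):
            for _attempt in range(100):
                glen = rng.lognormal(mu, sig)
                if glen > length - 2 * margin:
                    continue
                start = rng.uniform(margin, length - margin - glen)
                iv = (start, start + glen)
                if all(iv[1] <= g0 or iv[0] >= g1 for g0, g1 in gaps):
                    gaps.append(iv)
                    break
        gaps.sort()
        centers = (np.arange(n_px) + 0.5) * config.pixel_size_um
        intensity = np.full(n_px, config.ds_intensity)
        for g0, g1 in gaps:
            intensity[(centers >= g0) & (centers < g1)] = 0.0
        if config.noise_sd > 0:
            intensity = intensity + rng.normal(0.0, config.noise_sd, n_px)
        profiles.append(
            MoleculeProfile(f"mol{i:05d}", intensity, config.pixel_size_um)
        )
        truths.append(gaps)
    return profiles, truths
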