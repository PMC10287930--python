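"""Shared data containers for the imaging pipeline.

Coordinate convention, used everywhere in this package: pixel coordinates are
0-based with the *center* of pixel ``(row=0, col=0)`` at coordinate
``(x=0.0, y=0.0)``; ``x`` runs along columns, ``y`` along rows.  Physical
quantities always carry their unit in the attribute name (``_px``, ``_nm``,
``_um``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "FieldImage",
    "Focus",
    "Particle",
    "CellROI",
    "SceneConfig",
    "GroundTruth",
    "MoleculeSimConfig",
    "MoleculeProfile",
    "GapCall",
    "GapSummary",
    "ColocConfig",
    "ShellHistogram",
    "ColocReport",
]


@dataclass
class FieldImage:
    """A single-channel 2-D image with a physical pixel size.

    Parameters
    ----------
    pixels
        2-D array of non-negative, finite intensities (camera counts or
        photons; the pipeline is unit-agnostic).
    pixel_size_nm
        Physical edge length of one pixel, in nanometres.
    channel
        Free-form channel label (e.g. ``"647"``, ``"568"``).
    frame
        Time-frame index for multi-page stacks.
    """

    pixels: np.ndarray
    pixel_size_nm: float
    channel: str = ""
    frame: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("FieldImage.pixels must be 2-D")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("FieldImage.pixels must be finite")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class Focus:
    """A sub-pixel point detection (one diffraction-limited spot)."""

    x_px: float
    y_px: float
    amplitude: float = 0.0
    background: float = 0.0
    sigma_px: float = float("nan")
    frame: int = 0
    channel: str = ""
    flags: tuple[str, ...] = ()

    @property
    def xy(self) -> tuple[float, float]:
        return (self.x_px, self.y_px)


@dataclass
class Particle:
    """A connected component of a thresholded image.

    ``mean_intensity`` is measured on the original (flattened) image, not on
    the mask or the filtered image.
    """

    pixel_set: frozenset
    area_px2: int
    mean_intensity: float

    def __post_init__(self) -> None:
        if self.area_px2 != len(self.pixel_set):
            raise ValueError("area_px2 must equal |pixel_set|")


@dataclass
class CellROI:
    """A cell outline polygon in pixel coordinates.

    ``polygon`` is an ``(n, 2)`` array of ``(x, y)`` vertices (not closed;
    the last vertex implicitly connects back to the first).
    """

    polygon: np.ndarray
    cell_id: str

    def __post_init__(self) -> None:
        self.polygon = np.asarray(self.polygon, dtype=float)
        if self.polygon.ndim != 2 or self.polygon.shape[1] != 2 or len(self.polygon) < 3:
            raise ValueError(f"ROI {self.cell_id}: polygon needs >= 3 (x, y) vertices")

    def shapely(self):
        from shapely.geometry import Polygon

        return Polygon(self.polygon)

    @property
    def area_px2(self) -> float:
        return float(self.shapely().area)

    @property
    def length_px(self) -> float:
        """Cell length: long side of the minimum rotated bounding rectangle."""
        rect = self.shapely().minimum_rotated_rectangle
        xs, ys = rect.exterior.coords.xy
        sides = [float(np.hypot(xs[i + 1] - xs[i], ys[i + 1] - ys[i])) for i in range(2)]
        return max(sides)


# ---------------------------------------------------------------------------
# synthetic scenes
# ---------------------------------------------------------------------------

@dataclass
class SceneConfig:
    """Parameters of a synthetic two-channel cell-field scene.

    Defaults emulate live-cell imaging of fluorescently tagged replisome
    (channel A) and RecF (channel B) foci in rod-shaped E. coli on a
    512x512 EMCCD field at 109 nm/px: per-cell focus numbers of ~1.7 (A)
    and ~0.66 (B), and a planted true-colocalization fraction of 0.4 of
    the B foci, matching the densities such experiments report.

    ``mode="surface"`` instead scatters foci uniformly over the whole field
    with uniform background (the in vitro slide / flow-cell regime, typically
    at 160 nm/px); per-channel focus numbers are then Poisson with mean
    ``foci_per_fov_mean``.
    """

    fov_px: tuple[int, int] = (512, 512)
    pixel_size_nm: float = 109.0
    n_cells: int = 60
    cell_length_um_range: tuple[float, float] = (2.0, 4.0)
    cell_width_um: float = 1.0
    foci_per_cell_mean: tuple[float, float] = (1.7, 0.66)
    coloc_fraction: float = 0.4
    coloc_jitter_nm: float = 50.0
    channel_offset_px: tuple[float, float] = (0.0, 0.0)
    psf_sigma_px: float = 1.0
    photons_per_focus: float = 2000.0
    background_level: float = 100.0
    em_gain: float = 30.0
    read_noise_sd: float = 10.0
    seed: int = 0
    mode: str = "cells"
    foci_per_fov_mean: tuple[float, float] = (100.0, 100.0)
    shot_noise: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.coloc_fraction <= 1.0):
            raise ValueError("coloc_fraction must lie in [0, 1]")
        if min(self.foci_per_cell_mean) < 0 or min(self.foci_per_fov_mean) < 0:
            raise ValueError("Poisson focus means must be non-negative")
        for name in ("pixel_size_nm", "cell_width_um", "psf_sigma_px",
                     "photons_per_focus", "em_gain"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.background_level < 0 or self.read_noise_sd < 0 or self.coloc_jitter_nm < 0:
            raise ValueError("noise/background/jitter levels must be non-negative")
        if self.n_cells < 0:
            raise ValueError("n_cells must be non-negative")
        if self.cell_length_um_range[0] <= 0 or self.cell_length_um_range[1] < self.cell_length_um_range[0]:
            raise ValueError("cell_length_um_range must be a positive, ordered pair")
        if self.mode not in ("cells", "surface"):
            raise ValueError("mode must be 'cells' or 'surface'")


@dataclass
class GroundTruth:
    """The generator's record of what was planted in a scene.

    ``foci_true`` maps channel label -> ``(n, 3)`` array of ``(x_px, y_px,
    frame)``; ``coloc_pairs_true`` lists ``(index_A, index_B)`` pairs planted
    as colocalized; ``planted_flag_b`` marks which B foci were planted on an
    A partner.
    """

    cell_polygons: list[np.ndarray] = field(default_factory=list)
    foci_true: dict[str, np.ndarray] = field(default_factory=dict)
    coloc_pairs_true: list[tuple[int, int]] = field(default_factory=list)
    planted_flag_b: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))


# ---------------------------------------------------------------------------
# stretched-DNA molecules
# ---------------------------------------------------------------------------

@dataclass
class MoleculeSimConfig:
    """Parameters for synthetic flow-stretched DNA molecules with ssDNA gaps.

    Molecule lengths are exponential (rolling-circle products of widely
    varying length); gaps arrive as a Poisson process along the molecule at
    ``gap_rate_per_um`` and have log-normal lengths parameterized by their
    distribution mean and sd in micrometres.  ``ds_intensity`` is the stained
    double-stranded level; gaps drop to ~0 (unstained ssDNA).
    """

    n_molecules: int = 100
    mean_length_um: float = 50.0
    gap_rate_per_um: float = 0.06
    gap_length_um_params: tuple[float, float] = (0.8, 0.5)
    pixel_size_um: float = 0.16
    ds_intensity: float = 1000.0
    noise_sd: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_molecules < 0:
            raise ValueError("n_molecules must be non-negative")
        if self.mean_length_um <= 0 or self.pixel_size_um <= 0 or self.ds_intensity <= 0:
            raise ValueError("lengths, pixel size and ds_intensity must be positive")
        if self.gap_rate_per_um < 0 or self.noise_sd < 0:
            raise ValueError("gap rate and noise sd must be non-negative")
        if min(self.gap_length_um_params) <= 0:
            raise ValueError("gap length distribution parameters must be positive")


@dataclass
class MoleculeProfile:
    """1-D intensity versus position along one stretched DNA molecule."""

    molecule_id: str
    intensity: np.ndarray
    pixel_size_um: float
    flags: set = field(default_factory=set)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 1 or len(self.intensity) == 0:
            raise ValueError("intensity must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def n_px(self) -> int:
        return len(self.intensity)

    @property
    def length_um(self) -> float:
        return self.n_px * self.pixel_size_um

    @property
    def positions_um(self) -> np.ndarray:
        """Positions of pixel centers from the molecule start."""
        return (np.arange(self.n_px) + 0.5) * self.pixel_size_um


@dataclass
class GapCall:
    """One called unstained (ssDNA) gap, in micrometres from molecule start."""

    start_um: float
    end_um: float

    def __post_init__(self) -> None:
        if not (0 <= self.start_um < self.end_um):
            raise ValueError("need 0 <= start_um < end_um")

    @property
    def length_um(self) -> float:
        return self.end_um - self.start_um


@dataclass
class GapSummary:
    """Pooled gap statistics over a set of molecules."""

    n_gaps: int
    total_length_um: float
    gaps_per_um: float
    mean_gap_um: float
    sd_gap_um: float
    bootstrap_se: float
    per_molecule: "object"  # pandas.DataFrame: molecule_id, length_um, n_gaps, rate
    mean_per_molecule_rate: float
    n_molecules: int
    n_flagged: int


# ---------------------------------------------------------------------------
# colocalization
# ---------------------------------------------------------------------------

@dataclass
class ColocConfig:
    """Two-channel colocalization parameters.

    ``max_dist_nm`` is the centroid-distance classification threshold
    (default 218 nm = 2 px at 109 nm/px).  ``focus_radius_nm`` is the radius
    whose disc area A_R enters the coincidental-colocalization formula
    C = A_R * n / A_FOV; by default it equals the classification threshold.
    ``offset_px`` is either an explicit ``(dx, dy)`` translation applied to
    channel B or the string ``"estimate"``.
    """

    max_dist_nm: float = 218.0
    focus_radius_nm: float | None = None
    offset_px: tuple[float, float] | str = (0.0, 0.0)
    n_shells: int = 8

    def __post_init__(self) -> None:
        if self.max_dist_nm <= 0:
            raise ValueError("max_dist_nm must be positive")
        if self.focus_radius_nm is None:
            self.focus_radius_nm = self.max_dist_nm
        if self.focus_radius_nm <= 0:
            raise ValueError("focus_radius_nm must be positive")
        if self.n_shells < 1:
            raise ValueError("n_shells must be >= 1")


@dataclass
class ShellHistogram:
    """Distances binned into concentric shells of equal area.

    Edges are ``r_k = r_max * sqrt(k / K)`` so consecutive annuli all have
    area ``pi * r_max**2 / K``; a uniform-in-area (CSR-like) distance
    distribution gives flat counts.
    """

    shell_edges_nm: np.ndarray
    counts: np.ndarray
    n_excluded: int = 0

    def __post_init__(self) -> None:
        self.shell_edges_nm = np.asarray(self.shell_edges_nm, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if len(self.shell_edges_nm) != len(self.counts) + 1:
            raise ValueError("need K+1 edges for K counts")


@dataclass
class ColocReport:
    """Result of a two-channel colocalization analysis.

    Frequencies are per-focus nearest-neighbour classifications:
    ``freq_A_given_B`` is the fraction of A foci with at least one B focus
    within ``max_dist_nm`` (and symmetrically).  ``chance_C`` is the printed
    coincidental-colocalization formula with n = foci of both channels;
    ``chance_A``/``chance_B`` are the per-direction variants using the
    partner channel count only (used by the default chance correction).
    Frequencies on an empty channel are NaN and flagged, never 0.
    """

    pairs_ab: list  # (index_A, index_B_nearest, distance_nm) for colocalized A foci
    pairs_ba: list
    freq_A_given_B: float
    freq_B_given_A: float
    n_A: int
    n_B: int
    max_dist_nm: float
    offset_px: tuple[float, float] = (0.0, 0.0)
    chance_C: float | None = None
    chance_A: float | None = None
    chance_B: float | None = None
    corrected_A: float | None = None
    corrected_B: float | None = None
    shell_histogram: ShellHistogram | None = None
    flags: tuple[str, ...] = ()

    @property
    def pairs(self) -> list:
        return list(self.pairs_ab) + list(self.pairs_ba)


def foci_coordinates(foci: Sequence) -> np.ndarray:
    """Coerce a list of Focus objects or an (n, 2) array to an (n, 2) array."""
    if isinstance(foci, np.ndarray):
        arr = np.asarray(foci, dtype=float)
        if arr.size == 0:
            return arr.reshape(0, 2)
        return arr[:, :2]
    if len(foci) == 0:
        return np.zeros((0, 2))
    if isinstance(foci[0], Focus):
        return np.array([[f.x_px, f.y_px] for f in foci], dtype=float)
    return np.asarray(foci, dtype=float)[:, :2]
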