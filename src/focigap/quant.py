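"""Per-cell focus statistics and plate/plate-reader assay formulas.

The formulas are exact arithmetic on their inputs:

* dead-cell percentage   dead / (alive + dead) * 100
* SOS reporter signal    F_reporter/OD_reporter - F_control/OD_control
* Tet recombination %    100 * (TetAmp cfu / dilution) / (Amp cfu / dilution)
* plasmid-loss fraction  white / (blue + white), with an exact
  (Clopper-Pearson) binomial 95% interval
* dot-blot background subtraction, floored at zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .core import CellROI, foci_coordinates

__all__ = [
    "foci_per_cell",
    "FociPerCellResult",
    "live_dead_percentage",
    "sos_signal",
    "tet_recombination_frequency",
    "plasmid_loss_fraction",
    "background_subtract",
    "BackgroundResult",
]


@dataclass
class FociPerCellResult:
    """Per-cell focus counts plus the summary over cells (mean +/- SEM)."""

    table: pd.DataFrame  # cell_id, n_foci, area_px2, length_px
    mean: float
    sem: float
    n_outside: int
    assignments: list  # per focus: cell_id or None
    overlap_flagged: list  # focus indices that fell in >1 ROI


def foci_per_cell(foci: Sequence, rois: Sequence[CellROI]) -> FociPerCellResult:
    """Assign each focus to the cell outline containing its centroid.

    Boundary points count as inside; when outlines overlap, the first ROI
    in input order wins and the focus is flagged.  Foci outside all ROIs
    are counted separately, so assigned + outside = total input foci.
    """
    xy = foci_coordinates(foci)
    polys = [(roi.cell_id, roi.shapely()) for roi in rois]
    counts = {roi.cell_id: 0 for roi in rois}
    assignments: list = []
    overlap_flagged: list[int] = []
    n_outside = 0
    from shapely.geometry import Point

    for i, (x, y) in enumerate(xy):
        p = Point(x, y)
        hits = [cid for cid, poly in polys if poly.covers(p)]
        if not hits:
            assignments.append(None)
            n_outside += 1
            continue
        if len(hits) > 1:
            overlap_flagged.append(i)
        counts[hits[0]] += 1
        assignments.append(hits[0])

    table = pd.DataFrame(
        {
            "cell_id": [roi.cell_id for roi in rois],
            "n_foci": [counts[roi.cell_id] for roi in rois],
            "area_px2": [roi.area_px2 for roi in rois],
            "length_px": [roi.length_px for roi in rois],
        }
    )
    vals = table["n_foci"].to_numpy(dtype=float)
    mean = float(vals.mean()) if len(vals) else float("nan")
    sem = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else float("nan")
    return FociPerCellResult(table, mean, sem, n_outside, assignments, overlap_flagged)


def live_dead_percentage(alive: float, dead: float) -> float:
    """Percentage of dead cells: dead / (alive + dead) * 100."""
    if alive < 0 or dead < 0:
        raise ValueError("counts must be non-negative")
    total = alive + dead
    if total == 0:
        raise ValueError("alive + dead must be positive")
    return dead / total * 100.0


def sos_signal(
    reporter_fluorescence: float,
    reporter_od: float,
    control_fluorescence: float,
    control_od: float,
) -> float:
    """OD-normalized SOS reporter signal minus the empty-vector control."""
    if reporter_od <= 0 or control_od <= 0:
        raise ValueError("OD values must be positive")
    return reporter_fluorescence / reporter_od - control_fluorescence / control_od


def tet_recombination_frequency(
    tet_amp_cfu: float,
    amp_cfu: float,
    tet_amp_dilution: float = 1.0,
    amp_dilution: float = 1.0,
) -> float:
    """Tet recombination events as a percentage of viable cfu.

    Colony counts are divided by the dilution plated (e.g. ``1e-5`` for the
    10^-5 plate) to recover per-culture numbers before taking the ratio.
    """
    if tet_amp_cfu < 0 or amp_cfu < 0:
        raise ValueError("colony counts must be non-negative")
    if tet_amp_dilution <= 0 or amp_dilution <= 0:
        raise ValueError("dilutions must be positive")
    viable = amp_cfu / amp_dilution
    if viable == 0:
        raise ValueError("zero viable cfu")
    return 100.0 * (tet_amp_cfu / tet_amp_dilution) / viable


def plasmid_loss_fraction(
    blue: int, white: int, confidence: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Fraction of plasmid-free (white) colonies with an exact binomial CI.

    Blue colonies retain the reporter plasmid; white ones have lost it.
    """
    if blue < 0 or white < 0:
        raise ValueError("counts must be non-negative")
    total = blue + white
    if total == 0:
        raise ValueError("blue + white must be positive")
    ci = binomtest(white, total).proportion_ci(confidence_level=confidence, method="exact")
    return white / total, (float(ci.low), float(ci.high))


class BackgroundResult(NamedTuple):
    value: float
    floored: bool


def background_subtract(signal_membrane: float, control_membrane: float) -> BackgroundResult:
    """Dot-blot signal minus control-membrane background, floored at 0.

    ``floored`` is True when the control exceeded the signal.
    """
    diff = signal_membrane - control_membrane
    if diff < 0:
        return BackgroundResult(0.0, True)
    return BackgroundResult(float(diff), False)
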