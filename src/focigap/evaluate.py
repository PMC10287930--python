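"""Recovery and calibration studies on synthetic ground truth.

These helpers quantify how well each stage recovers what the generator
planted: detection recall/precision/localization, chance-corrected
colocalization-fraction recovery, agreement of the coincidental-
colocalization formula with Monte-Carlo complete spatial randomness (CSR),
equal-area shell uniformity under CSR, and gaps-per-um rate recovery.
They are used by the test suite, the acceptance script and the examples.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import chisquare

from . import coloc as coloc_mod
from . import detect as detect_mod
from . import gaps as gaps_mod
from . import synth
from .core import ColocConfig, MoleculeSimConfig, SceneConfig

__all__ = [
    "match_to_truth",
    "detection_study",
    "chance_vs_monte_carlo",
    "coloc_recovery_study",
    "shell_uniformity_study",
    "gap_rate_study",
]


def match_to_truth(
    truth_xy: np.ndarray, detected_xy: np.ndarray, max_dist_px: float = 2.0
) -> list[tuple[int, int, float]]:
    """Greedy one-to-one matching of detections to truth by distance.

    Candidate pairs within ``max_dist_px`` are taken closest-first; each
    truth focus and each detection matches at most once.  Returns
    ``(truth_index, detection_index, distance_px)`` triples.
    """
    if len(truth_xy) == 0 or len(detected_xy) == 0:
        return []
    tree = cKDTree(detected_xy)
    cand: list[tuple[float, int, int]] = []
    for i, p in enumerate(truth_xy):
        for j in tree.query_ball_point(p, r=max_dist_px):
            d = float(np.hypot(*(p - detected_xy[j])))
            cand.append((d, i, j))
    cand.sort()
    used_t: set[int] = set()
    used_d: set[int] = set()
    out = []
    for d, i, j in cand:
        if i in used_t or j in used_d:
            continue
        used_t.add(i)
        used_d.add(j)
        out.append((i, j, d))
    return out


def _resolvable(truth_xy: np.ndarray, min_separation_px: float) -> np.ndarray:
    """Truth foci with no same-channel neighbour within min_separation_px.

    The peak picker merges closer pairs by construction (documented
    separation rule), so recall is reported over resolvable foci.
    """
    if len(truth_xy) < 2:
        return np.ones(len(truth_xy), dtype=bool)
    tree = cKDTree(truth_xy)
    d, _ = tree.query(truth_xy, k=2)
    return d[:, 1] >= min_separation_px


def detection_study(
    n_fovs: int = 50,
    photons_per_focus: float = 620.0,
    shot_noise: bool = True,
    seed: int = 0,
    foci_per_fov_mean: float = 100.0,
    min_separation_px: float = 3.0,
    match_radius_px: float = 2.0,
) -> dict:
    """Detection recall/precision/localization on surface-mode scenes.

    One channel per FOV, foci scattered uniformly over the field (the
    in vitro slide regime), default detector settings.  Recall is over
    resolvable truth foci (no same-channel neighbour within
    ``min_separation_px``); localization RMSE is over matched *isolated*
    emitters (no neighbour inside the fit window, ``2 * fit_radius`` px) —
    the refinement is a single-emitter fit and does not deblend
    overlapping PSFs.
    """
    isolation_px = 2.0 * 4.0  # twice the default fit radius
    n_match = n_truth = n_det = matched_det = 0
    sq_err: list[float] = []
    for k in range(n_fovs):
        cfg = dataclasses.replace(
            SceneConfig(),
            mode="surface",
            foci_per_fov_mean=(foci_per_fov_mean, 0.0),
            coloc_fraction=0.0,
            photons_per_focus=photons_per_focus,
            shot_noise=shot_noise,
            read_noise_sd=10.0 if shot_noise else 0.0,
            seed=seed * 100003 + k,
        )
        truth, img_a, _ = synth.generate_scene(cfg)
        txy = truth.foci_true[synth.CHANNEL_A][:, :2]
        flat = detect_mod.flatten(img_a)
        foci = detect_mod.detect_foci(flat, min_separation_px=min_separation_px)
        dxy = np.array([[f.x_px, f.y_px] for f in foci]).reshape(-1, 2)
        keep = _resolvable(txy, min_separation_px)
        iso = _resolvable(txy, isolation_px)
        matches = match_to_truth(txy, dxy, match_radius_px)
        matched_t = {i for i, _, _ in matches}
        n_truth += int(keep.sum())
        n_match += sum(1 for i in matched_t if keep[i])
        n_det += len(dxy)
        matched_det += len(matches)
        sq_err.extend(
            float(((txy[i] - dxy[j]) ** 2).sum())
            for i, j, _ in matches
            if iso[i]
        )
    return {
        "recall": n_match / n_truth if n_truth else float("nan"),
        "precision": matched_det / n_det if n_det else float("nan"),
        "rmse_px": math.sqrt(np.mean(sq_err)) if sq_err else float("nan"),
        "n_truth": n_truth,
        "n_detected": n_det,
    }


def chance_vs_monte_carlo(
    n_foci: int,
    focus_radius_px: float = 2.0,
    fov_px: tuple[int, int] = (512, 512),
    n_reps: int = 100_000,
    seed: int = 0,
) -> dict:
    """Monte-Carlo check of the C = A_R * n / A_FOV chance formula.

    Each replicate drops the ``n_foci`` partner foci and one probe focus
    uniformly in the FOV; the empirical chance is the fraction of
    replicates in which the probe has a partner within ``focus_radius_px``.
    The formula is the first-order (small-C) approximation of that
    probability.
    """
    rng = np.random.default_rng(seed)
    w, h = fov_px
    r2 = focus_radius_px**2
    hits = 0
    chunk = max(1, int(5e6 // max(n_foci, 1)))
    done = 0
    while done < n_reps:
        m = min(chunk, n_reps - done)
        partners = rng.uniform([0, 0], [w, h], size=(m, n_foci, 2))
        probe = rng.uniform([0, 0], [w, h], size=(m, 1, 2))
        d2 = ((partners - probe) ** 2).sum(axis=2)
        hits += int((d2.min(axis=1) <= r2).sum())
        done += m
    emp = hits / n_reps
    se = math.sqrt(max(emp * (1 - emp), 1e-12) / n_reps)
    formula = coloc_mod.chance_colocalization(
        focus_radius_px, n_foci, float(w * h), pixel_size_nm=1.0
    )
    return {"empirical": emp, "se": se, "formula": formula, "n": n_foci}


def coloc_recovery_study(
    fractions=(0.0, 0.2, 0.5, 0.8),
    n_fovs: int = 100,
    seed: int = 0,
    base_config: SceneConfig | None = None,
) -> pd.DataFrame:
    """Recovery of planted colocalized fractions from ground-truth foci.

    For each planted fraction, ``n_fovs`` cell scenes are sampled at the
    default densities; each is classified at the default 218 nm threshold
    and chance-corrected with the partner-channel chance level computed on
    the total cell area (the area the foci occupy).  Reports the mean
    corrected B-direction frequency (the planted fraction lives on channel
    B) with its standard error.
    """
    base = base_config or SceneConfig()
    cfg_coloc = ColocConfig()
    rows = []
    for f in fractions:
        vals = []
        raw = []
        for k in range(n_fovs):
            cfg = dataclasses.replace(
                base, coloc_fraction=f, seed=seed * 1000003 + int(f * 1000) * 1009 + k
            )
            truth = synth.sample_truth(cfg)
            a = truth.foci_true[synth.CHANNEL_A][:, :2]
            b = truth.foci_true[synth.CHANNEL_B][:, :2]
            if len(a) == 0 or len(b) == 0:
                continue
            from shapely.geometry import Polygon

            cell_area = float(
                sum(Polygon(p).area for p in truth.cell_polygons)
            ) or float(cfg.fov_px[0] * cfg.fov_px[1])
            report = coloc_mod.full_report(
                a,
                b,
                cfg_coloc,
                cfg.pixel_size_nm,
                fov_area_px2=float(cfg.fov_px[0] * cfg.fov_px[1]),
                reference_area_px2=cell_area,
            )
            vals.append(report.corrected_B)
            raw.append(report.freq_B_given_A)
        vals_arr = np.asarray(vals)
        rows.append(
            {
                "planted_fraction": f,
                "mean_corrected": float(vals_arr.mean()),
                "se": float(vals_arr.std(ddof=1) / math.sqrt(len(vals_arr))),
                "mean_raw": float(np.mean(raw)),
                "n_fovs": len(vals_arr),
            }
        )
    return pd.DataFrame(rows)


def shell_uniformity_study(
    n_replicates: int = 200,
    n_pairs: int = 100_000,
    r_max_px: float = 10.0,
    n_shells: int = 8,
    fov_px: tuple[int, int] = (512, 512),
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Chi-square uniformity of equal-area shell counts under CSR.

    Each replicate draws ``n_pairs`` independent A-B point pairs uniform in
    the FOV, keeps pair distances <= ``r_max_px`` and tests the equal-area
    shell histogram for uniformity.  Under CSR the counts are flat, so the
    rejection rate should stay near ``alpha``.
    """
    rng = np.random.default_rng(seed)
    w, h = fov_px
    rejections = 0
    for _ in range(n_replicates):
        a = rng.uniform([0, 0], [w, h], size=(n_pairs, 2))
        b = rng.uniform([0, 0], [w, h], size=(n_pairs, 2))
        d = np.hypot(*(a - b).T)
        hist = coloc_mod.shell_area_histogram(d[d <= r_max_px], r_max_px, n_shells)
        if hist.counts.sum() < 5 * n_shells:
            continue
        _, p = chisquare(hist.counts)
        if p < alpha:
            rejections += 1
    return {
        "rejection_rate": rejections / n_replicates,
        "n_replicates": n_replicates,
        "alpha": alpha,
    }


def gap_rate_study(
    gap_rate_per_um: float,
    total_length_um: float = 5000.0,
    seed: int = 0,
    noise_sd_fraction: float = 0.1,
    min_gap_px: int = 2,
) -> dict:
    """Gaps-per-um recovery against the generator's callable ground truth.

    ``reference_rate`` is the planted rate of *callable* gaps (covering at
    least ``min_gap_px`` pixel centers, away from molecule ends) — the
    detection floor the caller states.  ``planted_rate`` counts every
    planted gap.
    """
    base = MoleculeSimConfig()
    n_mol = max(1, int(round(total_length_um / base.mean_length_um)))
    cfg = dataclasses.replace(
        base,
        n_molecules=n_mol,
        gap_rate_per_um=gap_rate_per_um,
        noise_sd=noise_sd_fraction * base.ds_intensity,
        seed=seed,
    )
    profiles, true_gaps = synth.generate_molecules(cfg)
    calls = [gaps_mod.call_gaps(p, min_gap_px=min_gap_px) for p in profiles]
    summary = gaps_mod.gap_frequency(calls, profiles, seed=seed)
    n_callable = sum(
        len(gaps_mod.true_gap_runs(g, p, min_gap_px))
        for g, p in zip(true_gaps, profiles)
    )
    n_planted = sum(len(g) for g in true_gaps)
    total_len = sum(p.length_um for p in profiles)
    return {
        "estimated_rate": summary.gaps_per_um,
        "bootstrap_se": summary.bootstrap_se,
        "reference_rate": n_callable / total_len,
        "planted_rate": n_planted / total_len,
        "total_length_um": total_len,
        "n_gaps_called": summary.n_gaps,
    }
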