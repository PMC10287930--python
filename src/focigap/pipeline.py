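"""Stage orchestration: simulate -> detect -> coloc -> gaps -> quant.

Each stage reads/writes CSV and TIFF files inside an output directory and
stamps every table with the config hash and seed that produced it.  Output
files deliberately carry no timestamps, so a fixed configuration yields
byte-identical outputs across runs.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import coloc as coloc_mod
from . import detect as detect_mod
from . import gaps as gaps_mod
from . import io as io_mod
from . import quant as quant_mod
from . import synth
from .core import CellROI

__all__ = [
    "run_simulate",
    "run_detect",
    "run_coloc",
    "run_gaps",
    "run_quant",
    "run_all",
]


def _prov(config: io_mod.PipelineConfig) -> dict:
    return {"config_hash": config.hash(), "seed": config.scene.seed}


def run_simulate(config: io_mod.PipelineConfig, outdir) -> dict:
    """Generate a scene and molecules; write images, truth and profiles."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prov = _prov(config)

    truth, img_a, img_b = synth.generate_scene(config.scene)
    io_mod.write_image(outdir / "channel_A.tif", img_a)
    io_mod.write_image(outdir / "channel_B.tif", img_b)

    rows = []
    for ch in (synth.CHANNEL_A, synth.CHANNEL_B):
        arr = truth.foci_true[ch]
        planted = (
            truth.planted_flag_b
            if ch == synth.CHANNEL_B
            else np.zeros(len(arr), dtype=bool)
        )
        for (x, y, frame), flag in zip(arr, planted):
            rows.append(
                {
                    "channel": ch,
                    "x_px": x,
                    "y_px": y,
                    "frame": int(frame),
                    "planted_coloc": bool(flag),
                }
            )
    io_mod._write_csv(
        outdir / "truth_foci.csv",
        pd.DataFrame(rows, columns=["channel", "x_px", "y_px", "frame", "planted_coloc"]),
        prov,
    )
    rois = [
        CellROI(poly, f"cell{i:04d}") for i, poly in enumerate(truth.cell_polygons)
    ]
    io_mod.write_rois_csv(outdir / "cell_rois.csv", rois, prov)
    if rois:
        io_mod.write_rois_imagej(outdir / "cell_rois.zip", rois)

    profiles, true_gaps = synth.generate_molecules(config.molecules)
    io_mod.write_profiles_csv(outdir / "molecule_profiles.csv", profiles, prov)
    gap_rows = [
        {"molecule_id": p.molecule_id, "start_um": g0, "end_um": g1}
        for p, gs in zip(profiles, true_gaps)
        for g0, g1 in gs
    ]
    io_mod._write_csv(
        outdir / "truth_gaps.csv",
        pd.DataFrame(gap_rows, columns=["molecule_id", "start_um", "end_um"]),
        prov,
    )
    return {"truth": truth, "profiles": profiles, "true_gaps": true_gaps}


def run_detect(config: io_mod.PipelineConfig, outdir, images: dict | None = None) -> dict:
    """Flatten and detect foci per channel; write one foci table per channel."""
    outdir = Path(outdir)
    prov = _prov(config)
    p = config.detect
    result = {}
    for ch in ("A", "B"):
        path = outdir / f"channel_{ch}.tif"
        frames = io_mod.read_image(path, config.scene.pixel_size_nm, channel=ch)
        foci = []
        for im in frames:
            flat = detect_mod.flatten(im, p["flatten_radius_px"])
            foci.extend(
                detect_mod.detect_foci(
                    flat,
                    r_inner=p["r_inner"],
                    r_outer=p["r_outer"],
                    min_separation_px=p["min_separation_px"],
                    fit_radius_px=p["fit_radius_px"],
                    threshold=p["threshold"],
                    noise_floor_nsigma=p["noise_floor_nsigma"],
                    refine=p["refine"],
                )
            )
        io_mod.write_foci_csv(outdir / f"foci_{ch}.csv", foci, prov)
        result[ch] = foci
    return result


def run_coloc(config: io_mod.PipelineConfig, outdir) -> "coloc_mod.ColocReport":
    """Offset-corrected colocalization report from the two foci tables."""
    outdir = Path(outdir)
    prov = _prov(config)
    foci_a = io_mod.read_foci_csv(outdir / "foci_A.csv")
    foci_b = io_mod.read_foci_csv(outdir / "foci_B.csv")
    w, h = config.scene.fov_px
    fov_area = float(w * h)
    reference_area = None
    roi_path = outdir / "cell_rois.csv"
    if roi_path.exists():
        rois = io_mod.read_rois(roi_path)
        if rois:
            reference_area = float(sum(r.area_px2 for r in rois))
    report = coloc_mod.full_report(
        foci_a,
        foci_b,
        config.coloc,
        config.scene.pixel_size_nm,
        fov_area_px2=fov_area,
        reference_area_px2=reference_area,
    )
    summary = pd.DataFrame(
        [
            {
                "n_A": report.n_A,
                "n_B": report.n_B,
                "freq_A_given_B": report.freq_A_given_B,
                "freq_B_given_A": report.freq_B_given_A,
                "chance_C": report.chance_C,
                "chance_A": report.chance_A,
                "chance_B": report.chance_B,
                "corrected_A": report.corrected_A,
                "corrected_B": report.corrected_B,
                "offset_dx_px": report.offset_px[0],
                "offset_dy_px": report.offset_px[1],
                "max_dist_nm": report.max_dist_nm,
                "flags": ";".join(report.flags),
            }
        ]
    )
    io_mod._write_csv(outdir / "coloc_summary.csv", summary, prov)
    pairs = pd.DataFrame(
        [
            {"direction": d, "index_src": i, "index_dst": j, "distance_nm": dist}
            for d, plist in (("A->B", report.pairs_ab), ("B->A", report.pairs_ba))
            for i, j, dist in plist
        ],
        columns=["direction", "index_src", "index_dst", "distance_nm"],
    )
    io_mod._write_csv(outdir / "coloc_pairs.csv", pairs, prov)
    sh = report.shell_histogram
    shells = pd.DataFrame(
        {
            "shell_inner_nm": sh.shell_edges_nm[:-1],
            "shell_outer_nm": sh.shell_edges_nm[1:],
            "count": sh.counts,
        }
    )
    io_mod._write_csv(outdir / "shell_histogram.csv", shells, prov)
    return report


def run_gaps(config: io_mod.PipelineConfig, outdir) -> "gaps_mod.GapSummary":
    """Call gaps on all molecule profiles and summarize the pooled rate."""
    outdir = Path(outdir)
    prov = _prov(config)
    p = config.gaps
    profiles = io_mod.read_profiles_csv(
        outdir / "molecule_profiles.csv", config.molecules.pixel_size_um
    )
    calls = [
        gaps_mod.call_gaps(
            prof,
            threshold_fraction=p["threshold_fraction"],
            min_gap_px=p["min_gap_px"],
            smooth_px=p["smooth_px"],
        )
        for prof in profiles
    ]
    call_rows = [
        {
            "molecule_id": prof.molecule_id,
            "start_um": c.start_um,
            "end_um": c.end_um,
            "length_um": c.length_um,
        }
        for prof, cl in zip(profiles, calls)
        for c in cl
    ]
    io_mod._write_csv(
        outdir / "gap_calls.csv",
        pd.DataFrame(call_rows, columns=["molecule_id", "start_um", "end_um", "length_um"]),
        prov,
    )
    summary = gaps_mod.gap_frequency(
        calls, profiles, n_bootstrap=p["n_bootstrap"], seed=config.molecules.seed
    )
    io_mod._write_csv(
        outdir / "gap_summary.csv",
        pd.DataFrame(
            [
                {
                    "n_gaps": summary.n_gaps,
                    "total_length_um": summary.total_length_um,
                    "gaps_per_um": summary.gaps_per_um,
                    "bootstrap_se": summary.bootstrap_se,
                    "mean_gap_um": summary.mean_gap_um,
                    "sd_gap_um": summary.sd_gap_um,
                    "mean_per_molecule_rate": summary.mean_per_molecule_rate,
                    "n_molecules": summary.n_molecules,
                    "n_flagged_unstained": summary.n_flagged,
                }
            ]
        ),
        prov,
    )
    io_mod._write_csv(outdir / "gap_per_molecule.csv", summary.per_molecule, prov)
    return summary


def run_quant(config: io_mod.PipelineConfig, outdir) -> "quant_mod.FociPerCellResult":
    """Per-cell focus statistics from detected foci and cell outlines."""
    outdir = Path(outdir)
    prov = _prov(config)
    rois = io_mod.read_rois(outdir / "cell_rois.csv")
    tables = []
    for ch in ("A", "B"):
        foci = io_mod.read_foci_csv(outdir / f"foci_{ch}.csv")
        res = quant_mod.foci_per_cell(foci, rois)
        t = res.table.copy()
        t.insert(0, "channel", ch)
        tables.append((ch, res, t))
    io_mod._write_csv(
        outdir / "foci_per_cell.csv", pd.concat([t for _, _, t in tables]), prov
    )
    io_mod._write_csv(
        outdir / "foci_per_cell_summary.csv",
        pd.DataFrame(
            [
                {
                    "channel": ch,
                    "mean_foci_per_cell": res.mean,
                    "sem": res.sem,
                    "n_cells": len(res.table),
                    "n_foci_outside": res.n_outside,
                    "n_overlap_flagged": len(res.overlap_flagged),
                }
                for ch, res, _ in tables
            ]
        ),
        prov,
    )
    return tables[0][1]


def run_all(config: io_mod.PipelineConfig, outdir) -> None:
    run_simulate(config, outdir)
    run_detect(config, outdir)
    run_coloc(config, outdir)
    run_gaps(config, outdir)
    run_quant(config, outdir)
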