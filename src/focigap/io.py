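"""File formats and configuration for the pipeline.

Images are TIFF only (16-bit or float, single- or multi-page).  Tables are
CSV with a provenance header of ``#``-prefixed comment lines (package
version, config hash, seed) so every output names the configuration that
produced it; readers skip those lines.  Cell outlines travel either as CSV
vertex tables (``cell_id,x_px,y_px`` — the lossless native format) or as
ImageJ ``.roi`` / ``RoiSet.zip`` polygon files via a minimal codec written
here (polygon type only; ImageJ stores integer corner-based coordinates,
which we convert to/from this package's 0-based pixel-center convention by
the half-pixel shift, rounding to integers on write).
"""

from __future__ import annotations

import hashlib
import io as _stdio
import json
import struct
import zipfile
from dataclasses import asdict, fields
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import (
    CellROI,
    ColocConfig,
    FieldImage,
    Focus,
    MoleculeProfile,
    MoleculeSimConfig,
    SceneConfig,
)

__all__ = [
    "read_image",
    "write_image",
    "read_rois",
    "write_rois_csv",
    "write_rois_imagej",
    "write_foci_csv",
    "read_foci_csv",
    "write_profiles_csv",
    "read_profiles_csv",
    "PipelineConfig",
    "config_hash",
]

PACKAGE_VERSION = "0.1.0"


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------

def read_image(path, pixel_size_nm: float, channel: str = "") -> list[FieldImage]:
    """Read a single- or multi-page TIFF into FieldImages (frames 0..T-1).

    The pixel size comes from the caller's configuration; TIFF metadata is
    not trusted for physical calibration.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    try:
        arr = tifffile.imread(path)
    except Exception as exc:  # pragma: no cover - error text passthrough
        raise ValueError(f"could not read TIFF {path}: {exc}") from exc
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected 2-D or 3-D TIFF, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer) and not np.issubdtype(arr.dtype, np.floating):
        raise ValueError(f"{path}: unsupported dtype {arr.dtype}")
    return [
        FieldImage(frame.astype(float), pixel_size_nm, channel=channel, frame=t)
        for t, frame in enumerate(arr)
    ]


def write_image(path, images: FieldImage | Sequence[FieldImage]) -> None:
    """Write FieldImage(s) as a (multi-page) 16-bit TIFF."""
    if isinstance(images, FieldImage):
        images = [images]
    stack = np.stack([np.clip(np.rint(im.pixels), 0, 65535).astype(np.uint16) for im in images])
    tifffile.imwrite(path, stack if len(stack) > 1 else stack[0], photometric="minisblack")


# ---------------------------------------------------------------------------
# ROIs
# ---------------------------------------------------------------------------

def _validate_roi(roi: CellROI) -> CellROI:
    poly = roi.shapely()
    if len(roi.polygon) < 3 or not poly.is_valid or poly.area <= 0:
        raise ValueError(f"ROI {roi.cell_id}: degenerate or self-intersecting polygon")
    return roi


def write_rois_csv(path, rois: Sequence[CellROI], provenance: dict | None = None) -> None:
    rows = [
        {"cell_id": roi.cell_id, "x_px": x, "y_px": y}
        for roi in rois
        for x, y in roi.polygon
    ]
    _write_csv(path, pd.DataFrame(rows, columns=["cell_id", "x_px", "y_px"]), provenance)


def _read_rois_csv(path) -> list[CellROI]:
    df = pd.read_csv(path, comment="#")
    rois = []
    for cid, grp in df.groupby("cell_id", sort=False):
        rois.append(_validate_roi(CellROI(grp[["x_px", "y_px"]].to_numpy(), str(cid))))
    return rois


# --- minimal ImageJ .roi polygon codec -------------------------------------

_IJ_HEADER = 64
_IJ_POLYGON = 0


def _encode_imagej_roi(roi: CellROI) -> bytes:
    # integer, corner-based ImageJ coordinates: ours + 0.5, rounded
    xs = np.rint(roi.polygon[:, 0] + 0.5).astype(int)
    ys = np.rint(roi.polygon[:, 1] + 0.5).astype(int)
    left, top = int(xs.min()), int(ys.min())
    right, bottom = int(xs.max()), int(ys.max())
    n = len(xs)
    header = bytearray(_IJ_HEADER)
    header[0:4] = b"Iout"
    struct.pack_into(">h", header, 4, 227)  # format version
    header[6] = _IJ_POLYGON
    struct.pack_into(">hhhh", header, 8, top, left, bottom, right)
    struct.pack_into(">h", header, 16, n)
    body = b"".join(struct.pack(">h", int(x - left)) for x in xs)
    body += b"".join(struct.pack(">h", int(y - top)) for y in ys)
    return bytes(header) + body


def _decode_imagej_roi(data: bytes, cell_id: str) -> CellROI:
    if data[0:4] != b"Iout":
        raise ValueError(f"ROI {cell_id}: not an ImageJ ROI file")
    roi_type = data[6]
    if roi_type != _IJ_POLYGON:
        raise ValueError(f"ROI {cell_id}: unsupported ROI type {roi_type} (polygon only)")
    top, left, _bottom, _right = struct.unpack_from(">hhhh", data, 8)
    (n,) = struct.unpack_from(">h", data, 16)
    xs = np.array(struct.unpack_from(f">{n}h", data, _IJ_HEADER)) + left
    ys = np.array(struct.unpack_from(f">{n}h", data, _IJ_HEADER + 2 * n)) + top
    verts = np.column_stack([xs - 0.5, ys - 0.5]).astype(float)
    return _validate_roi(CellROI(verts, cell_id))


def write_rois_imagej(path, rois: Sequence[CellROI]) -> None:
    """Write ROIs as a single ``.roi`` file or a ``RoiSet``-style zip."""
    path = Path(path)
    if path.suffix == ".roi":
        if len(rois) != 1:
            raise ValueError("a .roi file holds exactly one ROI; use .zip for sets")
        path.write_bytes(_encode_imagej_roi(rois[0]))
        return
    with zipfile.ZipFile(path, "w", zipfile.ZIP_STORED) as zf:
        for roi in rois:
            # fixed timestamp keeps archives byte-identical across runs
            info = zipfile.ZipInfo(f"{roi.cell_id}.roi", date_time=(1980, 1, 1, 0, 0, 0))
            zf.writestr(info, _encode_imagej_roi(roi))


def read_rois(path) -> list[CellROI]:
    """Read cell outlines from CSV, a single .roi, or an ImageJ ROI zip."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"ROI file not found: {path}")
    if path.suffix == ".csv":
        return _read_rois_csv(path)
    if path.suffix == ".roi":
        return [_decode_imagej_roi(path.read_bytes(), path.stem)]
    if path.suffix == ".zip":
        out = []
        with zipfile.ZipFile(path) as zf:
            for name in zf.namelist():
                out.append(_decode_imagej_roi(zf.read(name), Path(name).stem))
        return out
    raise ValueError(f"unrecognized ROI format: {path}")


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def _write_csv(path, df: pd.DataFrame, provenance: dict | None) -> None:
    buf = _stdio.StringIO()
    buf.write(f"# focigap {PACKAGE_VERSION}\n")
    for key, value in (provenance or {}).items():
        buf.write(f"# {key}={value}\n")
    df.to_csv(buf, index=False)
    Path(path).write_text(buf.getvalue())


def write_foci_csv(path, foci: Sequence[Focus], provenance: dict | None = None) -> None:
    df = pd.DataFrame(
        {
            "channel": [f.channel for f in foci],
            "frame": [f.frame for f in foci],
            "x_px": [f.x_px for f in foci],
            "y_px": [f.y_px for f in foci],
            "amplitude": [f.amplitude for f in foci],
            "background": [f.background for f in foci],
            "sigma_px": [f.sigma_px for f in foci],
            "flags": [";".join(f.flags) for f in foci],
        }
    )
    _write_csv(path, df, provenance)


def read_foci_csv(path) -> list[Focus]:
    df = pd.read_csv(path, comment="#", keep_default_na=False, na_values=["nan", ""])
    out = []
    for _, row in df.iterrows():
        flags = row.get("flags", "")
        flags = tuple(str(flags).split(";")) if isinstance(flags, str) and flags else ()
        out.append(
            Focus(
                x_px=float(row["x_px"]),
                y_px=float(row["y_px"]),
                amplitude=float(row.get("amplitude", 0.0)),
                background=float(row.get("background", 0.0)),
                sigma_px=float(row.get("sigma_px", float("nan"))),
                frame=int(row.get("frame", 0)),
                channel=str(row.get("channel", "")),
                flags=flags,
            )
        )
    return out


def write_profiles_csv(
    path, profiles: Sequence[MoleculeProfile], provenance: dict | None = None
) -> None:
    rows = []
    for p in profiles:
        for i, (pos, inten) in enumerate(zip(p.positions_um, p.intensity)):
            rows.append(
                {"molecule_id": p.molecule_id, "index": i, "position_um": pos, "intensity": inten}
            )
    _write_csv(path, pd.DataFrame(rows, columns=["molecule_id", "index", "position_um", "intensity"]), provenance)


def read_profiles_csv(path, pixel_size_um: float) -> list[MoleculeProfile]:
    df = pd.read_csv(path, comment="#")
    out = []
    for mid, grp in df.groupby("molecule_id", sort=False):
        grp = grp.sort_values("index")
        out.append(MoleculeProfile(str(mid), grp["intensity"].to_numpy(), pixel_size_um))
    return out


# ---------------------------------------------------------------------------
# pipeline configuration
# ---------------------------------------------------------------------------

class PipelineConfig:
    """Typed, validated configuration for every pipeline stage.

    Sections: ``scene`` (SceneConfig fields), ``molecules``
    (MoleculeSimConfig fields), ``coloc`` (ColocConfig fields), ``detect``
    and ``gaps`` (plain parameter dicts with documented defaults).  Unknown
    sections or keys are rejected by name.
    """

    DETECT_DEFAULTS = {
        "r_inner": 1,
        "r_outer": 4,
        "min_separation_px": 3.0,
        "fit_radius_px": 4,
        "threshold": "yen",
        "noise_floor_nsigma": 5.0,
        "refine": "gaussian",
        "flatten_radius_px": 15,
    }
    GAPS_DEFAULTS = {
        "threshold_fraction": 0.5,
        "min_gap_px": 2,
        "smooth_px": 3,
        "n_bootstrap": 1000,
    }

    def __init__(self, data: dict | None = None):
        data = dict(data or {})
        known = {"scene", "molecules", "coloc", "detect", "gaps"}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config section(s): {sorted(unknown)}")
        self.scene = self._build(SceneConfig, data.get("scene", {}), "scene")
        self.molecules = self._build(MoleculeSimConfig, data.get("molecules", {}), "molecules")
        self.coloc = self._build(ColocConfig, data.get("coloc", {}), "coloc")
        self.detect = self._merge(self.DETECT_DEFAULTS, data.get("detect", {}), "detect")
        self.gaps = self._merge(self.GAPS_DEFAULTS, data.get("gaps", {}), "gaps")

    @staticmethod
    def _build(cls, section: dict, name: str):
        valid = {f.name for f in fields(cls)}
        unknown = set(section) - valid
        if unknown:
            raise ValueError(f"unknown key(s) in [{name}]: {sorted(unknown)}")
        kwargs = {
            k: tuple(v) if isinstance(v, list) else v for k, v in section.items()
        }
        return cls(**kwargs)

    @staticmethod
    def _merge(defaults: dict, section: dict, name: str) -> dict:
        unknown = set(section) - set(defaults)
        if unknown:
            raise ValueError(f"unknown key(s) in [{name}]: {sorted(unknown)}")
        out = dict(defaults)
        out.update(section)
        return out

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        return cls(yaml.safe_load(path.read_text()) or {})

    def to_dict(self) -> dict:
        return {
            "scene": asdict(self.scene),
            "molecules": asdict(self.molecules),
            "coloc": {
                "max_dist_nm": self.coloc.max_dist_nm,
                "focus_radius_nm": self.coloc.focus_radius_nm,
                "offset_px": list(self.coloc.offset_px)
                if not isinstance(self.coloc.offset_px, str)
                else self.coloc.offset_px,
                "n_shells": self.coloc.n_shells,
            },
            "detect": dict(self.detect),
            "gaps": dict(self.gaps),
        }

    def hash(self) -> str:
        return config_hash(self.to_dict())


def config_hash(config: dict) -> str:
    """Short stable hash of a configuration mapping."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]
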