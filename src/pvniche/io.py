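"""Readers, writers and validation for cell tables, geometry and manifests.

On-disk formats are deliberately plain:

* cell tables — UTF-8 CSV, one row per segmented cell: ``cell_id``,
  ``x_um``, ``y_um`` and one 0/1 column per marker;
* geometry — either a single-channel uint8 TIFF label mask
  (0 stroma / 1 TCI / 2 vessel) with a stated pixel size, or a JSON file
  of polygon rings in µm;
* manifest — CSV with ``tumor_id``, ``group``, ``treatment``
  (untreated/NAC) and ``outcome`` (DF/Mets);
* results — tidy CSVs plus a run-metadata JSON.

Validation failures raise :class:`CellTableError` with the offending row
number and column so bad inputs are diagnosable without a debugger.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import Polygon

from .geometry import RoiGeometry
from .phenotyping import MARKERS

_TRUE = {"1", "true", "True", "TRUE", 1, True}
_FALSE = {"0", "false", "False", "FALSE", 0, False}

#: Markers that must be present in every cell table. PanCK and CD31 are
#: optional: tables restricted to non-epithelial, non-endothelial cells may
#: omit them (they then default to negative).
REQUIRED_MARKERS = [m for m in MARKERS if m not in ("PanCK", "CD31")]


class CellTableError(ValueError):
    """A cell table failed validation; message carries row/column context."""


class GeometryError(ValueError):
    """Geometry input is malformed (unknown label, missing pixel size...)."""


# ----------------------------------------------------------------------
# cell tables
# ----------------------------------------------------------------------

def read_cell_table(path, extent_um: tuple[float, float] | None = None) -> pd.DataFrame:
    """Load and validate a per-ROI cell table.

    Marker columns are coerced from {0,1,true,false} to booleans; row order
    is preserved. ``extent_um = (width, height)`` additionally checks that
    coordinates fall inside the ROI. Row numbers in error messages are
    1-based data rows (header excluded).
    """
    df = pd.read_csv(path, dtype={"cell_id": str})
    required = ["cell_id", "x_um", "y_um"] + REQUIRED_MARKERS
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CellTableError(f"{path}: missing column(s) {missing}")
    if df.empty:
        for m in MARKERS:
            if m not in df.columns:
                df[m] = pd.Series(dtype=bool)
            else:
                df[m] = df[m].astype(bool)
        return df

    dup = df["cell_id"].duplicated()
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0]) + 1
        raise CellTableError(f"{path}: duplicate cell_id {df['cell_id'].iloc[row - 1]!r} at row {row}")

    for coord in ("x_um", "y_um"):
        vals = pd.to_numeric(df[coord], errors="coerce")
        bad = vals.isna() | (vals < 0)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise CellTableError(f"{path}: invalid {coord} at row {row}")
        df[coord] = vals.astype(float)
    if extent_um is not None:
        w, h = extent_um
        out = (df["x_um"] > w) | (df["y_um"] > h)
        if out.any():
            row = int(np.flatnonzero(out.to_numpy())[0]) + 1
            raise CellTableError(f"{path}: coordinate outside ROI extent at row {row}")

    for m in MARKERS:
        if m not in df.columns:
            df[m] = False
            continue
        col = df[m]
        coerced = np.empty(len(col), dtype=bool)
        for i, v in enumerate(col):
            if v in _TRUE:
                coerced[i] = True
            elif v in _FALSE:
                coerced[i] = False
            else:
                raise CellTableError(
                    f"{path}: non-boolean marker value {v!r} in column {m!r} at row {i + 1}"
                )
        df[m] = coerced
    return df


def write_cell_table(df: pd.DataFrame, path) -> None:
    """Write a cell table as CSV with markers encoded 0/1 and µm rounded to nm."""
    out = df.copy()
    for m in MARKERS:
        if m in out.columns:
            out[m] = out[m].astype(int)
    for c in ("x_um", "y_um"):
        out[c] = out[c].round(3)
    cols = ["cell_id", "x_um", "y_um"] + [m for m in MARKERS if m in out.columns]
    out[cols].to_csv(path, index=False)


# ----------------------------------------------------------------------
# geometry
# ----------------------------------------------------------------------

def read_geometry_mask(path, pixel_size_um: float, roi_id: str | None = None) -> RoiGeometry:
    """Raster dialect: labeled uint8 TIFF → raster-backed geometry."""
    if pixel_size_um is None or pixel_size_um <= 0:
        raise GeometryError("pixel_size_um is required for raster geometry")
    mask = tifffile.imread(path)
    if mask.ndim != 2:
        raise GeometryError(f"{path}: expected a single-channel 2-D mask")
    labels = set(np.unique(mask))
    if not labels <= {0, 1, 2}:
        raise GeometryError(f"{path}: unknown label value(s) {sorted(labels - {0, 1, 2})}")
    nrow, ncol = mask.shape
    return RoiGeometry(
        roi_id=roi_id or Path(path).stem,
        width_um=ncol * pixel_size_um,
        height_um=nrow * pixel_size_um,
        pixel_size_um=pixel_size_um,
        mask=mask.astype(np.uint8),
    )


def read_geometry_polygons(path, pixel_size_um: float | None = None) -> RoiGeometry:
    """Vector dialect: JSON polygon sets → vector-backed geometry.

    Schema: ``{"roi_id", "width_um", "height_um", "pixel_size_um",
    "tci": [ring, ...], "vessels": [ring, ...]}`` with each ring a list of
    ``[x, y]`` vertices in µm.
    """
    with open(path) as fh:
        raw = json.load(fh)
    ps = pixel_size_um or raw.get("pixel_size_um")
    if ps is None or ps <= 0:
        raise GeometryError(f"{path}: pixel_size_um missing")
    return RoiGeometry(
        roi_id=raw.get("roi_id", Path(path).stem),
        width_um=float(raw["width_um"]),
        height_um=float(raw["height_um"]),
        pixel_size_um=float(ps),
        tci_polygons=[Polygon(r) for r in raw.get("tci", [])],
        vessel_polygons=[Polygon(r) for r in raw.get("vessels", [])],
    )


def read_geometry(path, pixel_size_um: float | None = None, roi_id: str | None = None) -> RoiGeometry:
    """Dispatch on extension: .tif/.tiff → mask dialect, .json → polygons."""
    p = str(path)
    if p.endswith((".tif", ".tiff")):
        return read_geometry_mask(path, pixel_size_um, roi_id)
    if p.endswith(".json"):
        g = read_geometry_polygons(path, pixel_size_um)
        if roi_id:
            g.roi_id = roi_id
        return g
    raise GeometryError(f"unrecognized geometry format: {path}")


def write_geometry_polygons(geometry: RoiGeometry, path) -> None:
    def ring(poly: Polygon):
        xy = np.asarray(poly.exterior.coords)[:-1]
        return [[round(float(x), 4), round(float(y), 4)] for x, y in xy]

    payload = {
        "roi_id": geometry.roi_id,
        "width_um": geometry.width_um,
        "height_um": geometry.height_um,
        "pixel_size_um": geometry.pixel_size_um,
        "tci": [ring(p) for p in geometry.tci_polygons],
        "vessels": [ring(p) for p in geometry.vessel_polygons],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, sort_keys=True)


def write_geometry_mask(geometry: RoiGeometry, path) -> None:
    """Write the labeled mask as uncompressed TIFF (deterministic bytes)."""
    tifffile.imwrite(path, geometry.rasterize(), photometric="minisblack")


# ----------------------------------------------------------------------
# manifests
# ----------------------------------------------------------------------

@dataclass
class StudyManifest:
    """Cohort design: tumor → (treatment, outcome) plus that tumor's ROIs."""

    table: pd.DataFrame  # tumor_id, group, treatment, outcome
    roi_ids: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"tumor_id", "group", "treatment", "outcome"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"manifest missing column(s) {sorted(missing)}")
        if self.table[["treatment", "outcome"]].isna().any().any():
            raise ValueError("manifest treatment/outcome must be non-missing")
        for t, rois in self.roi_ids.items():
            if not rois:
                raise ValueError(f"tumor {t!r} has no ROIs")

    @property
    def groups(self) -> list[str]:
        return sorted(self.table["group"].unique())

    def tumors_in(self, group: str) -> list[str]:
        return self.table.loc[self.table["group"] == group, "tumor_id"].tolist()


def read_manifest(path, roi_ids: dict[str, list[str]] | None = None) -> StudyManifest:
    return StudyManifest(pd.read_csv(path, dtype=str), roi_ids or {})


def write_manifest(manifest: StudyManifest, path) -> None:
    manifest.table.to_csv(path, index=False)


# ----------------------------------------------------------------------
# results
# ----------------------------------------------------------------------

def write_results(tables: dict[str, pd.DataFrame], out_dir, metadata: dict | None = None) -> list[Path]:
    """Write tidy CSVs (sorted, index-free) plus run metadata JSON.

    Deterministic: identical tables produce byte-identical files, so reruns
    can be compared by hash.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, df in tables.items():
        p = out / f"{name}.csv"
        df.to_csv(p, index=False, float_format="%.6g")
        written.append(p)
    if metadata is not None:
        p = out / "run_metadata.json"
        with open(p, "w") as fh:
            json.dump(metadata, fh, indent=2, sort_keys=True)
        written.append(p)
    return written


def sha256_of(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
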