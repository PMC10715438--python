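"""Compartment assignment: stroma/TCI crossed with perivascular status.

The perivascular (PV) niche is the tissue within ``pv_threshold_um``
(default 50 µm) of the abluminal — outer — surface of a vessel, excluding
the vessel region itself (CD31+ wall and lumen). PV status cross-cuts the
stroma/TCI split, giving four analysis compartments plus a sentinel for
cells lying inside a vessel:

    TCI_PV, TCI_NONPV, STROMA_PV, STROMA_NONPV, VESSEL_EXCLUDED

A cell whose centroid lies exactly at the threshold distance is PV
("within 50 µm" is inclusive; "non-PV" is strictly beyond). With no
vessels in the ROI, every distance is +inf and everything is non-PV.

Two computation routes exist and must agree to within one pixel:

* vector — exact point-to-polygon distances and PV bands obtained by
  polygon offsetting (``buffer``), used when the geometry carries polygons;
* raster — label lookup plus a Euclidean distance transform from the
  vessel pixels, used when only a labeled mask is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy.ndimage import distance_transform_edt
from shapely.ops import unary_union

from .geometry import LABEL_TCI, LABEL_VESSEL, RoiGeometry

DEFAULT_PV_THRESHOLD_UM = 50.0

#: The five compartment labels, in canonical order.
COMPARTMENTS = ["STROMA_PV", "STROMA_NONPV", "TCI_PV", "TCI_NONPV", "VESSEL_EXCLUDED"]
#: The four analysis compartments (vessel interiors excluded).
ANALYSIS_COMPARTMENTS = COMPARTMENTS[:4]

# integer codes for the compartment map raster
_COMP_CODE = {name: i for i, name in enumerate(COMPARTMENTS)}


@dataclass
class CompartmentAreas:
    """Realized area of each compartment in one ROI, in mm²."""

    roi_id: str
    areas_mm2: dict[str, float]

    @property
    def total_mm2(self) -> float:
        return float(sum(self.areas_mm2.values()))

    def __getitem__(self, name: str) -> float:
        return self.areas_mm2[name]


def distance_to_vessel(x, y, geometry: RoiGeometry) -> np.ndarray:
    """Distance (µm) from point(s) to the nearest vessel boundary.

    Positive outside vessels, 0 on the boundary, negative strictly inside
    (interior flag), +inf when the ROI has no vessels. Points must lie
    within the ROI extent.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    if np.any((x < 0) | (x > geometry.width_um) | (y < 0) | (y > geometry.height_um)):
        raise ValueError("point outside ROI extent")
    if geometry.is_vector:
        return _vector_distance(x, y, geometry)
    return _raster_distance(x, y, geometry)


def _vector_distance(x, y, geometry: RoiGeometry) -> np.ndarray:
    vu = geometry.vessel_union
    if vu.is_empty:
        return np.full(x.shape, np.inf)
    pts = shapely.points(x, y)
    d = shapely.distance(pts, vu)  # 0 for points on/inside the polygon
    inside = shapely.contains_xy(vu, x, y)
    if np.any(inside):
        d_in = shapely.distance(pts[inside], vu.boundary)
        d = d.astype(float)
        d[inside] = -d_in
    return d


def _raster_distance(x, y, geometry: RoiGeometry) -> np.ndarray:
    field = raster_distance_field(geometry)
    s = geometry.pixel_size_um
    nrow, ncol = field.shape
    j = np.clip((x / s).astype(int), 0, ncol - 1)
    i = np.clip((y / s).astype(int), 0, nrow - 1)
    return field[i, j]


def raster_distance_field(geometry: RoiGeometry, pixel_size_um: float | None = None) -> np.ndarray:
    """Per-pixel distance (µm) to the nearest vessel pixel; negative inside vessels.

    Computed with Euclidean distance transforms of the vessel mask and its
    complement.
    """
    mask = geometry.rasterize(pixel_size_um)
    s = pixel_size_um or geometry.pixel_size_um
    vessel = mask == LABEL_VESSEL
    if not vessel.any():
        return np.full(mask.shape, np.inf)
    d_out = distance_transform_edt(~vessel) * s
    d_in = distance_transform_edt(vessel) * s
    return np.where(vessel, -d_in, d_out)


def classify_cells(
    cells: pd.DataFrame,
    geometry: RoiGeometry,
    pv_threshold_um: float = DEFAULT_PV_THRESHOLD_UM,
) -> pd.Series:
    """Compartment label for every cell (columns ``x_um``, ``y_um``).

    Vessel interior wins; otherwise region (TCI vs stroma) crossed with
    PV status at ``pv_threshold_um`` (inclusive).
    """
    if pv_threshold_um <= 0:
        raise ValueError("pv_threshold_um must be positive")
    x = cells["x_um"].to_numpy(dtype=float)
    y = cells["y_um"].to_numpy(dtype=float)
    if len(x) == 0:
        return pd.Series([], dtype=object, index=cells.index, name="compartment")
    in_vessel = geometry.contains_vessel(x, y)
    in_tci = geometry.contains_tci(x, y)
    dist = distance_to_vessel(x, y, geometry)
    pv = dist <= pv_threshold_um
    labels = np.where(
        in_vessel,
        "VESSEL_EXCLUDED",
        np.where(
            in_tci,
            np.where(pv, "TCI_PV", "TCI_NONPV"),
            np.where(pv, "STROMA_PV", "STROMA_NONPV"),
        ),
    )
    return pd.Series(labels, index=cells.index, name="compartment")


def classify_cell(
    x: float, y: float, geometry: RoiGeometry, pv_threshold_um: float = DEFAULT_PV_THRESHOLD_UM
) -> str:
    """Compartment label of a single point (see :func:`classify_cells`)."""
    df = pd.DataFrame({"x_um": [x], "y_um": [y]})
    return classify_cells(df, geometry, pv_threshold_um).iloc[0]


def compartment_map(
    geometry: RoiGeometry,
    pv_threshold_um: float = DEFAULT_PV_THRESHOLD_UM,
    pixel_size_um: float | None = None,
) -> np.ndarray:
    """Integer raster of compartment codes (index into ``COMPARTMENTS``).

    For vector geometry the PV band is the rasterization of the offset
    polygons ``vessel.buffer(threshold)`` minus the vessels themselves, so
    the band edge is exact up to pixel-center sampling; for raster geometry
    the band comes from the distance transform.
    """
    s = pixel_size_um or geometry.pixel_size_um
    mask = geometry.rasterize(pixel_size_um)
    out = np.full(mask.shape, _COMP_CODE["STROMA_NONPV"], dtype=np.uint8)
    out[mask == LABEL_TCI] = _COMP_CODE["TCI_NONPV"]
    out[mask == LABEL_VESSEL] = _COMP_CODE["VESSEL_EXCLUDED"]

    if geometry.is_vector:
        if geometry.vessel_union.is_empty:
            return out
        band = unary_union(
            [p.buffer(pv_threshold_um, quad_segs=64) for p in geometry.vessel_polygons]
        )
        shapely.prepare(band)
        xx, yy = geometry.pixel_centers(s)
        pv = shapely.contains_xy(band, xx.ravel(), yy.ravel()).reshape(mask.shape)
    else:
        field = raster_distance_field(geometry, pixel_size_um)
        pv = field <= pv_threshold_um

    stroma_pv = pv & (mask == 0)
    tci_pv = pv & (mask == LABEL_TCI)
    out[stroma_pv] = _COMP_CODE["STROMA_PV"]
    out[tci_pv] = _COMP_CODE["TCI_PV"]
    return out


def compartment_areas(
    geometry: RoiGeometry,
    pv_threshold_um: float = DEFAULT_PV_THRESHOLD_UM,
    pixel_size_um: float | None = None,
) -> CompartmentAreas:
    """Integrate pixel areas per compartment (mm²).

    The five classes partition the ROI exactly: every pixel is counted
    once, so the areas sum to the ROI area to machine precision.
    """
    s = pixel_size_um or geometry.pixel_size_um
    cmap = compartment_map(geometry, pv_threshold_um, pixel_size_um)
    px_mm2 = (s * s) / 1e6
    areas = {
        name: float(np.count_nonzero(cmap == code) * px_mm2)
        for name, code in _COMP_CODE.items()
    }
    return CompartmentAreas(roi_id=geometry.roi_id, areas_mm2=areas)
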