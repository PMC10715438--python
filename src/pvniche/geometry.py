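"""ROI geometry: tumor-cell islands (TCIs), vessels, and raster/vector duality.

A region of interest (ROI) is a rectangular field of imaged tissue. Its
geometry consists of PanCK+ tumor-cell-island regions and CD31+ vessel
regions (wall + lumen treated as one region); everything else is stroma.
Geometry may be supplied as polygons (µm coordinates) or as a labeled raster
mask; both dialects are supported throughout and must agree to within one
pixel.

Conventions
-----------
* Coordinates are continuous µm, origin at the top-left corner of the ROI,
  y increasing downward (image convention).
* Raster pixel (row i, col j) covers the half-open square
  [j*s, (j+1)*s) x [i*s, (i+1)*s) where s is the pixel size in µm; a pixel
  is labeled by its center.
* Mask labels: 0 = stroma, 1 = TCI, 2 = vessel. Vessel wins where regions
  would overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import shapely
from shapely.geometry import Polygon, box
from shapely.ops import unary_union

#: Raster mask labels.
LABEL_STROMA = 0
LABEL_TCI = 1
LABEL_VESSEL = 2


@dataclass
class RoiGeometry:
    """Geometry of one ROI.

    Exactly one of the two dialects is primary: if ``tci_polygons`` /
    ``vessel_polygons`` are given the geometry is vector-backed (distances
    computed exactly, PV bands by polygon offsetting); if only ``mask`` is
    given it is raster-backed (labels by pixel lookup, distances by
    Euclidean distance transform).

    Parameters
    ----------
    roi_id
        Identifier, unique within a tumor.
    width_um, height_um
        ROI extent in µm.
    pixel_size_um
        Raster resolution used for area integration (and the native
        resolution of ``mask`` when raster-backed).
    tci_polygons, vessel_polygons
        Region outlines in µm (vector dialect).
    mask
        uint8 label image, shape (rows, cols) = (height/s, width/s)
        (raster dialect).
    """

    roi_id: str
    width_um: float
    height_um: float
    pixel_size_um: float
    tci_polygons: list[Polygon] = field(default_factory=list)
    vessel_polygons: list[Polygon] = field(default_factory=list)
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.width_um <= 0 or self.height_um <= 0:
            raise ValueError("ROI extent must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.mask is None and not self.is_vector:
            # all-stroma vector geometry is fine; nothing to check
            pass
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=np.uint8)
            bad = set(np.unique(self.mask)) - {LABEL_STROMA, LABEL_TCI, LABEL_VESSEL}
            if bad:
                raise ValueError(f"unknown mask label(s): {sorted(bad)}")

    # ------------------------------------------------------------------
    # dialect helpers
    # ------------------------------------------------------------------
    @property
    def is_vector(self) -> bool:
        """True when polygon regions are available (vector dialect)."""
        return bool(self.tci_polygons) or bool(self.vessel_polygons)

    @cached_property
    def extent_polygon(self) -> Polygon:
        return box(0.0, 0.0, self.width_um, self.height_um)

    @cached_property
    def tci_union(self):
        geom = unary_union(self.tci_polygons) if self.tci_polygons else Polygon()
        shapely.prepare(geom)
        return geom

    @cached_property
    def vessel_union(self):
        geom = unary_union(self.vessel_polygons) if self.vessel_polygons else Polygon()
        shapely.prepare(geom)
        return geom

    @property
    def area_mm2(self) -> float:
        return self.width_um * self.height_um / 1e6

    def grid_shape(self, pixel_size_um: float | None = None) -> tuple[int, int]:
        s = pixel_size_um or self.pixel_size_um
        return (int(round(self.height_um / s)), int(round(self.width_um / s)))

    def pixel_centers(self, pixel_size_um: float | None = None):
        """(x, y) coordinate arrays of all pixel centers, each shape (rows, cols)."""
        s = pixel_size_um or self.pixel_size_um
        nrow, ncol = self.grid_shape(s)
        xs = (np.arange(ncol) + 0.5) * s
        ys = (np.arange(nrow) + 0.5) * s
        return np.meshgrid(xs, ys)

    # ------------------------------------------------------------------
    # rasterization
    # ------------------------------------------------------------------
    def rasterize(self, pixel_size_um: float | None = None) -> np.ndarray:
        """Label mask from polygons (or return the native mask).

        Pixels are labeled by their center point; vessel overrides TCI.
        """
        s = pixel_size_um or self.pixel_size_um
        if not self.is_vector:
            if self.mask is None:
                return np.zeros(self.grid_shape(s), dtype=np.uint8)
            if abs(s - self.pixel_size_um) < 1e-12:
                return self.mask
            raise ValueError("cannot re-rasterize a raster-backed geometry at a different pixel size")
        mask = np.zeros(self.grid_shape(s), dtype=np.uint8)
        _paint(mask, self.tci_union, LABEL_TCI, s)
        _paint(mask, self.vessel_union, LABEL_VESSEL, s)
        return mask

    def contains_tci(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Vector point-in-TCI test (falls back to mask lookup when raster-backed)."""
        if self.is_vector:
            return shapely.contains_xy(self.tci_union, x, y)
        if self.mask is None:  # empty geometry: everything is stroma
            return np.zeros(np.shape(x), dtype=bool)
        return self.label_at(x, y) == LABEL_TCI

    def contains_vessel(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        if self.is_vector:
            return shapely.contains_xy(self.vessel_union, x, y)
        if self.mask is None:
            return np.zeros(np.shape(x), dtype=bool)
        return self.label_at(x, y) == LABEL_VESSEL

    def label_at(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Mask label under each point (half-open pixel convention)."""
        if self.mask is None:
            raise ValueError("geometry has no raster mask")
        s = self.pixel_size_um
        nrow, ncol = self.mask.shape
        j = np.clip((np.asarray(x) / s).astype(int), 0, ncol - 1)
        i = np.clip((np.asarray(y) / s).astype(int), 0, nrow - 1)
        return self.mask[i, j]


def _paint(mask: np.ndarray, geom, label: int, s: float) -> None:
    """Set pixels whose centers fall inside ``geom``, restricted to its bbox."""
    if geom.is_empty:
        return
    nrow, ncol = mask.shape
    minx, miny, maxx, maxy = geom.bounds
    j0 = max(int(minx / s) - 1, 0)
    j1 = min(int(maxx / s) + 2, ncol)
    i0 = max(int(miny / s) - 1, 0)
    i1 = min(int(maxy / s) + 2, nrow)
    if j0 >= j1 or i0 >= i1:
        return
    xs = (np.arange(j0, j1) + 0.5) * s
    ys = (np.arange(i0, i1) + 0.5) * s
    xx, yy = np.meshgrid(xs, ys)
    inside = shapely.contains_xy(geom, xx.ravel(), yy.ravel()).reshape(xx.shape)
    sub = mask[i0:i1, j0:j1]
    sub[inside] = label


def circle(cx: float, cy: float, r: float, n: int = 128) -> Polygon:
    """Regular-polygon approximation of a circle (used for synthetic vessels)."""
    t = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    return Polygon(np.column_stack([cx + r * np.cos(t), cy + r * np.sin(t)]))
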