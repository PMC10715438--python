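"""Synthetic tumor-map generator with known ground truth.

Emulates the tissue structure the analysis assumes: PanCK+ tumor-cell
islands (TCIs) embedded in stroma, circular vessels confined to the
stroma, immune cells drawn from an inhomogeneous Poisson process that is
piecewise-constant over the four analysis compartments (immune exclusion
from TCIs, configurable perivascular enrichment per phenotype,
configurable multiplicative group effects), and optionally seeded 3-cell
contact clusters in the perivascular stroma.

Every quantity the downstream pipeline estimates — compartment areas,
expected densities, seeded-cluster membership — is recorded as ground
truth at generation time, so recovery can be tested without external
data. The generator is fully deterministic given the seed.

What it does NOT emulate: pixel-level fluorescence, nucleus/membrane
shapes, segmentation errors, or between-tumor biological variance beyond
Poisson sampling noise (tumors within a group share their expected
densities unless group effects differ).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from . import io as pvio
from .compartments import (
    ANALYSIS_COMPARTMENTS,
    CompartmentAreas,
    compartment_areas,
    compartment_map,
    _COMP_CODE,
)
from .geometry import RoiGeometry, circle
from .phenotyping import MARKERS

#: The 2×2 cohort design: treatment × 3-year outcome.
DEFAULT_GROUPS = {
    "untreated_DF": ("untreated", "DF"),
    "untreated_Mets": ("untreated", "Mets"),
    "NAC_DF": ("NAC", "DF"),
    "NAC_Mets": ("NAC", "Mets"),
}

_DEFAULT_INTENSITIES = {
    # cells/mm², piecewise-constant base intensity per region class.
    # Stromal values are of the order seen in immune-rich breast-tumor
    # stroma; TCI values are ~10x lower (immune exclusion); cancer cells
    # live only in TCIs.
    "TAM": {"stroma": 250.0, "tci": 25.0},
    "CD4_T": {"stroma": 150.0, "tci": 15.0},
    "CD8_T": {"stroma": 150.0, "tci": 15.0},
    "TREG": {"stroma": 50.0, "tci": 5.0},
    "CANCER": {"stroma": 0.0, "tci": 2000.0},
}

_DEFAULT_PV_ENRICHMENT = {
    # multiplicative intensity factor inside the PV band; the qualitative
    # pattern observed in TNBC stroma: TAMs, CD4 T cells and Tregs
    # perivascularly enriched, CD8 T cells evenly distributed.
    "TAM": 2.0,
    "CD4_T": 2.0,
    "CD8_T": 1.0,
    "TREG": 2.0,
    "CANCER": 1.0,
}

_DEFAULT_COEXPRESSION = {
    # marginal marker probabilities given phenotype. ~78% of TAMs lack
    # PD-L1; the PD-1/LAG-3 split gives a 0.5/0.4/0.1
    # naive/active/exhausted T-cell mix.
    "*": {"tam_pdl1": 0.22, "tam_tim3": 0.30, "t_pd1": 0.5, "t_lag3_given_pd1": 0.2}
}


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults describe a 2×2 cohort (untreated/NAC × DF/+Mets) of
    600×600 µm ROIs at 0.5 µm/px with ~35% TCI coverage and three 8 µm
    vessels per ROI. Vessel density/size are not constrained by any
    measurement — tissue vessel statistics vary widely — and are simply
    plausible round numbers; treat them as free parameters.
    """

    seed: int = 0
    n_tumors_per_group: int = 5
    rois_per_tumor: int = 20
    roi_width_um: float = 600.0
    roi_height_um: float = 600.0
    pixel_size_um: float = 0.5
    tci_fraction: float = 0.35
    n_vessels_per_roi: int = 3
    vessel_radius_um: float = 8.0
    pv_threshold_um: float = 50.0
    contact_threshold_um: float = 12.0
    phenotype_intensities: dict = field(default_factory=lambda: _copy(_DEFAULT_INTENSITIES))
    pv_enrichment: dict = field(default_factory=lambda: dict(_DEFAULT_PV_ENRICHMENT))
    group_effects: dict = field(default_factory=dict)
    marker_coexpression: dict = field(default_factory=lambda: _copy(_DEFAULT_COEXPRESSION))
    n_seeded_clusters_per_roi: int = 0
    groups: dict = field(default_factory=lambda: dict(DEFAULT_GROUPS))

    def __post_init__(self) -> None:
        if not (0.0 <= self.tci_fraction < 1.0):
            raise ValueError("tci_fraction must be in [0, 1)")
        if self.rois_per_tumor < 1:
            raise ValueError("rois_per_tumor must be >= 1")
        if self.n_vessels_per_roi < 0 or self.n_seeded_clusters_per_roi < 0:
            raise ValueError("counts must be non-negative")
        for ph, levels in self.phenotype_intensities.items():
            for region, lam in levels.items():
                if lam < 0:
                    raise ValueError(f"negative intensity for {ph}/{region}")
        for ph, rho in self.pv_enrichment.items():
            if rho < 0:
                raise ValueError(f"negative PV enrichment for {ph}")

    # -- lookup helpers -------------------------------------------------
    def base_intensity(self, phenotype: str, region: str) -> float:
        return float(self.phenotype_intensities.get(phenotype, {}).get(region, 0.0))

    def group_factor(self, group: str, phenotype: str, compartment: str) -> float:
        g = self.group_effects.get(group, {})
        ph = g.get(phenotype, g.get("*", {}))
        return float(ph.get(compartment, ph.get("*", 1.0)))

    def coexpression(self, group: str) -> dict:
        base = dict(_DEFAULT_COEXPRESSION["*"])
        base.update(self.marker_coexpression.get("*", {}))
        base.update(self.marker_coexpression.get(group, {}))
        return base

    def expected_intensity(self, phenotype: str, compartment: str, group: str) -> float:
        """True expected density (cells/mm²) in one compartment — the
        quantity the density module should recover."""
        region = "tci" if compartment.startswith("TCI") else "stroma"
        lam = self.base_intensity(phenotype, region)
        if compartment.endswith("_PV"):
            lam *= float(self.pv_enrichment.get(phenotype, 1.0))
        return lam * self.group_factor(group, phenotype, compartment)

    def to_dict(self) -> dict:
        return {
            k: getattr(self, k)
            for k in (
                "seed", "n_tumors_per_group", "rois_per_tumor", "roi_width_um",
                "roi_height_um", "pixel_size_um", "tci_fraction",
                "n_vessels_per_roi", "vessel_radius_um", "pv_threshold_um",
                "contact_threshold_um", "phenotype_intensities", "pv_enrichment",
                "group_effects", "marker_coexpression",
                "n_seeded_clusters_per_roi", "groups",
            )
        }


def _copy(d: dict) -> dict:
    return json.loads(json.dumps(d))


@dataclass
class RoiGroundTruth:
    """Per-ROI truth: expected densities, realized areas, seeded clusters."""

    expected_density: dict  # phenotype -> compartment -> cells/mm²
    areas_mm2: dict  # compartment -> mm²
    seeded_clusters: list  # [{"member_ids": [...], "tcell_lineage": ...}, ...]


@dataclass
class RoiContext:
    """Cached per-geometry rasters so repeated sampling is cheap."""

    comp_map: np.ndarray
    areas: CompartmentAreas
    class_pixels: dict  # compartment -> (rows, cols) arrays

    @classmethod
    def build(cls, geometry: RoiGeometry, pv_threshold_um: float) -> "RoiContext":
        cmap = compartment_map(geometry, pv_threshold_um)
        areas = CompartmentAreas(
            roi_id=geometry.roi_id,
            areas_mm2={
                name: float(np.count_nonzero(cmap == code) * geometry.pixel_size_um ** 2 / 1e6)
                for name, code in _COMP_CODE.items()
            },
        )
        pixels = {
            name: np.nonzero(cmap == _COMP_CODE[name]) for name in ANALYSIS_COMPARTMENTS
        }
        return cls(comp_map=cmap, areas=areas, class_pixels=pixels)


# ----------------------------------------------------------------------
# geometry generation
# ----------------------------------------------------------------------

def generate_roi_geometry(
    config: SimulationConfig,
    rng: np.random.Generator,
    roi_id: str = "roi",
    max_attempts: int = 5000,
) -> RoiGeometry:
    """Random ROI geometry: smooth TCI blobs plus circular stromal vessels.

    TCI blobs are Fourier-perturbed ellipses placed without mutual overlap
    until their total (ROI-clipped) area reaches the target fraction of the
    ROI (±20%); vessels are circles whose centers lie in stroma, fully
    inside the ROI, not overlapping TCIs or each other. Raises ``RuntimeError``
    if placement cannot satisfy the targets within ``max_attempts``.
    """
    w, h = config.roi_width_um, config.roi_height_um
    roi_area = w * h
    target = config.tci_fraction * roi_area

    blobs: list[Polygon] = []
    placed_area = 0.0
    if target > 0:
        n_blobs = max(1, int(round(target / (np.pi * (min(w, h) / 8.0) ** 2))))
        blob_area = target / n_blobs
        attempts = 0
        while placed_area < 0.95 * target:
            attempts += 1
            if attempts > max_attempts:
                raise RuntimeError(
                    f"could not reach TCI fraction {config.tci_fraction:.2f} "
                    f"(placed {placed_area / roi_area:.2f}) in {max_attempts} attempts"
                )
            # size the last blob to the remaining deficit so the total
            # cannot overshoot the tolerance band
            nominal = min(blob_area, target - placed_area)
            blob = _random_blob(rng, nominal, w, h)
            if any(blob.distance(b) < 6.0 for b in blobs):
                continue
            clipped = blob.intersection(_roi_box(w, h))
            if clipped.is_empty or clipped.area < 0.25 * nominal:
                continue
            blobs.append(clipped)
            placed_area += clipped.area
        if not (0.8 * target <= placed_area <= 1.2 * target):
            raise RuntimeError(
                f"TCI area {placed_area / roi_area:.3f} of ROI is outside "
                f"±20% of target {config.tci_fraction:.3f}"
            )

    from shapely.ops import unary_union

    tci_union = unary_union(blobs) if blobs else Polygon()
    vessels: list[Polygon] = []
    r = config.vessel_radius_um
    attempts = 0
    while len(vessels) < config.n_vessels_per_roi:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not place {config.n_vessels_per_roi} vessels in {max_attempts} attempts"
            )
        cx = rng.uniform(r, w - r)
        cy = rng.uniform(r, h - r)
        c = circle(cx, cy, r)
        if not tci_union.is_empty and c.distance(tci_union) < 2.0:
            continue
        if any(c.distance(v) < 4.0 for v in vessels):
            continue
        vessels.append(c)

    return RoiGeometry(
        roi_id=roi_id,
        width_um=w,
        height_um=h,
        pixel_size_um=config.pixel_size_um,
        tci_polygons=blobs,
        vessel_polygons=vessels,
    )


def _roi_box(w: float, h: float):
    from shapely.geometry import box

    return box(0.0, 0.0, w, h)


def _random_blob(rng: np.random.Generator, area: float, w: float, h: float) -> Polygon:
    """Fourier-perturbed ellipse with the requested nominal area."""
    r0 = np.sqrt(area / np.pi)
    aspect = rng.uniform(0.6, 1.0)
    a, b = r0 / np.sqrt(aspect), r0 * np.sqrt(aspect)
    tilt = rng.uniform(0, np.pi)
    amps = rng.uniform(0.0, 0.15, size=4)  # harmonics k = 2..5
    phases = rng.uniform(0, 2 * np.pi, size=4)
    cx, cy = rng.uniform(0, w), rng.uniform(0, h)
    theta = np.linspace(0, 2 * np.pi, 64, endpoint=False)
    wobble = 1.0 + sum(
        amps[i] * np.cos((i + 2) * theta + phases[i]) for i in range(4)
    )
    x = a * wobble * np.cos(theta)
    y = b * wobble * np.sin(theta)
    xr = cx + x * np.cos(tilt) - y * np.sin(tilt)
    yr = cy + x * np.sin(tilt) + y * np.cos(tilt)
    poly = Polygon(np.column_stack([xr, yr]))
    if not poly.is_valid:
        poly = poly.buffer(0)
    # wobble perturbs the area; rescale so the blob has exactly the
    # requested area before ROI clipping
    f = float(np.sqrt(area / poly.area))
    from shapely.affinity import scale as _scale

    return _scale(poly, f, f, origin="centroid")


# ----------------------------------------------------------------------
# cell sampling
# ----------------------------------------------------------------------

def sample_cells(
    geometry: RoiGeometry,
    config: SimulationConfig,
    group: str,
    rng: np.random.Generator,
    context: RoiContext | None = None,
) -> tuple[pd.DataFrame, RoiGroundTruth]:
    """Draw one ROI's cells from the compartment-wise Poisson process.

    Within each of the four analysis compartments the process is
    homogeneous with intensity base × PV-enrichment × group-effect; counts
    are Poisson(intensity × realized area) and positions uniform over the
    compartment's pixels (jittered within the pixel, never inside a
    vessel). Marker booleans are assigned from the phenotype plus the
    group's co-expression probabilities, and always satisfy exactly one
    gating rule.
    """
    ctx = context or RoiContext.build(geometry, config.pv_threshold_um)
    coex = config.coexpression(group)
    s = geometry.pixel_size_um

    frames = []
    expected: dict[str, dict[str, float]] = {}
    for phenotype in config.phenotype_intensities:
        expected[phenotype] = {}
        for comp in ANALYSIS_COMPARTMENTS:
            lam = config.expected_intensity(phenotype, comp, group)
            expected[phenotype][comp] = lam
            area = ctx.areas.areas_mm2[comp]
            if lam <= 0 or area <= 0:
                continue
            n = int(rng.poisson(lam * area))
            if n == 0:
                continue
            rows_px, cols_px = ctx.class_pixels[comp]
            xy = _place_in_pixels(
                rng, rows_px, cols_px, n, s, geometry, comp, config.pv_threshold_um
            )
            frames.append(
                _make_cells(phenotype, xy, coex, rng, compartment_hint=comp)
            )

    if frames:
        cells = pd.concat(frames, ignore_index=True)
        # fixed ordering independent of dict iteration details
        cells = cells.sort_values(["y_um", "x_um"], kind="mergesort").reset_index(drop=True)
    else:
        cells = _empty_cells()
    cells["cell_id"] = [f"c{i:05d}" for i in range(len(cells))]
    cells["roi_id"] = geometry.roi_id
    truth = RoiGroundTruth(
        expected_density=expected,
        areas_mm2=dict(ctx.areas.areas_mm2),
        seeded_clusters=[],
    )
    return cells, truth


def _place_in_pixels(rng, rows_px, cols_px, n, s, geometry, comp, pv_threshold_um) -> np.ndarray:
    """Uniform positions over a compartment's pixel class.

    Pixels are labeled by their centers, so a jittered point in a boundary
    pixel can fall on the wrong side of a region or PV-band edge (or inside
    a vessel). Such points are resampled, which makes every placed cell's
    exact (vector) compartment equal its intended compartment — the ground
    truth stays leakage-free.
    """
    from .compartments import classify_cells as _classify

    out = np.empty((n, 2))
    need = np.arange(n)
    for _ in range(100):
        pick = rng.integers(0, len(rows_px), size=len(need))
        jit = rng.uniform(0, s, size=(len(need), 2))
        x = cols_px[pick] * s + jit[:, 0]
        y = rows_px[pick] * s + jit[:, 1]
        got = _classify(pd.DataFrame({"x_um": x, "y_um": y}), geometry, pv_threshold_um)
        ok = got.to_numpy() == comp
        out[need[ok], 0] = x[ok]
        out[need[ok], 1] = y[ok]
        need = need[~ok]
        if len(need) == 0:
            break
    else:  # pragma: no cover - would need a pathological geometry
        raise RuntimeError(f"could not place cells inside compartment {comp}")
    return out


_PHENOTYPE_BASE_MARKERS = {
    "TAM": ["CD163"],
    "CD4_T": ["CD3", "CD4"],
    "CD8_T": ["CD3", "CD8"],
    "TREG": ["CD3", "CD4", "FOXP3"],
    "CANCER": ["PanCK"],
    "ENDOTHELIAL": ["CD31"],
    "OTHER": [],
}


def _make_cells(phenotype, xy, coex, rng, compartment_hint=None) -> pd.DataFrame:
    n = len(xy)
    df = pd.DataFrame({"x_um": xy[:, 0], "y_um": xy[:, 1]})
    for m in MARKERS:
        df[m] = False
    for m in _PHENOTYPE_BASE_MARKERS[phenotype]:
        df[m] = True
    if phenotype == "TAM":
        df["PDL1"] = rng.random(n) < coex["tam_pdl1"]
        df["TIM3"] = rng.random(n) < coex["tam_tim3"]
    elif phenotype in ("CD4_T", "CD8_T"):
        pd1 = rng.random(n) < coex["t_pd1"]
        df["PD1"] = pd1
        df["LAG3"] = pd1 & (rng.random(n) < coex["t_lag3_given_pd1"])
    df["true_phenotype"] = phenotype
    df["seeded_cluster"] = -1
    df["true_compartment"] = compartment_hint
    return df


def _empty_cells() -> pd.DataFrame:
    df = pd.DataFrame({"x_um": pd.Series(dtype=float), "y_um": pd.Series(dtype=float)})
    for m in MARKERS:
        df[m] = pd.Series(dtype=bool)
    df["true_phenotype"] = pd.Series(dtype=object)
    df["seeded_cluster"] = pd.Series(dtype=int)
    df["true_compartment"] = pd.Series(dtype=object)
    return df


# ----------------------------------------------------------------------
# seeded clusters
# ----------------------------------------------------------------------

def seed_clusters(
    geometry: RoiGeometry,
    cells: pd.DataFrame,
    config: SimulationConfig,
    group: str,
    rng: np.random.Generator,
    context: RoiContext | None = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Append ``n_seeded_clusters_per_roi`` contact triples in PV stroma.

    Each triple is one TAM, one CD4+ or CD8+ T cell and one Treg placed on
    an equilateral triangle small enough that all pairwise distances are
    below the contact threshold, centered at a random perivascular stromal
    location; every member is itself perivascular stroma. Raises
    ``RuntimeError`` when no suitable PV stroma exists.
    """
    k = config.n_seeded_clusters_per_roi
    if k == 0:
        return cells, []
    ctx = context or RoiContext.build(geometry, config.pv_threshold_um)
    rows_px, cols_px = ctx.class_pixels["STROMA_PV"]
    if len(rows_px) == 0:
        raise RuntimeError("no perivascular stroma available to seed clusters in")
    s = geometry.pixel_size_um
    # triangle circumradius: pairwise distance = R*sqrt(3) stays below threshold
    R = config.contact_threshold_um / 3.0
    coex = config.coexpression(group)

    new_frames = []
    records = []
    next_id = len(cells)
    for ci in range(k):
        for _ in range(200):
            pick = int(rng.integers(0, len(rows_px)))
            cx = cols_px[pick] * s + rng.uniform(0, s)
            cy = rows_px[pick] * s + rng.uniform(0, s)
            rot = rng.uniform(0, 2 * np.pi)
            ang = rot + np.array([0.0, 2 * np.pi / 3, 4 * np.pi / 3])
            xs = cx + R * np.cos(ang)
            ys = cy + R * np.sin(ang)
            if np.any((xs < 0) | (xs > geometry.width_um) | (ys < 0) | (ys > geometry.height_um)):
                continue
            if _members_in_pv_stroma(xs, ys, geometry, config.pv_threshold_um):
                break
        else:
            raise RuntimeError("could not place a seeded cluster inside PV stroma")
        lineage = "CD4_T" if rng.random() < 0.5 else "CD8_T"
        xy = np.column_stack([xs, ys])
        member_frames = [
            _make_cells("TAM", xy[0:1], coex, rng, "STROMA_PV"),
            _make_cells(lineage, xy[1:2], coex, rng, "STROMA_PV"),
            _make_cells("TREG", xy[2:3], coex, rng, "STROMA_PV"),
        ]
        ids = []
        for f in member_frames:
            f["seeded_cluster"] = ci
            f["cell_id"] = [f"c{next_id:05d}"]
            f["roi_id"] = geometry.roi_id
            ids.append(f["cell_id"].iloc[0])
            next_id += 1
        new_frames.extend(member_frames)
        records.append(
            {"member_ids": ids, "tcell_lineage": lineage, "center": [float(cx), float(cy)]}
        )
    out = pd.concat([cells] + new_frames, ignore_index=True)
    return out, records


def _members_in_pv_stroma(xs, ys, geometry, pv_threshold_um) -> bool:
    from .compartments import distance_to_vessel

    if np.any(geometry.contains_vessel(xs, ys)) or np.any(geometry.contains_tci(xs, ys)):
        return False
    d = distance_to_vessel(xs, ys, geometry)
    # strict margin so raster/vector classification cannot disagree
    return bool(np.all(d > 0.5) and np.all(d <= pv_threshold_um - 0.5))


# ----------------------------------------------------------------------
# cohort generation
# ----------------------------------------------------------------------

@dataclass
class StudyBundle:
    """A complete in-memory synthetic study."""

    config: SimulationConfig
    manifest: pvio.StudyManifest
    cells: dict  # (tumor_id, roi_id) -> DataFrame
    geometries: dict  # (tumor_id, roi_id) -> RoiGeometry
    ground_truth: dict  # tumor_id -> roi_id -> RoiGroundTruth

    def write(self, out_dir) -> Path:
        out = Path(out_dir)
        (out / "cells").mkdir(parents=True, exist_ok=True)
        (out / "geometry").mkdir(exist_ok=True)
        (out / "masks").mkdir(exist_ok=True)
        pvio.write_manifest(self.manifest, out / "manifest.csv")
        for (t, r), df in sorted(self.cells.items()):
            pvio.write_cell_table(df, out / "cells" / f"{t}_{r}.csv")
        for (t, r), g in sorted(self.geometries.items()):
            pvio.write_geometry_polygons(g, out / "geometry" / f"{t}_{r}.json")
            pvio.write_geometry_mask(g, out / "masks" / f"{t}_{r}.tif")
        gt = {
            t: {
                r: {
                    "expected_density": tr.expected_density,
                    "areas_mm2": tr.areas_mm2,
                    "seeded_clusters": tr.seeded_clusters,
                }
                for r, tr in rois.items()
            }
            for t, rois in self.ground_truth.items()
        }
        with open(out / "ground_truth.json", "w") as fh:
            json.dump(gt, fh, sort_keys=True)
        with open(out / "config.json", "w") as fh:
            json.dump(self.config.to_dict(), fh, sort_keys=True, indent=1)
        return out


def generate_cohort(config: SimulationConfig, out_dir=None) -> StudyBundle:
    """Generate the full 2×2 cohort; optionally write the study directory.

    Seeding: one root ``SeedSequence`` per cohort, one spawned child per
    ROI, so output is reproducible and independent of generation order.
    """
    root = np.random.SeedSequence(config.seed)
    rows = []
    cells: dict = {}
    geoms: dict = {}
    truth: dict = {}
    roi_ids: dict = {}
    group_names = sorted(config.groups)
    n_rois = config.rois_per_tumor
    children = root.spawn(len(group_names) * config.n_tumors_per_group * n_rois)
    ci = 0
    for gi, gname in enumerate(group_names):
        treatment, outcome = config.groups[gname]
        for t in range(config.n_tumors_per_group):
            tumor_id = f"{gname}_T{t + 1:02d}"
            rows.append(
                {"tumor_id": tumor_id, "group": gname, "treatment": treatment, "outcome": outcome}
            )
            roi_ids[tumor_id] = []
            truth[tumor_id] = {}
            for r in range(n_rois):
                roi_id = f"R{r + 1:02d}"
                rng = np.random.default_rng(children[ci])
                ci += 1
                geom = generate_roi_geometry(config, rng, roi_id=roi_id)
                ctx = RoiContext.build(geom, config.pv_threshold_um)
                df, tr = sample_cells(geom, config, gname, rng, context=ctx)
                df, seeded = seed_clusters(geom, df, config, gname, rng, context=ctx)
                tr.seeded_clusters = seeded
                cells[(tumor_id, roi_id)] = df
                geoms[(tumor_id, roi_id)] = geom
                truth[tumor_id][roi_id] = tr
                roi_ids[tumor_id].append(roi_id)
    manifest = pvio.StudyManifest(pd.DataFrame(rows), roi_ids)
    bundle = StudyBundle(config, manifest, cells, geoms, truth)
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle


def load_study(study_dir) -> StudyBundle:
    """Load a study directory written by :meth:`StudyBundle.write`."""
    d = Path(study_dir)
    with open(d / "config.json") as fh:
        cfg = SimulationConfig(**json.load(fh))
    cells: dict = {}
    geoms: dict = {}
    roi_ids: dict = {}
    for gpath in sorted((d / "geometry").glob("*.json")):
        tumor_id, roi_id = gpath.stem.rsplit("_", 1)
        geom = pvio.read_geometry_polygons(gpath)
        geom.roi_id = roi_id
        geoms[(tumor_id, roi_id)] = geom
        df = pvio.read_cell_table(
            d / "cells" / f"{gpath.stem}.csv", extent_um=(geom.width_um, geom.height_um)
        )
        df["roi_id"] = roi_id
        cells[(tumor_id, roi_id)] = df
        roi_ids.setdefault(tumor_id, []).append(roi_id)
    manifest = pvio.read_manifest(d / "manifest.csv", roi_ids)
    truth: dict = {}
    gt_path = d / "ground_truth.json"
    if gt_path.exists():
        with open(gt_path) as fh:
            raw = json.load(fh)
        truth = {
            t: {
                r: RoiGroundTruth(
                    expected_density=v["expected_density"],
                    areas_mm2=v["areas_mm2"],
                    seeded_clusters=v["seeded_clusters"],
                )
                for r, v in rois.items()
            }
            for t, rois in raw.items()
        }
    return StudyBundle(cfg, manifest, cells, geoms, truth)
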