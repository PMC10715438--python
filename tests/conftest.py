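"""Shared fixtures and independent oracles.

The oracle functions here deliberately avoid the library code paths they
check: point-in-polygon is ray casting on raw vertex arrays (not shapely),
boundary distance is an explicit minimum over segments, triple detection
is a cubic scan over all index triples, and the Mann-Whitney p-value is
full enumeration over rank assignments.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings as hyp_settings

from pvniche import RoiGeometry, SimulationConfig, circle, generate_cohort
from pvniche.phenotyping import MARKERS

hyp_settings.register_profile("deterministic", derandomize=True, deadline=None)
hyp_settings.load_profile("deterministic")


# ----------------------------------------------------------------------
# cell-table construction helpers
# ----------------------------------------------------------------------

def make_cells(rows: list[dict]) -> pd.DataFrame:
    """Build a cell table from sparse dicts; unlisted markers are negative."""
    out = []
    for i, r in enumerate(rows):
        rec = {"cell_id": r.get("cell_id", f"c{i:04d}"),
               "x_um": r.get("x", 0.0), "y_um": r.get("y", 0.0)}
        for m in MARKERS:
            rec[m] = bool(r.get(m, False))
        out.append(rec)
    df = pd.DataFrame(out)
    if not len(df):
        df = pd.DataFrame(columns=["cell_id", "x_um", "y_um", *MARKERS])
    return df


PHENO_MARKERS = {
    "TAM": {"CD163": 1},
    "CD4_T": {"CD3": 1, "CD4": 1},
    "CD8_T": {"CD3": 1, "CD8": 1},
    "TREG": {"CD3": 1, "CD4": 1, "FOXP3": 1},
    "CANCER": {"PanCK": 1},
    "ENDOTHELIAL": {"CD31": 1},
    "OTHER": {},
}


def cells_at(points: list[tuple], labels: list[str]) -> pd.DataFrame:
    """Cell table with given positions and phenotype-consistent markers."""
    rows = []
    for (x, y), lab in zip(points, labels):
        r = {"x": x, "y": y}
        r.update(PHENO_MARKERS[lab])
        rows.append(r)
    return make_cells(rows)


# ----------------------------------------------------------------------
# geometry oracles (no shapely)
# ----------------------------------------------------------------------

def ring_of(poly) -> np.ndarray:
    return np.asarray(poly.exterior.coords)[:-1]


def pip_raycast(px: float, py: float, ring: np.ndarray) -> bool:
    """Point-in-polygon by ray casting over raw vertices."""
    inside = False
    n = len(ring)
    for i in range(n):
        x1, y1 = ring[i]
        x2, y2 = ring[(i + 1) % n]
        if (y1 > py) != (y2 > py):
            xint = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if xint > px:
                inside = not inside
    return inside


def segment_distance(px: float, py: float, ring: np.ndarray) -> float:
    """Min distance from a point to the polygon boundary, segment by segment."""
    a = ring
    b = np.roll(ring, -1, axis=0)
    ab = b - a
    ap = np.array([px, py]) - a
    denom = (ab ** 2).sum(axis=1)
    t = np.clip(np.where(denom > 0, (ap * ab).sum(axis=1) / np.where(denom > 0, denom, 1), 0), 0, 1)
    proj = a + t[:, None] * ab
    return float(np.sqrt(((np.array([px, py]) - proj) ** 2).sum(axis=1)).min())


def brute_classify(px: float, py: float, geometry: RoiGeometry, pv_um: float = 50.0) -> str:
    """Reference compartment classification from first principles."""
    vessel_rings = [ring_of(p) for p in geometry.vessel_polygons]
    tci_rings = [ring_of(p) for p in geometry.tci_polygons]
    if any(pip_raycast(px, py, r) for r in vessel_rings):
        return "VESSEL_EXCLUDED"
    region = "TCI" if any(pip_raycast(px, py, r) for r in tci_rings) else "STROMA"
    if vessel_rings:
        d = min(segment_distance(px, py, r) for r in vessel_rings)
    else:
        d = np.inf
    return f"{region}_{'PV' if d <= pv_um else 'NONPV'}"


# ----------------------------------------------------------------------
# cluster oracle
# ----------------------------------------------------------------------

def brute_triples(cells: pd.DataFrame, labels: np.ndarray, thr: float) -> set[tuple]:
    """All {TAM, T, TREG} triangles by scanning every index triple."""
    xy = cells[["x_um", "y_um"]].to_numpy(dtype=float)
    n = len(xy)
    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2))
    A = d <= thr
    np.fill_diagonal(A, False)
    found = set()
    if n <= 120:
        triples = combinations(range(n), 3)
        for i, j, k in triples:
            if A[i, j] and A[i, k] and A[j, k]:
                found |= _check_roles(cells, labels, (i, j, k))
    else:
        M = A[:, :, None] & A[:, None, :] & A[None, :, :]
        for i, j, k in np.argwhere(M):
            if i < j < k:
                found |= _check_roles(cells, labels, (int(i), int(j), int(k)))
    return found


def _check_roles(cells, labels, idx) -> set[tuple]:
    labs = [labels[i] for i in idx]
    tams = [i for i, l in zip(idx, labs) if l == "TAM"]
    ts = [i for i, l in zip(idx, labs) if l in ("CD4_T", "CD8_T")]
    tregs = [i for i, l in zip(idx, labs) if l == "TREG"]
    if len(tams) == 1 and len(ts) == 1 and len(tregs) == 1:
        cid = cells["cell_id"]
        return {(cid.iloc[tams[0]], cid.iloc[ts[0]], cid.iloc[tregs[0]])}
    return set()


# ----------------------------------------------------------------------
# statistics oracles
# ----------------------------------------------------------------------

def u_statistic(a, b) -> float:
    """Pairs (i, j) with a_i > b_j, plus half the ties."""
    a = np.asarray(a, float)[:, None]
    b = np.asarray(b, float)[None, :]
    return float((a > b).sum() + 0.5 * (a == b).sum())


def exact_mwu_p(a, b) -> float:
    """Two-sided exact p by enumerating every assignment of the pooled
    values to the two samples (tie-free data)."""
    a, b = list(a), list(b)
    pooled = a + b
    n1 = len(a)
    n = len(pooled)
    half = n1 * len(b) / 2.0
    obs = abs(u_statistic(a, b) - half)
    hits = 0
    total = 0
    for idx in combinations(range(n), n1):
        sel = set(idx)
        aa = [pooled[i] for i in idx]
        bb = [pooled[i] for i in range(n) if i not in sel]
        total += 1
        if abs(u_statistic(aa, bb) - half) >= obs - 1e-12:
            hits += 1
    return hits / total


def auc_concordance(scores, labels, positive) -> float:
    """AUC as the probability a random positive outscores a random negative."""
    s = np.asarray(scores, float)
    pos = s[np.asarray(labels) == positive]
    neg = s[np.asarray(labels) != positive]
    return u_statistic(pos, neg) / (len(pos) * len(neg))


# ----------------------------------------------------------------------
# fixtures
# ----------------------------------------------------------------------

@pytest.fixture(scope="session")
def annulus_geometry() -> RoiGeometry:
    """One circular vessel (r = 10 µm) in an otherwise all-stroma ROI."""
    return RoiGeometry(
        "annulus", 200.0, 200.0, 0.5,
        vessel_polygons=[circle(100.3, 99.7, 10.0, n=256)],
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A 2x2 cohort small enough for per-test reuse (seeded clusters on)."""
    cfg = SimulationConfig(
        seed=11,
        n_tumors_per_group=2,
        rois_per_tumor=3,
        roi_width_um=400.0,
        roi_height_um=400.0,
        pixel_size_um=1.0,
        n_vessels_per_roi=2,
        n_seeded_clusters_per_roi=2,
    )
    return generate_cohort(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
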