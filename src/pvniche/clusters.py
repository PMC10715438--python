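"""Detection and profiling of perivascular 3-cell immune clusters.

The structure of interest is a mutually contacting triple of one CD163+
TAM, one conventional T cell (CD4+ or CD8+), and one Treg. "Direct
contact" is operationalized as centroid distance ≤ a contact threshold
(default 12 µm ≈ two touching 6 µm-radius leukocytes); the threshold is a
parameter everywhere because segmentation masks are not available in the
cell-table data model.

Detection builds a contact graph with a KD-tree (identical result to the
all-pairs computation, just faster), then enumerates triangles whose
members carry exactly the three required phenotypes. By default every
unique id-triple is reported, so one cell may appear in several triples;
a greedy disjoint-matching count (most compact triple first) is available
since the counting convention for overlapping triples is a free choice.
A relaxed "path" mode accepts connected (2-edge) triples instead of
triangles.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .compartments import classify_cells
from .density import roi_density
from .geometry import RoiGeometry
from .phenotyping import T_CELL_LABELS

DEFAULT_CONTACT_THRESHOLD_UM = 12.0

CLUSTER_COLUMNS = [
    "roi_id",
    "tam_id",
    "tcell_id",
    "treg_id",
    "tcell_lineage",
    "tcell_activation",
    "tam_pdl1",
    "tam_tim3",
    "centroid_x_um",
    "centroid_y_um",
    "compartment",
    "max_pairwise_um",
]


def contact_graph(cells: pd.DataFrame, contact_threshold_um: float = DEFAULT_CONTACT_THRESHOLD_UM):
    """Undirected contact edges between cells with centroid distance ≤ threshold.

    Returns a set of index pairs (positional, i < j). Equivalent to the
    brute-force all-pairs check; the KD-tree only changes the complexity.
    """
    if contact_threshold_um < 0:
        raise ValueError("contact threshold must be non-negative")
    xy = cells[["x_um", "y_um"]].to_numpy(dtype=float)
    if len(xy) < 2:
        return set()
    tree = cKDTree(xy)
    return {(min(i, j), max(i, j)) for i, j in tree.query_pairs(r=contact_threshold_um)}


def find_triples(
    cells: pd.DataFrame,
    edges: set[tuple[int, int]],
    mode: str = "triangle",
) -> pd.DataFrame:
    """Enumerate {TAM, CD4/CD8 T cell, Treg} triples in the contact graph.

    ``cells`` must be phenotyped (``label``, ``activation``, ``tam_*``
    columns). ``mode="triangle"`` requires all three pairwise contacts;
    ``mode="path"`` accepts any connected triple (≥2 of the 3 edges). Each
    unique id-triple appears once.
    """
    if mode not in ("triangle", "path"):
        raise ValueError(f"unknown cluster mode {mode!r}")
    labels = cells["label"].to_numpy()
    xy = cells[["x_um", "y_um"]].to_numpy(dtype=float)
    adj: dict[int, set[int]] = {}
    for i, j in edges:
        adj.setdefault(i, set()).add(j)
        adj.setdefault(j, set()).add(i)

    tam_idx = [i for i in range(len(cells)) if labels[i] == "TAM"]
    records = []
    seen: set[tuple] = set()
    for t in tam_idx:
        nb_t = adj.get(t, set())
        # candidate partners: in triangle mode both must touch the TAM;
        # in path mode one of the three cells is the hub, so gather the
        # 2-neighborhood as candidates and check connectivity per triple.
        if mode == "triangle":
            tcells = [i for i in nb_t if labels[i] in T_CELL_LABELS]
            tregs = [i for i in nb_t if labels[i] == "TREG"]
        else:
            hood = set(nb_t)
            for v in list(nb_t):
                hood |= adj.get(v, set())
            hood.discard(t)
            tcells = [i for i in hood if labels[i] in T_CELL_LABELS]
            tregs = [i for i in hood if labels[i] == "TREG"]
        for c in tcells:
            for r in tregs:
                n_edges = sum(
                    1
                    for a, b in ((t, c), (t, r), (c, r))
                    if (min(a, b), max(a, b)) in edges
                )
                if mode == "triangle" and n_edges < 3:
                    continue
                if mode == "path" and n_edges < 2:
                    continue
                key = (t, c, r)
                if key in seen:
                    continue
                seen.add(key)
                trio = np.array([t, c, r])
                d = max(
                    float(np.hypot(*(xy[a] - xy[b])))
                    for a, b in combinations(trio, 2)
                )
                cx, cy = xy[trio].mean(axis=0)
                records.append(
                    {
                        "roi_id": cells["roi_id"].iloc[t] if "roi_id" in cells else None,
                        "tam_id": cells["cell_id"].iloc[t],
                        "tcell_id": cells["cell_id"].iloc[c],
                        "treg_id": cells["cell_id"].iloc[r],
                        "tcell_lineage": labels[c],
                        "tcell_activation": cells["activation"].iloc[c],
                        "tam_pdl1": bool(cells["tam_pdl1"].iloc[t]),
                        "tam_tim3": bool(cells["tam_tim3"].iloc[t]),
                        "centroid_x_um": float(cx),
                        "centroid_y_um": float(cy),
                        "compartment": None,
                        "max_pairwise_um": d,
                    }
                )
    return pd.DataFrame(records, columns=CLUSTER_COLUMNS)


def detect_clusters(
    cells: pd.DataFrame,
    geometry: RoiGeometry | None = None,
    contact_threshold_um: float = DEFAULT_CONTACT_THRESHOLD_UM,
    pv_threshold_um: float = 50.0,
    mode: str = "triangle",
    counting: str = "unique",
) -> pd.DataFrame:
    """End-to-end per-ROI detection: graph → triples → compartment labels.

    The cluster's compartment is that of the triple centroid (when
    ``geometry`` is given). ``counting="disjoint"`` keeps a greedy
    vertex-disjoint subset, most compact (smallest max pairwise distance)
    first.
    """
    edges = contact_graph(cells, contact_threshold_um)
    triples = find_triples(cells, edges, mode=mode)
    if geometry is not None and len(triples):
        pts = triples.rename(columns={"centroid_x_um": "x_um", "centroid_y_um": "y_um"})
        triples["compartment"] = classify_cells(pts, geometry, pv_threshold_um).to_numpy()
    if counting == "disjoint" and len(triples):
        triples = _greedy_disjoint(triples)
    elif counting not in ("unique", "disjoint"):
        raise ValueError(f"unknown counting rule {counting!r}")
    return triples.reset_index(drop=True)


def _greedy_disjoint(triples: pd.DataFrame) -> pd.DataFrame:
    used: set[str] = set()
    keep = []
    for idx in triples.sort_values("max_pairwise_um").index:
        ids = {triples.at[idx, "tam_id"], triples.at[idx, "tcell_id"], triples.at[idx, "treg_id"]}
        if ids & used:
            continue
        used |= ids
        keep.append(idx)
    return triples.loc[keep]


def cluster_density(
    clusters: pd.DataFrame,
    areas,
    tumor_id: str | None = None,
) -> pd.DataFrame:
    """Clusters per mm² per compartment, stratified by T-cell lineage.

    Reuses the cell-density row schema (``selector`` holds the lineage) so
    the ROI → tumor → group aggregation applies unchanged.
    """
    rows = []
    for lineage in T_CELL_LABELS:
        sub = clusters[clusters["tcell_lineage"] == lineage] if len(clusters) else clusters
        fake = pd.DataFrame(
            {
                "label": ["_cluster"] * len(sub),
                "compartment": sub["compartment"] if len(sub) else [],
            }
        )
        r = roi_density(fake, areas, "label==_cluster", tumor_id=tumor_id)
        r["selector"] = f"cluster_{lineage}"
        rows.append(r)
    return pd.concat(rows, ignore_index=True)


def cluster_composition(
    clusters: pd.DataFrame, strata: list[str] | None = None
) -> pd.DataFrame:
    """Per-stratum composition of detected clusters.

    Reports, within each stratum: the fraction of clusters whose T cell is
    naïve / active / exhausted (sums to 1), the fraction whose TAM is
    PD-L1+ vs PD-L1− (sums to 1), and the TIM-3+:TIM-3− TAM ratio within
    the PD-L1− clusters (NaN when there are no TIM-3− PD-L1− clusters).
    Strata with no clusters are absent from the output (NA by omission).
    """
    if not len(clusters):
        return pd.DataFrame()
    groups = clusters.groupby(strata, observed=True) if strata else [((), clusters)]
    rows = []
    for key, sub in groups:
        n = len(sub)
        row: dict = {}
        if strata:
            key = key if isinstance(key, tuple) else (key,)
            row.update(dict(zip(strata, key)))
        row["n_clusters"] = n
        for state in ("NAIVE", "ACTIVE", "EXHAUSTED"):
            row[f"frac_{state.lower()}"] = float((sub["tcell_activation"] == state).sum()) / n
        row["frac_tam_pdl1_pos"] = float(sub["tam_pdl1"].sum()) / n
        row["frac_tam_pdl1_neg"] = 1.0 - row["frac_tam_pdl1_pos"]
        neg = sub[~sub["tam_pdl1"].astype(bool)]
        tim3_pos = int(neg["tam_tim3"].sum())
        tim3_neg = len(neg) - tim3_pos
        row["tim3_ratio_in_pdl1_neg"] = tim3_pos / tim3_neg if tim3_neg else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
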