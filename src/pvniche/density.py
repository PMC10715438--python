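"""Cell densities per compartment and the two-level cohort aggregation.

Density is count / area (cells per mm²) within each ROI × compartment for a
phenotype selector. Aggregation follows the study design: each tumor is
summarized by the unweighted mean of its ROI densities (so tumors
contribute equally regardless of ROI count), and each group by the mean ±
SEM of its tumor values, with n = number of tumors.

Zero-area compartments yield NA (the compartment is absent from the ROI,
which is not the same as containing no cells); NA ROIs are dropped from
the tumor mean rather than zero-filled. A pooled mode (total count /
total area per tumor) is offered for sensitivity analysis.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .compartments import ANALYSIS_COMPARTMENTS, CompartmentAreas
from .io import StudyManifest
from .phenotyping import parse_selector

logger = logging.getLogger(__name__)


def roi_density(
    labeled: pd.DataFrame,
    areas: CompartmentAreas,
    selector: str,
    tumor_id: str | None = None,
    compartments: list[str] | None = None,
) -> pd.DataFrame:
    """Density rows for one ROI: one row per analysis compartment.

    ``labeled`` must carry ``label``-family columns (from phenotyping) and
    a ``compartment`` column (from compartment classification). Cells in
    vessel interiors are never counted.
    """
    sel = parse_selector(selector)
    match = sel(labeled) if len(labeled) else pd.Series(dtype=bool)
    comps = compartments or ANALYSIS_COMPARTMENTS
    rows = []
    for comp in comps:
        area = areas.areas_mm2.get(comp, 0.0)
        if len(labeled):
            count = int((match & (labeled["compartment"] == comp)).sum())
        else:
            count = 0
        if area > 0:
            dens = count / area
        else:
            dens = np.nan
            logger.warning("ROI %s: compartment %s has zero area; density is NA", areas.roi_id, comp)
        rows.append(
            {
                "tumor_id": tumor_id,
                "roi_id": areas.roi_id,
                "compartment": comp,
                "selector": selector,
                "count": count,
                "area_mm2": area,
                "density_per_mm2": dens,
            }
        )
    return pd.DataFrame(rows)


def aggregate(
    roi_rows: pd.DataFrame,
    manifest: StudyManifest,
    mode: str = "roi_mean",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ROI rows → (tumor-level, group-level) tables.

    ``mode="roi_mean"`` (default) averages ROI densities per tumor;
    ``mode="pooled"`` divides pooled counts by pooled area per tumor.
    Group level reports mean, SEM (sd/√n, ddof=1; 0 for n=1) and n over
    tumor values.
    """
    if mode not in ("roi_mean", "pooled"):
        raise ValueError(f"unknown aggregation mode {mode!r}")
    df = roi_rows.merge(manifest.table, on="tumor_id", how="left")
    if df["group"].isna().any():
        orphans = df.loc[df["group"].isna(), "tumor_id"].unique()
        raise ValueError(f"ROI rows reference tumors missing from manifest: {list(orphans)}")

    keys = ["tumor_id", "group", "treatment", "outcome", "compartment", "selector"]
    if mode == "roi_mean":
        tumor = (
            df.groupby(keys, observed=True)["density_per_mm2"]
            .agg(value="mean", n_roi="count")
            .reset_index()
        )
    else:
        g = df.groupby(keys, observed=True)[["count", "area_mm2"]].sum().reset_index()
        g["value"] = np.where(g["area_mm2"] > 0, g["count"] / g["area_mm2"], np.nan)
        g["n_roi"] = df.groupby(keys, observed=True).size().to_numpy()
        tumor = g[keys + ["value", "n_roi"]]
    empty = tumor["value"].isna()
    if empty.any():
        for t in tumor.loc[empty, "tumor_id"].unique():
            logger.warning("tumor %s has zero non-NA ROIs for some stratum; value is NA", t)

    gkeys = ["group", "treatment", "outcome", "compartment", "selector"]
    group = (
        tumor.dropna(subset=["value"])
        .groupby(gkeys, observed=True)["value"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0, n="count")
        .reset_index()
    )
    group["sem"] = group["sd"] / np.sqrt(group["n"])
    group = group.drop(columns="sd")
    return tumor, group


def density_table(
    roi_rows: pd.DataFrame, manifest: StudyManifest, mode: str = "roi_mean"
) -> dict[str, pd.DataFrame]:
    """Convenience bundle of all three levels keyed ``roi``/``tumor``/``group``."""
    tumor, group = aggregate(roi_rows, manifest, mode=mode)
    return {"roi": roi_rows, "tumor": tumor, "group": group}
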