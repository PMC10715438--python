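"""End-to-end orchestration: study directory → tables, figures, report.

Stages run in a fixed order — load, phenotype, compartments, density,
clusters, stats, report — each consuming and producing only documented
tables, so any stage can be rerun in place. Given the same inputs and
seed, the result tables are byte-identical between runs; the provenance
record (config hash, seed, package versions) makes runs auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clusters import cluster_composition, cluster_density, detect_clusters
from .compartments import classify_cells
from .density import aggregate, roi_density
from .io import StudyManifest, write_results
from .phenotyping import GatingConfig, phenotype_table
from .simulate import RoiContext, StudyBundle, load_study
from .stats import roc, run_comparisons

logger = logging.getLogger(__name__)

#: Density read-outs computed by default: the four phenotypes, the
#: PD-L1/TIM-3 TAM subsets, and T-cell activation subsets.
DEFAULT_SELECTORS = [
    "TAM",
    "CD4_T",
    "CD8_T",
    "TREG",
    "TAM & tam_pdl1",
    "TAM & !tam_pdl1",
    "TAM & tam_tim3",
    "TAM & !tam_tim3",
    "TAM & tam_tim3 & !tam_pdl1",
    "CD4_T & activation==NAIVE",
    "CD4_T & activation==ACTIVE",
    "CD4_T & activation==EXHAUSTED",
    "CD8_T & activation==NAIVE",
    "CD8_T & activation==ACTIVE",
    "CD8_T & activation==EXHAUSTED",
]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnosis."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Everything one pipeline run depends on."""

    study_dir: str
    out_dir: str
    pv_threshold_um: float = 50.0
    contact_threshold_um: float = 12.0
    cluster_mode: str = "triangle"
    cluster_counting: str = "unique"
    aggregation_mode: str = "roi_mean"
    gating_config: str | None = None
    contrast_plan: str | None = None
    selectors: list[str] = field(default_factory=lambda: list(DEFAULT_SELECTORS))
    roc_selectors: list[str] = field(
        default_factory=lambda: ["TAM", "TAM & tam_tim3", "TAM & !tam_tim3"]
    )
    seed: int = 0
    make_figures: bool = True
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.pv_threshold_um <= 0 or self.contact_threshold_um <= 0:
            raise ValueError("thresholds must be positive")
        if not Path(self.study_dir).is_dir():
            raise FileNotFoundError(f"study directory not found: {self.study_dir}")
        for p in (self.gating_config, self.contrast_plan):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"referenced config file not found: {p}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        return d


def run_pipeline(config: RunConfig, bundle: StudyBundle | None = None) -> dict:
    """Run every stage; returns ``{"tables": ..., "files": ..., "report": ...}``.

    ``bundle`` may be passed to skip the load stage (e.g. a cohort still in
    memory); otherwise the study directory is loaded from disk.
    """
    config.validate()
    out_dir = Path(config.out_dir)

    try:
        if bundle is None:
            bundle = load_study(config.study_dir)
    except Exception as e:  # noqa: BLE001
        raise StageError("load", e) from e

    gating = (
        GatingConfig.from_file(config.gating_config)
        if config.gating_config
        else GatingConfig.default()
    )

    try:
        labeled, qc_totals, cluster_frames, roi_rows, cluster_rows = _per_roi_stages(
            bundle, config, gating
        )
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError("per-roi", e) from e

    manifest = bundle.manifest
    tables: dict[str, pd.DataFrame] = {}
    try:
        tumor, group = aggregate(roi_rows, manifest, mode=config.aggregation_mode)
        tables["density_roi"] = roi_rows
        tables["density_tumor"] = tumor
        tables["density_group"] = group
    except Exception as e:  # noqa: BLE001
        raise StageError("density", e) from e

    try:
        clusters_all = (
            pd.concat(cluster_frames, ignore_index=True)
            if cluster_frames
            else pd.DataFrame()
        )
        tables["clusters"] = clusters_all
        if len(cluster_rows):
            ctumor, cgroup = aggregate(cluster_rows, manifest, mode=config.aggregation_mode)
            tables["cluster_density_tumor"] = ctumor
            tables["cluster_density_group"] = cgroup
        if len(clusters_all):
            merged = clusters_all.merge(
                manifest.table[["tumor_id", "treatment", "outcome"]], on="tumor_id"
            )
            pv_stroma = merged[merged["compartment"] == "STROMA_PV"]
            comp = cluster_composition(pv_stroma, ["treatment", "tcell_lineage"])
            tables["cluster_composition"] = comp
    except Exception as e:  # noqa: BLE001
        raise StageError("clusters", e) from e

    try:
        if config.contrast_plan:
            with open(config.contrast_plan) as fh:
                plan = yaml.safe_load(fh)
            tables["comparisons"] = run_comparisons(tumor, plan)
        tables["roc"] = _roc_table(tumor, config.roc_selectors)
    except Exception as e:  # noqa: BLE001
        raise StageError("stats", e) from e

    tables["qc"] = pd.DataFrame([qc_totals])

    meta = {
        "pvniche_version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "gating": gating.to_dict(),
        "n_tumors": int(len(manifest.table)),
        "n_rois": int(sum(len(v) for v in manifest.roi_ids.values())),
        "n_cells": int(len(labeled)),
    }
    files = write_results(tables, out_dir / "tables", metadata=meta)

    results_json = _results_json(tables)
    with open(out_dir / "results.json", "w") as fh:
        json.dump(results_json, fh, indent=1, sort_keys=True)

    if config.make_figures:
        try:
            _figures(tables["density_group"], out_dir / "figures")
        except Exception as e:  # noqa: BLE001
            raise StageError("figures", e) from e

    rep = report(tables)
    (out_dir / "report.md").write_text(rep)
    return {"tables": tables, "files": files, "report": rep, "metadata": meta}


def _per_roi_stages(bundle: StudyBundle, config: RunConfig, gating: GatingConfig):
    """Phenotype + compartments + per-ROI densities + clusters, one pass."""
    all_labeled = []
    qc_totals: dict[str, int] = {}
    cluster_frames = []
    roi_rows = []
    cluster_rows = []
    for (tumor_id, roi_id), cells in sorted(bundle.cells.items()):
        geom = bundle.geometries[(tumor_id, roi_id)]
        labeled, qc = phenotype_table(cells, gating)
        for k, v in qc.items():
            qc_totals[k] = qc_totals.get(k, 0) + v
        labeled["compartment"] = classify_cells(labeled, geom, config.pv_threshold_um)
        ctx = RoiContext.build(geom, config.pv_threshold_um)
        for sel in config.selectors:
            roi_rows.append(roi_density(labeled, ctx.areas, sel, tumor_id=tumor_id))
        cl = detect_clusters(
            labeled,
            geom,
            contact_threshold_um=config.contact_threshold_um,
            pv_threshold_um=config.pv_threshold_um,
            mode=config.cluster_mode,
            counting=config.cluster_counting,
        )
        cl.insert(0, "tumor_id", tumor_id)
        cluster_frames.append(cl)
        cluster_rows.append(cluster_density(cl, ctx.areas, tumor_id=tumor_id))
        labeled = labeled.assign(tumor_id=tumor_id)
        all_labeled.append(labeled)
    labeled_all = pd.concat(all_labeled, ignore_index=True) if all_labeled else pd.DataFrame()
    roi_df = pd.concat(roi_rows, ignore_index=True) if roi_rows else pd.DataFrame()
    cluster_df = pd.concat(cluster_rows, ignore_index=True) if cluster_rows else pd.DataFrame()
    return labeled_all, qc_totals, cluster_frames, roi_df, cluster_df


def _roc_table(tumor: pd.DataFrame, selectors: list[str]) -> pd.DataFrame:
    """ROC of NAC-treated tumor densities (whole stroma) against outcome."""
    rows = []
    nac = tumor[tumor["treatment"] == "NAC"]
    for sel in selectors:
        sub = nac[(nac["selector"] == sel) & nac["compartment"].str.startswith("STROMA")]
        per_tumor = sub.groupby(["tumor_id", "outcome"], observed=True)["value"].mean().reset_index()
        if per_tumor["outcome"].nunique() < 2 or len(per_tumor) < 4:
            continue
        # higher density hypothesized to mark the disease-free group
        r = roc(per_tumor["value"], per_tumor["outcome"], positive_label="DF")
        rows.append(
            {
                "selector": sel,
                "compartment": "STROMA",
                "positive_label": "DF",
                "auc": r.auc,
                "p_value": r.p_value,
                "n_pos": r.n_pos,
                "n_neg": r.n_neg,
                "quality": r.quality,
            }
        )
    return pd.DataFrame(rows)


def _results_json(tables: dict[str, pd.DataFrame]) -> dict:
    out: dict = {}
    grp = tables["density_group"]
    out["group_densities"] = {
        f"{r.selector}|{r.compartment}|{r.group}": {
            "mean": None if pd.isna(r.mean) else round(float(r.mean), 6),
            "sem": None if pd.isna(r.sem) else round(float(r.sem), 6),
            "n": int(r.n),
        }
        for r in grp.itertuples()
    }
    out["n_clusters_detected"] = int(len(tables.get("clusters", [])))
    if "comparisons" in tables and len(tables["comparisons"]):
        out["significant_contrasts"] = int(tables["comparisons"]["significant"].sum())
    if "roc" in tables and len(tables["roc"]):
        out["roc"] = {
            r.selector: {"auc": round(float(r.auc), 4), "p": round(float(r.p_value), 4)}
            for r in tables["roc"].itertuples()
        }
    return out


def _figures(group: pd.DataFrame, fig_dir: Path) -> None:
    """Bar charts of mean ± SEM per compartment × group, one per selector."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig_dir.mkdir(parents=True, exist_ok=True)
    comps = ["STROMA_PV", "STROMA_NONPV", "TCI_PV", "TCI_NONPV"]
    for sel, sub in group.groupby("selector"):
        groups = sorted(sub["group"].unique())
        width = 0.8 / max(len(groups), 1)
        fig, ax = plt.subplots(figsize=(7, 4))
        x = np.arange(len(comps))
        for i, g in enumerate(groups):
            gsub = sub[sub["group"] == g].set_index("compartment")
            means = [gsub["mean"].get(c, np.nan) for c in comps]
            sems = [gsub["sem"].get(c, 0.0) for c in comps]
            ax.bar(x + i * width, means, width, yerr=sems, capsize=2, label=g)
        ax.set_xticks(x + width * (len(groups) - 1) / 2)
        ax.set_xticklabels(comps, fontsize=8)
        ax.set_ylabel("cells / mm²")
        ax.set_title(sel)
        ax.legend(fontsize=7)
        fig.tight_layout()
        safe = sel.replace(" ", "").replace("&", "_and_").replace("==", "-").replace("!", "not_")
        fig.savefig(fig_dir / f"density_{safe}.png", dpi=120)
        plt.close(fig)


def report(tables: dict[str, pd.DataFrame]) -> str:
    """Human-readable markdown summary of a run."""
    lines = ["# Perivascular immune landscape — run summary", ""]
    grp = tables["density_group"]
    lines.append("## Group densities (mean ± SEM, cells/mm²)")
    for sel, sub in grp.groupby("selector"):
        lines.append(f"\n### {sel}\n")
        lines.append("| group | compartment | mean | SEM | n |")
        lines.append("|---|---|---|---|---|")
        for r in sub.itertuples():
            lines.append(
                f"| {r.group} | {r.compartment} | {r.mean:.1f} | {r.sem:.1f} | {r.n} |"
            )
    if "comparisons" in tables and len(tables["comparisons"]):
        cmp = tables["comparisons"]
        sig = cmp[cmp["significant"]]
        lines.append("\n## Contrasts (Mann-Whitney, Bonferroni-adjusted)")
        lines.append(f"\n{len(sig)} of {len(cmp)} contrasts significant at adjusted p ≤ 0.05.")
        for r in sig.itertuples():
            lines.append(
                f"- {r.block}: {r.selector} [{r.compartment}] {r.group_a} vs {r.group_b}: "
                f"p_adj = {r.p_adjusted:.4f}"
            )
    if "roc" in tables and len(tables["roc"]):
        lines.append("\n## ROC (stromal density vs outcome, NAC arm)")
        for r in tables["roc"].itertuples():
            lines.append(
                f"- {r.selector}: AUC = {r.auc:.3f} ({r.quality}), p = {r.p_value:.3f}"
            )
    cl = tables.get("clusters")
    lines.append("\n## 3-cell clusters")
    if cl is None or not len(cl):
        lines.append("\nno clusters detected")
    else:
        lines.append(f"\n{len(cl)} clusters detected.")
        comp = tables.get("cluster_composition")
        if comp is not None and len(comp):
            lines.append("\nComposition of PV stromal clusters (fractions):\n")
            lines.append(comp.round(3).to_markdown(index=False))
    if "qc" in tables:
        lines.append("\n## Gating QC tallies\n")
        lines.append(tables["qc"].to_markdown(index=False))
    return "\n".join(lines) + "\n"
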