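"""Group comparisons and ROC on a cohort with a built-in treatment effect.

Generates a cohort where the disease-free NAC group has twice the TAM
density of the metastatic NAC group, runs the density pipeline, then the
declared Mann-Whitney/Bonferroni contrast plan and a ROC of stromal TAM
density against outcome.
"""

import pandas as pd

from pvniche import (
    SimulationConfig,
    aggregate,
    classify_cells,
    generate_cohort,
    phenotype_table,
    roc,
    roi_density,
    run_comparisons,
)
from pvniche.simulate import RoiContext

config = SimulationConfig(
    seed=31, n_tumors_per_group=6, rois_per_tumor=3,
    roi_width_um=400.0, roi_height_um=400.0, pixel_size_um=1.0,
    n_vessels_per_roi=2,
    group_effects={"NAC_DF": {"TAM": {"*": 2.0}}},  # the known truth
)
cohort = generate_cohort(config)

rows = []
for (tumor_id, roi_id), cells in cohort.cells.items():
    geom = cohort.geometries[(tumor_id, roi_id)]
    labeled, _ = phenotype_table(cells)
    labeled["compartment"] = classify_cells(labeled, geom, 50.0)
    ctx = RoiContext.build(geom, 50.0)
    rows.append(roi_density(labeled, ctx.areas, "TAM", tumor_id=tumor_id))
tumor_table, group_table = aggregate(pd.concat(rows, ignore_index=True),
                                     cohort.manifest)

print("group means ± SEM, stromal non-PV TAM density (cells/mm²):")
sub = group_table[group_table["compartment"] == "STROMA_NONPV"]
for r in sub.itertuples():
    print(f"  {r.group:15s} {r.mean:7.1f} ± {r.sem:5.1f}  (n={r.n})")

plan = [{
    "name": "NAC_outcome",
    "contrasts": [
        {"selector": "TAM", "compartment": c, "group_by": "outcome",
         "arms": ["DF", "Mets"], "where": {"treatment": "NAC"}}
        for c in ("STROMA_PV", "STROMA_NONPV")
    ],
}]
comparisons = run_comparisons(tumor_table, plan)
print("\ncontrasts (two-sided Mann-Whitney, Bonferroni m=2):")
print(comparisons[["compartment", "U", "p_raw", "p_adjusted", "significant"]]
      .round(4).to_string(index=False))

nac = tumor_table[(tumor_table["treatment"] == "NAC")
                  & (tumor_table["compartment"] == "STROMA_NONPV")]
r = roc(nac["value"], nac["outcome"], positive_label="DF")
print(f"\nROC of stromal TAM density vs outcome: AUC = {r.auc:.3f} "
      f"({r.quality}), p = {r.p_value:.4f}")
# With a true 2x effect the contrasts should be significant after
# Bonferroni and the AUC near 1; rerun with group_effects={} to see the
# null behaviour (no significant contrasts, AUC near 0.5).
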