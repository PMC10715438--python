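# SimulationConfig for `pvniche simulate --config`. A cohort with
# treatment- and outcome-linked effects: NAC raises perivascular TAM/Treg
# intensity, and the disease-free NAC group carries extra stromal
# TIM-3+ TAM signal via co-expression.
seed: 7
n_tumors_per_group: 4
rois_per_tumor: 5
roi_width_um: 400.0
roi_height_um: 400.0
pixel_size_um: 1.0
tci_fraction: 0.35
n_vessels_per_roi: 3
vessel_radius_um: 8.0
n_seeded_clusters_per_roi: 2
group_effects:
  NAC_DF:
    TAM: {"*": 1.6, STROMA_PV: 2.2}
    TREG: {STROMA_PV: 2.0}
  NAC_Mets:
    TAM: {"*": 1.1}
    TREG: {STROMA_PV: 2.0}
marker_coexpression:
  NAC_DF: {tam_tim3: 0.45}
  NAC_Mets: {tam_tim3: 0.30}
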