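# Contrast plan for `pvniche run --plan` / `pvniche stats --plan`.
# Each named block is one Bonferroni family (family size = number of
# contrasts in the block). Two contrast forms:
#   paired compartments within the same tumors (compartment_a/_b), or
#   two arms of a grouping variable within one compartment.
- name: pv_vs_nonpv_stroma
  contrasts:
    - selector: TAM
      compartment_a: STROMA_PV
      compartment_b: STROMA_NONPV
    - selector: TREG
      compartment_a: STROMA_PV
      compartment_b: STROMA_NONPV
    - selector: CD4_T
      compartment_a: STROMA_PV
      compartment_b: STROMA_NONPV
    - selector: CD8_T
      compartment_a: STROMA_PV
      compartment_b: STROMA_NONPV

- name: nac_outcome_tam_subsets
  contrasts:
    - selector: TAM
      compartment: STROMA_NONPV
      group_by: outcome
      arms: [DF, Mets]
      where: {treatment: NAC}
    - selector: "TAM & tam_tim3"
      compartment: STROMA_NONPV
      group_by: outcome
      arms: [DF, Mets]
      where: {treatment: NAC}
    - selector: "TAM & !tam_tim3"
      compartment: STROMA_NONPV
      group_by: outcome
      arms: [DF, Mets]
      where: {treatment: NAC}
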