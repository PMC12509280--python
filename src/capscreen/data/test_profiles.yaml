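# Screening modality characteristics (probabilities as fractions; costs EUR 2018).
# Sensitivities are per lesion class; small-adenoma sensitivity of the stool
# and capsule tests is zero by assumption.  Reach anchors are visualisation
# probabilities at anchored colorectal locations; unanchored locations are
# interpolated piecewise-linearly along the instrument's travel order.
version: 1
profiles:
  FIT15:
    sensitivity:
      small_adenoma: 0.0
      medium_adenoma: 0.481
      large_adenoma: 0.550
      crc_early_preclinical: 0.343
      crc_late_preclinical: 0.708
    specificity: 0.963
    reach_anchors: {}
    perforation_risk: 0.0
    unit_cost: 22.0
  FIT47:
    sensitivity:
      small_adenoma: 0.0
      medium_adenoma: 0.193
      large_adenoma: 0.368
      crc_early_preclinical: 0.288
      crc_late_preclinical: 0.652
    specificity: 0.989
    reach_anchors: {}
    perforation_risk: 0.0
    unit_cost: 22.0
  CCE:
    sensitivity:
      small_adenoma: 0.0
      medium_adenoma: 0.865
      large_adenoma: 0.875
      crc_early_preclinical: 0.875
      crc_late_preclinical: 0.875
    specificity: 0.830
    reach_anchors:
      cecum: 0.993
      ascending: 0.978
      transverse: 0.954
      descending: 0.942
      rectum: 0.558
    perforation_risk: 0.0
    unit_cost: 600.0
  colonoscopy:
    sensitivity:
      small_adenoma: 0.750
      medium_adenoma: 0.850
      large_adenoma: 0.950
      crc_early_preclinical: 0.950
      crc_late_preclinical: 0.950
    specificity: 1.0
    reach_anchors:
      rectum: 1.0
      cecum: 0.960
    perforation_risk: 0.00001
    unit_cost: 686.0
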