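# Default run configuration: thresholds, cohort generator and analysis stage.
# The phenotype mixture describes the post-initial-cut presentation of the
# knee; weights and channel ranges (uniform low/high) are model defaults
# tuned so the closed-loop simulation reproduces ~3 corrections per case.
thresholds: {}
calibration: null  # null -> packaged default calibration
cohort:
  n: 479
  n_missing: 21
  max_corrections: 7
  batch_prob: 0.0
  demographics:
    age_mean: 68.6
    age_sd: 9.0
    age_min: 39.0
    age_max: 96.0
    male_fraction: 0.49
  phenotypes:
    balanced:
      weight: 0.04
      m10: [18.0, 32.0]
      l10: [18.0, 32.0]
      m90: [18.0, 32.0]
      l90: [18.0, 32.0]
      coronal: [-2.5, 0.5]
      ext_deficit: [-1.5, 0.0]
    medial_tight_varus:
      weight: 0.32
      m10: [44.0, 50.0]
      l10: [24.0, 30.0]
      m90: [44.0, 50.0]
      l90: [24.0, 30.0]
      coronal: [-6.0, -3.5]
      ext_deficit: [-0.5, 0.5]
    medial_tight_neutral:
      weight: 0.06
      m10: [41.0, 44.0]
      l10: [25.0, 30.0]
      m90: [41.0, 44.0]
      l90: [25.0, 30.0]
      coronal: [-1.0, 2.0]
      ext_deficit: [-0.5, 0.5]
    lateral_tight_valgus:
      weight: 0.18
      m10: [22.0, 32.0]
      l10: [42.0, 54.0]
      m90: [22.0, 32.0]
      l90: [42.0, 54.0]
      coronal: [1.5, 5.0]
      ext_deficit: [-0.5, 0.5]
    flexion_contracture:
      weight: 0.22
      m10: [28.0, 34.0]
      l10: [20.0, 26.0]
      m90: [22.0, 32.0]
      l90: [22.0, 30.0]
      coronal: [-2.5, 1.0]
      ext_deficit: [6.0, 12.0]
    hyperextension_loose:
      weight: 0.18
      m10: [8.0, 14.0]
      l10: [10.0, 18.0]
      m90: [16.0, 30.0]
      l90: [16.0, 30.0]
      coronal: [-2.5, 1.0]
      ext_deficit: [-8.0, -2.5]
analysis:
  criterion: reml
  alpha: 0.05
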