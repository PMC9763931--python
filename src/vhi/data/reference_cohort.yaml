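# Published group-level summaries for lean (LZR) and obese (OZR) Zucker rat
# cohorts, with exercise- and captopril-treated obese arms: per-component
# group means and SEs by vascular bed and age, group sizes, and baseline
# plasma biomarkers.  Component units: dilations μm, microvessel density
# #/mm², stiffness beta dimensionless.  Entries are [mean, se] keyed by age
# in weeks.  This file is both the default parameterization of the
# synthetic cohort generator and the input to group-mean-mode scoring.
version: 1

# n per (bed, group, age): primary n is the full 5-component cohort size;
# where no 5-component cohort exists the 3-component size is given.
n:
  peripheral:
    LZR: {7: 25, 10: 23, 13: 24, 17: 22, 20: 6}
    OZR: {7: 16, 10: 16, 13: 16, 17: 28, 20: 6}
    OZR_EXERCISE: {7: 7, 10: 7, 13: 7, 17: 7}
    OZR_CAPTOPRIL: {7: 4, 10: 4, 13: 4, 17: 4}
  cerebral:
    LZR: {7: 10, 10: 10, 13: 10, 17: 10, 20: 11}
    OZR: {7: 8, 10: 8, 13: 8, 17: 8, 20: 8}
    OZR_CAPTOPRIL: {7: 6, 13: 6, 17: 6}

components:
  peripheral:
    LZR:
      ach_dilation: {7: [119.2, 1.1], 10: [125.0, 1.1], 13: [129.3, 1.2], 17: [136.5, 2.0], 20: [139.9, 1.6]}
      snp_dilation: {7: [128.8, 0.9], 10: [130.6, 1.0], 13: [132.9, 1.2], 17: [140.3, 2.2], 20: [140.7, 1.4]}
      mvd: {7: [809.9, 13.9], 10: [810.4, 13.1], 13: [811.8, 11.9], 17: [863.1, 4.6], 20: [823.0, 9.1]}
      hypoxic_dilation: {7: [120.8, 1.1], 10: [125.0, 1.0], 13: [128.9, 1.2], 17: [135.3, 1.8], 20: [135.8, 2.0]}
      stiffness_beta: {7: [2.6, 0.1], 10: [2.6, 0.1], 13: [2.8, 0.1], 17: [3.1, 0.1], 20: [3.2, 0.1]}
    OZR:
      ach_dilation: {7: [115.3, 1.9], 10: [118.4, 3.2], 13: [120.5, 2.8], 17: [122.6, 2.9], 20: [119.3, 3.3]}
      snp_dilation: {7: [127.7, 2.2], 10: [131.5, 3.3], 13: [134.1, 2.6], 17: [139.8, 3.7], 20: [135.6, 4.8]}
      mvd: {7: [805.4, 25.2], 10: [782.4, 26.1], 13: [706.9, 16.9], 17: [656.3, 20.5], 20: [635.9, 11.6]}
      hypoxic_dilation: {7: [117.0, 2.2], 10: [118.1, 3.1], 13: [119.6, 3.1], 17: [121.6, 4.1], 20: [118.4, 2.1]}
      stiffness_beta: {7: [2.4, 0.3], 10: [3.4, 0.5], 13: [4.1, 0.6], 17: [6.2, 0.4], 20: [5.7, 0.7]}
    OZR_EXERCISE:
      ach_dilation: {7: [117.6, 2.6], 10: [127.3, 2.2], 13: [131.7, 2.3], 17: [129.6, 3.4]}
      snp_dilation: {7: [127.0, 2.7], 10: [132.0, 1.8], 13: [135.7, 2.3], 17: [134.4, 3.8]}
      mvd: {7: [881.4, 10.8], 10: [874.6, 14.6], 13: [832.3, 21.5], 17: [869.4, 17.3]}
      hypoxic_dilation: {7: [121.1, 2.3], 10: [126.6, 2.3], 13: [129.6, 2.5], 17: [125.6, 4.8]}
      stiffness_beta: {7: [3.7, 0.3], 10: [3.5, 0.3], 13: [3.8, 0.4], 17: [4.0, 0.3]}
    OZR_CAPTOPRIL:
      ach_dilation: {7: [118.3, 2.7], 10: [117.0, 2.1], 13: [124.8, 3.9], 17: [124.3, 1.9]}
      snp_dilation: {7: [130.8, 3.2], 10: [134.3, 1.5], 13: [138.5, 3.4], 17: [134.0, 2.6]}
      mvd: {7: [833.3, 12.3], 10: [813.3, 5.5], 13: [764.0, 8.0], 17: [730.5, 16.6]}
      hypoxic_dilation: {7: [119.5, 3.0], 10: [119.5, 2.3], 13: [126.8, 3.2], 17: [123.0, 4.0]}
      stiffness_beta: {7: [3.2, 0.2], 10: [3.5, 0.3], 13: [4.2, 0.2], 17: [4.8, 0.3]}
  cerebral:
    LZR:
      ach_dilation: {7: [135.2, 1.3], 10: [144.1, 0.9], 13: [151.8, 0.8], 17: [155.0, 1.4], 20: [163.0, 1.1]}
      snp_dilation: {7: [142.7, 1.2], 10: [151.4, 0.6], 13: [159.1, 1.2], 17: [158.6, 1.1], 20: [163.4, 1.1]}
      mvd: {7: [290.0, 1.9], 10: [293.0, 2.1], 13: [303.8, 1.2], 17: [313.6, 1.4], 20: [319.6, 1.0]}
      hypoxic_dilation: {7: [132.1, 1.2], 10: [140.2, 0.7], 13: [149.5, 0.9], 17: [152.6, 1.5], 20: [159.8, 0.9]}
      stiffness_beta: {7: [1.6, 0.1], 10: [1.7, 0.1], 13: [1.8, 0.1], 17: [2.0, 0.1], 20: [2.2, 0.1]}
    OZR:
      ach_dilation: {7: [122.4, 1.3], 10: [128.4, 1.0], 13: [125.1, 0.8], 17: [122.9, 1.7], 20: [119.8, 2.5]}
      snp_dilation: {7: [131.1, 1.5], 10: [135.3, 1.5], 13: [142.1, 1.3], 17: [139.8, 1.5], 20: [138.5, 2.1]}
      mvd: {7: [274.0, 3.2], 10: [270.1, 2.6], 13: [255.8, 2.6], 17: [249.1, 2.1], 20: [242.0, 1.9]}
      hypoxic_dilation: {7: [122.6, 1.6], 10: [129.1, 1.0], 13: [127.1, 0.8], 17: [123.5, 1.1], 20: [120.6, 2.4]}
      stiffness_beta: {7: [1.8, 0.1], 10: [2.1, 0.1], 13: [2.8, 0.2], 17: [4.0, 0.2], 20: [5.4, 0.1]}
    OZR_CAPTOPRIL:
      ach_dilation: {7: [137.5, 0.7], 13: [139.0, 0.7], 17: [132.5, 2.4]}
      mvd: {7: [337.3, 2.7], 13: [332.0, 1.7], 17: [310.3, 2.2]}
      stiffness_beta: {7: [2.5, 0.1], 13: [3.3, 0.1], 17: [4.7, 0.1]}

# Baseline plasma/body variables by group and age: [mean, se].
biomarkers:
  LZR:
    mass_g: {7: [149.7, 1.5], 10: [243.0, 2.1], 13: [307.2, 2.0], 17: [357.5, 1.5], 20: [374.3, 2.6]}
    insulin_ng_ml: {7: [1.0, 0.1], 10: [1.2, 0.1], 13: [1.3, 0.1], 17: [1.1, 0.1], 20: [1.5, 0.1]}
    glucose_mg_dl: {7: [93.7, 1.1], 10: [98.4, 1.1], 13: [100.9, 1.1], 17: [100.2, 1.4], 20: [104.7, 2.0]}
    ntyr_ng_dl: {7: [9.2, 0.3], 10: [10.4, 0.3], 13: [12.8, 0.3], 17: [16.5, 0.6], 20: [18.2, 1.0]}
    tnfa_pg_ml: {7: [1.7, 0.1], 10: [2.0, 0.1], 13: [2.4, 0.2], 17: [2.2, 0.1], 20: [2.6, 0.2]}
  OZR:
    mass_g: {7: [233.9, 1.8], 10: [409.4, 2.6], 13: [512.3, 3.2], 17: [682.3, 2.5], 20: [741.8, 11.0]}
    insulin_ng_ml: {7: [3.5, 0.1], 10: [5.0, 0.1], 13: [7.6, 0.2], 17: [7.8, 0.1], 20: [10.8, 0.6]}
    glucose_mg_dl: {7: [99.7, 1.4], 10: [118.6, 3.4], 13: [138.6, 2.7], 17: [179.1, 1.2], 20: [182.6, 2.7]}
    ntyr_ng_dl: {7: [15.0, 0.4], 10: [24.8, 0.4], 13: [45.4, 1.1], 17: [51.7, 0.9], 20: [59.6, 1.0]}
    tnfa_pg_ml: {7: [4.5, 0.2], 10: [8.6, 0.3], 13: [10.9, 0.2], 17: [8.1, 0.3], 20: [13.3, 0.4]}
  OZR_EXERCISE:
    mass_g: {7: [187.3, 27.2], 10: [291.3, 29.7], 13: [359.3, 41.1], 17: [441.0, 53.3]}
    insulin_ng_ml: {7: [1.7, 0.4], 10: [2.4, 0.8], 13: [3.6, 1.5], 17: [4.3, 1.9]}
    glucose_mg_dl: {7: [93.5, 5.4], 10: [94.0, 5.0], 13: [105.0, 6.6], 17: [119.0, 12.1]}
    ntyr_ng_dl: {7: [10.3, 0.7], 10: [11.8, 1.3], 13: [19.0, 4.7], 17: [20.5, 6.3]}
    tnfa_pg_ml: {7: [1.8, 0.3], 10: [2.8, 0.8], 13: [3.3, 1.0], 17: [3.5, 1.2]}
  OZR_CAPTOPRIL:
    mass_g: {7: [239.0, 2.7], 10: [409.0, 4.5], 13: [515.3, 4.6], 17: [624.3, 8.6]}
    insulin_ng_ml: {7: [3.5, 0.2], 10: [3.7, 0.3], 13: [5.4, 0.3], 17: [6.7, 0.2]}
    glucose_mg_dl: {7: [99.0, 3.5], 10: [100.0, 2.5], 13: [123.5, 2.5], 17: [137.5, 5.3]}
    ntyr_ng_dl: {7: [13.0, 0.6], 10: [16.0, 0.7], 13: [24.5, 0.3], 17: [34.0, 0.9]}
    tnfa_pg_ml: {7: [3.5, 0.3], 10: [6.5, 0.7], 13: [7.0, 0.9], 17: [9.5, 0.7]}

# Latent-severity coupling: per-group coefficient in [0,1] linking one
# standard-normal severity draw per animal to component deviations (worse
# with higher severity) and to insulin/TNF-alpha (higher with higher
# severity).  Zero in lean controls: their biomarkers carry no vascular
# signal.  Moderate default in diseased/treated groups; an assumption, the
# within-animal covariance is not published.
coupling:
  component:
    LZR: 0.0
    OZR: 0.6
    OZR_EXERCISE: 0.6
    OZR_CAPTOPRIL: 0.6
  biomarker:
    LZR: 0.0
    OZR: 0.6
    OZR_EXERCISE: 0.6
    OZR_CAPTOPRIL: 0.6
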