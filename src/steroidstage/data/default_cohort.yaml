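n_per_class:
  control: 106
  F0: 13
  F1: 13
  F2: 13
  F3: 41
  F4: 41
  alcohol_cirrhosis: 48
panel:
- androsterone
- etiocholanolone
- dehydroepiandrosterone
- androstenedione
- 11b_hydroxyetiocholanolone
- 11_oxoetiocholanolone
- pregnanediol
- pregnanetriol
- pregnenediol
- pregnenetriol
- cortisol
- 6b_hydroxycortisol
- cortisone
- tetrahydrocortisol
- 5a_tetrahydrocortisol
- tetrahydrocortisone
- a_cortol
- b_cortol
- a_cortolone
- b_cortolone
- tetrahydrocorticosterone
- 5a_tetrahydrocorticosterone
- tetrahydro_11_dehydrocorticosterone
- 5a_tetrahydro_11_dehydrocorticosterone
- tetrahydro_11_deoxycorticosterone
- tetrahydroaldosterone
- steroid_27
- steroid_28
- steroid_29
- steroid_30
- steroid_31
- steroid_32
informative_features:
  F0,F1,F2:F3,F4:
  - - etiocholanolone
    - 1.0
  - - dehydroepiandrosterone
    - 0.9666666667
  - - 5a_tetrahydro_11_dehydrocorticosterone
    - 0.9333333333
  - - androstenedione
    - 0.9
  - - 5a_tetrahydrocorticosterone
    - 0.8666666667
  - - pregnenetriol
    - 0.8333333333
  - - tetrahydro_11_deoxycorticosterone
    - 0.8
  - - tetrahydroaldosterone
    - 0.7666666667
  - - cortisone
    - 0.7333333333
  - - 11_oxoetiocholanolone
    - 0.7
  F0,F1,F2,F3:F4:
  - - etiocholanolone
    - 0.8
  - - tetrahydrocorticosterone
    - 0.7733333333
  - - 5a_tetrahydro_11_dehydrocorticosterone
    - 0.7466666667
  - - tetrahydro_11_deoxycorticosterone
    - 0.72
  - - dehydroepiandrosterone
    - 0.6933333333
  - - androsterone
    - 0.6666666667
  - - tetrahydrocortisone
    - 0.64
  - - tetrahydrocortisol
    - 0.6133333333
  - - pregnenetriol
    - 0.5866666667
  - - 5a_tetrahydrocorticosterone
    - 0.56
  control:F3,F4:
  - - 5a_tetrahydro_11_dehydrocorticosterone
    - 0.6
  - - 11_oxoetiocholanolone
    - 0.58
  - - etiocholanolone
    - 0.56
  - - cortisone
    - 0.54
  - - pregnenediol
    - 0.52
  - - pregnanetriol
    - 0.5
  - - tetrahydro_11_deoxycorticosterone
    - 0.48
  - - 11b_hydroxyetiocholanolone
    - 0.46
  - - pregnanediol
    - 0.44
  - - 5a_tetrahydrocorticosterone
    - 0.42
  control:F4:
  - - 5a_tetrahydro_11_dehydrocorticosterone
    - 0.6
  - - 11_oxoetiocholanolone
    - 0.58
  - - etiocholanolone
    - 0.56
  - - cortisone
    - 0.54
  - - tetrahydro_11_deoxycorticosterone
    - 0.52
  - - pregnenediol
    - 0.5
  - - pregnanetriol
    - 0.48
  - - tetrahydrocorticosterone
    - 0.46
  - - pregnanediol
    - 0.44
  - - 5a_tetrahydrocorticosterone
    - 0.42
  control:F0,F1,F2,F3,F4:
  - - 5a_tetrahydrocortisol
    - 0.6
  - - tetrahydrocortisol
    - 0.5
  - - etiocholanolone
    - 0.5
  - - androsterone
    - 0.4
  - - 5a_tetrahydrocorticosterone
    - 0.4
  F4:alcohol_cirrhosis:
  - - etiocholanolone
    - 0.9
  - - androsterone
    - 0.8
  - - tetrahydrocortisol
    - 0.7
  - - pregnanediol
    - 0.6
  - - dehydroepiandrosterone
    - 0.5
covariate_params:
  control:
    age:
    - 55.5
    - 11.1
    bmi:
    - 30.7
    - 5.8
    t2d_prevalence: 0.038
    male_fraction: 0.387
    ast:
    - 22.0
    - 6.0
    alt:
    - 13.2
    - 8.7
    platelets:
    - 250.0
    - 60.0
    albumin:
    - 4.4
    - 0.3
    hba1c:
    - 38.6
    - 10.4
    nas: null
  F0:
    age:
    - 45.6
    - 12.0
    bmi:
    - 38.5
    - 7.0
    t2d_prevalence: 0.308
    male_fraction: 0.513
    ast:
    - 34.4
    - 22.0
    alt:
    - 63.4
    - 51.4
    platelets:
    - 242.5
    - 64.2
    albumin:
    - 4.3
    - 0.35
    hba1c:
    - 40.8
    - 8.2
    nas:
    - 4.0
    - 1.7
  F1:
    age:
    - 45.6
    - 12.0
    bmi:
    - 38.5
    - 7.0
    t2d_prevalence: 0.308
    male_fraction: 0.513
    ast:
    - 34.4
    - 22.0
    alt:
    - 63.4
    - 51.4
    platelets:
    - 242.5
    - 64.2
    albumin:
    - 4.3
    - 0.35
    hba1c:
    - 40.8
    - 8.2
    nas:
    - 4.0
    - 1.7
  F2:
    age:
    - 45.6
    - 12.0
    bmi:
    - 38.5
    - 7.0
    t2d_prevalence: 0.308
    male_fraction: 0.513
    ast:
    - 34.4
    - 22.0
    alt:
    - 63.4
    - 51.4
    platelets:
    - 242.5
    - 64.2
    albumin:
    - 4.3
    - 0.35
    hba1c:
    - 40.8
    - 8.2
    nas:
    - 4.0
    - 1.7
  F3:
    age:
    - 61.8
    - 10.8
    bmi:
    - 33.7
    - 5.8
    t2d_prevalence: 0.634
    male_fraction: 0.476
    ast:
    - 49.1
    - 31.8
    alt:
    - 49.9
    - 36.9
    platelets:
    - 183.9
    - 67.0
    albumin:
    - 3.9
    - 0.45
    hba1c:
    - 50.0
    - 13.5
    nas:
    - 4.7
    - 1.3
  F4:
    age:
    - 61.8
    - 10.8
    bmi:
    - 33.7
    - 5.8
    t2d_prevalence: 0.634
    male_fraction: 0.476
    ast:
    - 49.1
    - 31.8
    alt:
    - 49.9
    - 36.9
    platelets:
    - 183.9
    - 67.0
    albumin:
    - 3.9
    - 0.45
    hba1c:
    - 50.0
    - 13.5
    nas:
    - 4.7
    - 1.3
  alcohol_cirrhosis:
    age:
    - 58.0
    - 11.0
    bmi:
    - 28.0
    - 5.0
    t2d_prevalence: 0.25
    male_fraction: 0.65
    ast:
    - 55.0
    - 30.0
    alt:
    - 40.0
    - 25.0
    platelets:
    - 150.0
    - 60.0
    albumin:
    - 3.6
    - 0.5
    hba1c:
    - 40.0
    - 9.0
    nas: null
baseline_log10: {}
creatinine_log10_params:
- 2.0
- 0.25
noise_sd: 0.35
detection_floor_ug_l: 1.0
seed: 0
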