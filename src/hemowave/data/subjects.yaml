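# Default male adult presets with normal physiology, by age.
# Units: height cm, weight kg, bsa m2, hr 1/min, blood_volume ml,
# contractility/stiffness mmHg/ml, resistances mmHg*s/ml,
# venous_compliance ml/mmHg, youngs_modulus mmHg.
version: 1
subjects:
  "20":
    age: 20
    height: 170
    weight: 60
    bsa: 1.683
    hr: 74
    blood_volume: 4767
    lv_contractility: 3.02
    lv_stiffness: 0.032
    rv_contractility: 0.77
    rv_stiffness: 0.016
    svr: 1.28
    pvr: 0.141
    venous_compliance: 173
    sys_art_stiffness: 0.44
    pulm_art_stiffness: 0.24
    youngs_modulus: 1.694
  "40":
    age: 40
    height: 170
    weight: 75
    bsa: 1.882
    hr: 71
    blood_volume: 5958
    lv_contractility: 2.71
    lv_stiffness: 0.029
    rv_contractility: 0.67
    rv_stiffness: 0.014
    svr: 1.13
    pvr: 0.121
    venous_compliance: 140
    sys_art_stiffness: 0.57
    pulm_art_stiffness: 0.30
    youngs_modulus: 2.361
  "60":
    age: 60
    height: 170
    weight: 80
    bsa: 1.944
    hr: 65
    blood_volume: 6355
    lv_contractility: 2.62
    lv_stiffness: 0.028
    rv_contractility: 0.65
    rv_stiffness: 0.014
    svr: 1.09
    pvr: 0.116
    venous_compliance: 106
    sys_art_stiffness: 0.76
    pulm_art_stiffness: 0.41
    youngs_modulus: 3.250
  "80":
    age: 80
    height: 170
    weight: 70
    bsa: 1.818
    hr: 72
    blood_volume: 5561
    lv_contractility: 2.80
    lv_stiffness: 0.030
    rv_contractility: 0.70
    rv_stiffness: 0.015
    svr: 1.18
    pvr: 0.127
    venous_compliance: 73
    sys_art_stiffness: 1.07
    pulm_art_stiffness: 0.58
    youngs_modulus: 4.361
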