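{
  "name": "vonoprazan",
  "smiles": "CNCc1cc(-c2ccccc2F)n(S(=O)(=O)c2cccnc2)c1",
  "fup": 0.13418,
  "bpr": 0.80581,
  "gi_ka_1_h": 1.51647,
  "clapp_L_h": 11.58736,
  "vss_L_kg": 3.497,
  "fa": 0.886,
  "fa_provenance": "baseline fraction absorbed back-computed from the AUC identity fa = AUC(0-inf) * clapp / dose using the published calibrated AUC and clearance; halved by the calibration preset",
  "molecular_weight": 345.39,
  "kp": {
    "bone": 3.28785,
    "brain": 90.15343,
    "adipose": 29.91066,
    "heart": 13.85107,
    "kidney": 20.40353,
    "gut": 14.27052,
    "liver": 13.84071,
    "lung": 6.48797,
    "muscle": 7.44037,
    "skin": 56.12225,
    "spleen": 7.81823
  },
  "kp_scaler": null,
  "published_kp_scaler": 0.3012
}
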