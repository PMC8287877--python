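{
  "age_group": "P13",
  "conditions": ["S", "EW4", "EW15", "Rec"],
  "n_mice": {"S": 4, "EW4": 3, "EW15": 4, "Rec": 3},
  "n_dendrites_per_mouse": 14,
  "asi_model": {
    "reference": "EW15",
    "intercept": -2.1445,
    "diameter_slope": 0.1656,
    "condition_effects": {"EW15": 0.0, "EW4": 0.3666, "S": 0.2317, "Rec": -0.1179},
    "endosome_effect": null,
    "endosome_interaction": null,
    "sd_mouse": 0.0273,
    "sd_dendrite": 0.1025,
    "sd_residual": 0.8974
  },
  "density_model": {
    "reference": "EW15",
    "intercept": 0.6077,
    "condition_effects": {"EW15": 0.0, "EW4": -0.1032, "S": -0.0559, "Rec": -0.0344},
    "sd_mouse": 0.0380,
    "sd_residual": 0.1217
  },
  "diameter_um": {
    "S": {"mean": 0.92, "sd": 0.33},
    "EW4": {"mean": 0.94, "sd": 0.35},
    "EW15": {"mean": 0.90, "sd": 0.24},
    "Rec": {"mean": 1.00, "sd": 0.30}
  },
  "diameter_range_um": [0.44, 2.24],
  "length_um": {
    "S": {"mean": 23.4, "sd": 8.5},
    "EW4": {"mean": 26.3, "sd": 7.1},
    "EW15": {"mean": 26.7, "sd": 8.7},
    "Rec": {"mean": 25.0, "sd": 5.7}
  },
  "length_range_um": [5.0, 60.0],
  "frac_without_synapse": {"S": 0.220, "EW4": 0.263, "EW15": 0.218, "Rec": 0.226},
  "endosome_prob": {"S": 0.701, "EW4": 0.746, "EW15": 0.726, "Rec": 0.660},
  "spine_apparatus_prob": {"S": 0.074, "EW4": 0.072, "EW15": 0.054, "Rec": 0.094},
  "endosome_log_volume": {
    "mean": {"S": -5.20, "EW4": -5.05, "EW15": -5.30, "Rec": -5.35},
    "sd": 0.9
  },
  "sa_log_volume": {
    "mean": {"S": -4.6, "EW4": -4.6, "EW15": -4.6, "Rec": -4.6},
    "sd": 0.8
  },
  "oblique_fraction": 0.0,
  "thickness_um": 0.045,
  "study_n_mice": {"S": 4, "EW4": 3, "EW15": 4, "Rec": 3},
  "study_spine_totals": {"S": 1066, "EW4": 912, "EW15": 1398, "Rec": 842},
  "notes": "P13 pup configuration. The log-ASI and sqrt-density mixed-model blocks transcribe the published model-parameter table (EW15 reference); diameter/length moments, synapse and organelle percentages and study sizes transcribe the published descriptive table and results text. Endosome and spine-apparatus log-volume blocks are plausible synthetic defaults (only their hierarchical structure is analysed, not their absolute level)."
}
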