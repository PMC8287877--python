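{
  "age_group": "P30",
  "conditions": ["S", "SW", "EW", "CSR"],
  "n_mice": {"S": 4, "SW": 4, "EW": 4, "CSR": 3},
  "n_dendrites_per_mouse": 9,
  "asi_model": {
    "reference": "CSR",
    "intercept": -1.9129,
    "diameter_slope": 0.1818,
    "condition_effects": {"CSR": 0.0, "EW": -0.0902, "SW": -0.1751, "S": -0.1166},
    "endosome_effect": 0.1985,
    "endosome_interaction": {"CSR": 0.0, "EW": 0.0781, "SW": 0.2596, "S": -0.1284},
    "sd_mouse": 0.0705,
    "sd_dendrite": 0.0792,
    "sd_residual": 0.9470
  },
  "density_model": {
    "reference": "CSR",
    "intercept": 0.845077,
    "condition_effects": {"CSR": 0.0, "S": -0.017940, "SW": -0.036278, "EW": 0.0},
    "sd_mouse": 0.0380,
    "sd_residual": 0.1200
  },
  "diameter_um": {
    "S": {"mean": 0.87, "sd": 0.23},
    "SW": {"mean": 0.92, "sd": 0.24},
    "EW": {"mean": 0.84, "sd": 0.22},
    "CSR": {"mean": 0.78, "sd": 0.18}
  },
  "diameter_range_um": [0.54, 1.74],
  "length_um": {
    "S": {"mean": 21.9, "sd": 7.0},
    "SW": {"mean": 26.2, "sd": 4.7},
    "EW": {"mean": 22.8, "sd": 5.9},
    "CSR": {"mean": 19.3, "sd": 5.1}
  },
  "length_range_um": [5.0, 60.0],
  "frac_without_synapse": {"S": 0.160, "SW": 0.127, "EW": 0.119, "CSR": 0.174},
  "endosome_prob": {"S": 0.497, "SW": 0.563, "EW": 0.612, "CSR": 0.544},
  "spine_apparatus_prob": {"S": 0.261, "SW": 0.305, "EW": 0.271, "CSR": 0.302},
  "endosome_log_volume": {
    "mean": {"S": -5.2, "SW": -5.2, "EW": -5.2, "CSR": -5.2},
    "sd": 0.9
  },
  "sa_log_volume": {
    "mean": {"S": -4.6, "SW": -4.6, "EW": -4.6, "CSR": -4.6},
    "sd": 0.8
  },
  "oblique_fraction": 0.0,
  "thickness_um": 0.045,
  "study_n_mice": {"S": 4, "SW": 4, "EW": 4, "CSR": 3},
  "study_spine_totals": {"S": 1367, "SW": 1347, "EW": 1167, "CSR": 905},
  "notes": "P30 adolescent configuration. The log-ASI mixed-model block (CSR reference, endosome main effect and condition-by-endosome interaction) transcribes the published model-parameter table; diameter/length moments, percentages and study sizes transcribe the published descriptive table and results text. No published sqrt-density model exists at P30: the density block is moment-matched to the descriptive synapse-density means (mean = mu^2 + sd_mouse^2 + sd_residual^2) with pup-like variance components. Log-volume blocks are plausible synthetic defaults."
}
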