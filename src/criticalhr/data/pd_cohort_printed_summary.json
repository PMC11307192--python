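{
  "comment": "Group summary cells as printed in the source publication's participant-characteristics table, kept as strings to preserve the printed precision. 'discrepant_cells' lists printed cells that do NOT equal the mean / sample SD (n-1) of the printed individual rows under round-half-up at the printed precision; they are preserved as printed, never forced. Several discrepant SD cells instead match truncation toward zero, suggesting a mixed rounding convention in the source; the two Experiment-2 TMT means match neither convention.",
  "printed": {
    "experiment1_all": {
      "age_years": {"mean": "71.93", "sd": "6.87"},
      "height_m": {"mean": "1.60", "sd": "0.10"},
      "mass_kg": {"mean": "66.6", "sd": "16.6"},
      "updrs2": {"mean": "10.6", "sd": "3.2"},
      "updrs3": {"mean": "30.6", "sd": "9.4"},
      "hy": {"mean": "2.1", "sd": "0.3"},
      "mmse": {"mean": "27.1", "sd": "2.4"},
      "tmt_a_s": {"mean": "67.84", "sd": "48.26"},
      "tmt_b_s": {"mean": "153.29", "sd": "46.80"},
      "tug_s": {"mean": "6.90", "sd": "1.57"}
    },
    "experiment2_subset": {
      "age_years": {"mean": "70.00", "sd": "7.27"},
      "height_m": {"mean": "1.63", "sd": "0.09"},
      "mass_kg": {"mean": "71.03", "sd": "15.04"},
      "updrs2": {"mean": "11.00", "sd": "3.34"},
      "updrs3": {"mean": "29.00", "sd": "8.72"},
      "hy": {"mean": "2", "sd": "0.3"},
      "mmse": {"mean": "27.00", "sd": "1.85"},
      "tmt_a_s": {"mean": "45.82", "sd": "20.75"},
      "tmt_b_s": {"mean": "149.56", "sd": "59.80"},
      "tug_s": {"mean": "6.42", "sd": "1.20"}
    }
  },
  "discrepant_cells": [
    "experiment1_all.mass_kg.mean",
    "experiment1_all.mass_kg.sd",
    "experiment1_all.updrs2.mean",
    "experiment1_all.updrs2.sd",
    "experiment1_all.updrs3.sd",
    "experiment2_subset.mass_kg.sd",
    "experiment2_subset.tmt_a_s.mean",
    "experiment2_subset.tmt_b_s.mean"
  ]
}
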