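{
  "description": "Printed per-cell values of the study's Tables 1-3, stored verbatim at printed precision.",
  "table1": {
    "n": 20,
    "angle_range_deg": [0, 19],
    "apsdp": {
      "x_error_mm": [0.58, 0.14],
      "y_error_mm": [0.62, 0.16],
      "z_error_mm": [0.58, 0.17],
      "total_error_mm": [1.04, 0.19],
      "angle_error_deg": [0.28, 0.15],
      "time_min": [23.15, 2.52]
    },
    "tpm": {
      "x_error_mm": [1.38, 0.15],
      "y_error_mm": [1.53, 0.16],
      "z_error_mm": [1.50, 0.18],
      "total_error_mm": [2.55, 0.21],
      "angle_error_deg": [0.29, 0.16],
      "time_min": [40.35, 2.99]
    },
    "p": {
      "angle_range": 1.000,
      "x_error": 0.001,
      "y_error": 0.001,
      "z_error": 0.001,
      "total_error": 0.001,
      "angle_error": 0.844,
      "time": 0.001
    }
  },
  "table2": {
    "n": 5,
    "seeds_per_case": 6,
    "deviations_mm": {
      "1": [0.72, 0.71, 0.77, 0.80, 0.53, 0.69],
      "2": [0.93, 0.82, 0.78, 0.68, 0.83, 0.64],
      "3": [0.67, 0.54, 0.91, 0.71, 0.75, 1.37],
      "4": [0.79, 0.82, 0.86, 0.72, 0.43, 1.01],
      "5": [0.71, 0.73, 0.39, 0.68, 0.93, 0.60]
    },
    "ave_d_mm": {
      "1": [0.70, 0.09],
      "2": [0.78, 0.11],
      "3": [0.82, 0.29],
      "4": [0.77, 0.19],
      "5": [0.67, 0.18]
    },
    "mean_d_mm": [0.75, 0.06],
    "d100_pct": {"1": 95, "2": 95, "3": 97, "4": 96, "5": 96}
  },
  "table3": {
    "n": 5,
    "ci_pre": [0.95, 0.97, 0.95, 0.98, 0.95],
    "ci_post": [0.94, 0.94, 0.95, 0.97, 0.96],
    "hi_pre": [3.62, 3.43, 3.48, 3.59, 3.78],
    "hi_post": [3.38, 3.25, 3.55, 3.46, 3.42],
    "dvh_pct_pre": {
      "d100": [95, 95, 97, 96, 96],
      "d90": [108, 108, 112, 108, 111],
      "v100": [95, 95, 96, 95, 96],
      "v90": [95, 96, 96, 95, 96]
    },
    "dvh_pct_post": {
      "d100": [93, 94, 94, 94, 93],
      "d90": [104, 101, 103, 100, 104],
      "v100": [92, 92, 92, 93, 94],
      "v90": [93, 94, 93, 93, 93]
    },
    "ave_printed": {
      "ci_pre": [0.960, 0.014],
      "ci_post": [0.952, 0.013],
      "hi_pre": [3.580, 0.136],
      "hi_post": [3.412, 0.110],
      "d100": [96, 94],
      "d90": [109, 102],
      "v100": [95, 93],
      "v90": [96, 93]
    },
    "p_printed": {
      "ci": 0.380,
      "hi": 0.230,
      "d100": 0.359,
      "d90": 0.204,
      "v100": 0.435,
      "v90": 0.458
    }
  },
  "seed": {
    "activity_mci": 0.7,
    "activity_bq": 2.59e7,
    "rod_length_mm": 3.0,
    "rod_diameter_mm": 0.5,
    "capsule_thickness_mm": 0.05
  }
}
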