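{
  "continuous": [
    {"name": "age", "cure": [54.5, 46.0, 65.0], "improved": [55.0, 41.0, 67.0], "poor": [58.5, 47.0, 73.0], "direction": "null"},
    {"name": "temperature", "cure": [36.5, 36.4, 36.8], "improved": [36.7, 36.5, 36.9], "poor": [36.6, 36.5, 36.8], "direction": "null"},
    {"name": "heart_rate", "cure": [85.0, 75.5, 90.0], "improved": [87.5, 75.0, 102.0], "poor": [100.0, 78.0, 119.0], "direction": "risk"},
    {"name": "respiratory_rate", "cure": [19.0, 18.0, 20.0], "improved": [20.0, 17.0, 22.0], "poor": [19.0, 16.0, 24.0], "direction": "null"},
    {"name": "systolic_bp", "cure": [127.5, 115.5, 144.5], "improved": [127.5, 112.0, 144.0], "poor": [125.0, 98.0, 144.0], "direction": "null"},
    {"name": "diastolic_bp", "cure": [80.0, 71.5, 89.0], "improved": [75.0, 65.0, 84.0], "poor": [72.0, 57.0, 85.0], "direction": "protective"},
    {"name": "hemoglobin", "cure": [121.5, 108.0, 136.0], "improved": [123.0, 102.0, 135.0], "poor": [103.0, 81.0, 124.0], "direction": "protective"},
    {"name": "prothrombin_time", "cure": [18.5, 7.0, 36.5], "improved": [22.0, 11.0, 45.0], "poor": [24.0, 10.0, 59.0], "direction": "null"},
    {"name": "inr", "cure": [21.0, 8.5, 38.5], "improved": [22.0, 8.0, 35.0], "poor": [22.5, 9.0, 52.0], "direction": "null"},
    {"name": "aptt", "cure": [49.5, 33.0, 84.0], "improved": [54.5, 25.0, 84.0], "poor": [53.5, 19.0, 105.0], "direction": "null"},
    {"name": "thrombin_time", "cure": [28.0, 13.5, 45.0], "improved": [29.5, 12.0, 49.0], "poor": [23.0, 10.0, 58.0], "direction": "null"},
    {"name": "fibrinogen", "cure": [86.0, 46.0, 123.5], "improved": [72.0, 38.0, 127.0], "poor": [81.0, 29.0, 113.0], "direction": "null"},
    {"name": "total_bilirubin", "cure": [14.4, 9.8, 20.0], "improved": [13.4, 9.4, 18.1], "poor": [11.9, 8.5, 16.1], "direction": "null"},
    {"name": "direct_bilirubin", "cure": [5.7, 3.9, 8.2], "improved": [5.2, 3.8, 6.8], "poor": [5.3, 3.4, 6.7], "direction": "null"},
    {"name": "indirect_bilirubin", "cure": [8.1, 6.0, 12.0], "improved": [7.9, 6.1, 11.1], "poor": [7.2, 5.8, 9.2], "direction": "null"},
    {"name": "total_protein", "cure": [59.8, 55.2, 64.8], "improved": [59.7, 52.9, 65.3], "poor": [56.6, 47.5, 63.0], "direction": "protective"},
    {"name": "albumin", "cure": [38.1, 35.0, 41.0], "improved": [38.0, 35.1, 41.8], "poor": [34.8, 29.3, 40.0], "direction": "protective"},
    {"name": "globulin", "cure": [21.6, 18.2, 24.8], "improved": [21.3, 18.1, 24.3], "poor": [19.5, 16.7, 23.5], "direction": "null"},
    {"name": "ag_ratio", "cure": [1.8, 1.5, 2.1], "improved": [1.8, 1.6, 2.1], "poor": [1.7, 1.4, 2.0], "direction": "null"},
    {"name": "alt", "cure": [27.3, 18.3, 52.4], "improved": [26.1, 16.3, 56.6], "poor": [30.1, 18.4, 65.5], "direction": "null"},
    {"name": "ast", "cure": [32.1, 21.9, 56.0], "improved": [34.4, 25.1, 61.3], "poor": [51.0, 31.5, 90.5], "direction": "risk"},
    {"name": "ast_alt_ratio", "cure": [1.3, 1.0, 1.6], "improved": [1.4, 1.1, 1.8], "poor": [1.5, 1.2, 2.1], "direction": "risk"},
    {"name": "alp", "cure": [62.0, 50.5, 78.0], "improved": [61.5, 50.3, 80.0], "poor": [63.5, 46.0, 81.0], "direction": "null"},
    {"name": "total_bile_acids", "cure": [2.7, 1.3, 5.4], "improved": [2.4, 1.1, 4.6], "poor": [2.4, 0.8, 4.4], "direction": "null"},
    {"name": "prealbumin", "cure": [250.0, 203.0, 294.0], "improved": [262.5, 204.0, 294.0], "poor": [226.0, 134.0, 263.0], "direction": "protective"},
    {"name": "afu", "cure": [21.8, 18.3, 25.9], "improved": [22.8, 18.6, 25.7], "poor": [25.7, 17.5, 25.7], "direction": "null"},
    {"name": "ada", "cure": [7.0, 5.0, 10.4], "improved": [7.0, 5.0, 10.0], "poor": [5.0, 5.0, 7.6], "direction": "protective"},
    {"name": "cholinesterase", "cure": [6162.0, 4973.0, 7489.0], "improved": [5948.0, 4569.0, 7559.0], "poor": [5305.0, 4569.0, 6507.0], "direction": "protective"},
    {"name": "mito_ast", "cure": [15.4, 9.7, 24.3], "improved": [14.3, 9.8, 24.3], "poor": [16.7, 9.5, 26.6], "direction": "null"},
    {"name": "urea", "cure": [6.0, 4.8, 7.3], "improved": [5.6, 4.5, 7.1], "poor": [6.2, 4.9, 8.0], "direction": "null"},
    {"name": "creatinine", "cure": [65.0, 57.1, 77.5], "improved": [59.9, 50.0, 78.3], "poor": [75.7, 54.3, 104.3], "direction": "risk"}
  ],
  "count": [
    {"name": "transfusion_count", "rates": {"cure": 0.5, "improved": 0.8, "poor": 1.3}, "direction": "null"},
    {"name": "rescue_count", "rates": {"cure": 0.1, "improved": 0.15, "poor": 1.2}, "direction": "risk"}
  ],
  "categorical": [
    {"name": "headache", "levels": ["no", "yes", "coma"], "counts": {"cure": [49, 49, 10], "improved": [29, 68, 33], "poor": [4, 18, 32]}, "direction": "risk"},
    {"name": "vomiting", "levels": ["no", "yes"], "counts": {"cure": [88, 20], "improved": [79, 51], "poor": [28, 26]}, "direction": "risk"},
    {"name": "meningeal_irritation", "levels": ["no", "yes"], "counts": {"cure": [104, 4], "improved": [120, 10], "poor": [51, 3]}, "direction": "null"},
    {"name": "open_airway", "levels": ["no", "yes"], "counts": {"cure": [97, 11], "improved": [97, 33], "poor": [19, 35]}, "direction": "risk"},
    {"name": "cranial_pressure_reduction", "levels": ["no", "yes"], "counts": {"cure": [106, 2], "improved": [122, 8], "poor": [47, 7]}, "direction": "risk"},
    {"name": "infection_prevention", "levels": ["no", "yes"], "counts": {"cure": [90, 18], "improved": [108, 22], "poor": [50, 4]}, "direction": "null"},
    {"name": "antishock_therapy", "levels": ["no", "yes"], "counts": {"cure": [91, 17], "improved": [106, 24], "poor": [40, 14]}, "direction": "null"},
    {"name": "gender", "levels": ["female", "male"], "counts": {"cure": [21, 87], "improved": [44, 86], "poor": [15, 39]}, "direction": "null"},
    {"name": "injury_type", "levels": ["traffic", "fall", "other"], "counts": {"cure": [47, 40, 21], "improved": [67, 51, 12], "poor": [26, 22, 6]}, "direction": "null"},
    {"name": "surgery", "levels": ["no", "yes"], "counts": {"cure": [22, 86], "improved": [42, 88], "poor": [26, 28]}, "direction": "null"}
  ]
}
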