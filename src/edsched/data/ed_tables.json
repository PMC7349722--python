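{
  "version": 1,
  "treatments": {
    "A": {"description": "Triage", "dist": {"kind": "exponential", "mean": 7.0}, "resource_group": "doctor"},
    "B": {"description": "Registration", "dist": {"kind": "exponential", "mean": 5.5}, "resource_group": "nurse"},
    "C": {"description": "Evaluation", "dist": {"kind": "normal", "mean": 14.0, "sd": 6.0}, "resource_group": "doctor"},
    "D": {"description": "Laboratory", "dist": {"kind": "normal", "mean": 35.0, "sd": 15.0}, "resource_group": "nurse", "capacity_exempt": true},
    "E": {"description": "X-ray", "dist": {"kind": "exponential", "mean": 12.0}, "resource_group": "xray"},
    "F": {"description": "Consultation", "dist": {"kind": "normal", "mean": 15.0, "sd": 8.0}, "resource_group": "nurse"},
    "G": {"description": "CT scan", "dist": {"kind": "normal", "mean": 29.0, "sd": 14.0}, "resource_group": "ct"},
    "H": {"description": "Discharge", "dist": {"kind": "constant", "value": 30.0}, "resource_group": "nurse"},
    "I": {"description": "Discharge (admission)", "dist": {"kind": "exponential", "mean": 3.0}, "resource_group": "nurse"}
  },
  "patterns": {
    "1": ["A", "B", "C", "H"],
    "2": ["A", "B", "C", "E", "H"],
    "3": ["A", "B", "C", "D", "E", "H"],
    "4": ["A", "B", "C", "F", "H"],
    "5": ["A", "B", "C", "D", "E", "F", "H"],
    "6": ["A", "B", "C", "D", "H"],
    "7": ["A", "B", "C", "E", "D", "H"],
    "8": ["A", "B", "C", "G", "H"],
    "9": ["A", "B", "C", "G", "E", "F", "I"],
    "10": ["A", "B", "C", "D", "I"],
    "11": ["A", "B", "C", "E", "D", "I"]
  },
  "acuity": {
    "1": {"waiting_weight": 30.0, "weighted_acuity": 5, "occurrence_ratio": 0.10},
    "2": {"waiting_weight": 15.0, "weighted_acuity": 4, "occurrence_ratio": 0.30},
    "3": {"waiting_weight": 1.0, "weighted_acuity": 3, "occurrence_ratio": 0.40},
    "4": {"waiting_weight": 1.0, "weighted_acuity": 2, "occurrence_ratio": 0.10},
    "5": {"waiting_weight": 1.0, "weighted_acuity": 1, "occurrence_ratio": 0.10}
  },
  "resource_groups": {
    "doctor": {"capacity": 3},
    "nurse": {"capacity": 5},
    "xray": {"capacity": 1},
    "ct": {"capacity": 1}
  }
}
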