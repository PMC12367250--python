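{
  "version": 1,
  "schemas": {
    "abdomen": {
      "labels": {
        "1": "VB",
        "2": "PM",
        "3": "CM",
        "4": "sSAT",
        "5": "dSAT",
        "6": "IPAT",
        "7": "RPAT"
      },
      "merge_rules": {
        "SAT": ["sSAT", "dSAT"],
        "VAT": ["IPAT", "RPAT"]
      },
      "muscle_for_imat": "CM",
      "circumference_label": "VB"
    },
    "thigh": {
      "labels": {
        "1": "femur",
        "2": "vessel",
        "3": "SAT",
        "4": "muscle"
      },
      "merge_rules": {},
      "muscle_for_imat": "muscle",
      "circumference_label": "femur"
    }
  }
}
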