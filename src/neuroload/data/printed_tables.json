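{
  "work_performance": {
    "title": "Impact on work performance (questionnaire composite)",
    "eta_convention": "classical",
    "strict_f_sources": [],
    "sources": {
      "condition": {"ss": 0.006, "df": 1, "F": 0.255, "p": 0.620, "eta2": 0.003},
      "interaction": {"ss": 0.007, "df": 1, "F": 0.337, "p": 0.568, "eta2": 0.003},
      "within_resid": {"ss": 0.422, "df": 19},
      "group": {"ss": 0.791, "df": 1, "F": 16.030, "p": "< .001", "eta2": 0.366},
      "between_resid": {"ss": 0.937, "df": 19}
    }
  },
  "willingness_to_use": {
    "title": "Willingness to use (questionnaire composite)",
    "eta_convention": "classical",
    "strict_f_sources": ["condition"],
    "sources": {
      "condition": {"ss": 0.240, "df": 1, "F": 4.453, "p": 0.048, "eta2": 0.072},
      "interaction": {"ss": 0.035, "df": 1, "F": 0.657, "p": 0.427, "eta2": 0.011},
      "within_resid": {"ss": 1.024, "df": 19},
      "group": {"ss": 0.836, "df": 1, "F": 13.210, "p": 0.002, "eta2": 0.251},
      "between_resid": {"ss": 1.203, "df": 19}
    }
  },
  "workload": {
    "title": "Mental workload neurometric (WL)",
    "eta_convention": "classical",
    "strict_f_sources": ["condition"],
    "sources": {
      "condition": {"ss": 0.313, "df": 1, "F": 5.221, "p": 0.034, "eta2": 0.016},
      "interaction": {"ss": 3.580e-4, "df": 1, "F": 0.006, "p": 0.939, "eta2": 1.822e-5},
      "within_resid": {"ss": 1.139, "df": 19},
      "group": {"ss": 0.544, "df": 1, "F": 0.586, "p": 0.454, "eta2": 0.028},
      "between_resid": {"ss": 17.652, "df": 19}
    }
  },
  "acceptance": {
    "title": "Acceptance neurometric (approach-withdrawal, AW)",
    "eta_convention": "partial",
    "strict_f_sources": [],
    "sources": {
      "condition": {"ss": 0.138, "df": 1, "F": 3.696, "p": 0.070, "eta2": 0.163},
      "interaction": {"ss": 0.025, "df": 1, "F": 0.675, "p": 0.421, "eta2": 0.034},
      "within_resid": {"ss": 0.708, "df": 19},
      "group": {"ss": 1.798, "df": 1, "F": 3.116, "p": 0.094, "eta2": 0.141},
      "between_resid": {"ss": 10.967, "df": 19}
    }
  }
}
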