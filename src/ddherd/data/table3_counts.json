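{
  "description": "Published contingency counts of the four ddPCR HER2 groups against clinical IHC score and ISH status for the 909-tumor cohort (aggregate counts only; no patient-level data).",
  "groups": {
    "1": {"ihc_0_1": 4,   "ihc_2": 16,  "ihc_3": 197, "ish_amplified": 211, "ish_normal": 5,   "ish_missing": 1},
    "2": {"ihc_0_1": 5,   "ihc_2": 7,   "ihc_3": 2,   "ish_amplified": 4,   "ish_normal": 9,   "ish_missing": 1},
    "3": {"ihc_0_1": 3,   "ihc_2": 10,  "ihc_3": 13,  "ish_amplified": 15,  "ish_normal": 11,  "ish_missing": 0},
    "5": {"ihc_0_1": 425, "ihc_2": 203, "ihc_3": 24,  "ish_amplified": 34,  "ish_normal": 456, "ish_missing": 162}
  }
}
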