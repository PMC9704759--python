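{
  "drug": {
    "name": "examplol",
    "kind": "nonprodrug",
    "dose_mg": 10.0,
    "F": 0.6,
    "Vd": 50.0,
    "IC50": 40.0
  },
  "arms": {"awakening": 0.0, "bedtime": 15.0},
  "clock": {"awakening_clock": 8.0, "bedtime_clock": 23.0},
  "fit": {"seed": 1, "n_starts": 4},
  "scan": {"grid_step": 0.25, "target_sbp": 130.0, "target_dbp": 80.0},
  "synth": {"profile": "dipper", "se_frac": 0.02,
            "include_concentrations": true}
}
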