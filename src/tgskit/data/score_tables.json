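{
  "PWM": {
    "model_name": "PWM",
    "entries": {
      "rs4341": {"DD": 0, "ID": 1, "II": 2},
      "rs1815739": {"CC": 2, "CT": 1, "TT": 0},
      "rs671": {"GG": 2, "GA": 1, "AA": 0},
      "rs4950": {"AA": 2, "GA": 1, "GG": 0},
      "rs8111989": {"AA": 0, "GA": 1, "GG": 2},
      "rs41274853": {"CC": 0, "CT": 1, "TT": 2},
      "rs9939609": {"TT": 0, "TA": 1, "AA": 2},
      "rs558129": {"CC": 0, "CT": 1, "TT": 2},
      "rs680": {"CC": 2, "CT": 1, "TT": 0},
      "rs1049434": {"AA": 0, "TA": 1, "TT": 2},
      "rs8192678": {"AA": 2, "GA": 1, "GG": 0},
      "rs7832552": {"TT": 2, "CT": 1, "CC": 0}
    }
  },
  "WRM": {
    "model_name": "WRM",
    "entries": {
      "rs4341": {"DD": 2, "ID": 1, "II": 0},
      "rs1815739": {"CC": 2, "CT": 1, "TT": 0},
      "rs4950": {"AA": 0, "GA": 1, "GG": 2},
      "rs41274853": {"CC": 0, "CT": 1, "TT": 2},
      "rs1049434": {"AA": 0, "TA": 1, "TT": 2},
      "rs8192678": {"AA": 2, "GA": 1, "GG": 0}
    }
  }
}
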