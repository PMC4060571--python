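{
  "schema_version": 1,
  "description": "Natural angular frequency omega_n (rad/s) measured at three EAA activity levels for subject A; anchors for the piecewise-linear activity-to-stiffness map.",
  "anchors": [
    {"a_e": 0.5, "omega_n": 14.3},
    {"a_e": 0.8, "omega_n": 19.0},
    {"a_e": 1.0, "omega_n": 20.5}
  ]
}
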